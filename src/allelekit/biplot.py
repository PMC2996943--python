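"""Rank-2 allele-frequency biplot via SVD.

The frequency matrix (SNPs x samples) is row-centered and decomposed as
F = P D Q'.  A SNP-effect biplot uses rows of P and rows of QD as
coordinates; a sample-effect biplot uses rows of PD and rows of Q.  Either
pairing reconstructs the same best rank-2 approximation of F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_io import AlleleFreqMatrix, ValidationError

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # consistency factor for a normal distribution


@dataclass
class BiplotResult:
    singular_values: np.ndarray   # full spectrum, nonincreasing
    snp_coords: np.ndarray        # (R, 2)
    sample_coords: np.ndarray     # (C, 2)
    flavor: str                   # snp_effect | sample_effect
    explained: float              # rank-2 share of squared Frobenius norm
    samples: list[str]
    snp_ids: np.ndarray
    sample_magnitude: np.ndarray = None  # full-rank column norms of F
    rank_deficient: bool = False


def center_matrix(freqs: AlleleFreqMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Row-center the frequency matrix (each SNP mean-zero across samples).

    Missing entries are imputed with the SNP's cross-sample mean first, so
    they become exact zeros after centering.  SNPs masked in every sample
    are dropped with a warning.  Returns (F, kept_snp_ids, samples).
    """
    r, c = freqs.shape
    if r < 2 or c < 2:
        raise ValidationError("need at least 2 SNPs and 2 samples")
    valid = ~freqs.mask
    keep = valid.any(axis=1)
    if not keep.all():
        logger.warning("dropping %d SNPs masked in all samples", int((~keep).sum()))
    a = freqs.freq[keep]
    v = valid[keep]
    cnt = v.sum(axis=1)
    row_mean = np.where(v, a, 0.0).sum(axis=1) / cnt
    a = np.where(v, a, row_mean[:, None])
    f = a - a.mean(axis=1, keepdims=True)
    return f, freqs.annotation.snp_id[keep], list(freqs.samples)


def decompose(f: np.ndarray, flavor: str = "sample_effect",
              snp_ids: np.ndarray = None, samples: list[str] = None) -> BiplotResult:
    """Thin SVD of a centered matrix with rank-2 biplot coordinates.

    Sign convention: each left singular vector's largest-magnitude entry is
    made positive (the right vector flips with it), so outputs are
    reproducible across LAPACK backends.
    """
    if flavor not in ("snp_effect", "sample_effect"):
        raise ValidationError(f"unknown biplot flavor {flavor!r}")
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValidationError("centered matrix contains non-finite values")
    p, d, qt = np.linalg.svd(f, full_matrices=False)
    q = qt.T
    for k in range(p.shape[1]):
        i = int(np.argmax(np.abs(p[:, k])))
        if p[i, k] < 0:
            p[:, k] = -p[:, k]
            q[:, k] = -q[:, k]

    total = float((d ** 2).sum())
    tol = max(f.shape) * np.finfo(float).eps * (d[0] if len(d) else 0.0)
    rank_deficient = (d > tol).sum() < 2
    d2 = np.zeros(2)
    d2[: min(2, len(d))] = d[:2]
    p2 = p[:, :2] if p.shape[1] >= 2 else np.pad(p, ((0, 0), (0, 2 - p.shape[1])))
    q2 = q[:, :2] if q.shape[1] >= 2 else np.pad(q, ((0, 0), (0, 2 - q.shape[1])))
    if flavor == "snp_effect":
        snp_coords = p2.copy()
        sample_coords = q2 * d2
    else:
        snp_coords = p2 * d2
        sample_coords = q2.copy()
    explained = float((d2 ** 2).sum() / total) if total > 0 else 1.0
    if snp_ids is None:
        snp_ids = np.arange(f.shape[0]).astype(object)
    if samples is None:
        samples = [f"s{j}" for j in range(f.shape[1])]
    return BiplotResult(
        singular_values=d, snp_coords=snp_coords, sample_coords=sample_coords,
        flavor=flavor, explained=explained, samples=list(samples),
        snp_ids=np.asarray(snp_ids, dtype=object),
        sample_magnitude=np.sqrt(((q * d) ** 2).sum(axis=1)),
        rank_deficient=rank_deficient,
    )


def biplot(freqs: AlleleFreqMatrix, flavor: str = "sample_effect") -> BiplotResult:
    """Convenience wrapper: center then decompose an allele-frequency matrix."""
    f, snp_ids, samples = center_matrix(freqs)
    return decompose(f, flavor=flavor, snp_ids=snp_ids, samples=samples)


def detect_outliers(result: BiplotResult, alpha: float = 0.01) -> list[str]:
    """Samples whose robust 2-D distance exceeds the chi-square(2) quantile.

    Coordinates are centered on the coordinate-wise median and scaled by the
    per-axis MAD (normal-consistent); the squared distance is compared with
    the (1 - alpha) quantile of chi-square with 2 df.
    """
    coords = result.sample_coords
    if coords.shape[0] < 5:
        raise ValidationError("need >= 5 samples for outlier detection")
    med = np.median(coords, axis=0)
    mad = _MAD_SCALE * np.median(np.abs(coords - med), axis=0)
    if np.all(mad == 0):
        if np.allclose(coords, coords[0]):
            return []
        # degenerate axis spread: fall back to SD scaling
        mad = coords.std(axis=0)
        if np.all(mad == 0):
            return []
    mad = np.where(mad == 0, np.max(mad), mad)
    d2 = (((coords - med) / mad) ** 2).sum(axis=1)
    if alpha >= 1.0:
        return list(result.samples)
    threshold = stats.chi2.ppf(1.0 - alpha, df=2)
    return [s for s, v in zip(result.samples, d2) if v > threshold]


def classify_samples(result: BiplotResult, k: int, seed: int = 0,
                     features: str = "coords") -> tuple[np.ndarray, float]:
    """K-means clustering of samples (10 restarts, fixed seed).

    ``features="coords"`` clusters the rank-2 coordinates, separating groups
    that differ in allele-frequency direction (e.g. diverged populations).
    ``features="magnitude"`` clusters the full-rank column norms instead:
    groups that differ only in spread, not direction — hemizygous (male) X
    chromosomes being the canonical case — have sign-symmetric coordinates
    and are separable only by vector length.

    Returns (labels, silhouette score); silhouette is NaN when every sample
    is its own cluster.
    """
    n = result.sample_coords.shape[0]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k = {k} exceeds sample count {n}")
    if features == "coords":
        x = result.sample_coords
    elif features == "magnitude":
        if result.sample_magnitude is None:
            raise ValidationError("result carries no sample magnitudes")
        x = result.sample_magnitude.reshape(-1, 1)
    else:
        raise ValidationError(f"unknown feature set {features!r}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    if 2 <= k < n:
        sil = float(silhouette_score(x, labels))
    else:
        sil = float("nan")
    return labels, sil
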