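"""Static figures: allele-frequency bands, aberration panels, biplots.

Plotting is best-effort; callers (the CLI) catch failures and warn instead
of failing the analysis.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .aberration import WindowTrack, control_quantile  # noqa: E402
from .biplot import BiplotResult  # noqa: E402
from .core_io import AlleleFreqMatrix  # noqa: E402


def allele_frequency_plot(freqs: AlleleFreqMatrix, sample: str, path,
                          ai_flags: np.ndarray = None) -> None:
    """Per-chromosome frequency-vs-position scatter for one sample.

    With AI flags supplied, flagged SNPs are drawn in red (extended plot).
    """
    j = freqs.samples.index(sample)
    slices = freqs.annotation.chrom_slices()
    n = len(slices)
    ncol = min(n, 4)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.5 * nrow),
                             squeeze=False)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, (chrom, sl) in zip(axes.flat, slices.items()):
        pos = freqs.annotation.position[sl] / 1e6
        f = np.where(freqs.mask[sl, j], np.nan, freqs.freq[sl, j])
        if ai_flags is not None:
            flagged = ai_flags[sl, j] == 1
            ax.plot(pos[~flagged], f[~flagged], ".", ms=2, color="tab:blue")
            ax.plot(pos[flagged], f[flagged], ".", ms=2, color="tab:red")
        else:
            ax.plot(pos, f, ".", ms=2, color="tab:blue")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"chr{chrom}", fontsize=9)
        ax.set_xlabel("position (Mb)", fontsize=8)
        ax.set_ylabel("allele frequency", fontsize=8)
    fig.suptitle(f"Allele frequencies: {sample}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def aberration_plot(freqs: AlleleFreqMatrix, sample: str,
                    patient: WindowTrack, controls: list[WindowTrack],
                    chromosome: str, path, ai_flags: np.ndarray = None) -> None:
    """Three-panel plot for one chromosome: extended allele-frequency panel,
    AI-index panel and LOH-index panel, each with the control 95% quantile."""
    sl = freqs.annotation.chrom_slices()[chromosome]
    j = freqs.samples.index(sample)
    pos = freqs.annotation.position[sl] / 1e6
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)

    f = np.where(freqs.mask[sl, j], np.nan, freqs.freq[sl, j])
    if ai_flags is not None:
        flagged = ai_flags[sl, j] == 1
        axes[0].plot(pos[~flagged], f[~flagged], ".", ms=2, color="tab:blue")
        axes[0].plot(pos[flagged], f[flagged], ".", ms=2, color="tab:red")
    else:
        axes[0].plot(pos, f, ".", ms=2, color="tab:blue")
    axes[0].set_ylabel("allele frequency")
    axes[0].set_ylim(-0.05, 1.05)

    for ax, which, label in ((axes[1], "ai", "AI index"),
                             (axes[2], "loh", "LOH index")):
        raw = getattr(patient, f"{which}_index")[sl, 0]
        smooth = getattr(patient, f"{which}_smooth")
        q = control_quantile(controls, which)[sl]
        ax.plot(pos, raw, ".", ms=2, color="lightcoral", label="patient")
        ax.plot(pos, q, ".", ms=2, color="lightblue", label="control 95%")
        if smooth is not None:
            ax.plot(pos, smooth[sl, 0], "-", color="darkred", lw=1.2)
        ax.set_ylabel(label)
        ax.set_ylim(-0.05, 1.05)
        ax.legend(fontsize=7, loc="upper right")
    axes[2].set_xlabel("position (Mb)")
    fig.suptitle(f"Chromosome {chromosome} aberration scan: {sample}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def biplot_plot(result: BiplotResult, path, labels=None,
                max_snps: int = 2000) -> None:
    """Joint 2-D projection of samples (lines from origin) and SNPs (points)."""
    fig, ax = plt.subplots(figsize=(6, 6))
    snp = result.snp_coords
    if snp.shape[0] > max_snps:
        step = snp.shape[0] // max_snps
        snp = snp[::step]
    ax.plot(snp[:, 0], snp[:, 1], ".", ms=2, color="grey", alpha=0.4)
    coords = result.sample_coords
    if labels is None:
        labels = [0] * coords.shape[0]
    uniq = sorted(set(labels))
    cmap = plt.get_cmap("tab10")
    for li, lab in enumerate(uniq):
        sel = [i for i, l in enumerate(labels) if l == lab]
        for i in sel:
            ax.plot([0, coords[i, 0]], [0, coords[i, 1]],
                    "-", color=cmap(li % 10), lw=0.8, alpha=0.7)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(f"{result.flavor} biplot (explained {result.explained:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
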