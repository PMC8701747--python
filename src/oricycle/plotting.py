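"""Optional figure helpers (PNG); matplotlib is imported lazily with the
Agg backend so headless runs never touch a display."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_vplot(vplot, path, log: bool = True) -> None:
    """Fragment-size vs midpoint heatmap of a region."""
    plt = _plt()
    counts = vplot.counts.astype(float)
    if log:
        counts = np.log1p(counts)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(counts, aspect="auto", origin="lower", cmap="viridis",
              extent=[vplot.start, vplot.end, vplot.size_min, vplot.size_max])
    ax.set_xlabel(f"{vplot.chrom} position (bp)")
    ax.set_ylabel("fragment size (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_entropy_heatmap(matrix, path) -> None:
    """Distance-by-time z-scored entropy heatmap around origins."""
    plt = _plt()
    z = matrix.aggregate_z
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(z.columns)), z.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(z.index)), [f"{d/1000:.1f} kb" for d in z.index],
                  fontsize=7)
    ax.set_xlabel("time point")
    ax.set_ylabel("|distance| from origin")
    fig.colorbar(im, label="entropy (row z-score)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profiles(profiles, path, ylabel: str = "score") -> None:
    """Overlay oriented aggregate profiles (rows = time points)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for label in profiles.index:
        ax.plot(profiles.columns, profiles.loc[label], lw=0.8, label=label)
    ax.axvline(0, color="k", ls=":", lw=0.7)
    ax.set_xlabel("offset from ACS (bp, T-rich orientation)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
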