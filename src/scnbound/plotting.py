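"""Figure rendering for meta-profiles, BBI boxplots and top-N heatmaps.

Figures are conveniences: every number shown is always written to TSV/JSON
first by the callers, and tests target those text outputs, never images.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bbi import HeatmapMatrix
from .profiles import BinnedProfile


def plot_meta_profile(profile: BinnedProfile, path, title: str = "") -> None:
    """Sense above / antisense below the axis, offsets in bp from the boundary."""
    fig, ax = plt.subplots(figsize=(5, 3))
    x = profile.offsets() + profile.bin_size / 2
    if profile.value_kind == "chip_over_input":
        ax.plot(x, profile.sense, color="tab:purple", lw=1.2)
        ax.axhline(1.0, color="grey", lw=0.6, ls="--")
        ax.set_ylabel("ChIP / input")
    else:
        ax.fill_between(x, 0, profile.sense, color="tab:blue", step="mid",
                        label="sense")
        if profile.antisense is not None:
            ax.fill_between(x, 0, -profile.antisense, color="tab:red",
                            step="mid", label="antisense")
            ax.legend(frameon=False, fontsize=7)
        ax.set_ylabel(profile.value_kind)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("offset from IES boundary (bp; + = inside IES)")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bbi_boxplot(summaries: dict[str, np.ndarray], path) -> None:
    """One box per strain of eligible-boundary BBI values (log scale)."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(summaries), 3.2))
    labels = list(summaries)
    ax.boxplot([summaries[k] for k in labels], tick_labels=labels,
               showfliers=False)
    ax.axhline(1.0, color="grey", lw=0.6, ls="--")
    ax.set_yscale("log")
    ax.set_ylabel("broken boundary index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: HeatmapMatrix, path) -> None:
    """Rank-ordered rows, boundary-axis columns, log-scaled RPM color."""
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(np.log1p(matrix.values), aspect="auto",
                   cmap="viridis", interpolation="nearest")
    ax.set_xlabel(f"boundary axis ({matrix.bin_size}-bp bins)")
    ax.set_ylabel("boundaries (rank order)")
    ax.axvline(matrix.values.shape[1] / 2 - 0.5, color="w", lw=0.8)
    ax.set_title(matrix.strain, fontsize=9)
    fig.colorbar(im, ax=ax, label="log1p RPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
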