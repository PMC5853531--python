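"""Optional per-chromosome score-track plot of a genome scan.

Requires matplotlib (install the ``plot`` extra).
"""

from __future__ import annotations

from typing import Sequence

from .types import ScanParams, Window


def plot_scan_tracks(
    windows: Sequence[Window],
    path: str,
    params: ScanParams = ScanParams(),
) -> None:
    """Draw one panel per chromosome of window scores with the threshold line.

    Windows with no blocks are not drawn (their score is undefined).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(w.chrom for w in windows))
    if not chroms:
        raise ValueError("no windows to plot")
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.8 * len(chroms)), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = [w for w in windows if w.chrom == chrom and w.avg_neglog10p is not None]
        x = [(w.start + w.end) / 2 / 1e6 for w in ws]
        y = [w.avg_neglog10p for w in ws]
        ax.plot(x, y, lw=0.8, color="steelblue")
        sig = [w for w in ws if w.significant]
        if sig:
            ax.scatter(
                [(w.start + w.end) / 2 / 1e6 for w in sig],
                [w.avg_neglog10p for w in sig],
                s=6, color="crimson", zorder=3,
            )
        ax.axhline(params.threshold, color="grey", ls="--", lw=0.8)
        ax.set_ylabel("avg $-\\log_{10}P$")
        ax.set_title(chrom, fontsize=9, loc="left")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
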