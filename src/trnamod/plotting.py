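"""Optional figures: concordance scatter and paired-MI plots.

Matplotlib is imported lazily so headless pipelines that never plot do not
pay for it.
"""

from __future__ import annotations

from pathlib import Path

from .homology import HomologyComparison
from .patterns import CooccurrenceResult


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_comparison(comp: HomologyComparison, path: str | Path) -> None:
    """Known-vs-predicted MI scatter with the identity line; +-2 SD
    outliers highlighted and labelled."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    sites = comp.sites
    ok = sites[~sites["outlier"]]
    out = sites[sites["outlier"]]
    ax.scatter(ok["known_mi"], ok["predicted_mi"], s=14, alpha=0.7,
               color="#4477aa", label="concordant")
    ax.scatter(out["known_mi"], out["predicted_mi"], s=22,
               color="#aa3377", label="outlier (±2 SD)")
    for _, rec in out.iterrows():
        ax.annotate(f"{rec['trna']} {rec['code']}{rec['position']}",
                    (rec["known_mi"], rec["predicted_mi"]), fontsize=6)
    ax.plot([0, 1], [0, 1], lw=0.8, color="grey", zorder=0)
    ax.set_xlabel(f"known MI ({comp.source_species})")
    ax.set_ylabel(f"predicted MI ({comp.target_species})")
    ax.set_title(f"r = {comp.pearson_r:.3f} (n = {len(sites)})", fontsize=9)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_paired_mi(result: CooccurrenceResult, path: str | Path) -> None:
    """Paired MI values at the two positions, one line per tRNA (modified
    status at either end marked)."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(3.5, 4.5))
    p, q = result.positions
    for _, rec in result.paired_mi.iterrows():
        color = ("#cc6677" if rec["modified_p"]
                 else "#88ccee" if rec["modified_q"] else "#cccccc")
        ax.plot([0, 1], [rec["mi_frequency_p"], rec["mi_frequency_q"]],
                marker="o", markersize=3, lw=0.8, color=color, alpha=0.8)
    ax.set_xticks([0, 1], [f"position {p}", f"position {q}"])
    ax.set_ylabel("MI frequency")
    ax.set_title(f"{result.group}: both={result.n_both}, "
                 f"{p}-only={result.n_p_only}, {q}-only={result.n_q_only}",
                 fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
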