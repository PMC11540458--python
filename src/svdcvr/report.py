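"""Result tables and forest plots for the association models.

``report_tables`` writes one tidy CSV per model family (linear coefficients,
ordinal and binomial odds ratios) and a forest plot of the standardized CVR
coefficients with 95% CI whiskers, one marker per outcome × tissue.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["report_tables", "forest_plot"]

_TISSUE_COLORS = {"sgm": "#d95f8a", "nawm": "#4878b0", "wmh": "#d9a21b"}


def forest_plot(std_cvr: pd.DataFrame, path: Path) -> None:
    """Forest plot of standardized CVR terms (rows: outcomes; colors: tissues)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    linear = std_cvr[std_cvr["model"] == "linear"]
    logistic = std_cvr[std_cvr["model"] != "linear"]
    fig, axes = plt.subplots(
        1, 2, figsize=(10, 0.35 * max(len(std_cvr), 8) + 1.5), sharey=False
    )
    for ax, grp, null, label in (
        (axes[0], linear, 0.0, "standardized B"),
        (axes[1], logistic, 1.0, "odds ratio"),
    ):
        outcomes = list(dict.fromkeys(grp["outcome"]))
        for i, outcome in enumerate(outcomes):
            sub = grp[grp["outcome"] == outcome]
            for j, (_, row) in enumerate(sub.iterrows()):
                y = i + (j - 1) * 0.2
                color = _TISSUE_COLORS.get(row["tissue"], "k")
                ax.plot(
                    [row["ci_low"], row["ci_high"]], [y, y], color=color, lw=1.2
                )
                ax.plot(row["estimate"], y, "o", color=color, ms=4)
        ax.axvline(null, ls="--", color="gray", lw=0.8)
        ax.set_yticks(range(len(outcomes)))
        ax.set_yticklabels(outcomes)
        ax.set_xlabel(label)
        if null == 1.0 and len(grp):
            ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report_tables(
    tidy: pd.DataFrame, standardized: pd.DataFrame, out_dir
) -> list[Path]:
    """Write per-family CSVs and the forest plot; return the written paths."""
    if tidy is None or len(tidy) == 0:
        raise ValueError("no model results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for family in tidy["model"].unique():
        sub = tidy[tidy["model"] == family]
        p = out / f"{family}_models.csv"
        sub.to_csv(p, index=False)
        paths.append(p)

    std_cvr = standardized[standardized["term"] == "cvr"].reset_index(drop=True)
    if len(std_cvr):
        plot_path = out / "forest_cvr.png"
        forest_plot(std_cvr, plot_path)
        paths.append(plot_path)
    return paths
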