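"""Cross-cell descriptive statistics: occupancy summaries, organelle
volume/surface correlations with explicit taxon exclusion, and
condition comparisons.

Only descriptive statistics and ordinary least squares are used; exclusion
of an outlying taxon (e.g. a species two orders of magnitude larger than
the rest, which clusters the scatter into two blobs and masks the
within-group relationship) is by explicit tag list, never automatic, so
every analysis stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationResult",
    "GroupSummary",
    "fit_linear",
    "summarize_groups",
    "compare_conditions",
]


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded_tags: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("correlation requires >= 3 points")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


@dataclass
class GroupSummary:
    tag: str
    compartment: str
    mean: float
    sd: float | None  # None when n == 1
    n: int


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    tags: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> CorrelationResult:
    """Ordinary least squares y = slope * x + intercept.

    Points whose tag is in ``exclude`` are dropped before fitting and the
    exclusion is recorded in the result. R^2 = 1 - SS_res / SS_tot.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    if exclude:
        if tags is None:
            raise ValueError("exclusions need per-point tags")
        tags = np.asarray(tags)
        keep = ~np.isin(tags, list(exclude))
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 retained points, have {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    note = ""
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        r2 = 0.0
        note = "zero variance in y; r_squared defined as 0"
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CorrelationResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n_points=n,
        excluded_tags=list(exclude),
        note=note,
    )


def summarize_groups(records: pd.DataFrame, value: str = "occupancy_pct") -> list[GroupSummary]:
    """Mean and sample standard deviation (n-1 denominator) of ``value``
    per (tag, compartment) group of a morphometrics table."""
    out: list[GroupSummary] = []
    for (tag, comp), grp in records.groupby(["tag", "compartment"], sort=True):
        vals = grp[value].dropna().to_numpy(dtype=np.float64)
        if len(vals) == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(GroupSummary(str(tag), str(comp), float(np.mean(vals)), sd, len(vals)))
    return out


def compare_conditions(
    a: Sequence[GroupSummary], b: Sequence[GroupSummary]
) -> pd.DataFrame:
    """Per-compartment comparison of two conditions.

    Columns: means, absolute difference, fold change, percent change, and a
    propagated relative error sqrt((sd_a/mean_a)^2 + (sd_b/mean_b)^2) *
    |percent change|. Compartments present in only one condition are kept
    and flagged rather than dropped.
    """
    by_a = {s.compartment: s for s in a}
    by_b = {s.compartment: s for s in b}
    rows = []
    for comp in sorted(set(by_a) | set(by_b)):
        sa, sb = by_a.get(comp), by_b.get(comp)
        row: dict = {"compartment": comp, "flag": ""}
        if sa is None or sb is None:
            row["flag"] = "missing_in_" + ("a" if sa is None else "b")
            row["mean_a"] = sa.mean if sa else np.nan
            row["mean_b"] = sb.mean if sb else np.nan
            row.update(abs_difference=np.nan, fold_change=np.nan,
                       percent_change=np.nan, percent_change_err=np.nan)
        else:
            diff = sb.mean - sa.mean
            fold = sb.mean / sa.mean if sa.mean else np.nan
            pct = 100.0 * diff / sa.mean if sa.mean else np.nan
            rel_a = (sa.sd / sa.mean) if (sa.sd is not None and sa.mean) else 0.0
            rel_b = (sb.sd / sb.mean) if (sb.sd is not None and sb.mean) else 0.0
            err = float(np.hypot(rel_a, rel_b) * abs(pct)) if np.isfinite(pct) else np.nan
            row.update(
                mean_a=sa.mean, mean_b=sb.mean, abs_difference=diff,
                fold_change=fold, percent_change=pct, percent_change_err=err,
            )
        rows.append(row)
    cols = ["compartment", "mean_a", "mean_b", "abs_difference",
            "fold_change", "percent_change", "percent_change_err", "flag"]
    return pd.DataFrame(rows, columns=cols)


def correlation_table(
    records: pd.DataFrame,
    x_compartment: str = "plastid",
    y_compartment: str = "mitochondrion",
    quantity: str = "volume_um3",
    exclude: Sequence[str] = (),
    normalize_per_cell: bool = False,
) -> CorrelationResult:
    """Fit the organelle-organelle relationship across cells.

    Each point is one cell: x = x_compartment's quantity, y =
    y_compartment's. With ``normalize_per_cell`` both are divided by that
    cell's whole-cell value (volume fractions rather than absolute sizes);
    both readings are meaningful and callers should report which they used.
    """
    piv = records.pivot_table(
        index=["cell_id", "tag"], columns="compartment", values=quantity
    )
    if normalize_per_cell:
        if "cell" not in piv.columns:
            raise ValueError("per-cell normalization requires 'cell' records")
        piv = piv.div(piv["cell"], axis=0)
    for comp in (x_compartment, y_compartment):
        if comp not in piv.columns:
            raise ValueError(f"no records for compartment {comp!r}")
    piv = piv.dropna(subset=[x_compartment, y_compartment])
    tags = piv.index.get_level_values("tag")
    return fit_linear(
        piv[x_compartment].to_numpy(),
        piv[y_compartment].to_numpy(),
        tags=tags,
        exclude=exclude,
    )


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------


def plot_occupancy(summaries: Sequence[GroupSummary], path, compartments=None):
    """Grouped bar chart of mean occupancy ± sd per tag, one bar colour per
    compartment (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = compartments or sorted({s.compartment for s in summaries})
    tags = sorted({s.tag for s in summaries})
    by = {(s.tag, s.compartment): s for s in summaries}
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(tags), 4))
    width = 0.8 / max(1, len(comps))
    for j, comp in enumerate(comps):
        xs, ys, es = [], [], []
        for i, tag in enumerate(tags):
            s = by.get((tag, comp))
            if s is None:
                continue
            xs.append(i + (j - (len(comps) - 1) / 2) * width)
            ys.append(s.mean)
            es.append(s.sd or 0.0)
        ax.bar(xs, ys, width=width, yerr=es, capsize=2, label=comp)
    ax.set_xticks(range(len(tags)))
    ax.set_xticklabels(tags, rotation=30, ha="right")
    ax.set_ylabel("cell-volume occupancy (%)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation(x, y, fit: CorrelationResult, path,
                     xlabel="plastid volume (um^3)",
                     ylabel="mitochondrion volume (um^3)"):
    """Scatter of per-cell organelle quantities with the OLS line and R^2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=25, edgecolor="k", linewidth=0.4)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.slope * grid + fit.intercept, color="C3",
            label=f"slope {fit.slope:.3g}, $R^2$ = {fit.r_squared:.3f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
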