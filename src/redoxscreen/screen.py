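"""Screen-level aggregation and comparisons.

Per-FOV gel records are joined with the plate design into a validated
ScreenTable (one row per formulation x replicate x day x group), from which
the longitudinal summaries are computed: per-group/per-formulation ORR
trajectories, day-vs-day percent changes, and high- vs low-efficiency group
separation by Welch's unequal-variance t-test.

Welch's statistic is computed from the closed form

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)

with Welch-Satterthwaite degrees of freedom; only the t-distribution CDF is
delegated to scipy.  Omnibus procedures (Welch ANOVA, Dunnett T3, Tukey)
are deliberately not reimplemented — export the ScreenTable CSV to a stats
package for those.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, JoinError
from .synthetic import PlateDesign, PlateResult
from .widefield import GelRecord, WidefieldConfig, process_fov

__all__ = [
    "ComparisonResult",
    "aggregate_screen",
    "percent_change",
    "welch_ttest",
    "compare_groups",
    "trajectory_report",
    "process_plate",
]

KEY_COLS = ["group", "formulation", "replicate", "day"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-sample or day-pair comparison."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    mean_diff: float
    percent_change: float
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    df: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for rec in records:
        rows.append(rec.to_dict() if isinstance(rec, GelRecord) else dict(rec))
    return pd.DataFrame(rows)


def process_plate(
    plate: PlateResult,
    config: WidefieldConfig | None = None,
) -> pd.DataFrame:
    """Run the widefield FOV pipeline over every image pair of a simulated
    plate and return records joined with the manifest truth.

    The returned frame carries the measured ``orr`` next to the generator's
    ``orr_true``, one row per FOV.
    """
    cfg = config or WidefieldConfig.for_shape(plate.design.shape)
    rows = []
    for (_, row), pair in zip(plate.manifest.iterrows(), plate.pairs.values()):
        rec = process_fov(pair, cfg)
        out = rec.to_dict()
        out["orr_true"] = row["orr_true"]
        rows.append(out)
    return pd.DataFrame(rows)


def aggregate_screen(records, design: PlateDesign) -> pd.DataFrame:
    """Join per-FOV records against the plate design into a ScreenTable.

    Every record must resolve to a (group, formulation, replicate, day)
    cell of the design; unknown keys raise :class:`JoinError` listing them.
    Rows are sorted on the key, so input order never matters.  Design cells
    with no record are reported in the ``missing`` attribute of the result
    (``df.attrs["missing"]``), not silently dropped.
    """
    table = _records_frame(records)
    for col in KEY_COLS:
        if col not in table.columns:
            raise JoinError(f"records lack required column {col!r}")

    valid_keys = {
        (f.group, f.label, rep, day)
        for f in design.formulations
        for rep in range(1, design.replicates + 1)
        for day in design.days
    }
    seen = set()
    bad = []
    for _, row in table.iterrows():
        key = (row["group"], row["formulation"], int(row["replicate"]), int(row["day"]))
        if key not in valid_keys:
            bad.append(key)
        elif key in seen:
            raise JoinError(f"duplicate record key {key}")
        else:
            seen.add(key)
    if bad:
        raise JoinError(f"records not resolvable in design: {bad}")

    meta = pd.DataFrame(
        [{"group": f.group, "formulation": f.label, "stiffness_kpa": f.stiffness_kpa}
         for f in design.formulations]
    )
    if "stiffness_kpa" not in table.columns:
        table = table.merge(meta, on=["group", "formulation"], how="left")
    table = table.sort_values(KEY_COLS, kind="mergesort").reset_index(drop=True)
    table.attrs["missing"] = sorted(valid_keys - seen)
    return table


def _group_day_mean(table, group, day, value_col):
    sel = table[(table["group"] == group) & (table["day"] == day)]
    if sel.empty:
        raise ComparisonError(f"no rows for group {group!r} day {day}")
    return sel[value_col].to_numpy(dtype=float)


def percent_change(
    table: pd.DataFrame,
    group: str,
    day_a: int,
    day_b: int,
    value_col: str = "orr",
    method: str = "group_mean",
) -> ComparisonResult:
    """Percent change of the group's ORR from ``day_a`` to ``day_b``.

    ``method="group_mean"`` (default) compares the day-level group means,
    ``100 * (mean_b - mean_a) / mean_a``; ``method="per_gel"`` averages the
    per-gel (formulation x replicate) percent changes instead — both
    conventions are defensible for "average change", so both are provided.
    """
    a = _group_day_mean(table, group, day_a, value_col)
    b = _group_day_mean(table, group, day_b, value_col)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if method == "group_mean":
        pct = 100.0 * (mean_b - mean_a) / mean_a
    elif method == "per_gel":
        sub = table[table["group"] == group]
        wide = sub.pivot_table(index=["formulation", "replicate"],
                               columns="day", values=value_col)
        if day_a not in wide.columns or day_b not in wide.columns:
            raise ComparisonError(f"days {day_a}/{day_b} absent for group {group!r}")
        per_gel = 100.0 * (wide[day_b] - wide[day_a]) / wide[day_a]
        pct = float(per_gel.dropna().mean())
    else:
        raise ComparisonError(f"unknown percent-change method {method!r}")
    return ComparisonResult(
        label_a=f"{group}@d{day_a}", label_b=f"{group}@d{day_b}",
        mean_a=mean_a, mean_b=mean_b, mean_diff=mean_b - mean_a,
        percent_change=pct, statistic=float("nan"), pvalue=float("nan"),
        n_a=a.size, n_b=b.size,
    )


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t-test from the standard closed form.

    Returns ``(t, p_two_sided, df)`` with Welch-Satterthwaite degrees of
    freedom.  Identical samples (zero pooled variance, zero difference)
    give ``t = 0, p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ComparisonError("need at least 2 observations per side")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, float(na + nb - 2)
        return float(np.sign(diff) * np.inf), 0.0, float(na + nb - 2)
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), float(df)


def compare_groups(
    table: pd.DataFrame,
    day: int,
    group_a: str,
    group_b: str,
    value_col: str = "orr",
    test: str = "welch",
) -> ComparisonResult:
    """Welch's t-test between two groups' per-FOV ORR values at one day."""
    if test != "welch":
        raise ComparisonError(f"unknown test {test!r}")
    a = _group_day_mean(table, group_a, day, value_col)
    b = _group_day_mean(table, group_b, day, value_col)
    if a.size < 2 or b.size < 2:
        raise ComparisonError("need >= 2 replicates per group for Welch's test")
    t, p, df = welch_ttest(a, b)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return ComparisonResult(
        label_a=f"{group_a}@d{day}", label_b=f"{group_b}@d{day}",
        mean_a=mean_a, mean_b=mean_b, mean_diff=mean_b - mean_a,
        percent_change=100.0 * (mean_b - mean_a) / mean_a,
        statistic=t, pvalue=p, n_a=a.size, n_b=b.size, df=df,
    )


def trajectory_report(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    value_col: str = "orr",
) -> pd.DataFrame:
    """Descriptive per-group/per-formulation day-series summary.

    One row per (group, formulation, day) with mean, sd and n; sd is NaN
    and flagged when n = 1.  With ``out_dir`` set, writes ``summary.csv``
    and a per-group trajectory figure; outputs are deterministic functions
    of the table contents.
    """
    if table.empty:
        raise ComparisonError("trajectory_report needs a non-empty table")
    # canonical row order -> byte-identical output under input permutation
    sort_cols = [c for c in ("group", "formulation", "day", "replicate")
                 if c in table.columns]
    table = table.sort_values(sort_cols, kind="mergesort")
    grouped = table.groupby(["group", "formulation", "day"], sort=True)[value_col]
    summary = grouped.agg(mean="mean", sd="std", n="size").reset_index()
    summary["sd_flag"] = np.where(summary["n"] < 2, "n=1: sd undefined", "")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        _plot_trajectories(summary, out / "trajectories.png", value_col)
    return summary


def _plot_trajectories(summary: pd.DataFrame, path: Path, value_col: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (group, form), sub in summary.groupby(["group", "formulation"]):
        ax.errorbar(sub["day"], sub["mean"], yerr=sub["sd"].fillna(0.0),
                    marker="o", ms=3, lw=1, alpha=0.6, label=f"{group}:{form}")
    ax.set_xlabel("day post-differentiation")
    ax.set_ylabel(f"normalized {value_col.upper()}")
    if summary["formulation"].nunique() <= 6:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
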