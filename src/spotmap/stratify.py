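"""Rurality/deprivation strata and nonparametric comparisons.

RUCA codes collapse to four categories (1-3 metropolitan, 4-6
micropolitan, 7-9 small town, 10 rural) and ADI values to quartiles of
the retained units.  Per-unit RR point estimates are then compared
across strata with a global Kruskal-Wallis test and Dunn's pairwise
z-tests under a Holm step-down adjustment, and summarized as median
differences against a reference stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .standardization import AreaTable

__all__ = [
    "RUCA_CATEGORIES",
    "ADI_QUARTILES",
    "StrataAssignment",
    "assign_strata",
    "kruskal_wallis",
    "dunn_holm",
    "holm_adjust",
    "median_diff_table",
    "strat_report",
    "format_report",
]

RUCA_CATEGORIES = ("metropolitan", "micropolitan", "small town", "rural")
ADI_QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class StrataAssignment:
    """Per-unit RUCA category and ADI quartile."""

    table: pd.DataFrame  # unit_id, ruca_cat, adi_q

    def groups(self, variable: str) -> pd.Series:
        col = {"ruca": "ruca_cat", "adi": "adi_q"}[variable]
        return self.table.set_index("unit_id")[col]


def recode_ruca(code: int, unit: str = "?") -> str:
    if 1 <= code <= 3:
        return "metropolitan"
    if 4 <= code <= 6:
        return "micropolitan"
    if 7 <= code <= 9:
        return "small town"
    if code == 10:
        return "rural"
    raise ValueError(f"RUCA code {code} outside 1-10 for unit {unit!r}")


def assign_strata(table: AreaTable) -> StrataAssignment:
    """RUCA recode plus ADI quartiles over the retained units.

    Quartile breaks sit at the 25/50/75th percentiles of the units'
    ADI values; ties at a break go to the lower quartile.  Constant ADI
    is an error (it cannot form four groups).
    """
    for col in ("ruca", "adi"):
        if col not in table.df.columns:
            raise ValueError(f"AreaTable missing {col!r} column")
    ruca = [
        recode_ruca(int(c), u)
        for u, c in zip(table.unit_ids, table.df["ruca"])
    ]
    adi = table.df["adi"].to_numpy(dtype=float)
    if np.ptp(adi) == 0:
        raise ValueError("degenerate quartiles: ADI constant across units")
    breaks = np.percentile(adi, [25, 50, 75])
    # value <= break -> lower quartile
    quart = np.searchsorted(breaks, adi, side="left")
    labels = [ADI_QUARTILES[q] for q in quart]
    return StrataAssignment(pd.DataFrame({
        "unit_id": table.unit_ids, "ruca_cat": ruca, "adi_q": labels,
    }))


def _group_arrays(values: Sequence[float], groups: Sequence) -> dict:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    out = {}
    for label in pd.unique(g):
        out[label] = v[g == label]
    return out


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    by = _group_arrays(values, groups)
    if len(by) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    arrays = list(by.values())
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        # scipy raises on all-identical data; H is 0 by convention
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down: sort ascending, multiply the i-th by (m - i),
    take the running maximum, clip at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((m - rank) * p[idx], 1.0))
        adj[idx] = running
    return adj


def dunn_holm(
    values: Sequence[float],
    groups: Sequence,
    reference,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Dunn's post-hoc z-tests with Holm-adjusted two-sided p-values.

    Rank means come from a single pooled mid-rank assignment; the
    standard error uses the tie-corrected pooled variance
    ``(N(N+1)/12 - T)(1/n_j + 1/n_k)`` with
    ``T = sum(t^3 - t) / (12(N - 1))``.  By default the comparison
    family is every stratum against ``reference``; ``all_pairs=True``
    adjusts over all pairwise comparisons instead.
    """
    by = _group_arrays(values, groups)
    if reference not in by:
        raise ValueError(f"reference stratum {reference!r} not present")
    for label, arr in by.items():
        if arr.size == 0:
            raise ValueError(f"empty stratum {label!r}")
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    n_total = v.size
    ranks = stats.rankdata(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    pooled_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_rank = {label: float(ranks[g == label].mean()) for label in by}
    sizes = {label: int((g == label).sum()) for label in by}

    labels = list(by)
    if all_pairs:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    else:
        pairs = [(label, reference) for label in labels if label != reference]

    rows = []
    for a, b in pairs:
        se = np.sqrt(pooled_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"stratum": a, "vs": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def median_diff_table(
    values: Sequence[float],
    strata: Sequence,
    reference,
    order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-stratum medians and differences against the reference.

    Medians use the even-count convention (mean of the two central
    order statistics); differences are rounded to two decimals.  The
    reference row reports a difference of 0 and is flagged.
    """
    by = _group_arrays(values, strata)
    if reference not in by:
        raise ValueError(f"reference stratum {reference!r} empty or absent")
    ref_median = float(np.median(by[reference]))
    labels = list(order) if order is not None else list(by)
    rows = []
    for label in labels:
        if label not in by:
            continue
        med = float(np.median(by[label]))
        rows.append({
            "stratum": label,
            "median": med,
            "difference": round(med - ref_median, 2),
            "is_reference": label == reference,
        })
    return pd.DataFrame(rows)


def strat_report(
    values: Sequence[float],
    assignment: StrataAssignment,
    unit_ids: Sequence,
    variable: str = "ruca",
    reference: Optional[str] = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Full per-stratum report: median, difference, Dunn z, Holm p.

    ``values`` align with ``unit_ids`` (per-unit RR point estimates).
    Attaches the global Kruskal-Wallis result in ``df.attrs``.
    """
    groups = assignment.groups(variable).loc[list(unit_ids)].to_numpy()
    order = RUCA_CATEGORIES if variable == "ruca" else ADI_QUARTILES
    if reference is None:
        reference = order[0]
    h, p_global = kruskal_wallis(values, groups)
    med = median_diff_table(values, groups, reference, order=order)
    dunn = dunn_holm(values, groups, reference, all_pairs=all_pairs)
    dunn_vs_ref = dunn[dunn["vs"] == reference] if not all_pairs else dunn
    out = med.merge(
        dunn_vs_ref[["stratum", "z", "p_raw", "p_holm"]], on="stratum", how="left"
    )
    out.attrs["kruskal_h"] = h
    out.attrs["kruskal_p"] = p_global
    out.attrs["variable"] = variable
    out.attrs["reference"] = reference
    return out


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Render a report for CSV output in the printed-table style:
    2-decimal medians/differences, 'Ref' rows, p-values below 0.001 as
    '<0.001'."""
    def fmt_p(p):
        if pd.isna(p):
            return "-"
        return "<0.001" if p < 0.001 else f"{p:.3f}"

    return pd.DataFrame({
        "stratum": report["stratum"],
        "median": [f"{m:.2f}" for m in report["median"]],
        "difference": [
            "Ref" if ref else f"{d:.2f}"
            for d, ref in zip(report["difference"], report["is_reference"])
        ],
        "p_holm": [
            "-" if ref else fmt_p(p)
            for p, ref in zip(report["p_holm"], report["is_reference"])
        ],
    })
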