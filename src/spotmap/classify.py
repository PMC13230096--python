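"""Relative-risk summaries and hot/cold-spot classification.

RR_i = exp(beta0 + b_i): each unit's risk relative to the reference
age-specific experience used to build the expected counts.  A unit is a
hot spot at level 1-alpha when the equal-tailed credible interval for
RR_i lies entirely above 1, a cold spot when entirely below 1, and not
significant otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import Bym2Posterior

__all__ = [
    "RRDraws",
    "RiskSummary",
    "SpotClass",
    "rr_draws",
    "summarize_and_classify",
    "export_maps",
    "plot_maps",
]


@dataclass(frozen=True)
class RRDraws:
    unit_ids: tuple
    rr: np.ndarray        # (total draws, n_units)
    baseline: np.ndarray  # (total draws,) exp(beta0)


@dataclass(frozen=True)
class RiskSummary:
    """Per-unit RR medians, equal-tailed CrIs, exceedance probabilities."""

    table: pd.DataFrame   # unit_id, rr_median, cri_lo, cri_hi, exceed_gt1
    baseline_median: float
    baseline_cri: tuple
    level: float
    point_estimate: str = "median"


@dataclass(frozen=True)
class SpotClass:
    table: pd.DataFrame   # unit_id, label
    level: float

    @property
    def counts(self) -> dict:
        c = self.table["label"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("hot", "cold", "ns")}


def rr_draws(post: Bym2Posterior) -> RRDraws:
    """Per-draw relative risks exp(beta0 + b_i) and baseline exp(beta0)."""
    beta0 = post.flat("beta0")
    b = post.flat("b")
    return RRDraws(post.unit_ids, np.exp(beta0[:, None] + b), np.exp(beta0))


def summarize_and_classify(
    rr: RRDraws,
    level: float = 0.99,
    point_estimate: str = "median",
    hpd: bool = False,
) -> tuple[RiskSummary, SpotClass]:
    """Equal-tailed CrI summary and hot/cold/ns labels at one level."""
    if not 0.5 < level < 1.0:
        raise ValueError(f"credible level must be in (0.5, 1), got {level}")
    if rr.rr.shape[0] < 100:
        raise ValueError("need >= 100 posterior draws per unit")
    alpha = 1.0 - level
    if hpd:
        import arviz as az

        bounds = np.array([
            az.hdi(np.asarray(col), hdi_prob=level) for col in rr.rr.T
        ])
        lo, hi = bounds[:, 0], bounds[:, 1]
        blo, bhi = az.hdi(np.asarray(rr.baseline), hdi_prob=level)
    else:
        lo, hi = np.quantile(rr.rr, [alpha / 2, 1 - alpha / 2], axis=0)
        blo, bhi = np.quantile(rr.baseline, [alpha / 2, 1 - alpha / 2])
    if point_estimate == "median":
        point = np.median(rr.rr, axis=0)
        bpoint = float(np.median(rr.baseline))
    elif point_estimate == "mean":
        point = np.mean(rr.rr, axis=0)
        bpoint = float(np.mean(rr.baseline))
    else:
        raise ValueError(f"unknown point estimate: {point_estimate!r}")
    exceed = np.mean(rr.rr > 1.0, axis=0)

    summary = RiskSummary(
        pd.DataFrame({
            "unit_id": rr.unit_ids,
            "rr_median": point,
            "cri_lo": lo,
            "cri_hi": hi,
            "exceed_gt1": exceed,
        }),
        baseline_median=bpoint,
        baseline_cri=(float(blo), float(bhi)),
        level=level,
        point_estimate=point_estimate,
    )
    labels = np.where(lo > 1.0, "hot", np.where(hi < 1.0, "cold", "ns"))
    spots = SpotClass(
        pd.DataFrame({"unit_id": rr.unit_ids, "label": labels}), level
    )
    return summary, spots


def export_maps(
    summary: RiskSummary,
    classes: SpotClass,
    geometries: Mapping,
    path,
) -> int:
    """Write a GeoJSON layer of RR estimates, CrIs, and labels.

    Units without geometry are dropped from the layer (with a warning)
    but remain in the tabular outputs.  Returns the feature count.
    """
    import warnings

    from shapely.geometry import mapping as shapely_mapping

    merged = summary.table.merge(classes.table, on="unit_id")
    features = []
    for row in merged.itertuples(index=False):
        geom = geometries.get(row.unit_id)
        if geom is None:
            warnings.warn(f"no geometry for unit {row.unit_id!r}; dropped from map",
                          stacklevel=2)
            continue
        features.append({
            "type": "Feature",
            "geometry": shapely_mapping(geom),
            "properties": {
                "unit_id": row.unit_id,
                "rr_median": float(row.rr_median),
                "cri_lo": float(row.cri_lo),
                "cri_hi": float(row.cri_hi),
                "exceed_gt1": float(row.exceed_gt1),
                "label": row.label,
                "level": summary.level,
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return len(features)


def plot_maps(
    summary: RiskSummary,
    classes: SpotClass,
    geometries: Mapping,
    path,
    title: Optional[str] = None,
) -> None:
    """Two-panel PNG: diverging RR ramp centred at 1, and the 3-class layer."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm
    from matplotlib.patches import Polygon as MplPolygon

    merged = summary.table.merge(classes.table, on="unit_id")
    merged = merged[merged["unit_id"].isin(geometries)]
    rr = merged["rr_median"].to_numpy()
    span = max(abs(np.log(rr)).max(), 0.1)
    norm = TwoSlopeNorm(vmin=np.exp(-span), vcenter=1.0, vmax=np.exp(span))
    cmap = plt.get_cmap("RdBu_r")
    class_color = {"hot": "#b2182b", "cold": "#2166ac", "ns": "#e0e0e0"}

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for row in merged.itertuples(index=False):
        geom = geometries[row.unit_id]
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            xy = np.asarray(poly.exterior.coords)
            axes[0].add_patch(MplPolygon(xy, facecolor=cmap(norm(row.rr_median)),
                                         edgecolor="white", linewidth=0.2))
            axes[1].add_patch(MplPolygon(xy, facecolor=class_color[row.label],
                                         edgecolor="white", linewidth=0.2))
    present = [lab for lab in ("hot", "cold", "ns")
               if (merged["label"] == lab).any()]
    axes[1].legend(handles=[
        plt.Rectangle((0, 0), 1, 1, color=class_color[lab], label=lab)
        for lab in present
    ], loc="lower left", fontsize=8)
    for ax in axes:
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.set_axis_off()
    axes[0].set_title("posterior RR")
    axes[1].set_title(f"hot/cold spots at {summary.level:.0%} CrI")
    if title:
        fig.suptitle(title)
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=axes[0],
                 shrink=0.7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
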