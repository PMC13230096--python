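"""Age-adjusted expected counts and the inclusion filter.

Expected counts per unit serve as the model offset: the count a unit
would record if reference age-specific rates applied to its own
population.  Two modes are provided: ``internal`` applies rates band by
band to each unit's age structure (indirect standardization; conserves
the total count when the rates come from the table itself), and
``standard_weighted`` multiplies total population by a standard-
population-weighted rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_AGE_BANDS",
    "AreaTable",
    "StandardWeights",
    "ExpectedCounts",
    "reference_age_rates",
    "expected_counts",
    "apply_exclusions",
]

N_AGE_BANDS = 11

POP_COLS = [f"pop_band_{k}" for k in range(1, N_AGE_BANDS + 1)]
OBS_COLS = [f"obs_band_{k}" for k in range(1, N_AGE_BANDS + 1)]


@dataclass
class AreaTable:
    """Per-unit observed counts, age-banded populations, covariates.

    Backed by a DataFrame indexed by unit id with columns ``O`` (total
    observed count for one cancer type), ``pop_band_1..11``, ``ruca``,
    ``adi``, and optionally ``obs_band_1..11`` (per-band counts, needed
    to derive reference rates from the data).
    """

    df: pd.DataFrame
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in ["O", *POP_COLS] if c not in self.df.columns]
        if missing:
            raise ValueError(f"AreaTable missing columns: {missing}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate unit ids: {dups}")
        if (self.df["O"] < 0).any():
            bad = self.df.index[self.df["O"] < 0].tolist()
            raise ValueError(f"negative observed count for units {bad}")
        if (self.df[POP_COLS] < 0).to_numpy().any():
            raise ValueError("negative population entries")

    @property
    def unit_ids(self) -> tuple:
        return tuple(str(u) for u in self.df.index)

    @property
    def observed(self) -> np.ndarray:
        return self.df["O"].to_numpy(dtype=float)

    @property
    def populations(self) -> np.ndarray:
        """(n_units, 11) population matrix."""
        return self.df[POP_COLS].to_numpy(dtype=float)

    @property
    def band_observed(self) -> Optional[np.ndarray]:
        if all(c in self.df.columns for c in OBS_COLS):
            return self.df[OBS_COLS].to_numpy(dtype=float)
        return None

    @property
    def total_population(self) -> np.ndarray:
        return self.populations.sum(axis=1)

    def restrict(self, unit_ids: Sequence) -> "AreaTable":
        return AreaTable(self.df.loc[list(unit_ids)].copy(), self.cancer_type)

    @classmethod
    def from_csv(cls, path, cancer_type: Optional[str] = None) -> "AreaTable":
        df = pd.read_csv(path, dtype={"unit_id": str})
        if "unit_id" not in df.columns:
            raise ValueError(f"{path}: missing unit_id column")
        if cancer_type is not None:
            if "cancer_type" not in df.columns:
                raise ValueError(f"{path}: missing cancer_type column")
            df = df[df["cancer_type"] == cancer_type]
            if df.empty:
                raise ValueError(f"{path}: no rows for cancer type {cancer_type!r}")
        return cls(df.set_index("unit_id"), cancer_type)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        if self.cancer_type is not None and "cancer_type" not in out.columns:
            out.insert(0, "cancer_type", self.cancer_type)
        out.to_csv(path, index_label="unit_id")


@dataclass(frozen=True)
class StandardWeights:
    """Standard-population age weights (proportions summing to one)."""

    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_AGE_BANDS,):
            raise ValueError(f"expected {N_AGE_BANDS} weights, got {w.shape}")
        if (w < 0).any():
            raise ValueError("negative standard-population weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.weights)

    @classmethod
    def from_csv(cls, path) -> "StandardWeights":
        df = pd.read_csv(path).sort_values("band")
        return cls(tuple(df["weight"].tolist()))


@dataclass(frozen=True)
class ExpectedCounts:
    unit_ids: tuple
    values: tuple
    method: str

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"unit_id": self.unit_ids, "E": self.values, "method": self.method}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExpectedCounts":
        df = pd.read_csv(path, dtype={"unit_id": str})
        return cls(
            tuple(df["unit_id"]),
            tuple(float(x) for x in df["E"]),
            str(df["method"].iloc[0]) if len(df) else "internal",
        )


def reference_age_rates(table: AreaTable) -> np.ndarray:
    """Pooled age-specific rates r_k = sum_i O_ik / sum_i n_ik.

    Requires per-band observed counts (``obs_band_*`` columns).  Bands
    with zero pooled population get a zero rate.  When per-band counts
    are unavailable, supply a rate schedule directly instead.
    """
    band_obs = table.band_observed
    if band_obs is None:
        raise ValueError(
            "per-band observed counts unavailable; supply a reference rate "
            "schedule explicitly"
        )
    pop = table.populations.sum(axis=0)
    obs = band_obs.sum(axis=0)
    if not (pop > 0).any():
        raise ValueError("all age bands have zero population")
    rates = np.zeros(N_AGE_BANDS)
    nz = pop > 0
    rates[nz] = obs[nz] / pop[nz]
    return rates


def expected_counts(
    table: AreaTable,
    rates: Sequence,
    mode: str = "internal",
    weights: Optional[StandardWeights] = None,
) -> ExpectedCounts:
    """Expected counts per unit from reference age-specific rates.

    internal:          E_i = sum_k n_ik * r_k
    standard_weighted: E_i = (sum_k n_ik) * (sum_k w_k * r_k)
    """
    r = np.asarray(rates, dtype=float)
    if r.shape != (N_AGE_BANDS,):
        raise ValueError(f"expected {N_AGE_BANDS} rates, got shape {r.shape}")
    if mode == "internal":
        e = table.populations @ r
    elif mode == "standard_weighted":
        if weights is None:
            raise ValueError("standard_weighted mode requires StandardWeights")
        e = table.total_population * float(weights.array @ r)
    else:
        raise ValueError(f"unknown standardization mode: {mode!r}")
    if (e <= 0).any():
        bad = [u for u, v in zip(table.unit_ids, e) if v <= 0]
        raise ValueError(
            f"zero expected count for units {bad}; apply_exclusions first"
        )
    return ExpectedCounts(table.unit_ids, tuple(float(x) for x in e), mode)


@dataclass(frozen=True)
class ExclusionLog:
    """Removed units with reasons; writable as CSV."""

    entries: tuple = field(default_factory=tuple)  # (unit_id, reason)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["unit_id", "reason"])
            w.writerows(self.entries)


def apply_exclusions(table: AreaTable) -> tuple[AreaTable, ExclusionLog]:
    """Drop units with zero total population or zero observed cases.

    The contiguity graph must be rebuilt or reduced to the retained
    units afterwards.  Idempotent.
    """
    entries = []
    keep = []
    totals = table.total_population
    obs = table.observed
    for uid, pop, o in zip(table.unit_ids, totals, obs):
        if pop <= 0:
            entries.append((uid, "zero population"))
        elif o <= 0:
            entries.append((uid, "zero cases"))
        else:
            keep.append(uid)
    if not keep:
        raise ValueError("all units excluded (zero population or zero cases)")
    return table.restrict(keep), ExclusionLog(tuple(entries))
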