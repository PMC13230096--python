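"""Synthetic geography, populations, covariates, and counts.

Generates lattice "tracts" with the statistical structure the pipeline
assumes — age-structured populations, a metro-core urbanicity gradient,
a deprivation-like covariate, and counts drawn from the negative
binomial BYM2 generative model (or with planted elevated-risk blocks of
known relative risk) — so every stage can be exercised against a known
truth without registry data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .geography import (
    AdjacencyGraph,
    ScalingReport,
    build_adjacency,
    square_grid_geometries,
)
from .standardization import (
    N_AGE_BANDS,
    AreaTable,
    ExpectedCounts,
    expected_counts,
)

__all__ = [
    "SyntheticTruth",
    "DEFAULT_AGE_PROFILE",
    "DEFAULT_RATE_SCHEDULE",
    "generate_geography",
    "simulate_counts",
    "sample_bym2_field",
    "scale_rates_for_expected",
    "plant_block_mask",
]

# fixed age simplex: working-age heavy, thinning into the oldest bands
DEFAULT_AGE_PROFILE = np.array(
    [0.13, 0.12, 0.12, 0.11, 0.10, 0.10, 0.09, 0.08, 0.07, 0.05, 0.03]
)
assert abs(DEFAULT_AGE_PROFILE.sum() - 1.0) < 1e-12

# reference incidence rising steeply with age band (per person per window)
DEFAULT_RATE_SCHEDULE = 0.0005 * 1.55 ** np.arange(N_AGE_BANDS)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated dataset.

    ``b`` and ``rr`` are per unit in table order once counts have been
    simulated; ``hot_mask`` flags planted elevated-risk units.
    """

    rows: int
    cols: int
    beta0: float
    phi: float
    tau: float
    psi: float
    seed: int
    b: Optional[np.ndarray] = None
    hot_mask: Optional[np.ndarray] = None
    hot_multiplier: float = 1.5

    @property
    def rr(self) -> Optional[np.ndarray]:
        if self.b is None:
            return None
        return np.exp(self.beta0 + self.b)


def generate_geography(
    rows: int,
    cols: int,
    seed: int,
    deletion: Union[float, Sequence, None] = None,
    pop_log_mean: float = np.log(3000.0),
    pop_log_sd: float = 0.35,
    age_profile: Optional[np.ndarray] = None,
    metro_core: Optional[tuple] = None,
    adi_noise_sd: float = 8.0,
    rule: str = "queen",
):
    """Lattice geography with populations and RUCA/ADI-like covariates.

    Returns ``(geometries, table, graph)``.  ``deletion`` may be a
    fraction of cells to drop at random (creating holes, possibly
    disconnection) or an explicit list of (row, col) cells.  RUCA-like
    codes 1-10 follow equal-count bins of distance from the metro core
    (default: grid centre); the ADI-like value rises linearly with that
    distance plus noise.  Deterministic given the seed.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    rng = np.random.default_rng(seed)
    geoms = square_grid_geometries(rows, cols)
    cells = [(r, c) for r in range(rows) for c in range(cols)]

    if deletion is not None:
        if isinstance(deletion, float):
            n_drop = int(round(deletion * len(cells)))
            drop_idx = rng.choice(len(cells), size=n_drop, replace=False)
            dropped = {cells[i] for i in drop_idx}
        else:
            dropped = {tuple(rc) for rc in deletion}
        cells = [rc for rc in cells if rc not in dropped]
        if len(cells) < 4:
            raise ValueError("deletion leaves fewer than 4 units")
        geoms = {f"u{r}-{c}": geoms[f"u{r}-{c}"] for r, c in cells}

    if metro_core is None:
        metro_core = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    dist = np.array([
        np.hypot(r - metro_core[0], c - metro_core[1]) for r, c in cells
    ])
    # equal-count distance bins -> codes 1..10, nearest cells most urban
    ranks = dist.argsort().argsort()
    ruca = 1 + (ranks * 10) // len(cells)
    ruca = np.clip(ruca, 1, 10)

    max_dist = dist.max() if dist.max() > 0 else 1.0
    adi = 20.0 + 60.0 * dist / max_dist + adi_noise_sd * rng.standard_normal(len(cells))

    profile = DEFAULT_AGE_PROFILE if age_profile is None else np.asarray(age_profile)
    totals = np.exp(pop_log_mean + pop_log_sd * rng.standard_normal(len(cells)))
    pops = np.round(totals[:, None] * profile[None, :])

    import pandas as pd

    df = pd.DataFrame(
        pops, columns=[f"pop_band_{k}" for k in range(1, N_AGE_BANDS + 1)],
        index=pd.Index([f"u{r}-{c}" for r, c in cells], name="unit_id"),
    )
    df.insert(0, "O", 0)
    df["ruca"] = ruca
    df["adi"] = adi
    table = AreaTable(df, cancer_type="synthetic")
    graph = build_adjacency(geoms, rule=rule)
    return geoms, table, graph


def sample_bym2_field(
    graph: AdjacencyGraph,
    scaling: ScalingReport,
    phi: float,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw b from the BYM2 prior, in graph unit order.

    The structured part is sampled per component from the ICAR
    distribution under the sum-to-zero constraint (covariance = the
    Laplacian pseudo-inverse), divided by sqrt(c) so its generalized
    variance is one; singleton units get the unstructured term only.
    """
    n = graph.n_units
    sigma = 1.0 / np.sqrt(tau)
    pos = {u: i for i, u in enumerate(graph.unit_ids)}
    b = sigma * np.sqrt(1.0 - phi) * rng.standard_normal(n)
    for label, members in graph.components().items():
        if len(members) == 1:
            b[pos[members[0]]] = sigma * rng.standard_normal()
            continue
        q = graph.laplacian(members)
        eigval, eigvec = np.linalg.eigh(q)
        z = rng.standard_normal(len(members))
        nonzero = eigval > 1e-9 * eigval[-1]
        u = eigvec[:, nonzero] @ (z[nonzero] / np.sqrt(eigval[nonzero]))
        u /= np.sqrt(scaling.factor[label])
        for m, val in zip(members, u):
            b[pos[m]] += sigma * np.sqrt(phi) * val
    return b


def plant_block_mask(
    table: AreaTable, blocks: Sequence[tuple]
) -> np.ndarray:
    """Boolean mask from (row0, row1, col0, col1) half-open cell ranges."""
    mask = np.zeros(len(table.unit_ids), dtype=bool)
    for i, uid in enumerate(table.unit_ids):
        r, c = (int(x) for x in uid[1:].split("-"))
        for r0, r1, c0, c1 in blocks:
            if r0 <= r < r1 and c0 <= c < c1:
                mask[i] = True
    return mask


def scale_rates_for_expected(
    table: AreaTable, rates: np.ndarray, target_mean_e: float
) -> np.ndarray:
    """Rescale a rate schedule so mean expected count hits the target."""
    e = table.populations @ np.asarray(rates, dtype=float)
    return np.asarray(rates, dtype=float) * target_mean_e / e.mean()


def simulate_counts(
    truth: SyntheticTruth,
    table: AreaTable,
    graph: AdjacencyGraph,
    scaling: Optional[ScalingReport],
    rates: Optional[np.ndarray] = None,
) -> tuple[AreaTable, ExpectedCounts, SyntheticTruth]:
    """Fill observed counts from the generative model.

    ``b`` is taken from ``truth`` if present (planted surface),
    otherwise sampled from the BYM2 prior at truth's (phi, tau).  Counts
    are NB(mean = E * exp(beta0 + b), dispersion psi); ``psi = inf``
    gives the Poisson limit.  The seed in ``truth`` drives everything.
    """
    rng = np.random.default_rng(truth.seed)
    if rates is None:
        rates = DEFAULT_RATE_SCHEDULE
    e = expected_counts(table, rates, mode="internal")
    e_arr = e.array

    if truth.b is not None:
        b = np.asarray(truth.b, dtype=float)
        if b.shape != (len(table.unit_ids),):
            raise ValueError("truth.b must align with table units")
    else:
        if scaling is None:
            raise ValueError("scaling required to sample the BYM2 field")
        order = {u: i for i, u in enumerate(graph.unit_ids)}
        b_graph = sample_bym2_field(graph, scaling, truth.phi, truth.tau, rng)
        b = np.array([b_graph[order[u]] for u in table.unit_ids])
    if truth.hot_mask is not None:
        b = b + np.log(truth.hot_multiplier) * truth.hot_mask

    mu = e_arr * np.exp(truth.beta0 + b)
    if np.isinf(truth.psi):
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(
            truth.psi, truth.psi / (truth.psi + mu)
        )
    out = table.df.copy()
    out["O"] = counts
    return (
        AreaTable(out, table.cancer_type),
        e,
        replace(truth, b=b),
    )
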