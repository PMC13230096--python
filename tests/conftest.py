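import numpy as np
import pandas as pd
import pytest

from spotmap.geography import icar_scaling_factor
from spotmap.model import SamplerConfig, sample_posterior
from spotmap.standardization import N_AGE_BANDS, AreaTable
from spotmap.synth import (
    DEFAULT_RATE_SCHEDULE,
    SyntheticTruth,
    generate_geography,
    scale_rates_for_expected,
    simulate_counts,
)


def make_area_table(
    observed,
    populations,
    ruca=None,
    adi=None,
    band_observed=None,
    cancer_type="test",
) -> AreaTable:
    """Build an AreaTable from plain arrays (n_units x 11 populations)."""
    populations = np.asarray(populations, dtype=float)
    n = populations.shape[0]
    df = pd.DataFrame(
        populations,
        columns=[f"pop_band_{k}" for k in range(1, N_AGE_BANDS + 1)],
        index=pd.Index([f"t{i}" for i in range(n)], name="unit_id"),
    )
    df.insert(0, "O", np.asarray(observed))
    if band_observed is not None:
        for k in range(N_AGE_BANDS):
            df[f"obs_band_{k + 1}"] = np.asarray(band_observed)[:, k]
    df["ruca"] = ruca if ruca is not None else 1
    df["adi"] = adi if adi is not None else np.arange(n, dtype=float)
    return AreaTable(df, cancer_type)


def simulate_lattice(
    rows,
    cols,
    data_seed,
    *,
    beta0=0.0,
    phi=0.5,
    tau=4.0,
    psi=10.0,
    b=None,
    hot_mask=None,
    hot_multiplier=1.5,
    mean_e=40.0,
):
    """Synthetic lattice dataset with aligned O/E arrays in graph order."""
    geoms, table, graph = generate_geography(rows, cols, seed=data_seed)
    scaling = icar_scaling_factor(graph)
    rates = scale_rates_for_expected(table, DEFAULT_RATE_SCHEDULE, mean_e)
    truth = SyntheticTruth(
        rows, cols, beta0=beta0, phi=phi, tau=tau, psi=psi,
        seed=data_seed + 7919, b=b, hot_mask=hot_mask,
        hot_multiplier=hot_multiplier,
    )
    table, e, truth = simulate_counts(truth, table, graph, scaling, rates)
    order = {u: i for i, u in enumerate(table.unit_ids)}
    o_arr = np.array([table.observed[order[u]] for u in graph.unit_ids])
    e_arr = np.array([e.array[order[u]] for u in graph.unit_ids])
    return {
        "geoms": geoms, "table": table, "graph": graph, "scaling": scaling,
        "truth": truth, "O": o_arr, "E": e_arr, "rates": rates,
    }


def fit_lattice(
    sim,
    seed,
    *,
    chains=2,
    draws=250,
    warmup=250,
    target_accept=0.9,
):
    """Fit the BYM2 model to a simulate_lattice dataset."""
    config = SamplerConfig(
        chains=chains, draws=draws, warmup=warmup, seed=seed,
        target_accept=target_accept,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sample_posterior(
            {"O": sim["O"], "E": sim["E"]}, sim["graph"], sim["scaling"],
            config=config,
        )


@pytest.fixture(scope="session")
def small_fit():
    """One shared small posterior fit for cheap downstream tests."""
    sim = simulate_lattice(8, 8, 11, beta0=0.1, phi=0.6, tau=4.0, psi=10.0)
    return sim, fit_lattice(sim, seed=3)
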