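"""Negative binomial BYM2 hierarchical spatial model.

Observed counts O_i are modelled as negative binomial with mean
``mu_i = E_i * exp(beta0 + b_i)`` and variance ``mu + mu^2/psi``.  The
combined random effect follows the variance-scaled BYM2 convolution

    b_i = (1/sqrt(tau)) * (sqrt(1-phi) * v_i + sqrt(phi) * u_i / sqrt(c_i))

with v iid standard normal, u an intrinsic CAR (ICAR) field on the
contiguity graph identified by per-component sum-to-zero constraints,
and c_i the component scaling factor so that b has marginal prior
variance ~ 1/tau for any mixing proportion phi.  Units with no
neighbors get the unstructured term only: b_i = v_i / sqrt(tau).

Priors (configurable): beta0 ~ Normal(0, 10^2); phi ~ Beta(1, 1);
sigma = 1/sqrt(tau) ~ Exponential with P(sigma > 1) = 0.01; the
inverse dispersion 1/psi ~ Exponential(0.1).

Sampling uses the in-package No-U-Turn sampler on an unconstrained
reparameterization; the ICAR field is hard-recentered per component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import digamma, expit, gammaln

from ._nuts import nuts_sample
from .geography import AdjacencyGraph, ScalingReport

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "Bym2Spec",
    "Bym2Posterior",
    "joint_log_density",
    "sample_posterior",
    "convergence_report",
]

_ETA_CAP = 30.0  # guards exp overflow far out in the tails


@dataclass(frozen=True)
class PriorConfig:
    beta0_sd: float = 10.0
    # rate such that P(sigma > 1) = 0.01 for sigma = 1/sqrt(tau)
    sigma_rate: float = float(np.log(100.0))
    phi_a: float = 1.0
    phi_b: float = 1.0
    inv_dispersion_rate: float = 0.1
    # soft sum-to-zero scale used by joint_log_density
    constraint_scale: float = 0.001


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10
    ess_floor: float = 100.0
    rhat_threshold: float = 1.05


@dataclass(frozen=True)
class Bym2Spec:
    """A single parameter point of the model.

    ``u`` holds one value per non-singleton unit, in graph order; ``v``
    one value per unit.  All on the natural scale.
    """

    beta0: float
    tau: float
    phi: float
    psi: float
    u: np.ndarray
    v: np.ndarray
    priors: PriorConfig = field(default_factory=PriorConfig)


class _ModelArrays:
    """Precomputed index structures shared by density and gradient."""

    def __init__(self, O, E, graph: AdjacencyGraph, scaling: ScalingReport):
        O = np.asarray(O, dtype=float)
        E = np.asarray(E, dtype=float)
        n = graph.n_units
        if O.shape != (n,) or E.shape != (n,):
            raise ValueError("O and E must align with graph.unit_ids")
        if np.any(E <= 0):
            raise ValueError("expected counts must be positive")
        self.O = O
        self.E = E
        self.log_E = np.log(E)
        self.n = n

        comps = graph.components()
        pos = {u: i for i, u in enumerate(graph.unit_ids)}
        ns_units = [u for members in comps.values() if len(members) > 1
                    for u in members]
        ns_units.sort(key=pos.__getitem__)
        self.ns_units = ns_units
        self.ns_idx = np.array([pos[u] for u in ns_units], dtype=np.intp)
        self.n_ns = len(ns_units)
        self.singleton_mask = np.ones(n, dtype=bool)
        self.singleton_mask[self.ns_idx] = False

        local = {u: i for i, u in enumerate(ns_units)}
        comp_labels = sorted(c for c, m in comps.items() if len(m) > 1)
        comp_local = {c: k for k, c in enumerate(comp_labels)}
        self.n_comp = len(comp_labels)
        self.comp_of = np.array(
            [comp_local[graph.component_id[u]] for u in ns_units], dtype=np.intp
        )
        self.comp_size = np.bincount(self.comp_of, minlength=self.n_comp).astype(float)
        self.sqrt_c = np.array(
            [np.sqrt(scaling.factor[graph.component_id[u]]) for u in ns_units]
        )

        rows, cols = [], []
        for e in graph.edges:
            a, b = tuple(e)
            if a in local and b in local:
                rows.append(local[a])
                cols.append(local[b])
        i = np.array(rows + cols, dtype=np.intp)
        j = np.array(cols + rows, dtype=np.intp)
        adj = sparse.coo_matrix(
            (np.ones(i.size), (i, j)), shape=(self.n_ns, self.n_ns)
        ).tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self.laplacian = sparse.diags(deg) - adj
        self.edge_i = np.array(rows, dtype=np.intp)
        self.edge_j = np.array(cols, dtype=np.intp)

    def comp_mean(self, x: np.ndarray) -> np.ndarray:
        return np.bincount(self.comp_of, weights=x, minlength=self.n_comp) / self.comp_size

    def center(self, x: np.ndarray) -> np.ndarray:
        return x - self.comp_mean(x)[self.comp_of]

    def combined_effect(self, sigma, phi, u, v) -> np.ndarray:
        b = np.empty(self.n)
        b[self.singleton_mask] = sigma * v[self.singleton_mask]
        b[self.ns_idx] = sigma * (
            np.sqrt(1.0 - phi) * v[self.ns_idx]
            + np.sqrt(phi) * u / self.sqrt_c
        )
        return b


def _nb_loglik_terms(O, eta, psi):
    """(sum log-pmf, d/d_eta vector, d/d_psi summed)."""
    mu = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
    ll = float(np.sum(
        gammaln(O + psi) - gammaln(psi) - gammaln(O + 1.0)
        + psi * np.log(psi) - (psi + O) * np.log(psi + mu) + O * np.log(mu)
    ))
    d_eta = O - mu * (psi + O) / (psi + mu)
    d_psi = float(np.sum(
        digamma(O + psi) - digamma(psi)
        + np.log(psi) - np.log(psi + mu) + 1.0 - (psi + O) / (psi + mu)
    ))
    return ll, d_eta, d_psi


def joint_log_density(
    spec: Bym2Spec,
    data: Mapping[str, Sequence],
    graph: AdjacencyGraph,
    scaling: ScalingReport,
) -> float:
    """Log prior + log likelihood at a natural-scale parameter point.

    The prior factorizes over (beta0, sigma, phi, 1/psi, u, v) with the
    ICAR term unnormalized (improper) and per-component soft sum-to-zero
    constraints Normal(component mean of u; 0, constraint_scale).
    Points outside the parameter support return ``-inf``.
    """
    pr = spec.priors
    if not (spec.tau > 0 and spec.psi > 0 and 0.0 <= spec.phi <= 1.0):
        return -np.inf
    arr = _ModelArrays(data["O"], data["E"], graph, scaling)
    u = np.asarray(spec.u, dtype=float)
    v = np.asarray(spec.v, dtype=float)
    if u.shape != (arr.n_ns,):
        raise ValueError(f"u must have one entry per non-singleton unit ({arr.n_ns})")
    if v.shape != (arr.n,):
        raise ValueError(f"v must have one entry per unit ({arr.n})")

    sigma = 1.0 / np.sqrt(spec.tau)
    from scipy.stats import beta as beta_dist, expon, norm

    lp = 0.0
    lp += norm.logpdf(spec.beta0, 0.0, pr.beta0_sd)
    lp += expon.logpdf(sigma, scale=1.0 / pr.sigma_rate)
    lp += beta_dist.logpdf(spec.phi, pr.phi_a, pr.phi_b)
    lp += expon.logpdf(1.0 / spec.psi, scale=1.0 / pr.inv_dispersion_rate)
    lp += float(np.sum(norm.logpdf(v)))
    # improper ICAR: -1/2 sum over edges of (u_i - u_j)^2
    diff = u[arr.edge_i] - u[arr.edge_j]
    lp += -0.5 * float(np.sum(diff**2))
    lp += float(np.sum(norm.logpdf(arr.comp_mean(u), 0.0, pr.constraint_scale)))

    b = arr.combined_effect(sigma, spec.phi, u, v)
    eta = arr.log_E + spec.beta0 + b
    ll, _, _ = _nb_loglik_terms(arr.O, eta, spec.psi)
    return lp + ll


def _make_logp_grad(arr: _ModelArrays, pr: PriorConfig):
    """Unconstrained-space posterior density and gradient.

    Layout: z = [beta0, log sigma, logit phi, log psi, u_raw (n_ns), v (n)].
    The ICAR field used in the linear predictor is u_raw hard-recentered
    per component; the free component means get a standard normal prior
    purely for identification.  Hot path: shared subexpressions are
    fused and observation constants precomputed.
    """
    n, n_ns = arr.n, arr.n_ns
    lam = pr.sigma_rate
    rho = pr.inv_dispersion_rate
    a_phi, b_phi = pr.phi_a, pr.phi_b
    inv_b0_var = 1.0 / pr.beta0_sd**2
    Q = arr.laplacian
    O = arr.O
    log_E = arr.log_E
    ns_idx = arr.ns_idx
    sing = arr.singleton_mask
    inv_sqrt_c = 1.0 / arr.sqrt_c
    comp_of = arr.comp_of
    inv_comp_size = 1.0 / arr.comp_size
    n_comp = arr.n_comp
    lgam_O1 = float(np.sum(gammaln(O + 1.0)))

    def logp_and_grad(z: np.ndarray):
        beta0, s, t, r_ = z[0], z[1], z[2], z[3]
        u_raw = z[4:4 + n_ns]
        v = z[4 + n_ns:]

        sigma = np.exp(s)
        phi = expit(t)
        psi = np.exp(r_)
        sqrt1m = np.sqrt(1.0 - phi)
        sqrtphi = np.sqrt(phi)

        means = np.bincount(comp_of, weights=u_raw, minlength=n_comp) * inv_comp_size
        w = (u_raw - means[comp_of]) * inv_sqrt_c

        b = np.empty(n)
        b[sing] = v[sing]
        b[ns_idx] = sqrt1m * v[ns_idx] + sqrtphi * w
        b *= sigma
        eta = log_E + beta0 + b
        np.clip(eta, -_ETA_CAP, _ETA_CAP, out=eta)
        mu = np.exp(eta)

        psi_mu = psi + mu
        log_psi_mu = np.log(psi_mu)
        t_over = (psi + O) / psi_mu
        d_eta = O - mu * t_over

        log_psi = np.log(psi)
        ll = (
            float(np.sum(gammaln(O + psi)))
            - n * float(gammaln(psi)) - lgam_O1
            + n * psi * log_psi
            - float((psi + O) @ log_psi_mu) + float(O @ eta)
        )
        d_psi = (
            float(np.sum(digamma(O + psi)))
            - n * float(digamma(psi))
            + n * (log_psi + 1.0)
            - float(np.sum(log_psi_mu)) - float(np.sum(t_over))
        )

        Qu = Q @ u_raw
        lp = ll
        lp += -0.5 * beta0 * beta0 * inv_b0_var
        lp += -lam * sigma + s                      # sigma ~ Exp(lam), + Jacobian
        # Beta + logit Jacobian, in overflow-safe form:
        # log phi = -log(1+e^-t), log(1-phi) = -log(1+e^t)
        lp += -a_phi * np.logaddexp(0.0, -t) - b_phi * np.logaddexp(0.0, t)
        lp += -rho / psi - r_                       # 1/psi ~ Exp(rho), + Jacobian
        lp += -0.5 * (float(u_raw @ Qu) + float(means @ means) + float(v @ v))

        grad = np.empty_like(z)
        grad[0] = float(np.sum(d_eta)) - beta0 * inv_b0_var
        grad[1] = float(d_eta @ b) - lam * sigma + 1.0
        d_eta_ns = d_eta[ns_idx]
        db_dt = 0.5 * sigma * (w * (sqrtphi * (1.0 - phi))
                               - v[ns_idx] * (phi * sqrt1m))
        grad[2] = float(d_eta_ns @ db_dt) + a_phi * (1.0 - phi) - b_phi * phi
        grad[3] = psi * d_psi + rho / psi - 1.0

        g_u = d_eta_ns * ((sigma * sqrtphi) * inv_sqrt_c)
        g_u_means = np.bincount(comp_of, weights=g_u, minlength=n_comp) * inv_comp_size
        g_u -= (g_u_means + means * inv_comp_size)[comp_of]
        g_u -= Qu
        grad[4:4 + n_ns] = g_u

        g_v = d_eta * sigma
        g_v[ns_idx] *= sqrt1m
        g_v -= v
        grad[4 + n_ns:] = g_v
        return lp, grad

    return logp_and_grad


@dataclass
class Bym2Posterior:
    """Posterior draws, (chains, draws) leading axes."""

    unit_ids: tuple
    beta0: np.ndarray
    tau: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    b: np.ndarray               # (chains, draws, n_units)
    diverging: np.ndarray
    tree_depth: np.ndarray
    accept_stat: np.ndarray
    seed: int
    config: SamplerConfig

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Chain-stacked draws of a field."""
        x = getattr(self, name)
        return x.reshape(-1, *x.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={
                "beta0": self.beta0,
                "tau": self.tau,
                "phi": self.phi,
                "psi": self.psi,
                "b": self.b,
            },
            sample_stats={
                "diverging": self.diverging,
                "tree_depth": self.tree_depth,
                "acceptance_rate": self.accept_stat,
            },
            coords={"unit": list(self.unit_ids)},
            dims={"b": ["unit"]},
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long per-draw table of the scalar parameters."""
        c, d = self.beta0.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d),
            "draw": np.tile(np.arange(d), c),
            "beta0": self.flat("beta0"),
            "tau": self.flat("tau"),
            "phi": self.flat("phi"),
            "psi": self.flat("psi"),
        })


def _initial_point(arr: _ModelArrays, rng: np.random.Generator) -> np.ndarray:
    z = np.empty(4 + arr.n_ns + arr.n)
    smart_b0 = np.log(max(arr.O.sum(), 1.0) / arr.E.sum())
    z[0] = smart_b0 + 0.1 * rng.standard_normal()
    z[1] = np.log(0.3) + 0.2 * rng.standard_normal()
    z[2] = 0.5 * rng.standard_normal()
    z[3] = np.log(5.0) + 0.2 * rng.standard_normal()
    z[4:] = 0.1 * rng.standard_normal(arr.n_ns + arr.n)
    return z


def sample_posterior(
    data: Mapping[str, Sequence],
    graph: AdjacencyGraph,
    scaling: ScalingReport,
    config: Optional[SamplerConfig] = None,
    priors: Optional[PriorConfig] = None,
) -> Bym2Posterior:
    """Fit the model by NUTS; seed-reproducible, >= 2 chains.

    ``data`` maps "O" and "E" to arrays aligned with ``graph.unit_ids``.
    Warns (never errors) when split R-hat or bulk ESS of the scalar
    parameters misses the configured thresholds.
    """
    config = config or SamplerConfig()
    priors = priors or PriorConfig()
    if config.chains < 2:
        raise ValueError("at least 2 chains required")
    arr = _ModelArrays(data["O"], data["E"], graph, scaling)
    f = _make_logp_grad(arr, priors)

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        last_err = None
        for _ in range(5):
            z0 = _initial_point(arr, rng)
            lp, _ = f(z0)
            if np.isfinite(lp):
                break
            last_err = lp
        else:
            raise RuntimeError(
                f"non-finite density at initialization after retries (logp={last_err})"
            )
        chains.append(nuts_sample(
            f, z0,
            warmup=config.warmup, draws=config.draws, rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        ))

    c, d, n, n_ns = config.chains, config.draws, arr.n, arr.n_ns
    beta0 = np.stack([ch.draws[:, 0] for ch in chains])
    sigma = np.exp(np.stack([ch.draws[:, 1] for ch in chains]))
    phi = expit(np.stack([ch.draws[:, 2] for ch in chains]))
    psi = np.exp(np.stack([ch.draws[:, 3] for ch in chains]))

    b = np.empty((c, d, n))
    for k, ch in enumerate(chains):
        u_raw = ch.draws[:, 4:4 + n_ns]
        v = ch.draws[:, 4 + n_ns:]
        means = np.stack([arr.comp_mean(row) for row in u_raw])
        ucent = u_raw - means[:, arr.comp_of]
        sig = sigma[k][:, None]
        ph = phi[k][:, None]
        b[k][:, arr.singleton_mask] = sig * v[:, arr.singleton_mask]
        b[k][:, arr.ns_idx] = sig * (
            np.sqrt(1.0 - ph) * v[:, arr.ns_idx]
            + np.sqrt(ph) * ucent / arr.sqrt_c
        )

    post = Bym2Posterior(
        unit_ids=tuple(graph.unit_ids),
        beta0=beta0, tau=1.0 / sigma**2, phi=phi, psi=psi, b=b,
        diverging=np.stack([ch.diverging for ch in chains]),
        tree_depth=np.stack([ch.tree_depth for ch in chains]),
        accept_stat=np.stack([ch.accept_stat for ch in chains]),
        seed=config.seed, config=config,
    )
    report = convergence_report(post)
    bad = report[~report["pass"]]
    if len(bad):
        warnings.warn(
            "sampler diagnostics below threshold for: "
            + ", ".join(bad["parameter"].tolist()),
            stacklevel=2,
        )
    return post


def convergence_report(
    post: Bym2Posterior,
    rhat_threshold: Optional[float] = None,
    ess_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Split R-hat and bulk ESS per scalar parameter, with pass flags.

    The overall verdict is in ``df.attrs["pass"]``.
    """
    import arviz as az

    if post.n_chains < 2:
        raise ValueError("convergence report requires >= 2 chains")
    rhat_threshold = rhat_threshold or post.config.rhat_threshold
    ess_floor = ess_floor or post.config.ess_floor
    rows = []
    for name in ("beta0", "tau", "phi", "psi"):
        x = getattr(post, name)
        rhat = float(az.rhat(x))
        ess = float(az.ess(x))
        rows.append({
            "parameter": name, "rhat": rhat, "ess_bulk": ess,
            "pass": bool(rhat <= rhat_threshold and ess >= ess_floor),
        })
    df = pd.DataFrame(rows)
    df.attrs["pass"] = bool(df["pass"].all())
    df.attrs["divergences"] = int(post.diverging.sum())
    return df
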