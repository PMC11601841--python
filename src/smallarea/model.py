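"""Bayesian hierarchical spatio-temporal Poisson model, fit by MCMC.

The model is a BYM-type convolution with a first-order random-walk year
effect.  For events ``y_iat`` and person-years ``n_iat`` in area *i*, age
group *a*, year *t*:

    y_iat ~ Poisson(n_iat * lambda_iat)
    log lambda_iat = mu + alpha_a + u_i + v_i + gamma_t

with
    u      intrinsic CAR (ICAR):  p(u | tau_u) ∝ exp(-tau_u/2 * sum_{i~j} (u_i - u_j)^2),
           rank-deficient by one per connected graph component, constrained to
           sum to zero within each component;
    v_i    ~ Normal(0, 1/tau_v)          (unstructured heterogeneity);
    gamma  first-order random walk, precision tau_g, constrained to sum to zero;
    alpha  sum-to-zero age contrasts, Normal(0, sd_fixed^2) priors;
    mu     ~ Normal(0, sd_fixed^2);
    tau_*  ~ Gamma(shape, rate)          (weakly informative, proper).

Sampling is component-wise Gaussian random-walk Metropolis for mu, alpha, u,
v and gamma, with conjugate Gibbs draws for the three precisions.  Proposal
SDs adapt toward 0.44 acceptance during burn-in and are then frozen, so the
post-burn-in kernel leaves the posterior invariant.  Constrained blocks are
re-centered after each block sweep, the subtracted mean being absorbed into
``mu`` (exact on a connected graph; per-component means are absorbed through
the area-weighted average on archipelagos).

Updates are applied in a canonical order (sorted area ids) with proposal
noise assigned by canonical position, so permuting the storage order of
areas permutes the posterior draws but does not change them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geography import AreaGraph
from .synthetic import stream

logger = logging.getLogger(__name__)

SUM_TOL = 1e-10


# ---------------------------------------------------------------------------
# specification and state


@dataclass
class ModelSpec:
    age_groups: tuple[str, ...]
    years: tuple[int, ...]
    use_spatial: bool = True
    use_temporal: bool = True
    prior_shape: float = 1.0  # Gamma hyperprior on precisions
    prior_rate: float = 0.01
    fixed_effect_sd: float = 10.0
    chains: int = 2
    iterations: int = 11000
    burn_in: int = 1000
    thin: int = 10
    init_proposal_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_shape <= 0 or self.prior_rate <= 0:
            raise ValueError("hyperprior shape and rate must be > 0")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def n_ages(self) -> int:
        return len(self.age_groups)

    @property
    def n_years(self) -> int:
        return len(self.years) if self.use_temporal else 1


@dataclass
class ModelState:
    """All latent parameters at one MCMC iteration."""

    mu: float
    alpha: np.ndarray  # per age group, sum-to-zero
    u: np.ndarray  # spatially structured, sum-to-zero per component
    v: np.ndarray  # unstructured
    gamma: np.ndarray  # per year, sum-to-zero
    tau_u: float
    tau_v: float
    tau_g: float

    def validate(self, graph: AreaGraph, atol: float = 1e-8) -> None:
        if min(self.tau_u, self.tau_v, self.tau_g) <= 0:
            raise ValueError("precisions must be strictly positive")
        if abs(self.alpha.sum()) > atol:
            raise ValueError("alpha must sum to zero")
        if len(self.gamma) > 1 and abs(self.gamma.sum()) > atol:
            raise ValueError("gamma must sum to zero")
        for comp in graph.components:
            if abs(self.u[comp].sum()) > atol:
                raise ValueError("u must sum to zero within each graph component")

    def copy(self) -> "ModelState":
        return ModelState(
            self.mu,
            self.alpha.copy(),
            self.u.copy(),
            self.v.copy(),
            self.gamma.copy(),
            self.tau_u,
            self.tau_v,
            self.tau_g,
        )


@dataclass
class ModelData:
    """Events and exposures as dense (areas x ages x years) tensors."""

    y: np.ndarray
    n: np.ndarray

    @classmethod
    def from_query(cls, df: pd.DataFrame, graph: AreaGraph, spec: ModelSpec) -> "ModelData":
        """Pivot one (site, outcome, stratum) query slice into tensors.

        With ``use_temporal`` off, years are collapsed by summing events and
        person-years (the year-range fit).
        """
        if (df["person_years"] < 0).any():
            raise ValueError("person_years must be >= 0")
        aidx = {a: i for i, a in enumerate(graph.area_ids)}
        gidx = {g: i for i, g in enumerate(spec.age_groups)}
        unknown = set(df["area_id"]) - set(aidx)
        if unknown:
            raise ValueError(f"areas absent from the graph: {sorted(unknown)[:5]}")
        T = spec.n_years
        y = np.zeros((graph.n_areas, spec.n_ages, T))
        n = np.zeros_like(y)
        if spec.use_temporal:
            tidx = {t: i for i, t in enumerate(spec.years)}
            it = df["year"].map(tidx).to_numpy()
        else:
            it = np.zeros(len(df), dtype=int)
        ii = df["area_id"].map(aidx).to_numpy()
        ia = df["age_group"].map(gidx).to_numpy()
        np.add.at(y, (ii, ia, it), df["events"].to_numpy(dtype=float))
        np.add.at(n, (ii, ia, it), df["person_years"].to_numpy(dtype=float))
        if n.sum() == 0:
            raise ValueError("no population at risk: all person_years are zero")
        return cls(y=y, n=n)


def initial_state(data: ModelData, graph: AreaGraph, spec: ModelSpec) -> ModelState:
    ytot, ntot = data.y.sum(), data.n.sum()
    mu0 = math.log(ytot / ntot) if ytot > 0 else math.log(0.5 / ntot)
    return ModelState(
        mu=mu0,
        alpha=np.zeros(spec.n_ages),
        u=np.zeros(graph.n_areas),
        v=np.zeros(graph.n_areas),
        gamma=np.zeros(spec.n_years),
        tau_u=10.0,
        tau_v=10.0,
        tau_g=10.0,
    )


# ---------------------------------------------------------------------------
# densities


def _icar_quadform(u: np.ndarray, graph: AreaGraph) -> float:
    q = 0.0
    for i, j in graph.edges:
        d = u[i] - u[j]
        q += d * d
    return q


def log_posterior(
    state: ModelState, data: ModelData, graph: AreaGraph, spec: ModelSpec
) -> float:
    """Log of the unnormalized posterior density.

    The Poisson terms include the ``-log y!`` constant; the ICAR density uses
    its pseudo-determinant rank ``(I - C)/2`` power of tau_u; the RW1 density
    is the product of the T-1 increment normals.  Constant choices are shared
    with any external oracle through this definition.
    """
    state.validate(graph)
    mu, alpha, u, v, gamma = state.mu, state.alpha, state.u, state.v, state.gamma
    eta = (
        mu
        + alpha[None, :, None]
        + (u + v)[:, None, None]
        + gamma[None, None, :]
    )
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    mask = data.n > 0
    lam = np.exp(eta)
    ll = float(
        (
            data.y[mask] * (np.log(data.n[mask]) + eta[mask])
            - data.n[mask] * lam[mask]
            - gammaln(data.y[mask] + 1.0)
        ).sum()
    )
    sd0 = spec.fixed_effect_sd
    lp = -0.5 * (mu**2) / sd0**2 - 0.5 * math.log(2 * math.pi * sd0**2)
    lp += float(
        (-0.5 * alpha**2 / sd0**2 - 0.5 * math.log(2 * math.pi * sd0**2)).sum()
    )
    a0, b0 = spec.prior_shape, spec.prior_rate
    if spec.use_spatial:
        rank = graph.n_areas - graph.n_components
        lp += 0.5 * rank * (math.log(state.tau_u) - math.log(2 * math.pi))
        lp += -0.5 * state.tau_u * _icar_quadform(u, graph)
        lp += _gamma_logpdf(state.tau_u, a0, b0)
    lp += float(
        (0.5 * (math.log(state.tau_v) - math.log(2 * math.pi)) - 0.5 * state.tau_v * v**2).sum()
    )
    lp += _gamma_logpdf(state.tau_v, a0, b0)
    T = len(gamma)
    if T > 1:
        diff = np.diff(gamma)
        lp += 0.5 * (T - 1) * (math.log(state.tau_g) - math.log(2 * math.pi))
        lp += -0.5 * state.tau_g * float((diff**2).sum())
        lp += _gamma_logpdf(state.tau_g, a0, b0)
    return ll + lp


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1) * math.log(x) - rate * x


def precision_posterior_params(
    state: ModelState, graph: AreaGraph, spec: ModelSpec
) -> dict[str, tuple[float, float]]:
    """Conjugate Gamma(shape, rate) full-conditional parameters for the
    three precisions; the ICAR shape uses the rank deficiency C (one per
    connected component)."""
    a0, b0 = spec.prior_shape, spec.prior_rate
    I = graph.n_areas
    C = graph.n_components
    out = {
        "tau_u": (a0 + 0.5 * (I - C), b0 + 0.5 * _icar_quadform(state.u, graph)),
        "tau_v": (a0 + 0.5 * I, b0 + 0.5 * float((state.v**2).sum())),
    }
    T = len(state.gamma)
    if T > 1:
        qf = float((np.diff(state.gamma) ** 2).sum())
        out["tau_g"] = (a0 + 0.5 * (T - 1), b0 + 0.5 * qf)
    return out


def gibbs_update_precisions(
    state: ModelState,
    data: ModelData,
    graph: AreaGraph,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> ModelState:
    """Draw tau_u, tau_v, tau_g from their conjugate Gamma full conditionals."""
    params = precision_posterior_params(state, graph, spec)
    new = state.copy()
    if spec.use_spatial:
        a, b = params["tau_u"]
        new.tau_u = float(rng.gamma(a, 1.0 / b))
    a, b = params["tau_v"]
    new.tau_v = float(rng.gamma(a, 1.0 / b))
    if "tau_g" in params:
        a, b = params["tau_g"]
        new.tau_g = float(rng.gamma(a, 1.0 / b))
    return new


# ---------------------------------------------------------------------------
# sampler


class Sampler:
    """Metropolis-within-Gibbs engine with cached sufficient statistics.

    The Poisson expectation factorizes as
    ``n_iat * exp(mu) * exp(alpha_a) * exp(u_i + v_i) * exp(gamma_t)``, so
    per-parameter likelihood deltas reduce to a handful of scalar operations
    against the cached contractions ``nG = sum_t n*G``, ``nA = sum_a n*A``
    and ``S = sum_{a,t} n*A*G``.
    """

    def __init__(
        self, data: ModelData, graph: AreaGraph, spec: ModelSpec, state: ModelState | None = None
    ):
        self.data = data
        self.graph = graph
        self.spec = spec
        self.I, self.A, self.T = data.y.shape
        # Everything runs in canonical area order (sorted ids): every
        # cross-area reduction then has a storage-order-independent
        # summation order, so permuting area storage permutes the draws
        # bit-exactly.
        self.cperm = sorted(range(self.I), key=lambda i: graph.area_ids[i])
        inv = {s: c for c, s in enumerate(self.cperm)}
        self.inv = np.array([inv[i] for i in range(self.I)])
        self.y = data.y[self.cperm]
        self.n = data.n[self.cperm]
        self.y_area = self.y.sum(axis=(1, 2))
        self.y_age = self.y.sum(axis=(0, 2))
        self.y_year = self.y.sum(axis=(0, 1))
        self.y_tot = float(self.y.sum())
        storage_nbrs = graph.neighbors()
        self.nbrs = [
            sorted(int(self.inv[j]) for j in storage_nbrs[s]) for s in self.cperm
        ]
        self.deg = np.array([len(a) for a in self.nbrs], dtype=float)
        self.edges = sorted(
            (min(self.inv[i], self.inv[j]), max(self.inv[i], self.inv[j]))
            for i, j in graph.edges
        )
        self.comps = sorted(
            (sorted(int(self.inv[i]) for i in comp) for comp in graph.components),
            key=lambda c: c[0],
        )
        st = state.copy() if state is not None else initial_state(data, graph, spec)
        st.validate(graph)
        self._st = ModelState(
            st.mu, st.alpha.copy(), st.u[self.cperm], st.v[self.cperm],
            st.gamma.copy(), st.tau_u, st.tau_v, st.tau_g,
        )
        s0 = spec.init_proposal_sd
        self.s_mu = s0
        self.s_alpha = np.full(self.A, s0)
        self.s_u = np.full(self.I, s0)
        self.s_v = np.full(self.I, s0)
        self.s_gamma = np.full(self.T, s0)
        self._n_params = 1 + self.A + 2 * self.I + (self.T if self.T > 1 else 0)
        self.accept_counts = {"mu": 0, "alpha": 0, "u": 0, "v": 0, "gamma": 0}
        self.proposal_counts = {"mu": 0, "alpha": 0, "u": 0, "v": 0, "gamma": 0}
        self._batch_acc = np.zeros(self._n_params)
        self._batch_n = 0
        self._adapt_round = 0
        self._refresh_cache()

    # -- caches ------------------------------------------------------------

    @property
    def state(self) -> ModelState:
        """Current state mapped back to the graph's storage order."""
        st = self._st
        u = np.empty(self.I)
        v = np.empty(self.I)
        u[self.cperm] = st.u
        v[self.cperm] = st.v
        return ModelState(
            st.mu, st.alpha.copy(), u, v, st.gamma.copy(),
            st.tau_u, st.tau_v, st.tau_g,
        )

    def _refresh_cache(self) -> None:
        st = self._st
        self.Aexp = np.exp(st.alpha)
        self.Gexp = np.exp(st.gamma) if self.T > 1 else np.ones(1)
        self.M = np.exp(st.u + st.v)
        self.emu = math.exp(st.mu)
        self.nG = self.n @ self.Gexp  # (I, A)
        self.nA = np.einsum("iat,a->it", self.n, self.Aexp)  # (I, T)
        self.S = self.nG @ self.Aexp  # (I,)

    # -- one sweep ---------------------------------------------------------

    def sweep(self, rng: np.random.Generator, adapt: bool = False, count: bool = True) -> None:
        z = rng.standard_normal(self._n_params)
        lnu = np.log(rng.random(self._n_params))
        st = self._st
        acc = np.zeros(self._n_params) if adapt else None
        p = 0

        # mu
        delta = self.s_mu * z[p]
        SM = float(self.M @ self.S)
        dll = self.y_tot * delta - self.emu * SM * math.expm1(delta)
        dlp = -0.5 * ((st.mu + delta) ** 2 - st.mu**2) / self.spec.fixed_effect_sd**2
        if count:
            self.proposal_counts["mu"] += 1
        if lnu[p] < dll + dlp:
            st.mu += delta
            self.emu = math.exp(st.mu)
            if adapt:
                acc[p] = 1
            if count:
                self.accept_counts["mu"] += 1
        p += 1

        # age effects
        sd0sq = self.spec.fixed_effect_sd**2
        for a in range(self.A):
            delta = self.s_alpha[a] * z[p]
            Pa = float(self.M @ self.nG[:, a]) * self.Aexp[a]
            dll = self.y_age[a] * delta - self.emu * Pa * math.expm1(delta)
            dlp = -0.5 * ((st.alpha[a] + delta) ** 2 - st.alpha[a] ** 2) / sd0sq
            if count:
                self.proposal_counts["alpha"] += 1
            if lnu[p] < dll + dlp:
                st.alpha[a] += delta
                dA = self.Aexp[a] * math.expm1(delta)
                self.nA += self.n[:, a, :] * dA
                self.S += self.nG[:, a] * dA
                self.Aexp[a] += dA
                if adapt:
                    acc[p] = 1
                if count:
                    self.accept_counts["alpha"] += 1
            p += 1
        c = float(st.alpha.mean())
        if c != 0.0:
            st.alpha -= c
            st.mu += c
            self._refresh_cache()

        # spatial effects
        if self.spec.use_spatial:
            u = st.u
            for i in range(self.I):
                delta = self.s_u[i] * z[p]
                nb = 0.0
                for j in self.nbrs[i]:
                    nb += u[j]
                dll = self.y_area[i] * delta - self.emu * self.M[i] * self.S[i] * math.expm1(delta)
                dlp = -st.tau_u * (0.5 * delta * delta * self.deg[i] + delta * (self.deg[i] * u[i] - nb))
                if count:
                    self.proposal_counts["u"] += 1
                if lnu[p] < dll + dlp:
                    u[i] += delta
                    self.M[i] *= math.exp(delta)
                    if adapt:
                        acc[p] = 1
                    if count:
                        self.accept_counts["u"] += 1
                p += 1
            shift = 0.0
            for comp in self.comps:
                ck = float(u[comp].mean())
                u[comp] -= ck
                shift += ck * len(comp)
            st.mu += shift / self.I
            self._refresh_cache()
        else:
            p += self.I

        # unstructured effects
        v = st.v
        for i in range(self.I):
            delta = self.s_v[i] * z[p]
            dll = self.y_area[i] * delta - self.emu * self.M[i] * self.S[i] * math.expm1(delta)
            dlp = -st.tau_v * (v[i] * delta + 0.5 * delta * delta)
            if count:
                self.proposal_counts["v"] += 1
            if lnu[p] < dll + dlp:
                v[i] += delta
                self.M[i] *= math.exp(delta)
                if adapt:
                    acc[p] = 1
                if count:
                    self.accept_counts["v"] += 1
            p += 1

        # year effects (random walk)
        if self.T > 1:
            g = st.gamma
            for t in range(self.T):
                delta = self.s_gamma[t] * z[p]
                Qt = float(self.M @ self.nA[:, t]) * self.Gexp[t]
                dll = self.y_year[t] * delta - self.emu * Qt * math.expm1(delta)
                dlp = 0.0
                if t > 0:
                    d0 = g[t] - g[t - 1]
                    dlp -= 0.5 * st.tau_g * ((d0 + delta) ** 2 - d0 * d0)
                if t < self.T - 1:
                    d1 = g[t + 1] - g[t]
                    dlp -= 0.5 * st.tau_g * ((d1 - delta) ** 2 - d1 * d1)
                if count:
                    self.proposal_counts["gamma"] += 1
                if lnu[p] < dll + dlp:
                    g[t] += delta
                    dG = self.Gexp[t] * math.expm1(delta)
                    self.nG += self.n[:, :, t] * dG
                    self.S += self.nA[:, t] * dG
                    self.Gexp[t] += dG
                    if adapt:
                        acc[p] = 1
                    if count:
                        self.accept_counts["gamma"] += 1
                p += 1
            c = float(g.mean())
            if c != 0.0:
                g -= c
                st.mu += c
                self._refresh_cache()

        if adapt:
            self._batch_acc += acc
            self._batch_n += 1
            if self._batch_n == 50:
                self._adapt_round += 1
                step = min(0.05, 1.0 / math.sqrt(self._adapt_round))
                rates = self._batch_acc / self._batch_n
                self._adapt_sds(rates, step)
                self._batch_acc[:] = 0.0
                self._batch_n = 0

    def _adapt_sds(self, rates: np.ndarray, step: float) -> None:
        def adj(s, r):
            return s * math.exp(step if r > 0.44 else -step)

        p = 0
        self.s_mu = adj(self.s_mu, rates[p])
        p += 1
        for a in range(self.A):
            self.s_alpha[a] = adj(self.s_alpha[a], rates[p])
            p += 1
        for i in range(self.I):
            self.s_u[i] = adj(self.s_u[i], rates[p])
            p += 1
        for i in range(self.I):
            self.s_v[i] = adj(self.s_v[i], rates[p])
            p += 1
        if self.T > 1:
            for t in range(self.T):
                self.s_gamma[t] = adj(self.s_gamma[t], rates[p])
                p += 1

    def gibbs_precisions(self, rng: np.random.Generator) -> None:
        """Conjugate precision draws, with quadratic forms accumulated in
        canonical order (matches :func:`gibbs_update_precisions`)."""
        st = self._st
        a0, b0 = self.spec.prior_shape, self.spec.prior_rate
        if self.spec.use_spatial:
            qf = 0.0
            for i, j in self.edges:
                d = st.u[i] - st.u[j]
                qf += d * d
            shape = a0 + 0.5 * (self.I - len(self.comps))
            st.tau_u = float(rng.gamma(shape, 1.0 / (b0 + 0.5 * qf)))
        shape = a0 + 0.5 * self.I
        st.tau_v = float(rng.gamma(shape, 1.0 / (b0 + 0.5 * float((st.v**2).sum()))))
        if self.T > 1:
            qf = float((np.diff(st.gamma) ** 2).sum())
            shape = a0 + 0.5 * (self.T - 1)
            st.tau_g = float(rng.gamma(shape, 1.0 / (b0 + 0.5 * qf)))


def metropolis_sweep(
    state: ModelState,
    data: ModelData,
    graph: AreaGraph,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> ModelState:
    """One full component-wise Metropolis sweep (no precision update);
    returns a new state, leaving the input untouched."""
    s = Sampler(data, graph, spec, state)
    s.sweep(rng, adapt=False)
    return s.state


# ---------------------------------------------------------------------------
# posterior container and fit


@dataclass
class PosteriorDraws:
    """Retained samples per chain, with convergence and sampler diagnostics."""

    mu: np.ndarray  # (chains, draws)
    alpha: np.ndarray  # (chains, draws, ages)
    u: np.ndarray  # (chains, draws, areas)
    v: np.ndarray  # (chains, draws, areas)
    gamma: np.ndarray  # (chains, draws, years)
    tau_u: np.ndarray
    tau_v: np.ndarray
    tau_g: np.ndarray
    spec: ModelSpec
    seed: int
    acceptance_rates: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    area_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws with chains stacked: shape (chains*draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def log_rate_draws(self, year: int | None = None) -> np.ndarray:
        """Per-draw, per-area, per-age log rates (chains stacked):
        shape (draws, areas, ages).  ``year`` selects the year effect; None
        uses zero (the year-centered / year-collapsed reference)."""
        mu = self.flat("mu")[:, None, None]
        alpha = self.flat("alpha")[:, None, :]
        uv = (self.flat("u") + self.flat("v"))[:, :, None]
        if year is not None and self.spec.use_temporal:
            ti = list(self.spec.years).index(year)
            g = self.flat("gamma")[:, ti][:, None, None]
        else:
            g = 0.0
        return mu + alpha + uv + g


def split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``x`` has shape (chains, draws); each chain is split in half, giving 2C
    sequences of length D//2.
    """
    C, D = x.shape
    half = D // 2
    if half < 2:
        return float("nan")
    parts = x[:, : 2 * half].reshape(C * 2, half)
    W = float(parts.var(axis=1, ddof=1).mean())
    B = half * float(parts.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return math.sqrt(var_plus / W)


def fit(data, graph: AreaGraph, spec: ModelSpec) -> PosteriorDraws:
    """Run the MCMC: independent chains from distinct substreams of
    ``spec.seed``, burn-in with proposal adaptation, then thinned retention.

    ``data`` is either a :class:`ModelData` or a query DataFrame from
    :meth:`RegistryTable.query`.
    """
    if isinstance(data, pd.DataFrame):
        if data.empty:
            raise ValueError("no data cells for this query")
        data = ModelData.from_query(data, graph, spec)
    keep = (spec.iterations - spec.burn_in) // spec.thin
    shp = (spec.chains, keep)
    out = PosteriorDraws(
        mu=np.empty(shp),
        alpha=np.empty(shp + (spec.n_ages,)),
        u=np.empty(shp + (graph.n_areas,)),
        v=np.empty(shp + (graph.n_areas,)),
        gamma=np.empty(shp + (spec.n_years,)),
        tau_u=np.empty(shp),
        tau_v=np.empty(shp),
        tau_g=np.empty(shp),
        spec=spec,
        seed=spec.seed,
        area_ids=list(graph.area_ids),
    )
    acc: dict[str, list] = {}
    for c in range(spec.chains):
        rng = stream(spec.seed, "chain", c)
        sampler = Sampler(data, graph, spec)
        k = 0
        for it in range(spec.iterations):
            warm = it < spec.burn_in
            sampler.sweep(rng, adapt=warm, count=not warm)
            sampler.gibbs_precisions(rng)
            if not warm and (it - spec.burn_in) % spec.thin == spec.thin - 1 and k < keep:
                st = sampler.state
                out.mu[c, k] = st.mu
                out.alpha[c, k] = st.alpha
                out.u[c, k] = st.u
                out.v[c, k] = st.v
                out.gamma[c, k] = st.gamma
                out.tau_u[c, k] = st.tau_u
                out.tau_v[c, k] = st.tau_v
                out.tau_g[c, k] = st.tau_g
                k += 1
        sampler.state.validate(graph, atol=SUM_TOL)
        for block in sampler.accept_counts:
            n = sampler.proposal_counts[block]
            if n:
                acc.setdefault(block, []).append(sampler.accept_counts[block] / n)
    out.acceptance_rates = {k: float(np.mean(v)) for k, v in acc.items()}
    monitored = {"mu": out.mu, "tau_v": out.tau_v}
    if spec.use_spatial:
        monitored["tau_u"] = out.tau_u
    if spec.n_years > 1:
        monitored["tau_g"] = out.tau_g
    pick = stream(spec.seed, "rhat").choice(
        graph.n_areas, size=min(3, graph.n_areas), replace=False
    )
    if spec.use_spatial:
        for i in pick:
            monitored[f"u[{graph.area_ids[i]}]"] = out.u[:, :, i]
    out.rhat = {k: split_rhat(v) for k, v in monitored.items()}
    logger.info("acceptance rates: %s", out.acceptance_rates)
    logger.info("split-Rhat: %s", out.rhat)
    return out


# ---------------------------------------------------------------------------
# serialization


def save_draws(draws: PosteriorDraws, csv_path, meta_path) -> None:
    """Wide columnar CSV (one row per chain x retained draw) plus a JSON
    metadata sidecar with the spec echo, seed, acceptance rates and R-hat."""
    C, D = draws.mu.shape
    cols: dict[str, np.ndarray] = {
        "chain": np.repeat(np.arange(C), D),
        "draw": np.tile(np.arange(D), C),
        "mu": draws.flat("mu"),
        "tau_u": draws.flat("tau_u"),
        "tau_v": draws.flat("tau_v"),
        "tau_g": draws.flat("tau_g"),
    }
    for a, label in enumerate(draws.spec.age_groups):
        cols[f"alpha[{label}]"] = draws.flat("alpha")[:, a]
    for i, aid in enumerate(draws.area_ids):
        cols[f"u[{aid}]"] = draws.flat("u")[:, i]
        cols[f"v[{aid}]"] = draws.flat("v")[:, i]
    for t in range(draws.gamma.shape[2]):
        label = draws.spec.years[t] if draws.spec.use_temporal else "all"
        cols[f"gamma[{label}]"] = draws.flat("gamma")[:, t]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "model": "poisson log-linear; BYM convolution (ICAR + iid) + RW1 year effect",
        "seed": draws.seed,
        "area_ids": draws.area_ids,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(draws.spec).items()
        },
        "acceptance_rates": draws.acceptance_rates,
        "rhat": draws.rhat,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_draws(csv_path, meta_path) -> PosteriorDraws:
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    sp = dict(meta["spec"])
    for k in ("age_groups", "years"):
        sp[k] = tuple(sp[k])
    spec = ModelSpec(**sp)
    area_ids = list(meta["area_ids"])
    C = int(df["chain"].max()) + 1
    D = len(df) // C

    def grab(names):
        return np.stack([df[n].to_numpy().reshape(C, D) for n in names], axis=-1)

    draws = PosteriorDraws(
        mu=df["mu"].to_numpy().reshape(C, D),
        alpha=grab([f"alpha[{g}]" for g in spec.age_groups]),
        u=grab([f"u[{a}]" for a in area_ids]),
        v=grab([f"v[{a}]" for a in area_ids]),
        gamma=grab(
            [f"gamma[{y}]" for y in spec.years] if spec.use_temporal else ["gamma[all]"]
        ),
        tau_u=df["tau_u"].to_numpy().reshape(C, D),
        tau_v=df["tau_v"].to_numpy().reshape(C, D),
        tau_g=df["tau_g"].to_numpy().reshape(C, D),
        spec=spec,
        seed=meta["seed"],
        acceptance_rates=meta.get("acceptance_rates", {}),
        rhat=meta.get("rhat", {}),
        area_ids=area_ids,
    )
    return draws
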