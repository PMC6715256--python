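"""Likelihood of msh observations given the first coalescent time t_c.

The model: looking out from a focal base, the distance to the first
mutation or recombination event on the focal branch (length t_c) or its
sister branch (length phi) is exponential with rate proportional to
t_c + phi.  Marginalizing phi over its coalescent density gives, for a
diploid population of constant size N and sample size n,

    p(phi) = n / (4N + n t_c)          for 0 <= phi < t_c, plus a point
    mass 1 - n t_c / (4N + n t_c)      at phi = t_c (single sister).

The per-copy likelihood of the composite statistic chi (see
``mshtc.genetic_map.compose_chi``) is

    p(chi | t_c) = int_0^tc p(phi) beta (t_c+phi)^2 e^{-chi (t_c+phi)} dphi
                   + p(phi = t_c) beta (2 t_c)^2 e^{-2 chi t_c}

for two complete msh tracts, with the single-event kernel
``beta_eoc (t_c+phi) e^{-chi(t_c+phi)}`` when one direction is truncated
at the end of the chromosome, and a pure no-event kernel when both are.
The constant-N integral has a closed form; it is evaluated here in log
space through the stable auxiliary integrals
``E_m(t) = int_0^1 s^m e^{-t s} ds`` so that it stays accurate from
chi*t_c -> 0 up to extreme tail values.  An adaptive-quadrature path is
retained both as a cross-check and for tabulated (non-constant)
demographies.

Estimation maximizes the composite log likelihood (summed over the k
copies of an allele, plus the derived-allele mutation factor
``1 - e^{-mu t_c}`` applied once per allele) over log10(t_c) with bounded
Brent search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .genetic_map import (DOUBLE_TRUNCATED, ONE_SIDED, TWO_SIDED, ChiStat,
                          GeneticMap, compose_chi)

DEFAULT_MU = 1e-8   # mutations / bp / generation
DEFAULT_N0 = 1e4    # diploid effective size


@dataclass
class DemographyModel:
    """Constant-size or tabulated N(t) history (t = generations ago).

    For tabulated mode supply ``size_fn`` mapping generations-before-
    sampling to diploid effective size; the coalescent intensity
    ``tau(t) = int_0^t dt' / (2 N(t'))`` is then computed by quadrature.
    """

    mode: str = "constant"
    N0: float = DEFAULT_N0
    size_fn: object = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "tabulated"):
            raise ValueError("mode must be 'constant' or 'tabulated'")
        if self.mode == "tabulated" and self.size_fn is None:
            raise ValueError("tabulated mode needs size_fn")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")

    def size(self, t: float) -> float:
        if self.mode == "constant":
            return self.N0
        N = float(self.size_fn(t))
        if N <= 0:
            raise ValueError(f"non-positive population size at t={t}")
        return N

    def tau(self, t: float) -> float:
        if self.mode == "constant":
            return t / (2.0 * self.N0)
        val, _ = integrate.quad(lambda u: 1.0 / (2.0 * self.size(u)), 0.0, t,
                                limit=200)
        return val

    def n_branches(self, t: float, n: int) -> float:
        """Expected lineages ancestral to the sample t generations ago."""
        return n / (1.0 + 0.5 * n * self.tau(t))


# ---------------------------------------------------------------------------
# phi (sister-branch length) density


def phi_density_constantN(phi, tc, n, N):
    """Continuous part of p(phi): n/(4N + n t_c) on [0, t_c), 0 outside."""
    if tc <= 0 or n < 2 or N <= 0:
        raise ValueError("need tc > 0, n >= 2, N > 0")
    phi = np.asarray(phi, dtype=float)
    dens = np.where((phi >= 0) & (phi < tc), n / (4.0 * N + n * tc), 0.0)
    return dens if dens.ndim else float(dens)


def phi_point_mass_constantN(tc, n, N):
    """Mass at phi = t_c (the focal chromosome has a single sister)."""
    if tc < 0 or n < 2 or N <= 0:
        raise ValueError("need tc >= 0, n >= 2, N > 0")
    return 1.0 - n * tc / (4.0 * N + n * tc)


def _hazard(phi, tc, n, demography: DemographyModel):
    # coalescence rate along one branch, forward in time from t_c
    t = tc - phi
    return n / (2.0 * demography.size(t) * (2.0 + n * demography.tau(t)))


def phi_density_numeric(phi, tc, n, demography: DemographyModel):
    """Continuous part of p(phi) by hazard integration (any demography).

    Uses the identity survivor(phi) = n_branches(t_c) / n_branches(t_c-phi)
    that follows from the lineage-count approximation, so no inner
    quadrature of the hazard is needed.  Reduces exactly to the constant-N
    closed form when the demography is constant.
    """
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    nb_tc = demography.n_branches(tc, n)
    out = np.zeros_like(phi_arr)
    for i, p in enumerate(phi_arr):
        if 0 <= p < tc:
            out[i] = _hazard(p, tc, n, demography) * \
                nb_tc / demography.n_branches(tc - p, n)
    return out if np.ndim(phi) else float(out[0])


def phi_point_mass_numeric(tc, n, demography: DemographyModel):
    """Residual mass at phi = t_c: survivor of the whole branch."""
    return demography.n_branches(tc, n) / n


# ---------------------------------------------------------------------------
# stable closed forms (constant N)


def _em(t, m):
    """E_m(t) = int_0^1 s^m e^{-t s} ds for m in {0, 1, 2}, t >= 0.

    Series below t = 0.1 (the closed forms cancel catastrophically as
    t -> 0), expm1-based closed forms above.
    """
    t = np.asarray(t, dtype=float)
    small = t < 0.1
    ts = np.where(small, t, 0.0)
    series = np.zeros_like(ts)
    term = np.ones_like(ts)
    for j in range(18):
        series += term / (m + j + 1)
        term *= -ts / (j + 1)
    tb = np.where(small, 1.0, t)  # safe divisor
    if m == 0:
        closed = -np.expm1(-tb) / tb
    elif m == 1:
        closed = (-np.expm1(-tb) - tb * np.exp(-tb)) / tb ** 2
    else:
        closed = (-2.0 * np.expm1(-tb) - tb * (tb + 2.0) * np.exp(-tb)) / tb ** 3
    return np.where(small, series, closed)


def loglik_arrays(chi, beta, kind, tc, n, N):
    """log p(chi | t_c) for arrays of per-copy statistics (constant N).

    ``chi``, ``beta``, ``kind`` broadcast against ``tc``; typical use is
    ``chi[:, None]`` against a 1-D grid of ``tc`` values, or scalar ``tc``.
    """
    chi = np.asarray(chi, dtype=float)
    beta = np.asarray(beta, dtype=float)
    kind = np.asarray(kind)
    tc_arr = np.asarray(tc, dtype=float)
    if np.any(tc_arr <= 0):
        raise ValueError("tc must be positive")
    if np.any(chi < 0):
        raise ValueError("chi must be non-negative")

    t = chi * tc_arr
    log_tc = np.log(tc_arr)
    log_denom = np.log(4.0 * N + n * tc_arr)
    log_f = np.log(n) - log_denom           # continuous phi density
    log_mass = np.log(4.0 * N) - log_denom  # point mass at phi = t_c
    with np.errstate(divide="ignore"):
        log_beta = np.log(beta)

    e0, e1, e2 = _em(t, 0), _em(t, 1), _em(t, 2)
    # integral and point-mass terms for each kernel
    log_int_two = log_f + log_beta + 3.0 * log_tc - t + np.log(e0 + 2.0 * e1 + e2)
    log_pm_two = log_mass + log_beta + np.log(4.0) + 2.0 * log_tc - 2.0 * t
    log_int_one = log_f + log_beta + 2.0 * log_tc - t + np.log(e0 + e1)
    log_pm_one = log_mass + log_beta + np.log(2.0) + log_tc - 2.0 * t
    log_int_dbl = log_f + log_tc - t + np.log(e0)
    log_pm_dbl = log_mass - 2.0 * t

    log_int = np.where(kind == TWO_SIDED, log_int_two,
                       np.where(kind == ONE_SIDED, log_int_one, log_int_dbl))
    log_pm = np.where(kind == TWO_SIDED, log_pm_two,
                      np.where(kind == ONE_SIDED, log_pm_one, log_pm_dbl))
    return np.logaddexp(log_int, log_pm)


def loglik_two_sided(chi, beta, tc, n, N):
    """log p(chi | t_c), both msh tracts complete (closed form)."""
    return float(loglik_arrays(chi, beta, TWO_SIDED, tc, n, N))


def loglik_one_sided_eoc(chi_eoc, beta_eoc, tc, n, N):
    """log p(chi_eoc | t_c), one tract truncated at the chromosome end."""
    return float(loglik_arrays(chi_eoc, beta_eoc, ONE_SIDED, tc, n, N))


# ---------------------------------------------------------------------------
# quadrature cross-check / tabulated-demography path


def loglik_quad(chi, beta, kind, tc, n, N=None,
                demography: DemographyModel | None = None):
    """log p(chi | t_c) by adaptive quadrature of the defining integral.

    Independent of the closed form; also the estimation path for tabulated
    demographies.  Scalar arguments only.
    """
    if tc <= 0:
        raise ValueError("tc must be positive")
    if demography is None:
        demography = DemographyModel(N0=N)
    if demography.mode == "constant":
        dens = lambda p: phi_density_constantN(p, tc, n, demography.N0)
        mass = phi_point_mass_constantN(tc, n, demography.N0)
    else:
        dens = lambda p: phi_density_numeric(p, tc, n, demography)
        mass = phi_point_mass_numeric(tc, n, demography)

    if kind == TWO_SIDED:
        kern = lambda u: beta * u * u * np.exp(-chi * u)
    elif kind == ONE_SIDED:
        kern = lambda u: beta * u * np.exp(-chi * u)
    else:
        kern = lambda u: np.exp(-chi * u)
    val, _ = integrate.quad(lambda p: dens(p) * kern(tc + p), 0.0, tc,
                            limit=400)
    val += mass * kern(2.0 * tc)
    if val <= 0:
        return -np.inf
    return float(np.log(val))


# ---------------------------------------------------------------------------
# composite likelihood and optimization


def singleton_mutation_factor(tc, mu):
    """P(at least one mutation on the focal branch) = 1 - e^{-mu t_c}."""
    return -np.expm1(-np.asarray(mu, dtype=float) * np.asarray(tc, dtype=float))


@dataclass
class EstimationParams:
    """Everything estimate_tc needs besides the observations themselves.

    ``n`` is the number of sampled chromosomes (the panel size) and ``N0``
    the diploid effective size of the constant-size reference demography;
    estimates are weak functions of N0.  Bounds and tolerance are on the
    log10(t_c) scale.
    """

    mu: float = DEFAULT_MU
    gmap: GeneticMap = field(default_factory=lambda: GeneticMap.uniform(DEFAULT_MU))
    n: int = 100
    N0: float = DEFAULT_N0
    demography: DemographyModel | None = None
    tc_bounds_log10: tuple = (0.0, 7.0)
    xatol: float = 1e-4
    use_quadrature: bool = False
    mutation_factor: bool = True
    start_bp: int | None = None
    end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.N0 <= 0 or self.n < 2:
            raise ValueError("need mu > 0, N0 > 0, n >= 2")


@dataclass
class TcEstimate:
    """Maximum-likelihood t_c with optimizer metadata."""

    tc: float
    loglik: float
    converged: bool
    k: int
    chis: np.ndarray
    bounds_log10: tuple
    double_truncated: bool = False
    n_eoc: int = 0


def composite_loglik_arrays(chi, beta, kind, tc, n, N, mu=None,
                            mutation_factor=False):
    """Sum of per-copy log likelihoods at t_c (scalar or grid).

    ``chi, beta, kind`` have one entry per copy; the derived-allele
    mutation factor is added once per allele, not once per copy.
    """
    chi = np.atleast_1d(np.asarray(chi, dtype=float))
    if chi.size == 0:
        raise ValueError("empty observation set")
    beta = np.broadcast_to(np.asarray(beta, dtype=float), chi.shape)
    kind = np.broadcast_to(np.asarray(kind), chi.shape)
    tc_arr = np.atleast_1d(np.asarray(tc, dtype=float))
    ll = loglik_arrays(chi[:, None], beta[:, None], kind[:, None],
                       tc_arr[None, :], n, N).sum(axis=0)
    if mutation_factor:
        if mu is None:
            raise ValueError("mu needed for the mutation factor")
        with np.errstate(divide="ignore"):
            ll = ll + np.log(singleton_mutation_factor(tc_arr, mu))
    return ll if np.ndim(tc) else float(ll[0])


def _stats_from_observations(observations, params: EstimationParams):
    if len(observations) == 0:
        raise ValueError("empty observation set")
    stats = [compose_chi(o, params.gmap, params.mu,
                         params.start_bp, params.end_bp)
             if not isinstance(o, ChiStat) else o
             for o in observations]
    chi = np.array([s.chi for s in stats])
    beta = np.array([s.beta for s in stats])
    kind = np.array([s.kind for s in stats])
    return chi, beta, kind


def composite_loglik(observations, tc, params: EstimationParams):
    """Composite log likelihood of a set of MshObservations at t_c."""
    chi, beta, kind = _stats_from_observations(observations, params)
    if params.use_quadrature or (params.demography is not None
                                 and params.demography.mode == "tabulated"):
        demog = params.demography or DemographyModel(N0=params.N0)
        ll = sum(loglik_quad(c, b, k, float(tc), params.n, demography=demog)
                 for c, b, k in zip(chi, beta, kind))
        if params.mutation_factor:
            ll += float(np.log(singleton_mutation_factor(tc, params.mu)))
        return ll
    return composite_loglik_arrays(chi, beta, kind, tc, params.n, params.N0,
                                   mu=params.mu,
                                   mutation_factor=params.mutation_factor)


def _maximize(objective, bounds_log10, xatol):
    """Bounded scalar maximization over log10(t_c); grid fallback."""
    res = optimize.minimize_scalar(
        lambda x: -objective(10.0 ** x), bounds=bounds_log10,
        method="bounded", options={"xatol": xatol})
    if res.success and np.isfinite(res.fun):
        return 10.0 ** float(res.x), -float(res.fun), True
    grid = np.logspace(bounds_log10[0], bounds_log10[1], 2000)
    vals = np.array([objective(t) for t in grid])
    i = int(np.nanargmax(vals))
    return float(grid[i]), float(vals[i]), False


def estimate_tc(observations, params: EstimationParams) -> TcEstimate:
    """Maximum-likelihood first coalescent time for one allele.

    ``observations`` is the list of per-copy MshObservations (or
    precomposed ChiStats) of the k copies of the allele; their composite
    log likelihood is maximized over log10(t_c) within
    ``params.tc_bounds_log10`` by bounded Brent search (deterministic).
    """
    chi, beta, kind = _stats_from_observations(observations, params)
    if params.use_quadrature or (params.demography is not None
                                 and params.demography.mode == "tabulated"):
        demog = params.demography or DemographyModel(N0=params.N0)

        def objective(t):
            ll = sum(loglik_quad(c, b, kk, t, params.n, demography=demog)
                     for c, b, kk in zip(chi, beta, kind))
            if params.mutation_factor:
                ll += float(np.log(singleton_mutation_factor(t, params.mu)))
            return ll
    else:
        def objective(t):
            return composite_loglik_arrays(
                chi, beta, kind, t, params.n, params.N0, mu=params.mu,
                mutation_factor=params.mutation_factor)

    tc, ll, ok = _maximize(objective, params.tc_bounds_log10, params.xatol)
    return TcEstimate(tc=tc, loglik=ll, converged=ok, k=chi.size, chis=chi,
                      bounds_log10=params.tc_bounds_log10,
                      double_truncated=bool(np.all(kind == DOUBLE_TRUNCATED)),
                      n_eoc=int(np.sum(kind == ONE_SIDED)))


def estimate_all(matrix, records, params: EstimationParams, pooled=True):
    """Estimate t_c for every eligible variant of a haplotype matrix.

    Returns a pandas DataFrame with one row per variant (``pooled=True``,
    the composite estimate over its k copies) or one row per copy.
    """
    import dataclasses

    import pandas as pd

    from .pbwt import extract_msh_all

    params = dataclasses.replace(
        params,
        start_bp=params.start_bp if params.start_bp is not None
        else matrix.start_bp,
        end_bp=params.end_bp if params.end_bp is not None
        else matrix.end_bp)
    all_obs = extract_msh_all(matrix, records)
    rows = []
    for rec, obs in zip(records, all_obs):
        if not obs:
            continue
        if pooled:
            est = estimate_tc(obs, params)
            rows.append(dict(
                site=rec.site_index, pos=rec.pos, ref=rec.ref, alt=rec.alt,
                k=rec.k, tc_hat=est.tc, loglik=est.loglik,
                converged=est.converged, n_eoc=est.n_eoc,
                double_truncated=est.double_truncated,
                msh5_bp=obs[0].msh5_bp, msh3_bp=obs[0].msh3_bp))
        else:
            for o in obs:
                est = estimate_tc([o], params)
                rows.append(dict(
                    site=rec.site_index, pos=rec.pos, ref=rec.ref,
                    alt=rec.alt, k=rec.k, row=o.row, tc_hat=est.tc,
                    loglik=est.loglik, converged=est.converged,
                    n_eoc=est.n_eoc, double_truncated=est.double_truncated,
                    msh5_bp=o.msh5_bp, msh3_bp=o.msh3_bp))
    return pd.DataFrame(rows)
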