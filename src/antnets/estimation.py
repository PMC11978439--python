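"""Fitting model inputs from colony-mapping tables.

Field mapping of a polydomous colony yields two tables: nests (positions
and mound-volume population estimates) and trails (endpoints, measured
lengths, strengths in ants/mm).  From such tables this module estimates the
distributions feeding the simulator (nests per colony, trail lengths, nest
sizes, foraging trails per nest) by maximum likelihood, and the gravity
coefficients by log-linear least squares.  A synthetic mapping-data
generator emulates the recorded fields so the whole pipeline round-trips
without access to field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

NEST_COLUMNS = ["colony", "nest", "x", "y", "size"]
TRAIL_COLUMNS = ["colony", "kind", "node_a", "node_b", "length", "strength"]


@dataclass
class DistributionFit:
    kind: str
    params: dict[str, float]
    log_likelihood: float
    n: int


@dataclass
class GravityFit:
    kind: str                      # internest | foraging
    theta: float
    alpha: float
    beta: float
    se: dict[str, float]           # standard errors of log-theta, alpha, beta
    r_squared: float
    n: int

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.theta, self.alpha, self.beta)


def fit_distribution(kind: str, data, *, truncation: tuple[int, int] | None
                     = None) -> DistributionFit:
    """Maximum-likelihood fit of one of the model's input families.

    ``gamma`` (location fixed at 0), ``poisson`` (closed form), or
    ``negative_binomial`` — optionally with the likelihood truncated to an
    observed count range, as used for the nests-per-colony distribution.
    """
    x = np.asarray(data, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if kind == "gamma":
        if np.any(x <= 0):
            raise ValueError("gamma requires positive values")
        if np.ptp(x) == 0:
            raise ValueError("degenerate (constant) sample")
        shape, _, scale = stats.gamma.fit(x, floc=0)
        ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
        return DistributionFit("gamma", {"shape": shape, "scale": scale},
                               ll, x.size)
    if kind == "poisson":
        if np.any(x < 0) or np.any(x != np.round(x)):
            raise ValueError("poisson requires non-negative counts")
        mu = float(x.mean())
        ll = float(stats.poisson.logpmf(x.astype(int), mu).sum())
        return DistributionFit("poisson", {"mean": mu}, ll, x.size)
    if kind == "negative_binomial":
        return _fit_negbinom(x, truncation)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _fit_negbinom(x: np.ndarray, truncation: tuple[int, int] | None
                  ) -> DistributionFit:
    k = x.astype(int)
    if np.any(k < 0) or np.any(x != k):
        raise ValueError("negative binomial requires non-negative counts")
    if truncation is not None:
        lo, hi = truncation
        if np.any((k < lo) | (k > hi)):
            raise ValueError("data outside the truncation range")

    def nll(theta):
        n, logit_p = theta
        p = 1.0 / (1.0 + np.exp(-logit_p))
        if n <= 0:
            return np.inf
        ll = stats.nbinom.logpmf(k, n, p)
        if truncation is not None:
            lo, hi = truncation
            mass = stats.nbinom.cdf(hi, n, p) - stats.nbinom.cdf(lo - 1, n, p)
            if mass <= 0:
                return np.inf
            ll = ll - np.log(mass)
        return -float(ll.sum())

    m, v = k.mean(), max(k.var(), k.mean() + 1e-6)
    p0 = min(max(m / v, 1e-3), 1 - 1e-3)
    n0 = max(m * p0 / (1 - p0), 1e-2)
    res = optimize.minimize(nll, x0=[n0, np.log(p0 / (1 - p0))],
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 5000})
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError(f"negative-binomial fit did not converge: "
                           f"{res.message}")
    n, logit_p = res.x
    p = 1.0 / (1.0 + np.exp(-logit_p))
    return DistributionFit("negative_binomial",
                           {"n": float(n), "p": float(p)},
                           -float(res.fun), k.size)


def fit_gravity(observations: pd.DataFrame, kind: str) -> GravityFit:
    """Least-squares fit of a gravity formula on the log scale.

    ``observations`` needs columns ``length``, ``strength`` and either
    ``size_a``/``size_b`` (internest: mass = size_a * size_b) or ``size``
    (foraging).  Model: log strength = log theta + alpha * log mass
    - beta * log length.
    """
    df = observations
    if len(df) < 3:
        raise ValueError("underdetermined: need at least 3 observations")
    if kind == "internest":
        mass = df["size_a"].to_numpy() * df["size_b"].to_numpy()
    elif kind == "foraging":
        mass = df["size"].to_numpy()
    else:
        raise ValueError(f"unknown gravity kind {kind!r}")
    length = df["length"].to_numpy(dtype=float)
    strength = df["strength"].to_numpy(dtype=float)
    if np.any(mass <= 0) or np.any(length <= 0) or np.any(strength <= 0):
        raise ValueError("gravity fit requires positive sizes, lengths "
                         "and strengths")
    X = sm.add_constant(np.column_stack([np.log(mass), -np.log(length)]))
    fit = sm.OLS(np.log(strength), X).fit()
    c, alpha, beta = fit.params
    se = dict(zip(("log_theta", "alpha", "beta"), fit.bse))
    return GravityFit(kind, float(np.exp(c)), float(alpha), float(beta),
                      {k: float(v) for k, v in se.items()},
                      float(fit.rsquared) if len(df) > 3 else 1.0, len(df))


# ---------------------------------------------------------------------------
# Synthetic mapping data


def synth_mapping_data(true_params, n_colonies: int,
                       rng: np.random.Generator,
                       noise_sd: float = 0.15
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic colony-mapping tables (nests, trails).

    Emulates the fields a mapping survey records: nests with coordinates
    and size estimates, internest and foraging trails with lengths and
    strengths.  Strengths follow the configured gravity formulae with
    multiplicative lognormal noise (``noise_sd`` on the log scale), so the
    estimation operations recover ``true_params`` on large samples.
    """
    from .morphogenesis import generate_network

    nest_rows, trail_rows = [], []
    ss = np.random.SeedSequence(rng.integers(2 ** 31))
    ti, ai, bi = true_params.gravity_internest
    tf, af, bf = true_params.gravity_foraging
    for c, child in enumerate(ss.spawn(n_colonies)):
        net = generate_network(true_params, child)
        noise_rng = np.random.default_rng(child.spawn(1)[0])
        for n in net.active_nests():
            nest_rows.append((c, n.id, n.x, n.y, n.size))
        for tr in net.trails.values():
            if tr.kind == "internest":
                mu = ti * (net.nests[tr.a].size
                           * net.nests[tr.b].size) ** ai / tr.length ** bi
            else:
                nest_id = tr.a if net.is_nest(tr.a) else tr.b
                mu = tf * net.nests[nest_id].size ** af / tr.length ** bf
            s = mu * np.exp(noise_rng.normal(0.0, noise_sd))
            trail_rows.append((c, tr.kind, tr.key[0], tr.key[1],
                               tr.length, s))
    nests = pd.DataFrame(nest_rows, columns=NEST_COLUMNS)
    trails = pd.DataFrame(trail_rows, columns=TRAIL_COLUMNS)
    return nests, trails


def gravity_observations(nests: pd.DataFrame, trails: pd.DataFrame,
                         kind: str) -> pd.DataFrame:
    """Join mapping tables into the rows ``fit_gravity`` consumes."""
    size = nests.set_index(["colony", "nest"])["size"]
    sub = trails[trails["kind"] == kind]
    missing = [
        (row.colony, nid)
        for row in sub.itertuples()
        for nid in ((row.node_a, row.node_b) if kind == "internest"
                    else ())
        if (row.colony, nid) not in size.index]
    if missing:
        raise ValueError(f"trails reference unknown nests: {missing[:5]}")
    out = sub[["colony", "length", "strength"]].copy()
    if kind == "internest":
        out["size_a"] = [size[(r.colony, r.node_a)]
                         for r in sub.itertuples()]
        out["size_b"] = [size[(r.colony, r.node_b)]
                         for r in sub.itertuples()]
    else:
        def nest_size(r):
            if (r.colony, r.node_a) in size.index:
                return size[(r.colony, r.node_a)]
            if (r.colony, r.node_b) in size.index:
                return size[(r.colony, r.node_b)]
            raise ValueError(f"foraging trail {r.node_a}-{r.node_b} "
                             "references no known nest")
        out["size"] = [nest_size(r) for r in sub.itertuples()]
    return out


def estimate_params(nests: pd.DataFrame, trails: pd.DataFrame,
                    base=None):
    """Estimate a full parameter set from mapping tables.

    Distribution and gravity estimates replace the corresponding fields of
    ``base`` (default parameters when omitted); constants a mapping survey
    cannot identify (growth, budding, thresholds) are left at their
    configured values.
    """
    from dataclasses import replace
    from .colony_graph import ModelParams

    base = base or ModelParams()
    counts = nests.groupby("colony")["nest"].count()
    kwargs = {}
    if counts.size >= 10:
        lo, hi = base.nest_count_range
        fit = fit_distribution("negative_binomial", counts,
                               truncation=(lo, hi)
                               if counts.between(lo, hi).all() else None)
        kwargs["nest_count_n"] = fit.params["n"]
        kwargs["nest_count_p"] = fit.params["p"]
    size_fit = fit_distribution("gamma", nests["size"])
    kwargs["nest_size_shape"] = size_fit.params["shape"]
    kwargs["nest_size_scale"] = size_fit.params["scale"]
    kwargs["nest_size_cap"] = float(stats.gamma.ppf(
        0.95, size_fit.params["shape"], scale=size_fit.params["scale"]))
    kwargs["nest_abandon_threshold"] = float(stats.gamma.ppf(
        0.05, size_fit.params["shape"], scale=size_fit.params["scale"]))

    nest_index = set(zip(nests["colony"], nests["nest"]))
    per_nest = {key: 0 for key in nest_index}
    for r in trails[trails["kind"] == "foraging"].itertuples():
        for nid in (r.node_a, r.node_b):
            if (r.colony, nid) in nest_index:
                per_nest[(r.colony, nid)] += 1
    kwargs["foraging_count_mean"] = float(np.mean(list(per_nest.values())))

    inter = gravity_observations(nests, trails, "internest")
    if len(inter) >= 3:
        g = fit_gravity(inter, "internest")
        kwargs["gravity_internest"] = g.coefficients
    fora = gravity_observations(nests, trails, "foraging")
    if len(fora) >= 3:
        g = fit_gravity(fora, "foraging")
        kwargs["gravity_foraging"] = g.coefficients
    return replace(base, **kwargs).validate()
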