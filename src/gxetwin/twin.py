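"""Maximum-likelihood multivariate twin modelling (correlated factors ACE).

The phenotypic covariance of a twin pair on p traits is modelled from
per-trait path coefficients a_i, c_i, e_i and aetiological correlation
matrices R_A, R_C, R_E.  With D_a = diag(a) and A = D_a R_A D_a (similarly
C, E), the expected 2p x 2p covariance is

    [[A + C + E,  w A + C ],
     [ w A + C,  A + C + E]]       w = 1 for MZ pairs, 0.5 for DZ pairs,

reflecting identity-by-descent of 1.0 (MZ) versus 0.5 on average (DZ) while
shared environment correlates both twin types equally.  Trait means are
equated across twins and zygosity groups.  The likelihood is full
information: pairs with partially missing trait vectors contribute the
marginal normal density of their observed subset.

Optimization is over unconstrained transforms -- log variances for the
squared paths and row-normalized Cholesky factors for the correlation
matrices -- so every parameter vector maps to a valid (positive-definite)
covariance structure.  Confidence intervals are profile-likelihood based:
the bound is where the re-optimized -2 log L rises by the chi-square
quantile above its minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "TwinData", "CorrelatedFactorsParams", "FitResult",
    "expected_covariance", "minus2_log_likelihood",
    "fit_correlated_factors", "fit_saturated", "compare_models",
    "profile_ci", "intraclass_correlations",
]

_LOG2PI = np.log(2.0 * np.pi)
_MODEL_COMPONENTS = {"ACE": "ace", "AE": "ae", "CE": "ce", "E": "e"}
_GROUP_W = {"MZ": 1.0, "DZ": 0.5}


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class TwinData:
    """Twin-pair trait matrices per zygosity group.

    ``groups`` maps 'MZ'/'DZ' to arrays of shape (n_pairs, 2p) ordered
    (twin-1 traits..., twin-2 traits...); NaN marks missing values.
    """

    groups: dict
    traits: tuple

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        p = len(self.traits)
        cleaned = {}
        for g, arr in self.groups.items():
            arr = np.asarray(arr, float)
            if arr.ndim != 2 or arr.shape[1] != 2 * p:
                raise ValueError(f"group {g}: expected shape (n, {2 * p})")
            keep = np.isfinite(arr).any(axis=1)
            cleaned[g] = arr[keep]
        self.groups = cleaned

    @property
    def p(self) -> int:
        return len(self.traits)

    @classmethod
    def from_phenotypes(cls, df: pd.DataFrame, traits,
                        pool_dz: bool = True) -> "TwinData":
        """Build pair matrices from a per-individual table with columns
        family_id, zygosity, twin_order and the trait columns."""
        traits = tuple(traits)
        sub = df[df["zygosity"].isin(["MZ", "DZ_ss", "DZ_os"])]
        wide = sub.pivot_table(index=["family_id", "zygosity"],
                               columns="twin_order", values=list(traits),
                               aggfunc="first")
        groups: dict = {}
        zyg = wide.index.get_level_values("zygosity")
        for label in ("MZ", "DZ_ss", "DZ_os"):
            rows = wide[zyg == label]
            if rows.empty:
                continue
            arr = np.column_stack(
                [rows[(t, 1)].to_numpy(float) for t in traits]
                + [rows[(t, 2)].to_numpy(float) for t in traits])
            key = "MZ" if label == "MZ" else ("DZ" if pool_dz else label)
            groups[key] = arr if key not in groups else np.vstack([groups[key], arr])
        return cls(groups=groups, traits=traits)

    def prepared(self):
        """Missingness-pattern sufficient statistics for fast likelihood."""
        pats = []
        n_values = 0
        for g, arr in self.groups.items():
            finite = np.isfinite(arr)
            codes = finite @ (1 << np.arange(arr.shape[1]))
            for code in np.unique(codes):
                rows = arr[codes == code]
                obs = np.flatnonzero(np.isfinite(rows[0]))
                sub = rows[:, obs]
                n = sub.shape[0]
                mean = sub.mean(axis=0)
                dev = sub - mean
                pats.append((g, obs, n, mean, dev.T @ dev))
                n_values += n * obs.size
        return pats, n_values


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class CorrelatedFactorsParams:
    """Path coefficients and aetiological correlations; e_i must be > 0."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    r_a: np.ndarray
    r_c: np.ndarray
    r_e: np.ndarray
    mu: np.ndarray | None = None

    @property
    def A(self):
        return np.diag(self.a) @ self.r_a @ np.diag(self.a)

    @property
    def C(self):
        return np.diag(self.c) @ self.r_c @ np.diag(self.c)

    @property
    def E(self):
        return np.diag(self.e) @ self.r_e @ np.diag(self.e)

    def standardized(self) -> pd.DataFrame:
        va, vc, ve = self.a ** 2, self.c ** 2, self.e ** 2
        tot = va + vc + ve
        return pd.DataFrame({"A": va / tot, "C": vc / tot, "E": ve / tot})


def expected_covariance(params: CorrelatedFactorsParams, group: str) -> np.ndarray:
    """Expected 2p x 2p twin-pair covariance for 'MZ' or 'DZ'."""
    if group not in _GROUP_W:
        raise ValueError(f"unknown group {group!r}")
    A, C, E = params.A, params.C, params.E
    within = A + C + E
    cross = _GROUP_W[group] * A + C
    top = np.hstack([within, cross])
    bottom = np.hstack([cross, within])
    sigma = np.vstack([top, bottom])
    return 0.5 * (sigma + sigma.T)


# --- unconstrained transform ------------------------------------------------

def _corr_from_z(z: np.ndarray, p: int) -> np.ndarray:
    """Row-normalized lower-triangular map: R^{p(p-1)/2} -> PD correlations."""
    L = np.eye(p)
    idx = 0
    for i in range(1, p):
        L[i, :i] = z[idx:idx + i]
        idx += i
        L[i, :i + 1] /= np.linalg.norm(L[i, :i + 1])
    return L @ L.T


def _z_from_corr(R: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
    out = []
    for i in range(1, R.shape[0]):
        out.extend(L[i, :i] / L[i, i])
    return np.asarray(out)


class _Spec:
    """Bookkeeping for packing/unpacking the free-parameter vector."""

    def __init__(self, p: int, model: str):
        model = model.upper()
        if model not in _MODEL_COMPONENTS:
            raise ValueError(f"unknown model {model!r}")
        self.p = p
        self.model = model
        self.components = [w for w in "ace" if w in _MODEL_COMPONENTS[model]]
        self.q = p * (p - 1) // 2
        self.n_params = len(self.components) * (p + self.q) + p  # + means

    def unpack(self, theta: np.ndarray) -> CorrelatedFactorsParams:
        p, q = self.p, self.q
        pos = 0
        paths, corrs = {}, {}
        for w in "ace":
            if w in self.components:
                paths[w] = np.exp(0.5 * theta[pos:pos + p])  # path = sqrt(var)
                pos += p
                corrs[w] = _corr_from_z(theta[pos:pos + q], p) if q else np.eye(p)
                pos += q
            else:
                paths[w] = np.zeros(p)
                corrs[w] = np.eye(p)
        mu = theta[pos:pos + p]
        return CorrelatedFactorsParams(a=paths["a"], c=paths["c"], e=paths["e"],
                                       r_a=corrs["a"], r_c=corrs["c"],
                                       r_e=corrs["e"], mu=mu)

    def pack(self, params: CorrelatedFactorsParams) -> np.ndarray:
        out = []
        for w in self.components:
            v = np.maximum(getattr(params, w) ** 2, 1e-6)
            out.append(np.log(v))
            if self.q:
                out.append(_z_from_corr(getattr(params, f"r_{w}")))
        out.append(params.mu if params.mu is not None else np.zeros(self.p))
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _m2ll_prepared(params: CorrelatedFactorsParams, patterns) -> float:
    p = params.a.size
    mu_full = np.tile(params.mu if params.mu is not None else np.zeros(p), 2)
    sigmas = {g: expected_covariance(params, g) for g in ("MZ", "DZ")}
    if not (np.isfinite(mu_full).all()
            and all(np.isfinite(s).all() for s in sigmas.values())):
        return 1e12
    total = 0.0
    for g, obs, n, mean, scatter in patterns:
        sub = sigmas[g][np.ix_(obs, obs)]
        try:
            cf = cho_factor(sub, lower=True)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        diff = mean - mu_full[obs]
        total += n * (obs.size * _LOG2PI + logdet)
        total += np.trace(cho_solve(cf, scatter))
        total += n * float(diff @ cho_solve(cf, diff))
    return float(total)


def minus2_log_likelihood(params: CorrelatedFactorsParams,
                          data: TwinData) -> float:
    """-2 log multivariate-normal likelihood of the twin pairs under the
    correlated-factors structure (FIML over missingness patterns)."""
    patterns, _ = data.prepared()
    return _m2ll_prepared(params, patterns)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    params: CorrelatedFactorsParams
    minus2LL: float
    n_params: int
    df: int
    aic: float
    std_props: pd.DataFrame
    converged: bool
    n_pairs: dict
    traits: tuple
    diagnostics: dict = field(default_factory=dict)
    _spec: object = field(default=None, repr=False)
    _patterns: object = field(default=None, repr=False)

    @property
    def correlations(self) -> dict:
        return {"r_a": self.params.r_a, "r_c": self.params.r_c,
                "r_e": self.params.r_e}


def _moment_start(data: TwinData) -> CorrelatedFactorsParams:
    """Falconer-style moment estimates as the primary starting point."""
    p = data.p
    icc = intraclass_correlations(data)
    var = np.ones(p)
    mu = np.zeros(p)
    stacked = {g: np.vstack([arr[:, :p], arr[:, p:]]) for g, arr in data.groups.items()}
    allv = np.vstack(list(stacked.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu = np.nanmean(allv, axis=0)
        var = np.nanvar(allv, axis=0)
    var = np.where(np.isfinite(var) & (var > 1e-8), var, 1.0)
    r_mz = icc.loc["MZ"].to_numpy() if "MZ" in icc.index else np.full(p, 0.6)
    r_dz = icc.loc["DZ"].to_numpy() if "DZ" in icc.index else np.full(p, 0.3)
    A0 = np.clip(2.0 * (r_mz - r_dz), 0.05, 0.9)
    C0 = np.clip(r_mz - A0, 0.02, 0.9)
    E0 = np.clip(1.0 - A0 - C0, 0.05, None)
    tot = A0 + C0 + E0
    A0, C0, E0 = A0 / tot, C0 / tot, E0 / tot
    # phenotypic correlations shrunk as common starting aetiological corr
    rp = np.corrcoef(allv[np.isfinite(allv).all(axis=1)].T) if p > 1 else np.eye(1)
    R0 = 0.5 * rp + 0.5 * np.eye(p)
    return CorrelatedFactorsParams(
        a=np.sqrt(A0 * var), c=np.sqrt(C0 * var), e=np.sqrt(E0 * var),
        r_a=R0.copy(), r_c=R0.copy(), r_e=R0.copy(), mu=mu)


def fit_correlated_factors(data: TwinData, model: str = "ACE",
                           n_starts: int = 5, seed: int = 0,
                           gtol: float = 1e-6,
                           start_agree_tol: float = 1e-4) -> FitResult:
    """Maximize the twin likelihood over the unconstrained parameterization.

    Multi-start: the moment-based start plus ``n_starts - 1`` seeded
    jittered starts; convergence requires the best two starts to agree in
    -2 log L within ``start_agree_tol`` (diagnosed in ``diagnostics``).
    """
    for g in ("MZ", "DZ"):
        if g not in data.groups:
            raise FitError(f"group {g!r} missing from data")
        if data.groups[g].shape[0] < data.p + 1:
            raise FitError(f"group {g!r} has too few pairs")
    spec = _Spec(data.p, model)
    patterns, n_values = data.prepared()
    theta0 = spec.pack(_moment_start(data))
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0.0, 0.3, theta0.size)
                         for _ in range(max(0, n_starts - 1))]

    def obj(theta):
        return _m2ll_prepared(spec.unpack(theta), patterns)

    bounds = [(-20.0, 20.0)] * (theta0.size - spec.p) + [(None, None)] * spec.p
    results = []
    for th in starts:
        res = optimize.minimize(obj, th, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 2000, "gtol": gtol,
                                         "ftol": 1e-12})
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError("no start converged to a finite likelihood")
    agree = (len(results) < 2
             or results[1].fun - best.fun < max(start_agree_tol, 1e-8 * abs(best.fun))
             or results[1].fun >= 1e12)
    params = spec.unpack(best.x)
    std = params.standardized()
    std.index = list(data.traits)
    n_pairs = {g: arr.shape[0] for g, arr in data.groups.items()}
    return FitResult(
        model=model.upper(), params=params, minus2LL=float(best.fun),
        n_params=spec.n_params, df=n_values - spec.n_params,
        aic=float(best.fun) + 2 * spec.n_params, std_props=std,
        converged=bool(best.success), n_pairs=n_pairs, traits=data.traits,
        diagnostics={"starts_m2ll": [float(r.fun) for r in results],
                     "start_agreement": bool(agree),
                     "grad_norm": float(np.max(np.abs(best.jac)))},
        _spec=spec, _patterns=patterns)


def fit_saturated(data: TwinData) -> FitResult:
    """Unstructured per-group means and covariances (listwise-complete MLE);
    the reference -2 log L for model-fit statistics."""
    p2 = 2 * data.p
    m2ll = 0.0
    n_params = 0
    n_values = 0
    n_pairs = {}
    for g, arr in data.groups.items():
        rows = arr[np.isfinite(arr).all(axis=1)]
        n = rows.shape[0]
        if n <= p2:
            raise FitError(f"group {g!r}: too few complete pairs for a "
                           "saturated covariance")
        mean = rows.mean(axis=0)
        dev = rows - mean
        cov = dev.T @ dev / n
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise FitError(f"group {g!r}: singular sample covariance")
        m2ll += n * (p2 * _LOG2PI + logdet + p2)
        n_params += p2 + p2 * (p2 + 1) // 2
        n_values += n * p2
        n_pairs[g] = n
    dummy = CorrelatedFactorsParams(
        a=np.zeros(data.p), c=np.zeros(data.p), e=np.ones(data.p),
        r_a=np.eye(data.p), r_c=np.eye(data.p), r_e=np.eye(data.p))
    return FitResult(model="SATURATED", params=dummy, minus2LL=float(m2ll),
                     n_params=n_params, df=n_values - n_params,
                     aic=float(m2ll) + 2 * n_params,
                     std_props=pd.DataFrame(), converged=True,
                     n_pairs=n_pairs, traits=data.traits)


_NESTING = {  # model -> models it is nested in
    "ACE": {"SATURATED"},
    "AE": {"SATURATED", "ACE"},
    "CE": {"SATURATED", "ACE"},
    "E": {"SATURATED", "ACE", "AE", "CE"},
}


def compare_models(fit_full: FitResult, fit_nested: FitResult) -> dict:
    """Likelihood-ratio and AIC comparison of nested fits."""
    same = fit_full.model == fit_nested.model
    if not same and fit_full.model not in _NESTING.get(fit_nested.model, set()):
        raise ValueError(f"{fit_nested.model} is not nested in {fit_full.model}")
    d_m2ll = fit_nested.minus2LL - fit_full.minus2LL
    d_df = fit_full.n_params - fit_nested.n_params
    p = float(stats.chi2.sf(max(d_m2ll, 0.0), d_df)) if d_df > 0 else 1.0
    d_aic = fit_nested.aic - fit_full.aic
    return {"delta_minus2LL": float(d_m2ll), "delta_df": int(d_df),
            "lrt_p": p, "delta_aic": float(d_aic),
            "preferred_by_aic": fit_nested.model if d_aic <= 0 else fit_full.model}


# ---------------------------------------------------------------------------
# profile likelihood CIs
# ---------------------------------------------------------------------------

def _selector_fn(spec: _Spec, traits, selector):
    """Map a selector to (g(theta), domain).  Selectors:
    ('A'|'C'|'E', trait) for standardized proportions,
    ('r_a'|'r_c'|'r_e', trait_i, trait_j) for aetiological correlations."""
    trait_idx = {t: i for i, t in enumerate(traits)}

    def resolve(t):
        return trait_idx[t] if isinstance(t, str) else int(t)

    kind = selector[0]
    if kind in ("A", "C", "E"):
        i = resolve(selector[1])
        comp = kind.lower()

        def g(theta):
            prm = spec.unpack(theta)
            va = getattr(prm, comp)[i] ** 2
            tot = prm.a[i] ** 2 + prm.c[i] ** 2 + prm.e[i] ** 2
            return va / tot

        return g, (0.0, 1.0)
    if kind in ("r_a", "r_c", "r_e"):
        i, j = resolve(selector[1]), resolve(selector[2])

        def g(theta):
            return getattr(spec.unpack(theta), kind)[i, j]

        return g, (-1.0, 1.0)
    raise ValueError(f"unknown selector {selector!r}")


def profile_ci(fit: FitResult, selector, level: float = 0.95) -> tuple:
    """Profile-likelihood interval for a standardized proportion or an
    aetiological correlation; bounds at the parameter-domain edge are
    returned as the edge value (censored)."""
    if fit._spec is None:
        raise ValueError("profile_ci requires a fit from fit_correlated_factors")
    spec, patterns = fit._spec, fit._patterns
    g, (lo_dom, hi_dom) = _selector_fn(spec, fit.traits, selector)
    q = stats.chi2.ppf(level, 1)
    target = fit.minus2LL + q
    theta_hat = spec.pack(fit.params)
    g_hat = g(theta_hat)

    warm = {"theta": theta_hat.copy()}
    slsqp_bounds = [(-20.0, 20.0)] * (theta_hat.size - spec.p) \
        + [(None, None)] * spec.p

    def profile(g0: float) -> float:
        cons = {"type": "eq", "fun": lambda th: g(th) - g0}
        res = optimize.minimize(
            lambda th: _m2ll_prepared(spec.unpack(th), patterns),
            warm["theta"], method="SLSQP", constraints=[cons],
            bounds=slsqp_bounds, options={"maxiter": 300, "ftol": 1e-10})
        if res.success or res.fun < 1e11:
            warm["theta"] = res.x
        return float(res.fun)

    def bisect(inside: float, outside: float) -> float:
        """Bound between a value with profile <= target (inside) and one
        with profile > target (outside); plain bisection is robust to the
        slight path dependence of warm-started re-optimization."""
        for _ in range(40):
            if abs(outside - inside) < 1e-3:
                break
            mid = 0.5 * (inside + outside)
            if profile(mid) > target:
                outside = mid
            else:
                inside = mid
        return 0.5 * (inside + outside)

    def bound(direction: int) -> float:
        edge = hi_dom if direction > 0 else lo_dom
        step = max(0.02, 0.1 * abs(edge - g_hat))
        prev = g_hat
        cur = g_hat + direction * step
        warm["theta"] = theta_hat.copy()
        while (cur - edge) * direction < 0:
            if profile(cur) > target:
                return bisect(prev, cur)
            prev = cur
            cur += direction * step
            step *= 1.6
        if profile(edge) > target:
            return bisect(prev, edge)
        return edge  # censored at the domain boundary

    lower = bound(-1)
    upper = bound(+1)
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# intraclass correlations
# ---------------------------------------------------------------------------

def intraclass_correlations(data: TwinData) -> pd.DataFrame:
    """Double-entry Pearson correlation per group and trait."""
    p = data.p
    rows = {}
    for g, arr in data.groups.items():
        vals = []
        for t in range(p):
            x, y = arr[:, t], arr[:, p + t]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                vals.append(np.nan)
                continue
            a = np.concatenate([x[ok], y[ok]])
            b = np.concatenate([y[ok], x[ok]])
            if a.std() < 1e-12:
                raise ValueError(f"degenerate variance for trait "
                                 f"{data.traits[t]} in group {g}")
            vals.append(float(np.corrcoef(a, b)[0, 1]))
        rows[g] = vals
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(data.traits))
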