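"""Linear mixed models for agreement tables: fitting, marginal effects, power.

The factorial analyses model per-trial segmentation agreement (or response
counts) as

    y ~ trend * framing * salience + (1 + trend + framing + salience | participant)

with treatment (reference-cell) coding — references endangered / hue /
distributed — and trend on its natural [-1, 1] scale. Estimation is
restricted maximum likelihood with an lme4-style profiled deviance: the
random-effect covariance is parameterized by its relative Cholesky factor
(G = sigma^2 * Lam Lam'), beta and sigma^2 are profiled out, and the
remaining parameters are optimized numerically. Fixed-effect tests use
Satterthwaite degrees of freedom computed from the numeric REML Hessian
(the same construction lmerTest uses); Wald 95% confidence intervals.

Two random-effect structures are supported: correlated random intercepts
and slopes within one grouping factor (the factorial models), and crossed
random intercepts over several factors (the contrast / time-unit /
descriptor models), handled with indicator-matrix Woodbury identities so
each deviance evaluation stays cheap.

Average marginal effects (AMEs) of trend per framing x salience cell are
coefficient sums with delta-method standard errors; for these linear models
they equal averaged per-observation derivatives exactly.

``power_simulation`` runs the Monte-Carlo design analysis: simulate
agreement tables from the mixed-model data-generating process with a chosen
three-way-interaction coefficient, refit the full model, and report the
rejection fraction at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimgen import enumerate_design

__all__ = [
    "LMMSpec",
    "RandomSlopes",
    "CrossedIntercepts",
    "LMMResult",
    "AMEResult",
    "VarianceComponents",
    "TABLE6_COMPONENTS",
    "PowerResult",
    "ConvergenceError",
    "encode_treatment",
    "fit_lmm",
    "fit_factorial",
    "ame_trend",
    "ame_trend_numeric",
    "exploratory_descriptor_model",
    "power_simulation",
    "build_power_design",
]

_Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer diagnostics."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomSlopes:
    """Correlated random intercept + slopes within one grouping factor."""

    group: str
    slopes: tuple[str, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return ("Intercept", *self.slopes)


@dataclass(frozen=True)
class CrossedIntercepts:
    """Independent random intercepts for each listed (crossed) factor."""

    factors: tuple[str, ...]


@dataclass(frozen=True)
class LMMSpec:
    """Model contract: outcome, fixed product terms, random structure.

    Each fixed term is a tuple of numeric column names whose product forms
    the regressor; the empty tuple is the intercept. Categorical factors
    must be pre-encoded (see ``encode_treatment``).
    """

    outcome: str
    fixed: tuple[tuple[str, ...], ...]
    random: RandomSlopes | CrossedIntercepts
    df_method: str = "satterthwaite"  # satterthwaite | residual

    def term_names(self) -> list[str]:
        return ["Intercept" if not t else ":".join(t) for t in self.fixed]


def encode_treatment(table: pd.DataFrame, column: str, reference: str) -> pd.DataFrame:
    """Add 0/1 indicator columns for the non-reference levels of ``column``."""
    out = table.copy()
    levels = sorted(set(out[column].astype(str)))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not found in {column}")
    for lev in levels:
        if lev != reference:
            out[lev] = (out[column].astype(str) == lev).astype(float)
    return out


def _design_matrix(table: pd.DataFrame, fixed) -> np.ndarray:
    cols = []
    for term in fixed:
        if not term:
            cols.append(np.ones(len(table)))
        else:
            v = np.ones(len(table))
            for c in term:
                v = v * table[c].to_numpy(dtype=float)
            cols.append(v)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient fixed effects; aliased terms: {bad}")


# ---------------------------------------------------------------------------
# REML engines
# ---------------------------------------------------------------------------


def _pack_lower(r: int):
    idx = [(i, j) for i in range(r) for j in range(i + 1)]
    diag_pos = [k for k, (i, j) in enumerate(idx) if i == j]
    return idx, diag_pos


class _GroupedEngine:
    """Profiled REML for y = X beta + Z_i b_i + e within groups.

    Works from per-group sufficient statistics; when every group shares the
    same (X, Z) block (balanced designs), the per-evaluation cost is
    independent of the number of observations.
    """

    kind = "grouped"

    def __init__(self, X, Z, y, codes):
        self.n, self.p = X.shape
        self.r = Z.shape[1]
        order = np.argsort(codes, kind="stable")
        X, Z, y, codes = X[order], Z[order], y[order], codes[order]
        _, starts = np.unique(codes, return_index=True)
        bounds = [*starts, len(codes)]
        self.m = len(starts)
        self.theta_idx, self.theta_diag = _pack_lower(self.r)

        blocks = []
        shared = True
        first = None
        for a, b in zip(bounds, bounds[1:]):
            Xi, Zi, yi = X[a:b], Z[a:b], y[a:b]
            blocks.append((Xi, Zi, yi))
            if first is None:
                first = (Xi, Zi)
            elif shared:
                shared = (Xi.shape == first[0].shape
                          and np.array_equal(Xi, first[0])
                          and np.array_equal(Zi, first[1]))
        self.shared = shared
        if shared:
            X0, Z0 = first
            Y = np.vstack([yi for _, _, yi in blocks])  # (m, g)
            self.XtX = X0.T @ X0
            self.ZtX = Z0.T @ X0
            self.ZtZ = Z0.T @ Z0
            self.Xty = X0.T @ Y.sum(axis=0)
            Zty = Y @ Z0  # (m, r)
            self.ZtSY = Zty.sum(axis=0)
            self.K = Zty.T @ Zty
            self.syy = float(np.einsum("ij,ij->", Y, Y))
        else:
            self.stats = [
                (Xi.T @ Xi, Zi.T @ Xi, Zi.T @ Zi, Xi.T @ yi, Zi.T @ yi,
                 float(yi @ yi))
                for Xi, Zi, yi in blocks
            ]

    def theta0(self) -> np.ndarray:
        th = np.zeros(len(self.theta_idx))
        th[self.theta_diag] = 0.5
        return th

    def bounds(self):
        return [(0.0, None) if k in self.theta_diag else (None, None)
                for k in range(len(self.theta_idx))]

    def _lam(self, theta) -> np.ndarray:
        lam = np.zeros((self.r, self.r))
        for k, (i, j) in enumerate(self.theta_idx):
            lam[i, j] = theta[k]
        return lam

    def parts(self, theta):
        """Accumulated (logdet sum, A, b, c) for the relative covariance."""
        lam = self._lam(theta)
        I_r = np.eye(self.r)
        if self.shared:
            M = I_r + lam.T @ self.ZtZ @ lam
            L = np.linalg.cholesky(M)
            ld = 2.0 * self.m * float(np.sum(np.log(np.diag(L))))
            Minv = np.linalg.inv(M)
            P = lam @ Minv @ lam.T
            A = self.m * (self.XtX - self.ZtX.T @ P @ self.ZtX)
            b = self.Xty - self.ZtX.T @ P @ self.ZtSY
            c = self.syy - float(np.einsum("ij,ji->", P, self.K))
            return ld, A, b, c
        ld, A, b, c = 0.0, np.zeros((self.p, self.p)), np.zeros(self.p), 0.0
        for XtX, ZtX, ZtZ, Xty, Zty, yty in self.stats:
            M = I_r + lam.T @ ZtZ @ lam
            L = np.linalg.cholesky(M)
            ld += 2.0 * float(np.sum(np.log(np.diag(L))))
            P = lam @ np.linalg.inv(M) @ lam.T
            A += XtX - ZtX.T @ P @ ZtX
            b += Xty - ZtX.T @ P @ Zty
            c += yty - float(Zty @ P @ Zty)
        return ld, A, b, c

    def G(self, theta, sigma2) -> np.ndarray:
        lam = self._lam(theta)
        return sigma2 * lam @ lam.T


class _CrossedEngine:
    """Profiled REML with crossed random intercepts (indicator Woodbury)."""

    kind = "crossed"

    def __init__(self, X, factors_codes, y):
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.m = 0
        self.sums_X, self.sums_y, self.counts, self.sizes = [], [], [], []
        for codes in factors_codes:
            m = int(codes.max()) + 1
            SX = np.zeros((m, self.p))
            np.add.at(SX, codes, X)
            Sy = np.bincount(codes, weights=y, minlength=m)
            self.sums_X.append(SX)
            self.sums_y.append(Sy)
            self.counts.append(np.bincount(codes, minlength=m).astype(float))
            self.sizes.append(m)
            self.m = max(self.m, m)
        self.codes = factors_codes
        self.nf = len(factors_codes)
        # pairwise cross-count tables
        self.cross = {}
        for a in range(self.nf):
            for b in range(a + 1, self.nf):
                C = np.zeros((self.sizes[a], self.sizes[b]))
                np.add.at(C, (factors_codes[a], factors_codes[b]), 1.0)
                self.cross[(a, b)] = C
        self.theta_diag = list(range(self.nf))

    def theta0(self) -> np.ndarray:
        return np.full(self.nf, 0.5)

    def bounds(self):
        return [(0.0, None)] * self.nf

    def parts(self, theta):
        lam = np.asarray(theta, dtype=float)
        q = sum(self.sizes)
        M = np.eye(q)
        UtX = np.vstack([lam[a] * self.sums_X[a] for a in range(self.nf)])
        Uty = np.concatenate([lam[a] * self.sums_y[a] for a in range(self.nf)])
        off = np.cumsum([0, *self.sizes])
        for a in range(self.nf):
            sl = slice(off[a], off[a + 1])
            M[sl, sl] += np.diag(lam[a] ** 2 * self.counts[a])
            for b in range(a + 1, self.nf):
                sl2 = slice(off[b], off[b + 1])
                M[sl, sl2] += lam[a] * lam[b] * self.cross[(a, b)]
                M[sl2, sl] = M[sl, sl2].T
        L = np.linalg.cholesky(M)
        ld = 2.0 * float(np.sum(np.log(np.diag(L))))
        W = np.linalg.solve(M, np.column_stack([UtX, Uty]))
        WX, Wy = W[:, :-1], W[:, -1]
        A = self.XtX - UtX.T @ WX
        b = self.Xty - UtX.T @ Wy
        c = self.yty - float(Uty @ Wy)
        return ld, A, b, c

    def G(self, theta, sigma2) -> np.ndarray:
        return sigma2 * np.diag(np.asarray(theta, dtype=float) ** 2)


def _profiled_deviance(engine, theta):
    ld, A, b, c = engine.parts(theta)
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss = max(c - float(b @ beta), 1e-300)
    nmp = engine.n - engine.p
    return ld + ldA + nmp * (1.0 + np.log(2.0 * np.pi * rss / nmp))


def _full_deviance(engine, theta, log_s2):
    ld, A, b, c = engine.parts(theta)
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss = max(c - float(b @ beta), 1e-300)
    nmp = engine.n - engine.p
    s2 = np.exp(log_s2)
    return ld + ldA + nmp * log_s2 + rss / s2 + nmp * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """Fitted mixed model: coefficient table, variance components, fit stats."""

    coefficients: pd.DataFrame  # estimate, se, ci_low, ci_high, t, df, p, d
    cov_beta: pd.DataFrame
    re_variances: dict[str, float]
    re_corr: pd.DataFrame | None
    sigma2: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    deviance: float
    converged: bool
    spec: LMMSpec
    factor_meta: dict = field(default_factory=dict)
    _engine: object | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_variance(self) -> float:
        return float(sum(self.re_variances.values()) + self.sigma2)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])


def _satterthwaite_dfs(engine, theta, sigma2, cov_rel, contrasts):
    """Satterthwaite dfs for each contrast via the numeric REML Hessian.

    ``cov_rel`` is A(theta)^-1 so Var(c'beta) = sigma2 * c' cov_rel c.
    Parameters are (theta, log sigma2); their covariance is 2 H^-1 with H
    the Hessian of the un-profiled -2 REML log-likelihood.
    """
    th_full = np.concatenate([theta, [np.log(sigma2)]])
    d = len(th_full)
    h = 1e-4 * np.maximum(np.abs(th_full), 0.1)

    def f(v):
        return _full_deviance(engine, v[:-1], v[-1])

    H = np.zeros((d, d))
    f0 = f(th_full)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(th_full + ei) - 2 * f0 + f(th_full - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(th_full + ei + ej) - f(th_full + ei - ej)
                    - f(th_full - ei + ej) + f(th_full - ei - ej)
                ) / (4 * h[i] * h[j])
    cov_theta = 2.0 * np.linalg.pinv(H)

    def varc(v, c):
        _, A, _, _ = engine.parts(v[:-1])
        return float(np.exp(v[-1]) * c @ np.linalg.solve(A, c))

    nmp = engine.n - engine.p
    dfs = []
    for c in contrasts:
        v0 = float(sigma2 * c @ cov_rel @ c)
        g = np.zeros(d)
        for i in range(d):
            e = np.zeros(d); e[i] = h[i]
            g[i] = (varc(th_full + e, c) - varc(th_full - e, c)) / (2 * h[i])
        denom = float(g @ cov_theta @ g)
        dfs.append(2.0 * v0 ** 2 / denom if denom > 1e-300 else float(nmp))
    return np.array([min(max(df, 1.0), 1e7) for df in dfs])


def fit_lmm(table: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """Fit a linear mixed model by profiled REML.

    Raises ``ValueError`` for rank-deficient fixed effects (naming the
    aliased terms) and ``ConvergenceError`` when the optimizer fails.
    """
    names = spec.term_names()
    y = table[spec.outcome].to_numpy(dtype=float)
    X = _design_matrix(table, spec.fixed)
    _check_rank(X, names)

    if isinstance(spec.random, RandomSlopes):
        codes = pd.Categorical(table[spec.random.group]).codes.astype(np.int64)
        Z = _design_matrix(table, [(), *[(s,) for s in spec.random.slopes]])
        engine = _GroupedEngine(X, Z, y, codes)
        re_names = [f"{spec.random.group}:{n}" for n in spec.random.names]
    else:
        factor_codes = [pd.Categorical(table[f]).codes.astype(np.int64)
                        for f in spec.random.factors]
        engine = _CrossedEngine(X, factor_codes, y)
        re_names = [f"{f}:Intercept" for f in spec.random.factors]

    if np.ptp(y) < 1e-14:
        return _constant_outcome_result(table, spec, names, X, y, engine, re_names)

    res = optimize.minimize(lambda th: _profiled_deviance(engine, th),
                            engine.theta0(), method="L-BFGS-B",
                            bounds=engine.bounds(),
                            options={"maxiter": 500, "ftol": 1e-12})
    if not res.success and res.status != 1:  # status 1: iteration cap
        raise ConvergenceError(f"REML optimization failed: {res.message}")
    theta = res.x

    ld, A, b, c = engine.parts(theta)
    beta = np.linalg.solve(A, b)
    rss = max(c - float(b @ beta), 0.0)
    nmp = engine.n - engine.p
    sigma2 = rss / nmp
    cov_rel = np.linalg.inv(A)
    cov_beta = sigma2 * cov_rel
    se = np.sqrt(np.diag(cov_beta))

    G = engine.G(theta, sigma2)
    re_var = {nm: float(G[i, i]) for i, nm in enumerate(re_names)}
    re_corr = None
    if isinstance(spec.random, RandomSlopes) and G.shape[0] > 1:
        sd = np.sqrt(np.maximum(np.diag(G), 1e-300))
        corr = G / np.outer(sd, sd)
        re_corr = pd.DataFrame(corr, index=re_names, columns=re_names)

    if spec.df_method == "satterthwaite":
        contrasts = [np.eye(engine.p)[j] for j in range(engine.p)]
        dfs = _satterthwaite_dfs(engine, theta, sigma2, cov_rel, contrasts)
    else:
        dfs = np.full(engine.p, float(nmp))

    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    total_var = float(np.sum(np.diag(G)) + sigma2)
    dcoh = beta / np.sqrt(total_var)

    # Nakagawa R2: fixed variance over the realized design, random variance
    # averaged over rows.
    var_f = float(np.var(X @ beta))
    if isinstance(spec.random, RandomSlopes):
        Zm = _design_matrix(table, [(), *[(s,) for s in spec.random.slopes]])
        var_re = float(np.mean(np.einsum("ij,jk,ik->i", Zm, G, Zm)))
    else:
        var_re = float(np.sum(np.diag(G)))
    denom = var_f + var_re + sigma2
    r2m = var_f / denom if denom > 0 else 0.0
    r2c = (var_f + var_re) / denom if denom > 0 else 0.0

    coefs = pd.DataFrame({
        "estimate": beta, "se": se,
        "ci_low": beta - _Z95 * se, "ci_high": beta + _Z95 * se,
        "t": tvals, "df": dfs, "p": pvals, "d": dcoh,
    }, index=names)
    return LMMResult(
        coefficients=coefs,
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        re_variances=re_var, re_corr=re_corr, sigma2=float(sigma2),
        r2_marginal=r2m, r2_conditional=r2c,
        n_obs=engine.n, n_groups=getattr(engine, "m", engine.n),
        deviance=float(res.fun), converged=bool(res.success),
        spec=spec, _engine=engine, _theta=theta)


def _constant_outcome_result(table, spec, names, X, y, engine, re_names):
    beta = np.zeros(engine.p)
    if () in spec.fixed:
        beta[list(spec.fixed).index(())] = float(y[0])
    coefs = pd.DataFrame({
        "estimate": beta, "se": 0.0, "ci_low": beta, "ci_high": beta,
        "t": np.nan, "df": np.nan, "p": np.nan, "d": np.nan}, index=names)
    return LMMResult(coefficients=coefs,
                     cov_beta=pd.DataFrame(np.zeros((engine.p, engine.p)),
                                           index=names, columns=names),
                     re_variances={nm: 0.0 for nm in re_names}, re_corr=None,
                     sigma2=0.0, r2_marginal=0.0, r2_conditional=0.0,
                     n_obs=engine.n, n_groups=getattr(engine, "m", engine.n),
                     deviance=np.nan, converged=True, spec=spec)


# ---------------------------------------------------------------------------
# Factorial convenience wrapper and marginal effects
# ---------------------------------------------------------------------------


def fit_factorial(table: pd.DataFrame, outcome: str = "agreement",
                  salience_column: str = "salience_factor",
                  salience_levels: tuple[str, str] = ("hue", "saturation"),
                  df_method: str = "satterthwaite") -> LMMResult:
    """Full trend x framing x salience model with participant random slopes.

    ``salience_levels`` is (reference, high-salience) — ("hue", "saturation")
    for the color-scale manipulation, ("distributed", "clustered") for the
    spatial-pattern manipulation.
    """
    ref, pos = salience_levels
    tab = encode_treatment(table, "framing", "endangered")
    tab = tab.rename(columns={salience_column: "_sal"})
    tab = encode_treatment(tab, "_sal", ref)
    fixed = ((), ("trend",), ("invasive",), (pos,),
             ("trend", "invasive"), ("trend", pos), ("invasive", pos),
             ("trend", "invasive", pos))
    spec = LMMSpec(outcome=outcome, fixed=fixed,
                   random=RandomSlopes(group="participant_id",
                                       slopes=("trend", "invasive", pos)),
                   df_method=df_method)
    result = fit_lmm(tab, spec)
    result.factor_meta = {"salience_positive": pos, "salience_reference": ref}
    return result


@dataclass(frozen=True)
class AMEResult:
    framing: str
    salience: str
    ame: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def _trend_contrast(result: LMMResult, framing: str, salience: str) -> np.ndarray:
    pos = result.factor_meta.get("salience_positive")
    if pos is None:
        raise ValueError("result lacks factor metadata; fit with fit_factorial")
    F = 1.0 if framing == "invasive" else 0.0
    S = 1.0 if salience == pos else 0.0
    names = list(result.coefficients.index)
    want = {"trend": 1.0, f"trend:invasive": F, f"trend:{pos}": S,
            f"trend:invasive:{pos}": F * S}
    missing = [t for t in want if t not in names]
    if missing:
        raise ValueError(f"model is missing interaction terms: {missing}")
    c = np.zeros(len(names))
    for term, w in want.items():
        c[names.index(term)] = w
    return c


def ame_trend(result: LMMResult, framing: str, salience: str) -> AMEResult:
    """Average marginal effect of trend in one framing x salience cell.

    With treatment coding this is the sum of the trend coefficient and the
    active interaction coefficients; the SE comes from the delta method on
    the coefficient covariance. Exactly equals the averaged per-observation
    derivative for this linear model.
    """
    c = _trend_contrast(result, framing, salience)
    beta = result.coefficients["estimate"].to_numpy()
    V = result.cov_beta.to_numpy()
    ame = float(c @ beta)
    se = float(np.sqrt(c @ V @ c))
    z = ame / se if se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else np.nan
    return AMEResult(framing=framing, salience=salience, ame=ame, se=se,
                     ci_low=ame - _Z95 * se, ci_high=ame + _Z95 * se, z=z, p=p)


def ame_trend_numeric(result: LMMResult, table: pd.DataFrame, framing: str,
                      salience: str, h: float = 1e-6) -> float:
    """AME by numeric differentiation of model predictions (cross-check)."""
    pos = result.factor_meta["salience_positive"]
    ref = result.factor_meta["salience_reference"]
    tab = encode_treatment(table, "framing", "endangered")
    tab = tab.rename(columns={"salience_factor": "_sal"})
    tab = encode_treatment(tab, "_sal", ref)
    cell = tab[(tab["framing"] == framing) & (tab["_sal"] == salience)]
    if cell.empty:
        raise ValueError(f"no rows in cell {framing} x {salience}")
    beta = result.coefficients["estimate"].to_numpy()
    lo = _design_matrix(cell, result.spec.fixed) @ beta
    bumped = cell.copy()
    bumped["trend"] = bumped["trend"] + h
    hi = _design_matrix(bumped, result.spec.fixed) @ beta
    return float(np.mean(hi - lo) / h)


def exploratory_descriptor_model(table: pd.DataFrame,
                                 outcome: str = "agreement",
                                 df_method: str = "satterthwaite") -> LMMResult:
    """Agreement on trend + summed values + max slope, crossed intercepts."""
    fixed = ((), ("trend",), ("summed_values",), ("max_slope",))
    spec = LMMSpec(outcome=outcome, fixed=fixed,
                   random=CrossedIntercepts(("participant_id", "stimulus_id")),
                   df_method=df_method)
    return fit_lmm(table, spec)


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variances (intercept, trend, framing, salience),
    their correlation matrix, and the residual variance."""

    variances: tuple[float, float, float, float]
    corr: tuple[tuple[float, ...], ...]
    residual: float

    def covariance(self) -> np.ndarray:
        sd = np.sqrt(np.asarray(self.variances))
        G = np.asarray(self.corr) * np.outer(sd, sd)
        w, V = np.linalg.eigh(G)
        if w.min() < 0:  # guard against a rounded, slightly indefinite matrix
            G = (V * np.maximum(w, 0.0)) @ V.T
        return G


# Published fitted components of the experiment 2 agreement model
# (participant intercept / trend / framing / color-scale, residual 0.0316).
TABLE6_COMPONENTS = VarianceComponents(
    variances=(0.00829, 9.63e-4, 7.81e-6, 2.01e-4),
    corr=((1.0, 0.61, -0.32, -0.20),
          (0.61, 1.0, -0.74, -0.69),
          (-0.32, -0.74, 1.0, 0.99),
          (-0.20, -0.69, 0.99, 1.0)),
    residual=0.0316,
)


@dataclass(frozen=True)
class PowerResult:
    power: float
    rejections: int
    reps: int
    non_converged: int
    ci_low: float
    ci_high: float
    effect: float
    alpha: float


def build_power_design(experiment: int) -> pd.DataFrame:
    """One participant's 32-trial factorial table for the power simulation."""
    designs = enumerate_design(experiment)
    pos = "saturation" if experiment == 2 else "clustered"
    rows = [{"stimulus_id": d.stimulus_id, "trend": d.trend_level,
             "invasive": 1.0 if d.framing == "invasive" else 0.0,
             pos: 1.0 if d.salience_factor == pos else 0.0}
            for d in designs]
    return pd.DataFrame(rows)


def power_simulation(effect: float, n_participants: int, experiment: int = 3,
                     variance_components: VarianceComponents | None = None,
                     reps: int = 200, alpha: float = 0.05,
                     seed: int = 0) -> PowerResult:
    """Monte-Carlo power for the three-way interaction test.

    Each rep simulates one agreement value per trial from the mixed-model
    data-generating process (all fixed effects 0 except the three-way
    interaction coefficient = ``effect``, random effects and residual from
    ``variance_components``, default the published experiment 2 fit),
    refits the full factorial model, and tests the interaction at ``alpha``.
    Non-converged reps count as non-rejections and are reported separately.
    """
    if reps < 50:
        warnings.warn("fewer than 50 reps gives a wide binomial CI", stacklevel=2)
    vc = variance_components or TABLE6_COMPONENTS
    G = vc.covariance()
    Gchol = np.linalg.cholesky(G + 1e-12 * np.eye(4))
    pos = "saturation" if experiment == 2 else "clustered"
    base = build_power_design(experiment)
    fixed = ((), ("trend",), ("invasive",), (pos,),
             ("trend", "invasive"), ("trend", pos), ("invasive", pos),
             ("trend", "invasive", pos))
    term = f"trend:invasive:{pos}"
    X = _design_matrix(base, fixed)
    Z = X[:, :4]  # intercept, trend, framing, salience
    beta = np.zeros(X.shape[1])
    beta[fixed.index(("trend", "invasive", pos))] = effect
    g = len(base)
    tab = pd.concat([base] * n_participants, ignore_index=True)
    tab["participant_id"] = np.repeat(np.arange(n_participants), g)
    spec = LMMSpec(outcome="agreement", fixed=fixed,
                   random=RandomSlopes("participant_id",
                                       ("trend", "invasive", pos)),
                   df_method="residual")

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    rejections = 0
    non_converged = 0
    mu = X @ beta
    for _ in range(reps):
        b = rng.standard_normal((n_participants, 4)) @ Gchol.T
        eps = rng.normal(0.0, np.sqrt(vc.residual), size=(n_participants, g))
        y = mu[None, :] + b @ Z.T + eps
        tab["agreement"] = y.ravel()
        try:
            res = fit_lmm(tab, spec)
        except (ConvergenceError, np.linalg.LinAlgError):
            non_converged += 1
            continue
        if res.coefficients.loc[term, "p"] < alpha:
            rejections += 1
    power = rejections / reps
    lo, hi = _wilson_ci(rejections, reps)
    return PowerResult(power=power, rejections=rejections, reps=reps,
                       non_converged=non_converged, ci_low=lo, ci_high=hi,
                       effect=effect, alpha=alpha)


def _wilson_ci(k: int, n: int, z: float = _Z95) -> tuple[float, float]:
    phat = k / n
    denom = 1 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return center - half, center + half
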