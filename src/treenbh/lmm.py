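"""Linear mixed models with crossed random effects.

Fits Gaussian mixed models of the form

    y = X beta + sum_f Z_f u_f + e,    u_f ~ N(0, sigma_f^2 I),  e ~ N(0, sigma^2 I)

where the grouping factors f are crossed (non-nested), by maximising the
profiled (restricted) likelihood over relative standard deviations
theta_f = sigma_f / sigma.  One factor may additionally carry a correlated
random slope on a numeric covariate, in which case its per-level covariance
is parameterised through a lower-triangular relative Cholesky factor
(three parameters), so a likelihood-ratio test of slope + correlation has
two degrees of freedom.

The profiled deviance follows the standard sparse-Cholesky formulation:
with Lambda(theta) the relative covariance factor and A = Lambda'Z'Z Lambda + I,

    -2 l_ML   = log|A| + n (1 + log(2 pi r^2 / n))
    -2 l_REML = log|A| + log|X'V*^-1 X| + (n-p)(1 + log(2 pi r^2 / (n-p)))

with r^2 the penalised residual sum of squares at the conditional modes.
A dense brute-force multivariate-normal evaluation (`loglik_bruteforce`)
is provided as an independent oracle for small problems.

Fixed-effect terms are tuples of column names; an interaction is the
elementwise product of its (already transformed/standardised) columns.
Reported t statistics use a normal approximation for p-values; no
Satterthwaite/Kenward-Roger correction is applied.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "ModelFit",
    "StandardizationRecord",
    "standardize",
    "fit_lmm",
    "loglik_bruteforce",
    "akaike_compare",
    "lr_test",
    "vif",
    "r2_nakagawa",
    "predict_fixed",
    "term_label",
]

FixedTerm = tuple[str, ...]


def term_label(term: FixedTerm) -> str:
    return ":".join(term) if term else "(Intercept)"


@dataclass(frozen=True)
class RandomTerm:
    """A random-effects term: intercept by factor, optionally + correlated slope."""

    factor: str
    slope: str | None = None

    @property
    def n_theta(self) -> int:
        return 3 if self.slope else 1

    @property
    def label(self) -> str:
        return f"{self.slope or 1}|{self.factor}"


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[FixedTerm, ...]
    random: tuple[RandomTerm, ...] = ()
    method: str = "REML"

    def __post_init__(self):
        if self.method not in ("REML", "ML"):
            raise ValueError(f"method must be 'REML' or 'ML', got {self.method!r}")
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicated fixed terms")
        if len({r.label for r in self.random}) != len(self.random):
            raise ValueError("duplicated random terms")

    def with_method(self, method: str) -> "ModelSpec":
        return replace(self, method=method)

    def fixed_labels(self) -> list[str]:
        return ["(Intercept)"] + [term_label(t) for t in self.fixed]


@dataclass
class StandardizationRecord:
    """Training-set scale divisors (sample sd) and raw ranges per predictor.

    Predictors are divided by their standard deviation, not mean-centred.
    The record is reapplied verbatim to new data so that cross-site
    predictions use the training-set scale.
    """

    divisors: dict[str, float]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def apply(
        self, data: pd.DataFrame, columns: Sequence[str] | None = None
    ) -> pd.DataFrame:
        out = data.copy()
        cols = self.divisors if columns is None else columns
        for col in cols:
            if col not in self.divisors:
                continue
            if col not in out.columns:
                raise KeyError(f"missing covariate {col!r} in new data")
            out[col] = out[col] / self.divisors[col]
        return out

    def to_dict(self) -> dict:
        return {
            "divisors": dict(self.divisors),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls(
            divisors=dict(d["divisors"]),
            ranges={k: (v[0], v[1]) for k, v in d.get("ranges", {}).items()},
        )


def standardize(
    data: pd.DataFrame, predictors: Sequence[str]
) -> tuple[pd.DataFrame, StandardizationRecord]:
    """Divide each predictor by its sample standard deviation (no centring)."""
    out = data.copy()
    divisors: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for col in predictors:
        x = np.asarray(data[col], dtype=float)
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd <= 1e-12:
            raise ValueError(f"predictor {col!r} has zero or undefined sd")
        out[col] = x / sd
        divisors[col] = sd
        ranges[col] = (float(np.min(x)), float(np.max(x)))
    return out, StandardizationRecord(divisors, ranges)


# ---------------------------------------------------------------------------
# design construction


def build_fixed_matrix(data: pd.DataFrame, fixed: Sequence[FixedTerm]) -> np.ndarray:
    n = len(data)
    cols = [np.ones(n)]
    for term in fixed:
        x = np.ones(n)
        for name in term:
            x = x * np.asarray(data[name], dtype=float)
        cols.append(x)
    return np.column_stack(cols)


class _RandomStructure:
    """Sparse Z and the theta -> Lambda mapping for a set of random terms."""

    def __init__(self, data: pd.DataFrame, random: Sequence[RandomTerm]):
        n = len(data)
        self.terms = list(random)
        self.levels: list[np.ndarray] = []
        z_blocks = []
        self.block_slices: list[slice] = []
        offset = 0
        for term in self.terms:
            codes, levels = pd.factorize(data[term.factor], sort=True)
            if (codes < 0).any():
                raise ValueError(f"missing values in factor {term.factor!r}")
            q = len(levels)
            if q < 2:
                raise ValueError(
                    f"random factor {term.factor!r} needs >= 2 levels, has {q}"
                )
            self.levels.append(np.asarray(levels))
            rows = np.arange(n)
            if term.slope is None:
                z = sparse.csc_matrix(
                    (np.ones(n), (rows, codes)), shape=(n, q)
                )
                ncol = q
            else:
                x = np.asarray(data[term.slope], dtype=float)
                r = np.concatenate([rows, rows])
                c = np.concatenate([2 * codes, 2 * codes + 1])
                v = np.concatenate([np.ones(n), x])
                z = sparse.csc_matrix((v, (r, c)), shape=(n, 2 * q))
                ncol = 2 * q
            z_blocks.append(z)
            self.block_slices.append(slice(offset, offset + ncol))
            offset += ncol
        self.q = offset
        self.Z = sparse.hstack(z_blocks, format="csc") if z_blocks else None
        self.n_theta = sum(t.n_theta for t in self.terms)
        # precompute Lambda sparsity pattern: (row, col, theta index)
        rows, cols, tidx = [], [], []
        th_off = 0
        for term, sl in zip(self.terms, self.block_slices):
            idx = np.arange(sl.start, sl.stop)
            if term.slope is None:
                rows.append(idx)
                cols.append(idx)
                tidx.append(np.full(len(idx), th_off))
                th_off += 1
            else:
                ints = idx[0::2]
                slps = idx[1::2]
                rows.extend([ints, slps, slps])
                cols.extend([ints, ints, slps])
                tidx.extend(
                    [
                        np.full(len(ints), th_off),
                        np.full(len(ints), th_off + 1),
                        np.full(len(ints), th_off + 2),
                    ]
                )
                th_off += 3
        if rows:
            self._lrows = np.concatenate(rows)
            self._lcols = np.concatenate(cols)
            self._ltidx = np.concatenate(tidx)
        else:
            self._lrows = self._lcols = self._ltidx = np.empty(0, dtype=int)

    def lam(self, theta: np.ndarray) -> sparse.csc_matrix:
        data = np.asarray(theta, dtype=float)[self._ltidx]
        return sparse.csc_matrix(
            (data, (self._lrows, self._lcols)), shape=(self.q, self.q)
        )

    def default_bounds(self) -> list[tuple[float, float]]:
        bounds = []
        for term in self.terms:
            if term.slope is None:
                bounds.append((0.0, 1e3))
            else:
                bounds.extend([(0.0, 1e3), (-1e3, 1e3), (0.0, 1e3)])
        return bounds


# ---------------------------------------------------------------------------
# profiled deviance


def _profiled_pieces(theta, rs: _RandomStructure | None, X, y):
    """Return (logdet_A, logdet_RX, pwrss, beta, XtX_adj_cholesky)."""
    n, p = X.shape
    if rs is None or rs.q == 0:
        XtX = X.T @ X
        cf = cho_factor(XtX, lower=True)
        beta = cho_solve(cf, X.T @ y)
        resid = y - X @ beta
        pwrss = float(resid @ resid)
        logdet_rx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return 0.0, logdet_rx, pwrss, beta, cf, None
    lam = rs.lam(theta)
    ZL = rs.Z @ lam
    A = (ZL.T @ ZL).toarray()
    A[np.diag_indices_from(A)] += 1.0
    L = np.linalg.cholesky(A)
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(L))))
    ZLty = ZL.T @ y
    ZLtX = ZL.T @ X
    cu = solve_triangular(L, ZLty, lower=True)
    Cx = solve_triangular(L, ZLtX, lower=True)
    XtX_adj = X.T @ X - Cx.T @ Cx
    Xty_adj = X.T @ y - Cx.T @ cu
    cf = cho_factor(XtX_adj, lower=True)
    beta = cho_solve(cf, Xty_adj)
    u = solve_triangular(L.T, cu - Cx @ beta, lower=False)
    resid = y - X @ beta - ZL @ u
    pwrss = float(resid @ resid + u @ u)
    logdet_rx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return logdet_a, logdet_rx, pwrss, beta, cf, u


_PWRSS_FLOOR = 1e-28


def _deviance(theta, rs, X, y, method) -> float:
    n, p = X.shape
    try:
        logdet_a, logdet_rx, pwrss, _, _, _ = _profiled_pieces(theta, rs, X, y)
    except np.linalg.LinAlgError:
        return np.inf
    pwrss = max(pwrss, _PWRSS_FLOOR)
    if method == "ML":
        return logdet_a + n * (1.0 + math.log(2.0 * math.pi * pwrss / n))
    return (
        logdet_a
        + logdet_rx
        + (n - p) * (1.0 + math.log(2.0 * math.pi * pwrss / (n - p)))
    )


# ---------------------------------------------------------------------------
# fit result


@dataclass
class ModelFit:
    spec: ModelSpec
    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    varcomps: dict[str, float | dict]
    resid_var: float
    theta: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    singular: bool
    var_fixed: float
    ranef_var: dict[str, float]
    standardization: StandardizationRecord | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def method(self) -> str:
        return self.spec.method

    def coefficients(self) -> pd.DataFrame:
        t = np.divide(
            self.beta, self.se, out=np.full_like(self.beta, np.nan),
            where=self.se > 0,
        )
        p = 2.0 * norm_dist.sf(np.abs(t))
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "t": t, "p": p},
            index=self.fixed_names,
        )

    def coef(self, label: str) -> float:
        return float(self.beta[self.fixed_names.index(label)])

    def total_random_variance(self) -> float:
        return float(sum(self.ranef_var.values()))

    def to_json(self) -> str:
        d = {
            "response": self.spec.response,
            "fixed": [list(t) for t in self.spec.fixed],
            "random": [
                {"factor": r.factor, "slope": r.slope} for r in self.spec.random
            ],
            "method": self.spec.method,
            "fixed_names": self.fixed_names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "varcomps": self.varcomps,
            "resid_var": self.resid_var,
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "singular": self.singular,
            "var_fixed": self.var_fixed,
            "ranef_var": self.ranef_var,
            "messages": self.messages,
        }
        if self.standardization is not None:
            d["standardization"] = self.standardization.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        d = json.loads(text)
        spec = ModelSpec(
            response=d["response"],
            fixed=tuple(tuple(t) for t in d["fixed"]),
            random=tuple(
                RandomTerm(r["factor"], r.get("slope")) for r in d["random"]
            ),
            method=d["method"],
        )
        rec = d.get("standardization")
        return cls(
            spec=spec,
            fixed_names=list(d["fixed_names"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            varcomps=d["varcomps"],
            resid_var=d["resid_var"],
            theta=np.asarray(d["theta"], dtype=float),
            loglik=d["loglik"],
            aic=d["aic"],
            n_obs=d["n_obs"],
            n_params=d["n_params"],
            converged=d["converged"],
            singular=d["singular"],
            var_fixed=d["var_fixed"],
            ranef_var=d["ranef_var"],
            standardization=StandardizationRecord.from_dict(rec) if rec else None,
            messages=list(d.get("messages", [])),
        )


def _validate_spec(data: pd.DataFrame, spec: ModelSpec) -> None:
    needed = {spec.response}
    for t in spec.fixed:
        needed.update(t)
    for r in spec.random:
        needed.add(r.factor)
        if r.slope:
            needed.add(r.slope)
    missing = needed - set(data.columns)
    if missing:
        raise KeyError(f"data is missing columns: {sorted(missing)}")
    sub = data[sorted(needed)]
    if sub.isna().any().any():
        raise ValueError("data contains missing values in model columns")


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    theta0: np.ndarray | None = None,
    n_starts: int = 2,
    standardization: StandardizationRecord | None = None,
) -> ModelFit:
    """Fit the mixed model by maximising the profiled (RE)ML likelihood.

    Variance parameters are optimised as relative standard deviations
    (bounded at zero, so singular fits are representable); `n_starts`
    multi-start points guard against local optima, and `theta0` can warm
    start from a previous fit of the same random structure.
    """
    _validate_spec(data, spec)
    y = np.asarray(data[spec.response], dtype=float)
    X = build_fixed_matrix(data, spec.fixed)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"not enough observations ({n}) for {p} fixed effects")
    rs = _RandomStructure(data, spec.random) if spec.random else None

    messages: list[str] = []
    if rs is None or rs.n_theta == 0:
        theta = np.empty(0)
        converged = True
    else:
        bounds = rs.default_bounds()
        starts: list[np.ndarray] = []
        n_base = max(1, n_starts)
        if theta0 is not None and len(theta0) == rs.n_theta:
            starts.append(np.asarray(theta0, dtype=float))
            n_base = max(0, n_starts - 1)
        base_starts = [1.0, 0.1]
        for s in base_starts[:n_base]:
            t0 = []
            for term in rs.terms:
                t0.extend([s] if term.slope is None else [s, 0.0, s])
            starts.append(np.array(t0))
        best = None
        converged = False
        for t0 in starts:
            res = optimize.minimize(
                _deviance,
                t0,
                args=(rs, X, y, spec.method),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        theta = np.maximum(
            best.x, [b[0] for b in rs.default_bounds()]
        )
        converged = bool(best.success) or np.isfinite(best.fun)
        if not best.success:
            messages.append(f"optimizer: {best.message}")

    logdet_a, logdet_rx, pwrss, beta, cf, _ = _profiled_pieces(theta, rs, X, y)
    pwrss = max(pwrss, _PWRSS_FLOOR)
    denom = n if spec.method == "ML" else n - p
    sigma2 = pwrss / denom
    dev = _deviance(theta, rs, X, y, spec.method)
    loglik = -0.5 * dev

    # variance components on the response scale
    varcomps: dict[str, float | dict] = {}
    ranef_var: dict[str, float] = {}
    singular = False
    if rs is not None:
        off = 0
        for term in rs.terms:
            if term.slope is None:
                v = sigma2 * theta[off] ** 2
                varcomps[term.factor] = float(v)
                ranef_var[term.label] = float(v)
                if theta[off] < 1e-4:
                    singular = True
                off += 1
            else:
                t11, t21, t22 = theta[off : off + 3]
                g = sigma2 * np.array(
                    [[t11**2, t11 * t21], [t11 * t21, t21**2 + t22**2]]
                )
                varcomps[term.factor] = {
                    "intercept": float(g[0, 0]),
                    "slope": float(g[1, 1]),
                    "cov": float(g[0, 1]),
                }
                x = np.asarray(data[term.slope], dtype=float)
                ranef_var[term.label] = float(
                    g[0, 0] + 2.0 * g[0, 1] * x.mean() + g[1, 1] * np.mean(x**2)
                )
                if t11 < 1e-4 or t22 < 1e-4:
                    singular = True
                off += 3
    if singular:
        messages.append("singular fit: one or more variance components near zero")
        warnings.warn("singular fit: variance component at boundary", RuntimeWarning)

    # SE(beta) = sqrt(diag(sigma2 * (X'V*^-1 X)^-1))
    cov_beta = sigma2 * cho_solve(cf, np.eye(p))
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    eta = X @ beta
    var_fixed = float(np.var(eta, ddof=1)) if n > 1 else 0.0

    n_theta = 0 if rs is None else rs.n_theta
    n_params = p + n_theta + 1
    aic = -2.0 * loglik + 2.0 * n_params

    return ModelFit(
        spec=spec,
        fixed_names=spec.fixed_labels(),
        beta=beta,
        se=se,
        varcomps=varcomps,
        resid_var=float(sigma2),
        theta=np.asarray(theta, dtype=float),
        loglik=float(loglik),
        aic=float(aic),
        n_obs=n,
        n_params=n_params,
        converged=converged,
        singular=singular,
        var_fixed=var_fixed,
        ranef_var=ranef_var,
        standardization=standardization,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# dense oracle


def loglik_bruteforce(
    data: pd.DataFrame,
    spec: ModelSpec,
    varcomps: Mapping[str, float | Mapping[str, float]],
    resid_sd: float,
) -> float:
    """Evaluate the (restricted) log-likelihood by dense covariance assembly.

    ``V = sum_f Z_f G_f Z_f' + resid_sd^2 I`` is formed explicitly and the
    Gaussian likelihood computed at the GLS fixed-effect solution — an
    independent check of the profiled sparse computation; restricted to
    small n (dense n x n algebra).
    """
    _validate_spec(data, spec)
    n = len(data)
    if n > 2000:
        raise ValueError("brute-force oracle is restricted to small n")
    y = np.asarray(data[spec.response], dtype=float)
    X = build_fixed_matrix(data, spec.fixed)
    p = X.shape[1]
    V = resid_sd**2 * np.eye(n)
    for term in spec.random:
        codes, levels = pd.factorize(data[term.factor], sort=True)
        q = len(levels)
        g = varcomps[term.factor]
        if term.slope is None:
            Z = np.zeros((n, q))
            Z[np.arange(n), codes] = 1.0
            V += float(g) * Z @ Z.T
        else:
            x = np.asarray(data[term.slope], dtype=float)
            G = np.array(
                [[g["intercept"], g["cov"]], [g["cov"], g["slope"]]]
            )
            Z = np.zeros((n, 2 * q))
            Z[np.arange(n), 2 * codes] = 1.0
            Z[np.arange(n), 2 * codes + 1] = x
            Gfull = np.kron(np.eye(q), G)
            V += Z @ Gfull @ Z.T
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    if spec.method == "ML":
        return -0.5 * (n * math.log(2 * math.pi) + logdet_v + quad)
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    return -0.5 * (
        (n - p) * math.log(2 * math.pi) + logdet_v + logdet_x + quad
    )


# ---------------------------------------------------------------------------
# model comparison


def akaike_compare(fits: Sequence[ModelFit], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """AIC table with delta-AIC and Akaike weights w = exp(-d/2)/sum."""
    if not fits:
        raise ValueError("no fits to compare")
    methods = {f.method for f in fits}
    if len(methods) != 1:
        raise ValueError("cannot compare fits with mixed REML/ML estimation")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits were not obtained on identical data (n differs)")
    if fits[0].method == "REML":
        fixed_sets = {tuple(f.spec.fixed) for f in fits}
        if len(fixed_sets) != 1:
            raise ValueError(
                "REML fits with different fixed effects are not comparable; "
                "use ML for fixed-structure comparison"
            )
    if labels is None:
        labels = [
            " + ".join(f.fixed_names[1:]) or "(Intercept)" for f in fits
        ]
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    tab = pd.DataFrame(
        {"aic": aics, "delta_aic": delta, "weight": w, "n_params": [f.n_params for f in fits]},
        index=list(labels),
    )
    return tab.sort_values("aic")


def lr_test(nested: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    Enforces the two-stage convention: random-structure comparisons (same
    fixed part) must both be REML; fixed-structure comparisons must both
    be ML.
    """
    if nested.method != full.method:
        raise ValueError("cannot mix REML and ML log-likelihoods in one test")
    if nested.spec.response != full.spec.response or nested.n_obs != full.n_obs:
        raise ValueError("fits are not on identical data")
    same_fixed = tuple(nested.spec.fixed) == tuple(full.spec.fixed)
    same_random = tuple(nested.spec.random) == tuple(full.spec.random)
    if nested.method == "REML" and not same_fixed:
        raise ValueError(
            "REML likelihood-ratio tests require identical fixed effects "
            "(random-structure test); refit with ML to compare fixed effects"
        )
    if nested.method == "ML" and not same_random:
        raise ValueError(
            "ML likelihood-ratio tests here compare fixed structures; "
            "random structures must match"
        )
    if not set(nested.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("models are not nested in their fixed effects")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 and chi2 <= 1e-12 else float(chi2_dist.sf(chi2, max(df, 1)))
    if df == 0:
        p = 1.0 if chi2 <= 1e-8 else 0.0
    return chi2, df, p


def vif(data: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors, VIF_k = 1/(1 - R^2_k), main effects only."""
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for k in predictors:
        others = [c for c in predictors if c != k]
        X = np.column_stack(
            [np.ones(len(data))] + [np.asarray(data[c], float) for c in others]
        )
        yk = np.asarray(data[k], float)
        coef, *_ = np.linalg.lstsq(X, yk, rcond=None)
        resid = yk - X @ coef
        sst = float(np.sum((yk - yk.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    if np.isinf(s).any():
        warnings.warn("perfect collinearity: infinite VIF", RuntimeWarning)
    return s


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional r² (fixed vs fixed+random variance shares)."""
    vf = fit.var_fixed
    vr = fit.total_random_variance()
    tot = vf + vr + fit.resid_var
    if tot <= 0:
        return 0.0, 0.0
    return vf / tot, (vf + vr) / tot


def predict_fixed(
    fit: ModelFit,
    record: StandardizationRecord | None,
    newdata: pd.DataFrame,
    *,
    back_transform: bool = True,
    extrapolation_factor: float = 5.0,
) -> np.ndarray:
    """Fixed-effects-only predictions (random effects at zero).

    `newdata` carries covariates on the raw (log-transformed but not yet
    standardised) scale; the training standardisation record is applied
    before evaluating the linear predictor.  With ``back_transform`` the
    log10-scale predictor is returned as cm^3 year^-1.
    """
    record = record if record is not None else fit.standardization
    needed = sorted({name for term in fit.spec.fixed for name in term})
    missing = [c for c in needed if c not in newdata.columns]
    if missing:
        raise KeyError(f"new data is missing covariates: {missing}")
    scaled = record.apply(newdata, needed) if record is not None else newdata.copy()
    if record is not None and record.ranges:
        for col, (lo, hi) in record.ranges.items():
            if col not in needed or col not in newdata.columns:
                continue
            x = np.asarray(newdata[col], float)
            width = max(hi - lo, 1e-12)
            if np.any(x < lo - extrapolation_factor * width) or np.any(
                x > hi + extrapolation_factor * width
            ):
                warnings.warn(
                    f"covariate {col!r} far outside training range: "
                    "extrapolating fixed-effect predictions",
                    RuntimeWarning,
                )
    X = build_fixed_matrix(scaled, fit.spec.fixed)
    eta = X @ fit.beta
    return np.power(10.0, eta) if back_transform else eta
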