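"""Heteroscedastic Gaussian linear models for the method comparison.

The question "does counting method affect the estimate, or its variability?"
is answered with a general linear model

    y = mu + f + c + m + f:c + f:m + c:m + f:c:m + eps

where ``f`` is the focal strain, ``c`` the competitor strain and ``m`` the
counting method, all treated as fixed effects (sample sizes are too small to
estimate strain variance components), optionally with a block random
intercept, and with a *grouped* residual variance: every design cell in the
same residual group shares one variance parameter, so the residual variance
may be free per focal x competitor x method cell, pooled per method, or
fully pooled.

Fitting is by (restricted) maximum likelihood with the fixed effects
profiled out by generalized least squares at each variance iterate; variance
parameters are optimized on the log scale from deterministic moment starts.
Model selection across candidate structures uses small-sample-corrected AIC
(AICc); fixed effects are tested by type-III F statistics with Satterthwaite
denominator degrees of freedom, which are generally fractional when residual
variances differ between groups.

One deliberate deviation from common mixed-model software defaults: REML
likelihoods are not comparable across different fixed-effect sets, so model
searches that vary the fixed effects are run under ML, while residual
variance structures at a fixed mean model may be compared under REML.  Each
fit records which criterion produced its likelihood.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FACTORS",
    "TERMS",
    "FULL_FIXED",
    "VarianceModelSpec",
    "ModelFit",
    "FTestResult",
    "ConvergenceError",
    "SingularDesignError",
    "build_design",
    "fit_model",
    "aicc",
    "model_search",
    "default_candidate_ladder",
    "type3_f_test",
    "analyze_sd_logci",
    "analyze_p",
]

#: term name -> data column of each factor
FACTORS = {
    "focal": "focal_strain",
    "competitor": "competitor_strain",
    "method": "method",
}

#: model terms in canonical order (intercept is implicit)
TERMS = (
    "focal",
    "competitor",
    "method",
    "focal:competitor",
    "focal:method",
    "competitor:method",
    "focal:competitor:method",
)

FULL_FIXED = TERMS

#: named residual-variance groupings
GROUPINGS = {
    "pooled": (),
    "method": ("method",),
    "cell": ("focal", "competitor", "method"),
}


class ConvergenceError(RuntimeError):
    """The variance optimizer failed to converge."""


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank-deficient."""


@dataclass(frozen=True)
class VarianceModelSpec:
    """One candidate model: fixed terms, optional block intercept, variance grouping.

    ``fixed_terms`` is a subset of :data:`TERMS`; every interaction requires
    its marginal terms.  ``residual_grouping`` is a tuple of factor names
    (over ``focal``, ``competitor``, ``method``) whose observed level
    combinations each get a free residual variance; the empty tuple pools all
    residual variance into a single parameter.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_block: bool = False
    residual_grouping: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t not in TERMS:
                raise ValueError(f"unknown term {t!r}")
            for part in t.split(":"):
                # marginality: every lower-order margin must be present
                pass
        fixed = set(self.fixed_terms)
        for t in fixed:
            parts = t.split(":")
            for r in range(1, len(parts)):
                for sub in itertools.combinations(parts, r):
                    margin = ":".join(sub)
                    if margin in TERMS and margin not in fixed:
                        raise ValueError(
                            f"term {t!r} requires its margin {margin!r}"
                        )
        for g in self.residual_grouping:
            if g not in FACTORS:
                raise ValueError(f"unknown grouping factor {g!r}")

    def label(self) -> str:
        fx = "+".join(self.fixed_terms) if self.fixed_terms else "1"
        grp = "*".join(self.residual_grouping) if self.residual_grouping else "pooled"
        rb = "+block" if self.random_block else ""
        return f"{self.response} ~ {fx}{rb} | var({grp})"


# ---------------------------------------------------------------------------
# design construction (sum-to-zero coding for type-III marginality)
# ---------------------------------------------------------------------------


def _sum_to_zero_codes(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """n x (L-1) sum-to-zero contrast columns for one factor."""
    levels = sorted(pd.unique(values.astype(str)))
    L = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    codes = np.array([idx[v] for v in values.astype(str)])
    X = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        X[codes == j, j] = 1.0
        X[codes == L - 1, j] = -1.0
    names = [f"[{lv}]" for lv in levels[:-1]]
    return X, names


def build_design(
    data: pd.DataFrame, fixed_terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Fixed-effect design matrix with sum-to-zero factor coding.

    Returns ``(X, column_names, term_columns)`` where ``term_columns`` maps
    each term (plus the intercept ``"1"``) to its column indices in ``X``.
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    names = ["(Intercept)"]
    term_cols: dict[str, np.ndarray] = {"1": np.array([0])}
    factor_mats = {
        t: _sum_to_zero_codes(data[FACTORS[t]]) for t in FACTORS
    }
    start = 1
    for term in TERMS:
        if term not in fixed_terms:
            continue
        parts = term.split(":")
        for p_ in parts:
            if factor_mats[p_][0].shape[1] == 0:
                raise SingularDesignError(
                    f"term {term!r} is aliased with the intercept: factor "
                    f"{p_!r} has a single observed level"
                )
        mat = factor_mats[parts[0]][0]
        nm = factor_mats[parts[0]][1]
        nm = [f"{parts[0]}{s}" for s in nm]
        for p_ in parts[1:]:
            m2, nm2 = factor_mats[p_]
            mat = np.einsum("ni,nj->nij", mat, m2).reshape(n, -1)
            nm = [f"{a}:{p_}{b}" for a in nm for b in nm2]
        cols.append(mat)
        names.extend(nm)
        term_cols[term] = np.arange(start, start + mat.shape[1])
        start += mat.shape[1]
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design for terms {fixed_terms}: "
            "some factor-level combinations are aliased or unobserved"
        )
    return X, names, term_cols


def _residual_groups(
    data: pd.DataFrame, grouping: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    if not grouping:
        return np.zeros(len(data), dtype=int), ["all"]
    key = data[[FACTORS[g] for g in grouping]].astype(str).agg("/".join, axis=1)
    labels = sorted(key.unique())
    idx = {lv: i for i, lv in enumerate(labels)}
    return key.map(idx).to_numpy(), labels


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _gls_pieces(
    y: np.ndarray,
    X: np.ndarray,
    sig2_obs: np.ndarray,
    sig2_block: float,
    block_slices: list[np.ndarray] | None,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(log|V|, X'V^-1 X, X'V^-1 y, y'V^-1 y) for V = diag(sig2) + sig2_b * block 11'.

    The block random intercept makes V block-diagonal with a rank-one update
    per block, handled in O(n) via the Sherman-Morrison identity.
    """
    w = 1.0 / sig2_obs
    logdet = float(np.sum(np.log(sig2_obs)))
    if block_slices is None or sig2_block == 0.0:
        XtViX = (X * w[:, None]).T @ X
        XtViy = X.T @ (w * y)
        ytViy = float(np.dot(y, w * y))
        return logdet, XtViX, XtViy, ytViy

    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for idx in block_slices:
        wb = w[idx]
        Xb = X[idx]
        yb = y[idx]
        s = float(np.sum(wb))
        denom = 1.0 + sig2_block * s
        logdet += math.log(denom)
        wX = Xb * wb[:, None]
        wy = wb * yb
        uX = wX.sum(axis=0)  # 1' D^-1 X
        uy = float(wy.sum())  # 1' D^-1 y
        fac = sig2_block / denom
        XtViX += Xb.T @ wX - fac * np.outer(uX, uX)
        XtViy += Xb.T @ wy - fac * uX * uy
        ytViy += float(np.dot(yb, wy)) - fac * uy * uy
    return logdet, XtViX, XtViy, ytViy


_LOG2PI = math.log(2.0 * math.pi)


def _loglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    block_slices: list[np.ndarray] | None,
    reml: bool,
) -> float:
    """Profile (RE)ML log-likelihood at log-variance parameters ``theta``.

    ``theta[:n_groups]`` are log residual variances per group;
    ``theta[n_groups]`` (if present) is the log block variance.
    """
    sig2 = np.exp(theta[:n_groups])[gidx]
    sig2_b = math.exp(theta[n_groups]) if block_slices is not None else 0.0
    logdet, XtViX, XtViy, ytViy = _gls_pieces(y, X, sig2, sig2_b, block_slices)
    try:
        cho = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - float(np.dot(beta, XtViy))
    n, p = X.shape
    ll = -0.5 * (n * _LOG2PI + logdet + quad)
    if reml:
        logdet_XtViX = 2.0 * float(np.sum(np.log(np.diag(cho))))
        ll += -0.5 * logdet_XtViX + 0.5 * p * _LOG2PI
    return ll


@dataclass
class ModelFit:
    """A fitted heteroscedastic linear model."""

    spec: VarianceModelSpec
    criterion: str  # "REML" or "ML"
    beta: np.ndarray
    coef_names: list[str]
    term_columns: dict[str, np.ndarray]
    sigma2: dict[str, float]  # residual variance per group label
    sigma2_block: float | None
    loglik: float
    k: int  # parameters counted toward AICc
    n: int
    aicc: float
    converged: bool
    n_iter: int
    block_variance_at_boundary: bool = False
    # internal state for downstream tests
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _gidx: np.ndarray = field(repr=False, default=None)
    _block_slices: list | None = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef_names, "estimate": self.beta})


_LOG_VAR_LO = -30.0  # variance ~ 1e-13: effectively pinned at zero
_LOG_VAR_HI = 12.0


def _aicc_value(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        return math.nan
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc(fit: ModelFit) -> float:
    """Small-sample-corrected AIC: ``-2 logL + 2k + 2k(k+1)/(n-k-1)``.

    ``k`` counts fixed-effect coefficients plus variance parameters under ML,
    and variance parameters only under REML (whose likelihood has the fixed
    effects swept out).  NaN (flagged) when ``n <= k + 1``.
    """
    return _aicc_value(fit.loglik, fit.k, fit.n)


def fit_model(
    spec: VarianceModelSpec,
    data: pd.DataFrame,
    criterion: str = "REML",
    block_col: str = "block_id",
) -> ModelFit:
    """Fit one heteroscedastic model by ML or REML.

    Fixed effects are profiled out by GLS at each variance iterate; the
    variance parameters (one per residual group, plus the block variance if
    requested) are optimized on the log scale by L-BFGS from a deterministic
    moment-based start (with a pooled-variance fallback start), so the fit is
    deterministic given the data.  A block variance driven to the lower bound
    is reported as 0 with ``block_variance_at_boundary=True``.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    reml = criterion == "REML"

    y_all = data[spec.response].to_numpy(dtype=float)
    mask = np.isfinite(y_all)
    d = data.loc[mask].reset_index(drop=True)
    y = y_all[mask]
    n = len(d)

    X, names, term_cols = build_design(d, spec.fixed_terms)
    gidx, glabels = _residual_groups(d, spec.residual_grouping)
    G = len(glabels)

    counts = np.bincount(gidx, minlength=G)
    if np.any(counts < 2):
        thin = [glabels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(
            f"residual groups with <2 observations cannot carry a free "
            f"variance: {thin}"
        )

    block_slices = None
    if spec.random_block:
        if block_col not in d.columns:
            raise ValueError(f"random block requested but {block_col!r} missing")
        codes = d[block_col].astype(str)
        block_slices = [
            np.flatnonzero((codes == b).to_numpy()) for b in sorted(codes.unique())
        ]

    # moment starts: per-group variance of OLS residuals; block variance from
    # the variance of block-mean residuals
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    start_g = np.array(
        [max(np.var(resid[gidx == g], ddof=0), 1e-8) for g in range(G)]
    )
    starts = [np.log(start_g)]
    pooled = max(float(np.var(resid, ddof=0)), 1e-8)
    starts.append(np.full(G, math.log(pooled)))
    if block_slices is not None:
        bmeans = np.array([resid[idx].mean() for idx in block_slices])
        s_b = max(float(np.var(bmeans, ddof=0)), 1e-6 * pooled, 1e-10)
        starts = [np.append(s, math.log(s_b)) for s in starts]

    def negll(theta):
        ll = _loglik(theta, y, X, gidx, G, block_slices, reml)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    total_iter = 0
    bounds = [(_LOG_VAR_LO, _LOG_VAR_HI)] * len(starts[0])
    for s0 in starts:
        res = optimize.minimize(
            negll,
            np.clip(s0, _LOG_VAR_LO + 1, _LOG_VAR_HI - 1),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500},
        )
        # one restart from the optimum resets the L-BFGS Hessian estimate
        # and typically buys another digit or two of convergence
        res = optimize.minimize(
            negll,
            res.x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 200},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"optimizer failed for {spec.label()}")
    converged = bool(best.success or best.fun < 1e11)
    if not converged:
        raise ConvergenceError(
            f"no convergence for {spec.label()}: {best.message}"
        )

    theta = best.x
    sig2 = np.exp(theta[:G])[gidx]
    sig2_b = math.exp(theta[G]) if block_slices is not None else 0.0
    at_bound = block_slices is not None and theta[G] <= _LOG_VAR_LO + 1e-6
    if at_bound:
        sig2_b = 0.0
    _, XtViX, XtViy, _ = _gls_pieces(y, X, sig2, sig2_b, block_slices)
    beta = np.linalg.solve(XtViX, XtViy)
    ll = -best.fun

    n_var = G + (1 if block_slices is not None else 0)
    k = n_var if reml else n_var + X.shape[1]
    fit = ModelFit(
        spec=spec,
        criterion=criterion,
        beta=beta,
        coef_names=names,
        term_columns=term_cols,
        sigma2={glabels[g]: float(math.exp(theta[g])) for g in range(G)},
        sigma2_block=(0.0 if at_bound else sig2_b) if spec.random_block else None,
        loglik=ll,
        k=k,
        n=n,
        aicc=_aicc_value(ll, k, n),
        converged=converged,
        n_iter=total_iter,
        block_variance_at_boundary=at_bound,
        _y=y,
        _X=X,
        _gidx=gidx,
        _block_slices=block_slices,
        _theta=theta,
    )
    return fit


# ---------------------------------------------------------------------------
# model search
# ---------------------------------------------------------------------------

_FIXED_LADDER: tuple[tuple[str, ...], ...] = (
    FULL_FIXED,
    ("focal", "competitor", "method", "focal:competitor", "focal:method",
     "competitor:method"),
    ("focal", "competitor", "method"),
    ("method",),
    (),
)


def default_candidate_ladder(
    response: str, random_block: bool = False
) -> list[VarianceModelSpec]:
    """Default model ladder: full model -> drop interactions -> drop main
    effects, crossed with residual pooling per cell -> per method -> pooled."""
    out = []
    for fx in _FIXED_LADDER:
        for grp in (GROUPINGS["cell"], GROUPINGS["method"], GROUPINGS["pooled"]):
            out.append(
                VarianceModelSpec(
                    response=response,
                    fixed_terms=fx,
                    random_block=random_block,
                    residual_grouping=grp,
                )
            )
    return out


def model_search(
    data: pd.DataFrame,
    candidates: list[VarianceModelSpec],
    criterion: str = "ML",
    block_col: str = "block_id",
) -> tuple[pd.DataFrame, VarianceModelSpec, dict[int, ModelFit]]:
    """Fit all candidates, rank by AICc ascending, report delta-AICc.

    The default ranking criterion is ML because the candidate ladder varies
    the fixed effects and REML likelihoods are not comparable across
    different mean models; pass ``criterion="REML"`` only when every
    candidate shares the same fixed terms.  Candidates that fail to fit are
    ranked last and flagged, never silently dropped.  Ties are broken by
    input order (stable).
    """
    if len(candidates) < 2:
        raise ValueError("model_search requires >=2 candidates")
    if criterion == "REML":
        fixed_sets = {c.fixed_terms for c in candidates}
        if len(fixed_sets) > 1:
            raise ValueError(
                "REML AICc cannot compare different fixed-effect sets; "
                "use criterion='ML'"
            )
    rows = []
    fits: dict[int, ModelFit] = {}
    for i, spec in enumerate(candidates):
        try:
            fit = fit_model(spec, data, criterion=criterion, block_col=block_col)
            fits[i] = fit
            rows.append(
                {
                    "index": i,
                    "model": spec.label(),
                    "criterion": criterion,
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "n": fit.n,
                    "aicc": fit.aicc,
                    "converged": True,
                    "error": "",
                }
            )
        except (ConvergenceError, SingularDesignError, ValueError) as exc:
            rows.append(
                {
                    "index": i,
                    "model": spec.label(),
                    "criterion": criterion,
                    "loglik": math.nan,
                    "k": math.nan,
                    "n": len(data),
                    "aicc": math.inf,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["aicc", "index"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    finite = table.loc[np.isfinite(table["aicc"]), "aicc"]
    if finite.empty:
        raise ConvergenceError("no candidate converged")
    table["delta_aicc"] = table["aicc"] - finite.iloc[0]
    best = candidates[int(table.iloc[0]["index"])]
    return table, best, fits


# ---------------------------------------------------------------------------
# type-III F tests with Satterthwaite denominator df
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FTestResult:
    term: str
    f_value: float
    num_df: int
    denom_df: float
    p_value: float


def _beta_cov_fn(fit: ModelFit):
    """C(theta_var): covariance of beta as a function of variance-scale params."""
    G = len(fit.sigma2)
    has_block = fit._block_slices is not None

    def C(var_params: np.ndarray) -> np.ndarray:
        sig2 = var_params[:G][fit._gidx]
        sig2_b = var_params[G] if has_block else 0.0
        _, XtViX, _, _ = _gls_pieces(
            fit._y, fit._X, sig2, sig2_b, fit._block_slices
        )
        return np.linalg.inv(XtViX)

    return C, G, has_block


def _var_param_cov(fit: ModelFit) -> np.ndarray:
    """Asymptotic covariance of the variance parameters (variance scale).

    Inverse of the negative numerical Hessian of the profile (RE)ML
    log-likelihood at the optimum, by central differences.
    """
    G = len(fit.sigma2)
    has_block = fit._block_slices is not None
    reml = fit.criterion == "REML"
    v0 = np.exp(fit._theta)

    def ll(v):
        theta = np.log(np.maximum(v, 1e-300))
        return _loglik(
            theta, fit._y, fit._X, fit._gidx, G, fit._block_slices, reml
        )

    m = len(v0)
    H = np.zeros((m, m))
    h = np.maximum(1e-4 * np.abs(v0), 1e-10)
    for i in range(m):
        for j in range(i, m):
            vpp = v0.copy(); vpp[i] += h[i]; vpp[j] += h[j]
            vpm = v0.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
            vmp = v0.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
            vmm = v0.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                ll(vpp) - ll(vpm) - ll(vmp) + ll(vmm)
            ) / (4.0 * h[i] * h[j])
    return np.linalg.pinv(-H)


def type3_f_test(fit: ModelFit, term: str) -> FTestResult:
    """Type-III (marginal) F-test of one fixed term.

    With sum-to-zero factor coding, the type-III hypothesis for a term is
    that all of its contrast coefficients vanish, marginal to every other
    term in the model.  The denominator degrees of freedom come from the
    Satterthwaite approximation: each eigen-direction of the contrast
    covariance gets df ``2 v^2 / Var(v)``, with ``Var(v)`` from the delta
    method over the variance-parameter covariance, and the per-direction dfs
    are pooled as in standard mixed-model practice.  Under a single pooled
    variance this reproduces the exact integer residual df; with free group
    variances and two groups it reproduces the Welch-Satterthwaite df.
    """
    if term not in fit.term_columns:
        raise ValueError(
            f"term {term!r} not among fitted fixed terms "
            f"{sorted(fit.term_columns)}"
        )
    cols = fit.term_columns[term]
    q = len(cols)
    p = len(fit.beta)
    L = np.zeros((q, p))
    L[np.arange(q), cols] = 1.0

    Cfun, G, has_block = _beta_cov_fn(fit)
    v0 = np.exp(fit._theta)
    C0 = Cfun(v0)
    LCL = L @ C0 @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(LCL, Lb) / q)

    # Satterthwaite: per-eigendirection df, pooled
    d, P = np.linalg.eigh(LCL)
    A = _var_param_cov(fit)
    h = np.maximum(1e-4 * np.abs(v0), 1e-10)
    nus = []
    for i in range(q):
        a = P[:, i] @ L  # contrast on beta
        grad = np.zeros(len(v0))
        for j in range(len(v0)):
            vp = v0.copy(); vp[j] += h[j]
            vm = v0.copy(); vm[j] = max(vm[j] - h[j], 1e-12)
            grad[j] = (a @ Cfun(vp) @ a - a @ Cfun(vm) @ a) / (vp[j] - vm[j])
        denom = float(grad @ A @ grad)
        nu = 2.0 * d[i] ** 2 / denom if denom > 0 else math.inf
        nus.append(nu)
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if E > q:
        ddf = 2.0 * E / (E - q)
    else:
        ddf = math.inf
    pval = float(stats.f.sf(F, q, ddf)) if math.isfinite(ddf) else float(
        stats.chi2.sf(F * q, q)
    )
    return FTestResult(term=term, f_value=F, num_df=q, denom_df=ddf, p_value=pval)


# ---------------------------------------------------------------------------
# headline analyses
# ---------------------------------------------------------------------------


def _require_levels(data: pd.DataFrame) -> None:
    missing = [
        t for t, col in FACTORS.items() if data[col].astype(str).nunique() < 2
    ]
    missing += ["block"] if data["block_id"].astype(str).nunique() < 2 else []
    if missing:
        raise ValueError(
            "method-comparison models need >=2 levels of each factor; "
            f"single-level factors: {missing}"
        )


def analyze_sd_logci(obs: pd.DataFrame) -> dict:
    """Method comparison on the variability scale: response SD of log CI.

    Pipeline: per block-group SD of log CI -> ML AICc search over the model
    ladder (fixed effects x residual pooling) -> type-III F-test of method on
    the best structure, refitted by REML.  The block-group is the unit of
    observation (one SD per focal x competitor x method x block).
    """
    from .metrics import add_fitness_columns
    from .variability import group_summaries

    _require_levels(obs)
    with_est = add_fitness_columns(obs) if "log_ci" not in obs.columns else obs
    summ = group_summaries(with_est, "log_ci")
    resp = summ.loc[summ["sd_defined"]].rename(columns={"sd": "sd_log_ci"})
    if resp["block_id"].nunique() < 2:
        raise ValueError("analyze_sd_logci needs >=2 blocks with defined SDs")

    candidates = default_candidate_ladder("sd_log_ci", random_block=False)
    table, best, fits = model_search(resp, candidates, criterion="ML")

    test_terms = best.fixed_terms if "method" in best.fixed_terms else tuple(
        t for t in TERMS if t == "method" or t in best.fixed_terms
    )
    test_spec = VarianceModelSpec(
        response="sd_log_ci",
        fixed_terms=test_terms,
        random_block=False,
        residual_grouping=best.residual_grouping,
    )
    reml_fit = fit_model(test_spec, resp, criterion="REML")
    ftest = type3_f_test(reml_fit, "method")
    return {
        "response": "sd_log_ci",
        "summaries": summ,
        "model_table": table,
        "best_spec": best,
        "best_fit": reml_fit,
        "method_added_for_test": "method" not in best.fixed_terms,
        "f_test": ftest,
    }


def analyze_p(obs: pd.DataFrame) -> dict:
    """Method comparison on the mean scale: response p at replicate level.

    Same ladder, with a block random intercept and the replicate (nested
    within block) as the unit of observation.  Blocks missing a method (e.g.
    no by-eye counts in one block) are handled simply by the absence of those
    cells.
    """
    from .metrics import add_fitness_columns

    _require_levels(obs)
    d = add_fitness_columns(obs) if "p" not in obs.columns else obs
    d = d.loc[np.isfinite(d["p"])].reset_index(drop=True)

    candidates = default_candidate_ladder("p", random_block=True)
    table, best, fits = model_search(d, candidates, criterion="ML")

    test_terms = best.fixed_terms if "method" in best.fixed_terms else tuple(
        t for t in TERMS if t == "method" or t in best.fixed_terms
    )
    test_spec = VarianceModelSpec(
        response="p",
        fixed_terms=test_terms,
        random_block=True,
        residual_grouping=best.residual_grouping,
    )
    reml_fit = fit_model(test_spec, d, criterion="REML")
    ftest = type3_f_test(reml_fit, "method")
    return {
        "response": "p",
        "model_table": table,
        "best_spec": best,
        "best_fit": reml_fit,
        "method_added_for_test": "method" not in best.fixed_terms,
        "f_test": ftest,
    }
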