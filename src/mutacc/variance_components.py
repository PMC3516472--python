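"""Among-subline and residual variance components of relative fitness.

The workhorse model is the one-way random-effects layout

    w_ij = mu + subline_i + replicate_ij,   subline ~ N(0, v_subline),
                                            replicate ~ N(0, v_residual)

estimated either by the method of moments (one-way ANOVA mean squares with
the standard unbalanced coefficient k0, truncated at zero) or by restricted
maximum likelihood (normal theory, profiled over the variance ratio so the
optimization is one-dimensional and boundary estimates at v_subline = 0 are
exact).  Normal-theory REML is used deliberately even though w is
non-negative and zero-inflated: it mirrors the mixed-model analysis the
assay design calls for.

``lrt_variance`` compares nested variance structures by likelihood-ratio
test on a small declarative model spec; the default p-value uses the plain
upper-tail chi-square (a 50:50 boundary-mixture option is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2 as chi2_dist

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VarianceComponents:
    """Among-subline (V_L analogue) and within-subline (V_E analogue) estimates."""

    v_subline: float
    v_residual: float
    method: str
    n_sublines: int
    n_total: int
    loglik: float | None = None
    truncated: bool = False  # moments estimate was negative before truncation
    ms_among: float | None = None
    ms_within: float | None = None


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float
    loglik_full: float
    loglik_reduced: float


@dataclass(frozen=True)
class VcModelSpec:
    """Tiny declarative spec for a nested variance model on subline-grouped data.

    ``subline_var``: None (no among-subline component), "pooled" (one
    component), or a column name (one component per level of that column).
    ``resid_var``: "pooled" or a column name.  ``mean``: "pooled" or a column
    name (fixed intercept per level).  Stratum columns must be constant
    within a subline.
    """

    subline_var: str | None = "pooled"
    resid_var: str = "pooled"
    mean: str = "pooled"

    def n_variance_params(self, data: pd.DataFrame) -> int:
        n = 0
        if self.subline_var is not None:
            n += 1 if self.subline_var == "pooled" else data[self.subline_var].nunique()
        n += 1 if self.resid_var == "pooled" else data[self.resid_var].nunique()
        return n


# ---------------------------------------------------------------------------
# one-way components


def _group_stats(values: np.ndarray, groups: np.ndarray):
    df = pd.DataFrame({"y": values, "g": groups})
    agg = df.groupby("g", sort=False)["y"].agg(["count", "mean", "sum"])
    n = agg["count"].to_numpy(dtype=float)
    means = agg["mean"].to_numpy(dtype=float)
    ssw = float(((df["y"] - df.groupby("g", sort=False)["y"].transform("mean")) ** 2).sum())
    return n, means, ssw


def _moments_oneway(n: np.ndarray, means: np.ndarray, ssw: float):
    """Unbalanced one-way ANOVA moments estimators (untruncated v_subline)."""
    a = len(n)
    N = float(n.sum())
    grand = float((n * means).sum() / N)
    ssa = float((n * (means - grand) ** 2).sum())
    ms_among = ssa / (a - 1)
    ms_within = ssw / (N - a)
    k0 = (N - float((n**2).sum()) / N) / (a - 1)
    v_sub_raw = (ms_among - ms_within) / k0
    return v_sub_raw, ms_within, ms_among, k0


def _reml_criterion(lam: float, n: np.ndarray, means: np.ndarray, ssw: float):
    """-2 * restricted loglik profiled over sigma_e^2, at ratio lam = va/ve."""
    N = float(n.sum())
    d = 1.0 + n * lam
    wi = n / d
    mu = float((wi * means).sum() / wi.sum())
    q = ssw + float((n * (means - mu) ** 2 / d).sum())
    sig2 = q / (N - 1.0)
    crit = (
        (N - 1.0) * np.log(sig2)
        + float(np.log(d).sum())
        + np.log(float(wi.sum()))
        + (N - 1.0)
        + (N - 1.0) * _LOG2PI
    )
    return crit, sig2, mu


def _oneway_reml(values: np.ndarray, groups: np.ndarray):
    """REML for the one-way random model; exact at the v_subline = 0 boundary."""
    n, means, ssw = _group_stats(values, groups)

    def crit(lam: float) -> float:
        return _reml_criterion(lam, n, means, ssw)[0]

    # coarse log-grid (plus the boundary) then local refinement
    grid = np.concatenate(([0.0], np.logspace(-8, 6, 57)))
    vals = np.array([crit(l) for l in grid])
    i = int(np.argmin(vals))
    if i == 0:
        lo, hi = 0.0, grid[1]
    else:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    if crit(0.0) <= crit(lam):
        lam = 0.0
    c, sig2, _ = _reml_criterion(lam, n, means, ssw)
    return lam * sig2, sig2, -0.5 * c


def fit_oneway_components(
    values,
    groups=None,
    method: str = "moments",
) -> VarianceComponents:
    """Estimate among-subline and residual variance of a one-way layout.

    ``values`` may be a DataFrame with columns ``value`` (or ``w``/``w_star``)
    and ``subline``, or an array paired with a ``groups`` label array.

    moments: v_subline = (MS_among - MS_within)/k0 truncated at 0, with k0
    the standard unbalanced coefficient; reml: non-negative maximizer of the
    normal-theory restricted likelihood (equal to moments on balanced data
    whenever the untruncated moments estimate is non-negative).
    """
    if isinstance(values, pd.DataFrame):
        df = values
        vcol = next(c for c in ("value", "w_star", "w") if c in df.columns)
        y = df[vcol].to_numpy(dtype=float)
        g = df["subline"].to_numpy()
    else:
        y = np.asarray(values, dtype=float)
        g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    uniq = pd.unique(g)
    if len(uniq) < 2:
        raise ValueError("need at least 2 sublines to separate variance components")
    if len(y) == len(uniq):
        raise ValueError("no residual degrees of freedom (1 replicate per subline)")
    n, means, ssw = _group_stats(y, g)

    if float(np.var(y)) == 0.0:
        warnings.warn("zero total variance; both components set to 0", stacklevel=2)
        return VarianceComponents(0.0, 0.0, method, len(uniq), len(y), loglik=None)

    if method == "moments":
        v_raw, ms_w, ms_a, _ = _moments_oneway(n, means, ssw)
        return VarianceComponents(
            v_subline=max(0.0, v_raw),
            v_residual=ms_w,
            method="moments",
            n_sublines=len(uniq),
            n_total=len(y),
            truncated=v_raw < 0,
            ms_among=ms_a,
            ms_within=ms_w,
        )
    if method == "reml":
        va, ve, ll = _oneway_reml(y, g)
        return VarianceComponents(
            v_subline=va,
            v_residual=ve,
            method="reml",
            n_sublines=len(uniq),
            n_total=len(y),
            loglik=ll,
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# general nested variance models (sublines as blocks, tied components)


def _check_constant_within_subline(data: pd.DataFrame, col: str) -> None:
    if data.groupby("subline", sort=False)[col].nunique().max() > 1:
        raise ValueError(f"column {col!r} is not constant within sublines")


def _fit_vc_model(spec: VcModelSpec, data: pd.DataFrame):
    """REML fit of a VcModelSpec.  Returns (loglik, params, n_var_params)."""
    vcol = next(c for c in ("value", "w_star", "w") if c in data.columns)
    y = data[vcol].to_numpy(dtype=float)
    N = len(y)

    # per-subline bookkeeping
    sub = data["subline"].astype(str)
    if spec.subline_var not in (None, "pooled"):
        _check_constant_within_subline(data, spec.subline_var)
    if spec.resid_var != "pooled":
        _check_constant_within_subline(data, spec.resid_var)

    gv_levels: list = []
    if spec.subline_var == "pooled":
        gv_levels = ["_all"]
    elif spec.subline_var is not None:
        gv_levels = sorted(data[spec.subline_var].astype(str).unique())
    rv_levels = (
        ["_all"] if spec.resid_var == "pooled"
        else sorted(data[spec.resid_var].astype(str).unique())
    )
    if spec.mean == "pooled":
        X = np.ones((N, 1))
    else:
        X = pd.get_dummies(data[spec.mean].astype(str)).to_numpy(dtype=float)
    p = X.shape[1]

    blocks = []
    for s, idx in data.groupby(sub, sort=False).indices.items():
        idx = np.asarray(idx)
        row = data.iloc[idx[0]]
        gk = (
            None if spec.subline_var is None
            else ("_all" if spec.subline_var == "pooled" else str(row[spec.subline_var]))
        )
        rk = "_all" if spec.resid_var == "pooled" else str(row[spec.resid_var])
        blocks.append((idx, gk, rk))

    gv_index = {k: i for i, k in enumerate(gv_levels)}
    rv_index = {k: i for i, k in enumerate(rv_levels)}
    n_gv, n_rv = len(gv_levels), len(rv_levels)

    def neg2_reml(theta: np.ndarray) -> float:
        gv = theta[:n_gv]
        rv = theta[n_gv:]
        logdet = 0.0
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        for idx, gk, rk in blocks:
            yb = y[idx]
            Xb = X[idx]
            nb = len(idx)
            ve = max(rv[rv_index[rk]], 1e-300)
            va = gv[gv_index[gk]] if gk is not None else 0.0
            # V = va*J + ve*I; closed-form inverse and determinant
            denom = ve + nb * va
            logdet += (nb - 1) * np.log(ve) + np.log(denom)
            c = va / (ve * denom)
            sy = yb.sum()
            sX = Xb.sum(axis=0)
            ytvy += yb @ yb / ve - c * sy * sy
            xtvy += Xb.T @ yb / ve - c * sX * sy
            xtvx += Xb.T @ Xb / ve - c * np.outer(sX, sX)
        sign, ld_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        quad = ytvy - beta @ xtvy
        return logdet + ld_x + quad + (N - p) * _LOG2PI

    # starting values from pooled moments
    v0 = float(np.var(y)) or 1.0
    x0 = np.concatenate([np.full(n_gv, v0 / 4), np.full(n_rv, v0 / 2)])
    bounds = [(0.0, None)] * n_gv + [(1e-12, None)] * n_rv
    res = minimize(neg2_reml, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12})
    theta = res.x
    loglik = -0.5 * float(neg2_reml(theta))
    params = {
        **{f"v_subline[{k}]": float(theta[gv_index[k]]) for k in gv_levels},
        **{f"v_residual[{k}]": float(theta[n_gv + rv_index[k]]) for k in rv_levels},
    }
    return loglik, params, n_gv + n_rv


def _is_nested(reduced: VcModelSpec, full: VcModelSpec, data: pd.DataFrame) -> bool:
    def order(v):
        return 0 if v is None else (1 if v == "pooled" else 2)

    if reduced.mean != full.mean:
        return False
    if order(reduced.subline_var) > order(full.subline_var):
        return False
    if (
        order(reduced.subline_var) == 2
        and reduced.subline_var != full.subline_var
    ):
        return False
    if order(reduced.resid_var) > order(full.resid_var):
        return False
    if order(reduced.resid_var) == 2 and reduced.resid_var != full.resid_var:
        return False
    return True


def lrt_variance(
    full: VcModelSpec,
    reduced: VcModelSpec,
    data: pd.DataFrame,
    boundary_mixture: bool = False,
) -> LrtResult:
    """Likelihood-ratio test of nested variance structures.

    chi2 = 2 (loglik_full - loglik_reduced), df = difference in the number
    of variance parameters, p from the plain chi-square upper tail (pass
    ``boundary_mixture=True`` for the 50:50 chi2_{df-1}:chi2_df mixture
    appropriate when the reduced model pins a component at its boundary).
    Identical specs give chi2 = 0 and p = 1.
    """
    if not _is_nested(reduced, full, data):
        raise ValueError("reduced model is not nested in the full model")
    ll_full, _, k_full = _fit_vc_model(full, data)
    ll_red, _, k_red = _fit_vc_model(reduced, data)
    if k_red > k_full:
        raise ValueError("reduced model has more variance parameters than full")
    df = k_full - k_red
    chi2 = max(0.0, 2.0 * (ll_full - ll_red))
    if df == 0:
        p = 1.0
    elif boundary_mixture:
        lower = 1.0 if df == 1 else float(chi2_dist.sf(chi2, df - 1))
        if df == 1:
            lower = 1.0 if chi2 == 0 else 0.0  # chi2_0 is a point mass at 0
        p = 0.5 * lower + 0.5 * float(chi2_dist.sf(chi2, df))
    else:
        p = float(chi2_dist.sf(chi2, df))
    return LrtResult(chi2=chi2, df=df, p=p, loglik_full=ll_full, loglik_reduced=ll_red)
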