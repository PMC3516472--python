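"""Hierarchical mixed model comparing mutational decay between fitness groups.

Fits, by normal-theory REML,

    w = Gmax + Gmax x Fitness + Line(Fitness x Treatment)
        + Subline[Line(...)] + Replicate{Subline[...]}

where Gmax (0 for controls, t for MA sublines) and the Gmax x Fitness
interaction are fixed effects and Line, Subline and Replicate (residual) are
random, with the variance of each random effect estimated separately per
Fitness x Treatment stratum.  Two constraints follow from defining each
line's control mean relative fitness equal to 1: the Fitness main effect is
omitted, and the among-line variance of the control strata is constrained
to zero.

A significant Gmax effect means mean fitness changes with mutation
accumulation (delta M != 0); a significant Gmax x Fitness interaction means
the decay rate differs between high- and low-fitness founder lines.

Fixed-effect tests are Wald t-tests with Satterthwaite degrees of freedom
computed numerically from the REML information (the SAS-specific
Kenward-Roger correction is intentionally not replicated; a containment-style
fallback df is used if the information matrix is singular at a boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import t as t_dist

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HierarchicalFit:
    fixed_effects: pd.DataFrame  # term, estimate, se, t, df, p
    components: pd.DataFrame  # fitness, treatment, v_line, v_subline, v_residual
    loglik: float
    converged: bool
    n_obs: int
    fitness_levels: tuple[str, str]


def _design(records: pd.DataFrame, fitness_levels):
    base, other = fitness_levels
    gmax = records["gmax"].to_numpy(dtype=float)
    is_other = (records["fitness"] == other).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(records)), gmax, gmax * is_other])
    terms = ["intercept", "gmax", f"gmax:fitness[{other}]"]
    return X, terms


class _NestedReml:
    """REML machinery for the line/subline/replicate nested design."""

    def __init__(self, records: pd.DataFrame, fitness_levels):
        self.y = records["w"].to_numpy(dtype=float)
        self.X, self.terms = _design(records, fitness_levels)
        self.N, self.p = self.X.shape
        self.fitness_levels = fitness_levels
        strata = [(f, tr) for f in fitness_levels for tr in ("control", "ma")]
        self.strata = strata
        self.stratum_index = {s: i for i, s in enumerate(strata)}
        # theta layout: vL per MA stratum (2), then vS per stratum (4), vR per stratum (4)
        self.vl_strata = [(f, "ma") for f in fitness_levels]
        self.n_theta = len(self.vl_strata) + 2 * len(strata)
        self.blocks = []
        for (line, tr), idx in records.groupby(["line", "treatment"], sort=True).indices.items():
            idx = np.asarray(idx)
            fit = str(records["fitness"].iloc[idx[0]])
            st = (fit, str(tr))
            subs = records["subline"].iloc[idx].astype(str).to_numpy()
            _, sub_codes = np.unique(subs, return_inverse=True)
            Z = np.zeros((len(idx), sub_codes.max() + 1))
            Z[np.arange(len(idx)), sub_codes] = 1.0
            self.blocks.append((idx, st, Z))
        self.n_line_cells = len(self.blocks)

    def unpack(self, theta):
        nvl = len(self.vl_strata)
        vl = {s: theta[i] for i, s in enumerate(self.vl_strata)}
        vs = {s: theta[nvl + i] for i, s in enumerate(self.strata)}
        vr = {s: theta[nvl + len(self.strata) + i] for i, s in enumerate(self.strata)}
        return vl, vs, vr

    def _accumulate(self, theta):
        vl, vs, vr = self.unpack(theta)
        logdet = 0.0
        xtvx = np.zeros((self.p, self.p))
        xtvy = np.zeros(self.p)
        ytvy = 0.0
        for idx, st, Z in self.blocks:
            yb = self.y[idx]
            Xb = self.X[idx]
            nb = len(idx)
            ve = max(vr[st], 1e-12)
            vsub = vs[st]
            vline = vl.get(st, 0.0)  # control strata constrained to 0
            V = ve * np.eye(nb) + vsub * (Z @ Z.T) + vline
            try:
                c, low = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Vy = cho_solve((c, low), yb)
            VX = cho_solve((c, low), Xb)
            ytvy += yb @ Vy
            xtvy += Xb.T @ Vy
            xtvx += Xb.T @ VX
        return logdet, xtvx, xtvy, ytvy

    def neg2_reml(self, theta):
        acc = self._accumulate(theta)
        if acc is None:
            return np.inf
        logdet, xtvx, xtvy, ytvy = acc
        sign, ld_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        quad = ytvy - beta @ xtvy
        return logdet + ld_x + quad + (self.N - self.p) * _LOG2PI

    def beta_cov(self, theta):
        acc = self._accumulate(theta)
        logdet, xtvx, xtvy, _ = acc
        C = np.linalg.inv(xtvx)
        beta = C @ xtvy
        return beta, C


def _satterthwaite_df(model: _NestedReml, theta: np.ndarray, k: int) -> float:
    """df for the k-th fixed effect via the delta method on Var(beta_k)."""
    active = np.where(theta > 1e-8)[0]
    if len(active) == 0:
        raise np.linalg.LinAlgError("all components at boundary")

    def ckk(th_active):
        th = theta.copy()
        th[active] = th_active
        _, C = model.beta_cov(th)
        return C[k, k]

    th0 = theta[active]
    steps = np.maximum(1e-8, 1e-4 * np.abs(th0))
    grad = np.zeros(len(active))
    for i in range(len(active)):
        e = np.zeros(len(active))
        e[i] = steps[i]
        grad[i] = (ckk(th0 + e) - ckk(np.maximum(th0 - e, 0.0))) / (
            steps[i] + min(steps[i], th0[i])
        )

    def f(th_active):
        th = theta.copy()
        th[active] = th_active
        return model.neg2_reml(th)

    m = len(active)
    H = np.zeros((m, m))
    f0 = f(th0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            fpp = f(th0 + ei + ej)
            fpm = f(th0 + ei - np.minimum(ej, th0))
            fmp = f(th0 - np.minimum(ei, th0) + ej)
            fmm = f(th0 - np.minimum(ei, th0) - np.minimum(ej, th0))
            hi = steps[i] + min(steps[i], th0[i])
            hj = steps[j] + min(steps[j], th0[j])
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (hi * hj)
    # Var(theta_hat) ~ 2 * inv(Hessian of -2*loglik)
    W = 2.0 * np.linalg.inv(H)
    _, C = model.beta_cov(theta)
    v = C[k, k]
    denom = float(grad @ W @ grad)
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError("non-positive Satterthwaite denominator")
    return 2.0 * v * v / denom


def fit_hierarchical_model(records: pd.DataFrame) -> HierarchicalFit:
    """Fit the nested fixed+random model to per-worm fitness records.

    ``records`` needs columns ``line, fitness, treatment, subline, rep,
    gmax, w`` covering both fitness groups and both treatments (a missing
    Fitness x Treatment stratum raises, naming it).  Returns fixed-effect
    estimates/tests and per-stratum variance components.
    """
    needed = {"line", "fitness", "treatment", "subline", "gmax", "w"}
    missing_cols = needed - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    records = records.copy()
    records["fitness"] = records["fitness"].astype(str)
    records["treatment"] = records["treatment"].astype(str)
    # sublines are only unique within line x treatment; make labels global
    records["subline"] = (
        records["line"].astype(str)
        + ":"
        + records["treatment"]
        + ":"
        + records["subline"].astype(str)
    )
    fitness_levels = tuple(sorted(records["fitness"].unique()))
    if len(fitness_levels) != 2:
        raise ValueError(f"need exactly two fitness groups, got {fitness_levels}")
    present = set(map(tuple, records[["fitness", "treatment"]].drop_duplicates().to_numpy()))
    expected = {(f, tr) for f in fitness_levels for tr in ("control", "ma")}
    absent = sorted(expected - present)
    if absent:
        raise ValueError(f"missing Fitness x Treatment strata: {absent}")

    model = _NestedReml(records, fitness_levels)
    v0 = float(np.var(model.y)) or 1.0
    x0 = np.concatenate(
        [
            np.full(len(model.vl_strata), v0 / 8),
            np.full(len(model.strata), v0 / 8),
            np.full(len(model.strata), v0 / 2),
        ]
    )
    bounds = (
        [(0.0, None)] * len(model.vl_strata)
        + [(0.0, None)] * len(model.strata)
        + [(1e-10, None)] * len(model.strata)
    )
    res = minimize(
        model.neg2_reml, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13},
    )
    theta = res.x
    beta, C = model.beta_cov(theta)
    se = np.sqrt(np.diag(C))
    tvals = beta / se
    rows = []
    fallback_df = max(1.0, model.n_line_cells - model.p)
    for k, term in enumerate(model.terms):
        try:
            df = _satterthwaite_df(model, theta, k)
            if not np.isfinite(df) or df < 1.0:
                df = fallback_df
        except np.linalg.LinAlgError:
            df = fallback_df
        p = 2.0 * float(t_dist.sf(abs(tvals[k]), df))
        rows.append(
            {"term": term, "estimate": float(beta[k]), "se": float(se[k]),
             "t": float(tvals[k]), "df": float(df), "p": p}
        )
    vl, vs, vr = model.unpack(theta)
    comp_rows = []
    for st in model.strata:
        comp_rows.append(
            {
                "fitness": st[0],
                "treatment": st[1],
                "v_line": float(vl.get(st, 0.0)),
                "v_subline": float(vs[st]),
                "v_residual": float(vr[st]),
            }
        )
    return HierarchicalFit(
        fixed_effects=pd.DataFrame(rows),
        components=pd.DataFrame(comp_rows),
        loglik=-0.5 * float(res.fun),
        converged=bool(res.success),
        n_obs=model.N,
        fitness_levels=fitness_levels,
    )
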