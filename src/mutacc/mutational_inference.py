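"""Per-line mutational parameters and their bootstrap uncertainty.

Quantities estimated per first-order line from the fitness records of its
control pseudolines (relative fitness scaled so the control mean is 1) and
its second-order MA sublines:

* delta M  -- per-generation change in mean relative fitness,
  (w̄_MA - w̄_0) / (w̄_0 t); negative under mutational decay.
* V_M      -- per-generation mutational variance,
  max(0, (V_L,MA - V_L,0) / (2t)), computed on two scales: the common
  ancestor's mean (feeds Bateman-Mukai) and each group's own mean (the
  "opportunity for selection" w* scaling, used for comparing variances
  between groups whose means differ).
* h²_M     -- mutational heritability, V_M* divided by the average of the
  control and MA within-subline (environmental) components.
* U_MIN, E[a]_MAX -- Bateman-Mukai bounds: assuming all mutations have equal
  effects, 2 (delta M)² / V_M bounds the genomic mutation rate from below
  and V_M / (2 delta M) bounds the mean effect from above (in magnitude).
  Both are undefined when mean fitness did not decline; an |E[a]_MAX| > 1 is
  reported but flagged nonsensical (an average effect on relative fitness
  cannot exceed 1).

Uncertainty comes from a subline-level bootstrap: sublines are resampled
with replacement separately within the control and MA strata (all
replicates of a drawn subline travel together), group means are recomputed
from the unweighted subline means of each resample, variance components are
re-estimated per resample, and point estimates / percentile intervals are
taken over the resamples.  U_MIN and E[a]_MAX are computed from the
bootstrap means of delta M and V_M (a ratio of means, better behaved than a
mean of ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mutacc.variance_components import fit_oneway_components, _moments_oneway


@dataclass(frozen=True)
class VmEstimate:
    """Per-generation mutational variance with its scaling recorded."""

    value: float
    scale: str  # "control_mean" or "ma_mean"


@dataclass(frozen=True)
class BatemanMukai:
    u_min: float | None
    e_a_max: float | None
    u_min_reason: str | None = None
    e_a_reason: str | None = None
    nonsensical: bool = False  # |e_a_max| > 1

    @property
    def defined(self) -> bool:
        return self.u_min is not None and self.e_a_max is not None


@dataclass(frozen=True)
class BootstrapSettings:
    """Subline-level bootstrap configuration (resample unit is fixed)."""

    n_reps: int = 1000
    seed: int | None = None
    ci_level: float = 0.95
    resample_unit: str = "subline"

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.resample_unit != "subline":
            raise ValueError("resampling is defined at the subline level only")


@dataclass
class LineEstimate:
    """Per-line bundle of mutational parameter estimates.

    NaN marks a quantity that is undefined for this line (the reason lives
    in ``flags``); it is pandas' native missing marker, not a sentinel.
    """

    line_id: str
    assay_id: str
    fitness_class: str
    t: int
    delta_m: float
    v_m_control_scale: float
    v_m_star: float
    h2_m: float
    v_e_star_control: float
    v_e_star_ma: float
    w0_mean: float
    wma_mean: float
    u_min: float | None
    e_a_max: float | None
    flags: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    resamples: pd.DataFrame | None = None

    NUMERIC_FIELDS = (
        "delta_m",
        "v_m_control_scale",
        "v_m_star",
        "h2_m",
        "v_e_star_control",
        "v_e_star_ma",
        "w0_mean",
        "wma_mean",
        "u_min",
        "e_a_max",
    )

    def as_row(self) -> dict:
        row = {
            "line": self.line_id,
            "assay_id": self.assay_id,
            "fitness": self.fitness_class,
            "t": self.t,
        }
        for f in self.NUMERIC_FIELDS:
            v = getattr(self, f)
            row[f] = np.nan if v is None else float(v)
        row["n_boot"] = self.n_boot
        return row


# ---------------------------------------------------------------------------
# elementary estimators


def delta_m(w_ma_mean: float, t: int) -> float:
    """Per-generation change in mean relative fitness, (w̄_MA - 1)/t.

    The control mean is 1 by construction of w; negative values mean
    mutational decay of fitness.
    """
    if t <= 0:
        raise ValueError("t (generations of MA) must be positive")
    return (w_ma_mean - 1.0) / t


def delta_m_from_means(w0_mean: float, wma_mean: float, t: int) -> float:
    """(w̄_MA - w̄_0) / (w̄_0 t): the form used inside bootstrap resamples."""
    if t <= 0:
        raise ValueError("t (generations of MA) must be positive")
    if w0_mean <= 0:
        raise ValueError("control mean must be positive")
    return (wma_mean - w0_mean) / (w0_mean * t)


def v_m(v_l_ma: float, v_l_0: float, t: int, scale: str = "control_mean") -> VmEstimate:
    """Per-generation mutational variance max(0, (V_L,MA - V_L,0)/(2t)).

    Inputs are among-subline variance components of w (scale
    ``control_mean``) or w* (scale ``ma_mean``); they must already be
    truncated at zero.  The floor at 0 applies whenever V_L,MA <= V_L,0.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if v_l_ma < 0 or v_l_0 < 0:
        raise ValueError("variance components must be pre-truncated at zero")
    if scale not in ("control_mean", "ma_mean"):
        raise ValueError(f"unknown scale {scale!r}")
    return VmEstimate(value=max(0.0, (v_l_ma - v_l_0) / (2.0 * t)), scale=scale)


def bateman_mukai(delta_m_value: float, v_m_control_scale: float | VmEstimate) -> BatemanMukai:
    """Bateman-Mukai bounds U_MIN = 2 dM²/V_M and E[a]_MAX = V_M/(2 dM).

    V_M must be measured on the scale of the common ancestor for the bounds
    to be consistent with delta M = U E[a] and V_M = U E[a²].  Both bounds
    are flagged undefined when delta M >= 0 (no decline to attribute to
    mutation); U_MIN is undefined when V_M = 0.  |E[a]_MAX| > 1 is returned
    but flagged: an average effect on relative fitness cannot exceed 1.
    """
    vm = v_m_control_scale.value if isinstance(v_m_control_scale, VmEstimate) else float(v_m_control_scale)
    if vm < 0:
        raise ValueError("V_M must be non-negative")
    if delta_m_value >= 0:
        reason = "mean fitness did not decline (delta M >= 0)"
        return BatemanMukai(None, None, u_min_reason=reason, e_a_reason=reason)
    if vm == 0.0:
        return BatemanMukai(
            None,
            0.0,
            u_min_reason="zero mutational variance",
        )
    u_min = 2.0 * delta_m_value**2 / vm
    e_a = vm / (2.0 * delta_m_value)
    return BatemanMukai(u_min, e_a, nonsensical=abs(e_a) > 1.0)


def mutational_heritability(v_m_star: float, v_e_control: float, v_e_ma: float) -> float:
    """h²_M = V_M* / mean(V_E*, control; V_E*, MA)."""
    denom = 0.5 * (v_e_control + v_e_ma)
    if denom <= 0:
        raise ValueError("environmental variance denominator must be positive")
    return v_m_star / denom


def exact_rank_probability(n_low: int, n_high: int, k: int) -> float:
    """P(the k most extreme ranks are all low-group) under exchangeability.

    Equals C(n_low, k) / C(n_low + n_high, k); 0 when k > n_low.
    """
    if min(n_low, n_high, k) < 0:
        raise ValueError("counts must be non-negative")
    if k > n_low + n_high:
        raise ValueError("k cannot exceed the number of lines")
    if k > n_low:
        return 0.0
    return math.comb(n_low, k) / math.comb(n_low + n_high, k)


# ---------------------------------------------------------------------------
# per-line estimation (plug-in and bootstrap)


def _subline_arrays(records: pd.DataFrame, treatment: str) -> list[np.ndarray]:
    sub = records[records["treatment"] == treatment]
    return [g.to_numpy(dtype=float) for _, g in sub.groupby("subline", sort=True)["w"]]


def _stratum_stats(arrays: list[np.ndarray]):
    """Per-subline (n, sum, sumsq) for fast moments on resamples."""
    n = np.array([len(a) for a in arrays], dtype=float)
    s = np.array([a.sum() for a in arrays], dtype=float)
    ss = np.array([(a**2).sum() for a in arrays], dtype=float)
    return n, s, ss


def _moments_from_stats(n, s, ss):
    """Moments one-way components from per-subline sufficient statistics."""
    means = s / n
    ssw = float((ss - s * means).sum())
    v_raw, ms_w, _, _ = _moments_oneway(n, means, ssw)
    return max(0.0, v_raw), ms_w


def _stratum_components(arrays, idx, method):
    if method == "moments":
        n, s, ss = _stratum_stats(arrays)
        return _moments_from_stats(n[idx], s[idx], ss[idx])
    # reml path: rebuild labelled data for the drawn sublines
    y = np.concatenate([arrays[i] for i in idx])
    g = np.concatenate([np.full(len(arrays[i]), j) for j, i in enumerate(idx)])
    vc = fit_oneway_components(y, g, method="reml")
    return vc.v_subline, vc.v_residual


def _line_quantities(w0_sub, wma_sub, idx0, idxm, t, method):
    """All per-resample quantities from drawn subline index vectors."""
    means0 = np.array([w0_sub[i].mean() for i in idx0])
    meansm = np.array([wma_sub[i].mean() for i in idxm])
    w0_mean = float(means0.mean())  # unweighted subline means
    wma_mean = float(meansm.mean())
    dm = delta_m_from_means(w0_mean, wma_mean, t)
    vl0, ve0 = _stratum_components(w0_sub, idx0, method)
    vlm, vem = _stratum_components(wma_sub, idxm, method)
    vm_ctrl = max(0.0, (vlm - vl0) / (2.0 * t))
    # own-group-mean scaling: Var(w*) = Var(w) / mean(w)^2
    vl0_star, ve0_star = vl0 / w0_mean**2, ve0 / w0_mean**2
    vlm_star, vem_star = vlm / wma_mean**2, vem / wma_mean**2
    vm_star = max(0.0, (vlm_star - vl0_star) / (2.0 * t))
    h2 = vm_star / (0.5 * (ve0_star + vem_star)) if (ve0_star + vem_star) > 0 else np.nan
    return {
        "w0_mean": w0_mean,
        "wma_mean": wma_mean,
        "delta_m": dm,
        "v_l_0": vl0,
        "v_l_ma": vlm,
        "v_e_0": ve0,
        "v_e_ma": vem,
        "v_m_control_scale": vm_ctrl,
        "v_m_star": vm_star,
        "v_e_star_control": ve0_star,
        "v_e_star_ma": vem_star,
        "h2_m": h2,
    }


def _require_line_records(records: pd.DataFrame):
    for col in ("treatment", "subline", "w"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    n0 = records.loc[records["treatment"] == "control", "subline"].nunique()
    nma = records.loc[records["treatment"] == "ma", "subline"].nunique()
    if n0 < 2 or nma < 2:
        raise ValueError(
            f"need >=2 control pseudolines and >=2 MA sublines, got ({n0}, {nma})"
        )


def estimate_line(
    records: pd.DataFrame,
    t: int,
    components_method: str = "moments",
    line_id: str | None = None,
    assay_id: str = "assay",
    fitness_class: str = "",
) -> LineEstimate:
    """Plug-in (no bootstrap) per-line estimates from fitness records."""
    _require_line_records(records)
    w0_sub = _subline_arrays(records, "control")
    wma_sub = _subline_arrays(records, "ma")
    q = _line_quantities(
        w0_sub, wma_sub, np.arange(len(w0_sub)), np.arange(len(wma_sub)), t,
        components_method,
    )
    bm = bateman_mukai(q["delta_m"], q["v_m_control_scale"])
    return LineEstimate(
        line_id=line_id or str(records["line"].iloc[0]) if "line" in records else (line_id or ""),
        assay_id=assay_id,
        fitness_class=fitness_class or _infer_fitness(records),
        t=t,
        delta_m=q["delta_m"],
        v_m_control_scale=q["v_m_control_scale"],
        v_m_star=q["v_m_star"],
        h2_m=q["h2_m"],
        v_e_star_control=q["v_e_star_control"],
        v_e_star_ma=q["v_e_star_ma"],
        w0_mean=q["w0_mean"],
        wma_mean=q["wma_mean"],
        u_min=bm.u_min,
        e_a_max=bm.e_a_max,
        flags=_bm_flags(bm),
        n_boot=0,
    )


def _infer_fitness(records: pd.DataFrame) -> str:
    if "fitness" in records.columns:
        vals = [v for v in records["fitness"].unique() if v != "ancestor"]
        if len(vals) == 1:
            return str(vals[0])
    return ""


def _bm_flags(bm: BatemanMukai) -> dict:
    flags = {}
    if bm.u_min_reason:
        flags["u_min_undefined"] = bm.u_min_reason
    if bm.e_a_reason:
        flags["e_a_max_undefined"] = bm.e_a_reason
    if bm.nonsensical:
        flags["e_a_max_nonsensical"] = "average effect on relative fitness cannot exceed 1"
    return flags


_CI_QUANTITIES = (
    "delta_m",
    "v_m_control_scale",
    "v_m_star",
    "h2_m",
    "w0_mean",
    "wma_mean",
    "v_e_star_control",
    "v_e_star_ma",
)


def bootstrap_line(
    records: pd.DataFrame,
    t: int,
    settings: BootstrapSettings | None = None,
    components_method: str = "moments",
    line_id: str | None = None,
    assay_id: str = "assay",
    fitness_class: str = "",
    keep_resamples: bool = False,
) -> LineEstimate:
    """Subline-level bootstrap of one line's mutational parameters.

    Each resample draws control pseudolines and MA sublines with replacement
    within their own strata (all replicates of a drawn subline included),
    recomputes group means from unweighted subline means, refits one-way
    components per stratum (moments by default; ``components_method='reml'``
    behind the flag) and applies the V_M floor.  Point estimates are
    bootstrap means, intervals are the middle ``ci_level`` percentiles, and
    U_MIN / E[a]_MAX come from the bootstrap means of delta M and V_M.
    Identical seed and input order give bit-identical output.
    """
    settings = settings or BootstrapSettings()
    _require_line_records(records)
    w0_sub = _subline_arrays(records, "control")
    wma_sub = _subline_arrays(records, "ma")
    n0, nma = len(w0_sub), len(wma_sub)
    rng = np.random.default_rng(settings.seed)

    rows = []
    for _ in range(settings.n_reps):
        idx0 = rng.integers(0, n0, n0)
        idxm = rng.integers(0, nma, nma)
        rows.append(_line_quantities(w0_sub, wma_sub, idx0, idxm, t, components_method))
    boot = pd.DataFrame(rows)

    alpha = 1.0 - settings.ci_level
    ci = {
        q: (
            float(np.percentile(boot[q].to_numpy(), 100 * alpha / 2)),
            float(np.percentile(boot[q].to_numpy(), 100 * (1 - alpha / 2))),
        )
        for q in _CI_QUANTITIES
    }
    means = boot.mean(numeric_only=True)
    bm = bateman_mukai(float(means["delta_m"]), float(means["v_m_control_scale"]))
    est = LineEstimate(
        line_id=line_id or (str(records["line"].iloc[0]) if "line" in records else ""),
        assay_id=assay_id,
        fitness_class=fitness_class or _infer_fitness(records),
        t=t,
        delta_m=float(means["delta_m"]),
        v_m_control_scale=float(means["v_m_control_scale"]),
        v_m_star=float(means["v_m_star"]),
        h2_m=float(means["h2_m"]),
        v_e_star_control=float(means["v_e_star_control"]),
        v_e_star_ma=float(means["v_e_star_ma"]),
        w0_mean=float(means["w0_mean"]),
        wma_mean=float(means["wma_mean"]),
        u_min=bm.u_min,
        e_a_max=bm.e_a_max,
        flags=_bm_flags(bm),
        ci95=ci,
        n_boot=settings.n_reps,
        seed=settings.seed,
        resamples=boot if keep_resamples else None,
    )
    return est


# ---------------------------------------------------------------------------
# group summaries


def merge_assays(estimates: Sequence[LineEstimate]) -> pd.DataFrame:
    """Merge re-assays: one row per line, the unweighted mean across assays.

    Undefined quantities (NaN) are excluded from the across-assay mean, so a
    line whose first assay has undefined U_MIN contributes its re-assay
    value alone (matching how a published re-assay is folded in).
    """
    rows = pd.DataFrame([e.as_row() for e in estimates])
    if rows.empty:
        raise ValueError("no estimates to merge")
    grouped = rows.groupby("line", sort=True)
    merged = grouped[list(LineEstimate.NUMERIC_FIELDS)].mean()  # skipna=True
    merged["fitness"] = grouped["fitness"].first()
    merged["n_assays"] = grouped.size()
    return merged.reset_index()


def group_summary(
    estimates: Sequence[LineEstimate],
    fields: Sequence[str] = ("delta_m", "v_m_control_scale", "v_m_star", "h2_m", "u_min", "e_a_max"),
) -> pd.DataFrame:
    """Group means and medians (high, low, all) after the re-assay merge.

    A line assayed more than once contributes the unweighted mean of its
    per-assay estimates; group values are unweighted means/medians over the
    merged per-line values, and "all" averages over every line (equal to the
    mean of the two group means when group sizes are equal).
    """
    merged = merge_assays(estimates)
    out_rows = []
    groups = [g for g in ("high", "low") if (merged["fitness"] == g).any()]
    for name, sel in [*((g, merged["fitness"] == g) for g in groups), ("all", slice(None))]:
        sub = merged[sel] if not isinstance(sel, slice) else merged
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        row = {"group": name, "n_lines": len(sub)}
        for f in fields:
            row[f"{f}_mean"] = float(sub[f].mean())
            row[f"{f}_median"] = float(sub[f].median())
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("group")
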