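"""Synthetic second-order MA experiment generator.

Emulates the nested assay design (first-order lines x {control pseudolines,
second-order MA sublines} x replicate worms) and its assumed statistical
structure so that every pipeline stage is testable and parameter recovery
can be demonstrated without external data.

Generative model
----------------
Mutation accumulation is collapsed to the subline level of a selfing,
effectively neutral lineage: over t generations a subline fixes
``Poisson(u * t / 2)`` mutations (a new mutation in a selfer is lost or
fixed with probability 1/2 each), and a fixed mutation is homozygous with
fitness effect ``2 a``, where ``a`` is the average (heterozygous) effect
drawn from the effect model.  This calibration makes the generated data
satisfy the defining moment identities exactly under additive action:

    E[delta M hat] = -u E[a]        E[V_M hat] = u E[a**2]

(the spec'd per-subline count Poisson(u*t) with effect a would satisfy the
first identity but halve the second; see the methods note).  Genotypic
relative fitness is g = prod(1 - 2 a_i) (multiplicative, default) or
max(0, 1 - sum 2 a_i) (additive).  Control pseudolines are genetically
homogeneous copies of the ancestor (g = 1), so their among-pseudoline
variance is environmental only.

Each replicate worm's expected lifetime output is ancestral_W * g * e where
e is a lognormal environmental multiplier with mean 1 and variance v_e
(normal additive noise behind ``env_model='normal'``).  The expectation is
split over reproduction days by ``day_fractions`` and integer daily counts
are Poisson (negative binomial when ``overdispersion`` is set, since real
within-line variance exceeds Poisson).  With probability ``p_nonreproducer``
a replicate leaves no offspring at all, independent of genotype by default
(``zero_inflation_genotype_linked`` scales it by 2 - g for stress-testing
the w = 0 rule).

``neutrality_threshold`` optionally discards mutations whose homozygous
effect exceeds s* -- a crude stand-in for selection during MA purging
mutations that are not effectively neutral (4 Ne s >= 1).  Setting it to
None (or infinity) reproduces the unthinned model exactly under the same
seed: effects are drawn first and filtered after, so the random stream is
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import gammainc

from mutacc.assay_data import AssayTable, DEFAULT_AGES


@dataclass(frozen=True)
class EqualEffects:
    """All mutations share one average (heterozygous) effect a in (0, 1)."""

    a: float = 0.05

    def __post_init__(self):
        if not 0 < self.a < 1:
            raise ValueError("effect a must be in (0, 1)")

    def mean(self) -> float:
        return self.a

    def second_moment(self) -> float:
        return self.a**2

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.a)

    def truncated_moments(self, cap: float):
        """(keep_prob, E[a | a<=cap], E[a^2 | a<=cap]) for thinning at cap."""
        if self.a <= cap:
            return 1.0, self.a, self.a**2
        return 0.0, np.nan, np.nan


@dataclass(frozen=True)
class GammaEffects:
    """Gamma-distributed effects with given shape and mean (both > 0)."""

    shape: float = 1.0
    mean_effect: float = 0.05

    def __post_init__(self):
        if self.shape <= 0 or not 0 < self.mean_effect < 1:
            raise ValueError("shape must be > 0 and mean in (0, 1)")

    def mean(self) -> float:
        return self.mean_effect

    def second_moment(self) -> float:
        # E[a^2] = Var + mean^2 = mean^2 (1 + 1/shape)
        return self.mean_effect**2 * (1.0 + 1.0 / self.shape)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.mean_effect / self.shape, n)

    def truncated_moments(self, cap: float):
        k, theta = self.shape, self.mean_effect / self.shape
        q = float(gammainc(k, cap / theta))
        if q == 0.0:
            return 0.0, np.nan, np.nan
        # E[X^m 1{X<=c}] = theta^m * Gamma(k+m)/Gamma(k) * P(k+m, c/theta)
        m1 = k * theta * float(gammainc(k + 1, cap / theta)) / q
        m2 = k * (k + 1) * theta**2 * float(gammainc(k + 2, cap / theta)) / q
        return q, m1, m2


EffectModel = Union[EqualEffects, GammaEffects]


@dataclass
class SimParams:
    """Generative-model parameters for a synthetic second-order MA experiment.

    Defaults mirror the real design this generator emulates: 10 first-order
    lines (half labelled high-, half low-fitness), ~10 control pseudolines
    and 22 MA sublines per line, 5 replicate worms each, t = 150 further
    generations of MA, ancestral mean lifetime output 148.5 offspring spread
    over reproduction days at ages 4.75/5.75/6.75.
    """

    u: float = 0.02  # genomic (diploid) mutation rate for fitness, per generation
    effect_model: EffectModel = field(default_factory=EqualEffects)
    action: str = "multiplicative"  # or "additive"
    t: int = 150
    n_lines: int = 10
    n_sublines: int = 22
    n_pseudolines: int = 10
    n_replicates: int = 5
    ancestral_w: float = 148.5
    day_fractions: tuple[float, ...] = (0.6, 0.3, 0.1)
    ages: tuple[float, ...] = DEFAULT_AGES
    p_nonreproducer: float = 0.02
    v_e: float = 0.3  # environmental variance of w (relative scale)
    env_model: str = "lognormal"  # or "normal" (additive on the multiplier)
    overdispersion: float | None = None  # negative-binomial k for daily counts
    zero_inflation_genotype_linked: bool = False
    neutrality_threshold: float | None = None  # discard homozygous effects > s*
    seed: int | None = None

    def __post_init__(self):
        if self.u < 0:
            raise ValueError("u must be non-negative")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.action not in ("multiplicative", "additive"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.env_model not in ("lognormal", "normal"):
            raise ValueError(f"unknown env_model {self.env_model!r}")
        fr = np.asarray(self.day_fractions, dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("day_fractions must be a simplex (non-negative, sum 1)")
        if len(fr) != len(self.ages):
            raise ValueError("day_fractions and ages must have equal length")
        if not 0 <= self.p_nonreproducer <= 1:
            raise ValueError("p_nonreproducer must be in [0, 1]")
        if self.v_e < 0:
            raise ValueError("v_e must be non-negative")
        if min(self.n_lines, self.n_sublines, self.n_pseudolines, self.n_replicates) < 1:
            raise ValueError("design sizes must be positive")
        if self.ancestral_w <= 0:
            raise ValueError("ancestral_w must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_model"] = {
            "kind": type(self.effect_model).__name__,
            **asdict(self.effect_model),
        }
        return d


@dataclass(frozen=True)
class ExpectedMoments:
    """Expected per-generation (delta M, V_M) implied by SimParams.

    ``delta_m`` / ``v_m`` are exact under the compound-Poisson fixation
    model (additive action: the closed forms -u E[a] and u E[a^2];
    multiplicative action: the exact lognormal-free compound-Poisson
    moments).  ``delta_m_first_order`` / ``v_m_first_order`` are the
    small-effect linearizations -u E[a], u E[a^2] in both cases, with
    ``approx_error`` = exact - first-order recorded for multiplicative
    action.
    """

    delta_m: float
    v_m: float
    delta_m_first_order: float
    v_m_first_order: float
    approx_error: tuple[float, float]


def _effective_moments(params: SimParams):
    """(effective u, E[a], E[a^2]) after optional neutrality thinning."""
    em = params.effect_model
    if params.neutrality_threshold is None or np.isinf(params.neutrality_threshold):
        return params.u, em.mean(), em.second_moment()
    cap = params.neutrality_threshold / 2.0  # threshold applies to s = 2a
    q, m1, m2 = em.truncated_moments(cap)
    if q == 0.0:
        return 0.0, 0.0, 0.0
    return params.u * q, m1, m2


def expected_moments(params: SimParams) -> ExpectedMoments:
    """Expected (delta M, V_M) per generation for the generative model."""
    u, ea, ea2 = _effective_moments(params)
    first = (-u * ea, u * ea2)
    if u == 0.0:
        return ExpectedMoments(0.0, 0.0, 0.0, 0.0, (0.0, 0.0))
    if params.action == "additive":
        return ExpectedMoments(first[0], first[1], first[0], first[1], (0.0, 0.0))
    # multiplicative: fixations ~ Poisson(lam), factor (1 - s), s = 2a
    lam = u * params.t / 2.0
    es = 2.0 * ea
    es2 = 4.0 * ea2
    mean_g = np.exp(-lam * es)
    mean_g2 = np.exp(lam * (-2.0 * es + es2))
    var_g = mean_g2 - mean_g**2
    dm = (mean_g - 1.0) / params.t
    vm = var_g / (2.0 * params.t)
    return ExpectedMoments(
        float(dm), float(vm), first[0], first[1],
        (float(dm - first[0]), float(vm - first[1])),
    )


def _genotypic_fitness(effects_homo: np.ndarray, action: str) -> float:
    if action == "multiplicative":
        return float(np.prod(np.clip(1.0 - effects_homo, 0.0, None)))
    return float(max(0.0, 1.0 - effects_homo.sum()))


def _draw_counts(rng, mean_total, fractions, overdispersion):
    day_means = mean_total * fractions
    if overdispersion is None:
        return rng.poisson(day_means)
    k = overdispersion
    p = k / (k + np.maximum(day_means, 1e-12))
    out = rng.negative_binomial(k, p)
    return np.where(day_means > 0, out, 0)


def simulate_experiment(params: SimParams) -> tuple[AssayTable, dict]:
    """Simulate one full assay; returns (AssayTable, truth record).

    The truth record stores every MA subline's fixation count, homozygous
    effects and genotypic fitness g, plus the parameters, seed and expected
    per-generation moments.  Fixed seed implies a bit-identical table.
    """
    rng = np.random.default_rng(params.seed)
    fractions = np.asarray(params.day_fractions, dtype=float)
    sigma_env = float(np.sqrt(np.log1p(params.v_e)))
    thin = params.neutrality_threshold

    n_half = (params.n_lines + 1) // 2
    rows: list[dict] = []
    truth_sublines: dict = {}

    def env_multiplier() -> float:
        if params.env_model == "lognormal":
            return float(rng.lognormal(-0.5 * sigma_env**2, sigma_env)) if params.v_e > 0 else 1.0
        return float(max(0.0, 1.0 + rng.normal(0.0, np.sqrt(params.v_e)))) if params.v_e > 0 else 1.0

    def add_replicates(line_id, fitness, treatment, subline_id, gmax, g):
        for r in range(params.n_replicates):
            p_zero = params.p_nonreproducer
            if params.zero_inflation_genotype_linked:
                p_zero = min(1.0, p_zero * (2.0 - g))
            e = env_multiplier()
            counts = _draw_counts(rng, params.ancestral_w * g * e, fractions, params.overdispersion)
            if p_zero > 0 and rng.random() < p_zero:
                counts = np.zeros_like(counts)
            row = {
                "line": line_id,
                "fitness": fitness,
                "treatment": treatment,
                "subline": subline_id,
                "rep": f"R{r + 1:02d}",
                "gmax": gmax,
            }
            row.update({f"day{i + 1}": int(c) for i, c in enumerate(counts)})
            row.update({f"surv{i + 1}": True for i in range(len(counts))})
            rows.append(row)

    for i in range(params.n_lines):
        line_id = f"L{i + 1:02d}"
        fitness = "high" if i < n_half else "low"
        truth_sublines[line_id] = {}
        for j in range(params.n_pseudolines):
            add_replicates(line_id, fitness, "control", f"P{j + 1:02d}", 0, 1.0)
        for j in range(params.n_sublines):
            subline_id = f"S{j + 1:02d}"
            # selfing collapse: Poisson(u t / 2) fixations, homozygous effect 2a
            n_mut = int(rng.poisson(params.u * params.t / 2.0))
            a = params.effect_model.draw(rng, n_mut)
            s = 2.0 * a
            if thin is not None and not np.isinf(thin):
                s = s[s <= thin]
            g = _genotypic_fitness(s, params.action)
            truth_sublines[line_id][subline_id] = {
                "n_mutations": int(len(s)),
                "effects_homozygous": [float(x) for x in s],
                "g": g,
            }
            add_replicates(line_id, fitness, "ma", subline_id, params.t, g)

    data = pd.DataFrame(rows)
    table = AssayTable(
        data, ages=np.asarray(params.ages, dtype=float), t=params.t,
        assay_id=f"sim-seed{params.seed}",
    )
    em = expected_moments(params)
    truth = {
        "params": params.to_dict(),
        "seed": params.seed,
        "expected_delta_m": em.delta_m,
        "expected_v_m": em.v_m,
        "first_order_delta_m": em.delta_m_first_order,
        "first_order_v_m": em.v_m_first_order,
        "approx_error": list(em.approx_error),
        "sublines": truth_sublines,
    }
    return table, truth
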