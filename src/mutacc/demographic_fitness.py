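"""Demographic relative fitness w from day-structured reproduction.

Absolute fitness W is a worm's total lifetime reproductive output.  The
demographic measure weights each day's reproduction by the population growth
implied by the control cohort:

    w_i = sum_x exp(-r0 * x) * l_x(i) * m_x(i)

where l_x m_x is the product of survivorship to and fecundity at age x, and
r0 is the intrinsic rate of increase of the ancestral control pseudolines,
chosen so that the mean control fitness equals 1, i.e. r0 solves the
Euler-Lotka-type equation

    sum_x exp(-r0 * x) * mean(l_x m_x over controls) = 1.

One r0 is estimated per assay and reused for every worm in that assay; since
r0 is never fit per worm, a worm with no offspring has w = 0 exactly.  The
left-hand side is strictly decreasing in r0 whenever the schedule has a
positive entry, so the root is unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mutacc.assay_data import AssayIndividual, AssayTable, KEY_COLUMNS


@dataclass(frozen=True)
class ReproSchedule:
    """Ages x and the mean survivorship-fecundity products l̄_x m̄_x."""

    ages: np.ndarray
    lxmx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "lxmx", np.asarray(self.lxmx, dtype=float))
        if self.ages.shape != self.lxmx.shape:
            raise ValueError("ages and lxmx must have matching shapes")
        if np.any(self.lxmx < 0):
            raise ValueError("mean l_x m_x values must be non-negative")


@dataclass(frozen=True)
class ControlRate:
    """Per-day intrinsic rate of increase of the controls, with solve state."""

    r0: float
    converged: bool
    residual: float


@dataclass(frozen=True)
class FitnessRecord:
    """Per-individual absolute (W) and relative (w) fitness."""

    line_id: str
    treatment: str
    subline_id: str
    replicate_id: str
    W: int
    w: float


def mean_control_schedule(
    table: AssayTable,
    scope: pd.Series | None = None,
    per_line_weighting: bool = False,
) -> ReproSchedule:
    """Mean l_x m_x schedule over the control individuals in scope.

    By default averages over individual worms; with ``per_line_weighting``
    each first-order line's mean schedule gets equal weight regardless of
    how many pseudoline replicates it contributed.
    """
    mask = table.data["treatment"] == "control"
    if scope is not None:
        mask = mask & scope.reindex(table.data.index, fill_value=False)
    controls = table.data[mask]
    if len(controls) == 0:
        raise ValueError("no control individuals in scope")
    lm = controls[table.day_columns].to_numpy(dtype=float)
    lm = lm * controls[table.survived_columns].to_numpy(dtype=float)
    if per_line_weighting:
        means = (
            pd.DataFrame(lm, index=controls.index)
            .groupby(controls["line"].to_numpy())
            .mean()
            .mean(axis=0)
            .to_numpy()
        )
    else:
        means = lm.mean(axis=0)
    return ReproSchedule(ages=table.ages, lxmx=means)


def euler_lotka_residual(r0: float, schedule: ReproSchedule) -> float:
    """Value of sum_x exp(-r0 x) l̄_x m̄_x - 1 at a candidate r0."""
    with np.errstate(over="ignore"):
        return float(np.sum(np.exp(-r0 * schedule.ages) * schedule.lxmx) - 1.0)


def solve_r0(
    schedule: ReproSchedule,
    tol: float = 1e-10,
    bracket: tuple[float, float] = (-10.0, 10.0),
) -> ControlRate:
    """Solve sum_x exp(-r0 x) l̄_x m̄_x = 1 for r0 (per day).

    The function is smooth and strictly decreasing in r0, so a bracketing +
    Brent refinement is both robust and exact to floating tolerance.  The
    initial bracket is expanded geometrically if it does not straddle the
    root.  Raises on an all-zero schedule (no root exists).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if np.all(schedule.lxmx == 0):
        raise ValueError("all-zero schedule: the Euler-Lotka equation has no root")
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo >= hi:
        raise ValueError("invalid bracket")
    f = lambda r: euler_lotka_residual(r, schedule)
    flo, fhi = f(lo), f(hi)
    # need f(lo) > 0 > f(hi); expand away from zero, guarding exp overflow
    n_expand = 0
    while flo <= 0 and n_expand < 60 and lo > -700 / schedule.ages.max():
        lo -= (hi - lo)
        flo = f(lo)
        n_expand += 1
    while fhi >= 0 and n_expand < 120:
        hi += (hi - lo)
        fhi = f(hi)
        n_expand += 1
    if not (flo > 0 > fhi):
        raise ValueError(
            f"could not bracket r0: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    r0 = brentq(f, lo, hi, xtol=1e-14, rtol=4 * np.finfo(float).eps, maxiter=200)
    residual = f(r0)
    converged = abs(residual) <= tol
    if not converged:
        raise ValueError(
            f"r0 solve did not reach tolerance: residual {residual:.3g} on "
            f"bracket [{lo}, {hi}]"
        )
    return ControlRate(r0=float(r0), converged=True, residual=residual)


def _fitness_from_counts(
    counts: np.ndarray, survived: np.ndarray, r0: float, ages: np.ndarray
) -> np.ndarray:
    weights = np.exp(-r0 * ages)
    return (counts * survived.astype(float)) @ weights


def compute_relative_fitness(
    source: AssayTable | AssayIndividual,
    r0: ControlRate,
    ages: np.ndarray | None = None,
) -> pd.DataFrame | FitnessRecord:
    """Per-individual W and w using the assay-wide control rate.

    For an :class:`AssayTable`, returns a DataFrame with the nesting key
    columns plus ``gmax``, ``W`` and ``w``.  For a single
    :class:`AssayIndividual` (``ages`` required), returns a
    :class:`FitnessRecord`.
    """
    if not r0.converged:
        raise ValueError("r0 has not converged; refusing to compute fitness")
    if isinstance(source, AssayIndividual):
        if ages is None:
            raise ValueError("ages must be supplied for a single individual")
        ages = np.asarray(ages, dtype=float)
        counts = np.asarray(source.offspring_by_day, dtype=float)
        if counts.shape != ages.shape:
            raise ValueError("offspring_by_day and ages length mismatch")
        w = float(
            _fitness_from_counts(
                counts[None, :], np.asarray(source.survived)[None, :], r0.r0, ages
            )[0]
        )
        return FitnessRecord(
            line_id=source.line_id,
            treatment=source.treatment,
            subline_id=source.subline_id,
            replicate_id=source.replicate_id,
            W=source.lifetime_output,
            w=w,
        )
    table = source
    counts = table.counts().astype(float)
    w = _fitness_from_counts(counts, table.survived(), r0.r0, table.ages)
    out = table.data[[*KEY_COLUMNS, "gmax"]].copy()
    out["W"] = table.counts().sum(axis=1)
    out["w"] = w
    out["assay_id"] = table.assay_id
    return out


def rescale_within_group(
    records: pd.DataFrame,
    grouping: tuple[str, ...] = ("line", "treatment"),
    value: str = "w",
    out: str = "w_star",
) -> pd.DataFrame:
    """Divide each w by its own group's mean (w* scaling).

    Control data are divided by the control mean and MA data by the MA mean
    within each first-order line, so that rescaled group means equal 1
    exactly and Var(w*) = Var(w)/mean(w)^2 -- the opportunity for selection.
    Raises on a group with zero mean (degenerate group).
    """
    records = records.copy()
    means = records.groupby(list(grouping), sort=False)[value].transform("mean")
    if np.any(means.to_numpy() == 0):
        bad = records.loc[means == 0, list(grouping)].drop_duplicates()
        raise ValueError(f"zero-mean group(s): {bad.to_dict('records')}")
    records[out] = records[value] / means
    return records
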