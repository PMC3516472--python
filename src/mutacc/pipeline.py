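"""End-to-end pipeline: read -> fitness -> components -> inference -> report.

``run_pipeline`` consumes a :class:`RunConfig` (fully serializable; a run is
reproducible from config + inputs alone), processes each assay table
(computing one control rate r0 per assay), bootstraps every line within
every assay, merges re-assayed lines at the estimate level, fits the
hierarchical decay model on the pooled records, and writes per-line and
group summary tables plus a machine-readable results JSON.

The single global seed is expanded into independent per-line streams via
``numpy.random.SeedSequence`` in a deterministic (assay, line) order; every
derived seed is recorded in the results JSON, so reruns are byte-identical
and any stage can be re-derived in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mutacc.assay_data import AssayTable, read_assay_table, summarize_design
from mutacc.demographic_fitness import (
    compute_relative_fitness,
    mean_control_schedule,
    solve_r0,
)
from mutacc.hierarchical import fit_hierarchical_model
from mutacc.mutational_inference import (
    BootstrapSettings,
    LineEstimate,
    bootstrap_line,
    group_summary,
    merge_assays,
)

logger = logging.getLogger("mutacc")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending identifier."""

    def __init__(self, stage: str, ident: str, cause: Exception):
        self.stage = stage
        self.ident = ident
        super().__init__(f"stage {stage!r} failed for {ident!r}: {cause}")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    inputs: list = field(default_factory=list)  # paths or {"path":…, "assay_id":…}
    ages: tuple[float, ...] = (4.75, 5.75, 6.75)
    t: int | None = None  # None: inferred per assay from MA gmax
    n_boot: int = 1000
    ci_level: float = 0.95
    components_method: str = "moments"
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"
    hierarchical: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ages" in data:
            data["ages"] = tuple(data["ages"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "inputs": [
                i if isinstance(i, (str, dict)) else str(i) for i in self.inputs
            ],
            "ages": list(self.ages),
            "t": self.t,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "components_method": self.components_method,
            "seed": self.seed,
            "outdir": self.outdir,
            "log_level": self.log_level,
            "hierarchical": self.hierarchical,
        }


def _load_tables(config: RunConfig, tables: Sequence[AssayTable] | None):
    if tables is not None:
        return list(tables)
    out = []
    for item in config.inputs:
        if isinstance(item, dict):
            path, assay_id = item["path"], item.get("assay_id")
        else:
            path, assay_id = item, None
        out.append(
            read_assay_table(path, ages=config.ages, assay_id=assay_id)
        )
    return out


def _line_seed(ss_child: np.random.SeedSequence) -> int:
    return int(ss_child.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: RunConfig, tables: Sequence[AssayTable] | None = None
) -> dict:
    """Run the full analysis; returns (and optionally writes) the result bundle.

    ``tables`` bypasses file input for library use.  With ``config.outdir``
    set, writes ``per_line_estimates.csv``, ``group_summary.csv``,
    ``model_summary.json`` and ``results.json`` (sorted keys, no
    timestamps -- reruns with the same config are byte-identical).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    assays = _load_tables(config, tables)
    if not assays:
        raise ValueError("no input assay tables")

    # deterministic per-line seed streams
    order = []
    for table in assays:
        for line in sorted(table.data["line"].unique()):
            order.append((table.assay_id, line))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(order))
    seeds = {key: _line_seed(child) for key, child in zip(order, children)}

    estimates: list[LineEstimate] = []
    fitness_frames = []
    assay_meta = {}
    for table in assays:
        try:
            schedule = mean_control_schedule(table)
            rate = solve_r0(schedule)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("solve_r0", table.assay_id, exc) from exc
        logger.info("assay %s: r0 = %.6f (residual %.2e)", table.assay_id, rate.r0, rate.residual)
        fit = compute_relative_fitness(table, rate)
        fitness_frames.append(fit)
        t = config.t if config.t is not None else table.t
        design = summarize_design(table)
        assay_meta[table.assay_id] = {
            "r0": rate.r0,
            "r0_residual": rate.residual,
            "t": t,
            "n_lines": int(design.shape[0]),
            "n_individuals": int(len(table.data)),
        }
        for line, sub in fit.groupby("line", sort=True):
            settings = BootstrapSettings(
                n_reps=config.n_boot,
                seed=seeds[(table.assay_id, line)],
                ci_level=config.ci_level,
            )
            try:
                est = bootstrap_line(
                    sub,
                    t=t,
                    settings=settings,
                    components_method=config.components_method,
                    line_id=str(line),
                    assay_id=table.assay_id,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("bootstrap_line", f"{table.assay_id}:{line}", exc) from exc
            for flag, msg in est.flags.items():
                logger.info("line %s (%s): %s -- %s", line, table.assay_id, flag, msg)
            estimates.append(est)

    per_line = pd.DataFrame([e.as_row() for e in estimates])
    merged = merge_assays(estimates)
    summary = group_summary(estimates)

    model_summary = None
    if config.hierarchical:
        pooled = pd.concat(fitness_frames, ignore_index=True)
        pooled = pooled[pooled["fitness"] != "ancestor"]
        try:
            hfit = fit_hierarchical_model(pooled)
            model_summary = {
                "fixed_effects": hfit.fixed_effects.to_dict(orient="records"),
                "components": hfit.components.to_dict(orient="records"),
                "loglik": hfit.loglik,
                "converged": hfit.converged,
                "n_obs": hfit.n_obs,
            }
        except ValueError as exc:
            logger.warning("hierarchical model skipped: %s", exc)
            model_summary = {"skipped": str(exc)}

    results = {
        "config": config.to_dict(),
        "assays": assay_meta,
        "line_seeds": {f"{a}:{l}": s for (a, l), s in seeds.items()},
        "per_line": per_line.to_dict(orient="records"),
        "per_line_ci95": {
            f"{e.assay_id}:{e.line_id}": {k: list(v) for k, v in e.ci95.items()}
            for e in estimates
        },
        "flags": {
            f"{e.assay_id}:{e.line_id}": e.flags for e in estimates if e.flags
        },
        "merged_lines": merged.to_dict(orient="records"),
        "group_summary": summary.reset_index().to_dict(orient="records"),
        "model": model_summary,
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_line.to_csv(outdir / "per_line_estimates.csv", index=False)
        merged.to_csv(outdir / "merged_lines.csv", index=False)
        summary.to_csv(outdir / "group_summary.csv")
        (outdir / "model_summary.json").write_text(
            json.dumps(model_summary, indent=2, sort_keys=True, default=_json_default),
            encoding="utf-8",
        )
        (outdir / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True, default=_json_default),
            encoding="utf-8",
        )
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
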