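"""Data model, validation and delimited-text I/O for nested MA fitness assays.

An assay scores individual hermaphrodites from a nested design: first-order
MA lines, each represented in the assay by ancestral control *pseudolines*
(replicate lineages recovered from a cryopreserved progenitor before
reproduction, hence genetically homogeneous; generations of further MA,
``gmax`` = 0) and by second-order MA *sublines* (``gmax`` = t).  Each
pseudoline/subline is scored on several replicate worms, and each worm's
offspring are counted on a fixed set of reproduction days (ages in days,
default 4.75, 5.75, 6.75).

The canonical in-memory container is :class:`AssayTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per worm.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_AGES: tuple[float, ...] = (4.75, 5.75, 6.75)

#: canonical column names used internally (and as the default CSV header)
KEY_COLUMNS = ("line", "fitness", "treatment", "subline", "rep")
FITNESS_LEVELS = frozenset({"high", "low", "ancestor"})
TREATMENT_LEVELS = frozenset({"control", "ma"})


class ConfigError(ValueError):
    """Raised for malformed format configuration or missing columns."""


class ValidationError(ValueError):
    """Raised when one or more rows fail validation.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        ``row_number`` is the 1-based line number in the source file
        (header = line 1), or the 0-based DataFrame index when the table was
        built in memory.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.row_errors[:20])
        more = "" if len(self.row_errors) <= 20 else f" (+{len(self.row_errors) - 20} more)"
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class AssayIndividual:
    """One worm's identity in the nested design plus its day-structured counts."""

    line_id: str
    fitness_class: str
    treatment: str
    subline_id: str
    replicate_id: str
    offspring_by_day: tuple[int, ...]
    survived: tuple[bool, ...]
    gmax: int

    @property
    def lifetime_output(self) -> int:
        """Absolute fitness W: total lifetime reproductive output."""
        return int(sum(self.offspring_by_day))


@dataclass(frozen=True)
class FormatConfig:
    """Delimiter and column-name mapping for reading/writing assay tables.

    ``columns`` maps canonical names (``line``, ``fitness``, ``treatment``,
    ``subline``, ``rep``, ``gmax``) to the names used in the file.
    ``day_columns`` lists the per-day offspring-count columns in age order;
    ``survived_columns`` (optional, same length) lists 0/1 survival
    indicators.  When absent, every worm is assumed to have survived the
    assay (a dead day must then carry a zero count).
    """

    delimiter: str | None = None  # None = auto-detect
    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in (*KEY_COLUMNS, "gmax")}
    )
    day_columns: tuple[str, ...] = ("d1", "d2", "d3")
    survived_columns: tuple[str, ...] | None = None

    def required_file_columns(self) -> list[str]:
        cols = [self.columns.get(c, c) for c in (*KEY_COLUMNS, "gmax")]
        cols += list(self.day_columns)
        if self.survived_columns is not None:
            cols += list(self.survived_columns)
        return cols


@dataclass
class AssayTable:
    """Validated per-worm assay records plus the assay's age structure.

    ``data`` holds canonical columns ``line, fitness, treatment, subline,
    rep, gmax, day1..dayN, surv1..survN``.  ``t`` is the number of MA
    generations separating the second-order sublines from the control
    pseudolines (uniform across MA rows).
    """

    data: pd.DataFrame
    ages: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_AGES))
    t: int = 0
    assay_id: str = "assay"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.ndim != 1 or len(self.ages) == 0:
            raise ConfigError("ages must be a non-empty 1-d vector")
        if np.any(np.diff(self.ages) <= 0):
            raise ConfigError("ages must be strictly increasing")
        if np.any(self.ages <= 0):
            raise ConfigError("ages must be positive")

    @property
    def n_days(self) -> int:
        return len(self.ages)

    @property
    def day_columns(self) -> list[str]:
        return [f"day{i + 1}" for i in range(self.n_days)]

    @property
    def survived_columns(self) -> list[str]:
        return [f"surv{i + 1}" for i in range(self.n_days)]

    def counts(self) -> np.ndarray:
        """Offspring counts as an (n_individuals, n_days) integer array."""
        return self.data[self.day_columns].to_numpy(dtype=np.int64)

    def survived(self) -> np.ndarray:
        return self.data[self.survived_columns].to_numpy(dtype=bool)

    def individuals(self) -> Iterator[AssayIndividual]:
        dcols, scols = self.day_columns, self.survived_columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield AssayIndividual(
                line_id=str(d["line"]),
                fitness_class=str(d["fitness"]),
                treatment=str(d["treatment"]),
                subline_id=str(d["subline"]),
                replicate_id=str(d["rep"]),
                offspring_by_day=tuple(int(d[c]) for c in dcols),
                survived=tuple(bool(d[c]) for c in scols),
                gmax=int(d["gmax"]),
            )

    def equals(self, other: "AssayTable") -> bool:
        """Bit-exact on identifiers and counts, tolerance-exact on ages."""
        if self.n_days != other.n_days or len(self.data) != len(other.data):
            return False
        if not np.allclose(self.ages, other.ages, rtol=0, atol=1e-9):
            return False
        cols = [*KEY_COLUMNS, "gmax", *self.day_columns, *self.survived_columns]
        a = self.data[cols].reset_index(drop=True)
        b = other.data[cols].reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return self.t == other.t


def _detect_delimiter(path: Path) -> str:
    sample = Path(path).read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        # fall back: whichever of comma/tab splits the header into more fields
        header = sample.splitlines()[0] if sample else ""
        return "\t" if header.count("\t") >= header.count(",") else ","


def _validate_rows(
    df: pd.DataFrame, day_cols: Sequence[str], surv_cols: Sequence[str]
) -> list[tuple[int, str]]:
    """Collect per-row validation failures.  Row numbers come from df['_row']."""
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(row["_row"])
        treatment = str(row["treatment"]).strip().lower()
        if treatment not in TREATMENT_LEVELS:
            errors.append((rownum, f"treatment must be control/ma, got {row['treatment']!r}"))
            continue
        fitness = str(row["fitness"]).strip().lower()
        if fitness not in FITNESS_LEVELS:
            errors.append((rownum, f"fitness must be high/low/ancestor, got {row['fitness']!r}"))
            continue
        try:
            gmax = int(row["gmax"])
        except (TypeError, ValueError):
            errors.append((rownum, f"gmax is not an integer: {row['gmax']!r}"))
            continue
        if gmax < 0:
            errors.append((rownum, f"gmax must be non-negative, got {gmax}"))
            continue
        if treatment == "control" and gmax != 0:
            errors.append((rownum, f"control row must have gmax=0, got {gmax}"))
            continue
        if treatment == "ma" and gmax <= 0:
            errors.append((rownum, f"ma row must have gmax>0, got {gmax}"))
            continue
        bad = False
        for dcol, scol in zip(day_cols, surv_cols):
            surv = bool(row[scol])
            val = row[dcol]
            if pd.isna(val):
                if surv:
                    errors.append((rownum, f"missing offspring count in {dcol} for a surviving worm"))
                    bad = True
                    break
                val = 0
            try:
                count = int(val)
            except (TypeError, ValueError):
                errors.append((rownum, f"non-integer offspring count in {dcol}: {val!r}"))
                bad = True
                break
            if float(val) != count:
                errors.append((rownum, f"non-integer offspring count in {dcol}: {val!r}"))
                bad = True
                break
            if count < 0:
                errors.append((rownum, f"negative offspring count in {dcol}: {count}"))
                bad = True
                break
            if not surv and count > 0:
                errors.append((rownum, f"dead worm has positive count in {dcol}"))
                bad = True
                break
        if bad:
            continue
    return errors


def build_assay_table(
    df: pd.DataFrame,
    ages: Sequence[float] = DEFAULT_AGES,
    assay_id: str = "assay",
    errors: str = "raise",
) -> AssayTable | tuple[AssayTable, pd.DataFrame]:
    """Validate a canonical-column DataFrame and wrap it in an AssayTable.

    ``df`` must carry ``line, fitness, treatment, subline, rep, gmax,
    day1..dayN`` and optionally ``surv1..survN`` and ``_row`` (source line
    numbers).  With ``errors='raise'`` any invalid row raises
    :class:`ValidationError`; with ``errors='collect'`` returns
    ``(table_of_valid_rows, rejected_rows_with_reason)`` so that
    count(in) == count(accepted) + count(reported).
    """
    ages = np.asarray(ages, dtype=float)
    n_days = len(ages)
    day_cols = [f"day{i + 1}" for i in range(n_days)]
    surv_cols = [f"surv{i + 1}" for i in range(n_days)]
    df = df.copy()
    if "_row" not in df.columns:
        df["_row"] = df.index.astype(int)
    for c in surv_cols:
        if c not in df.columns:
            df[c] = True
    missing = [c for c in (*KEY_COLUMNS, "gmax", *day_cols) if c not in df.columns]
    if missing:
        raise ConfigError(f"missing required columns: {missing}")

    row_errors = _validate_rows(df, day_cols, surv_cols)
    bad_rows = {r for r, _ in row_errors}
    valid = df[~df["_row"].isin(bad_rows)].copy()

    # duplicate nesting keys among the structurally valid rows
    dup_mask = valid.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup_mask.any():
        first_seen = valid.duplicated(subset=list(KEY_COLUMNS), keep="first")
        for rownum in valid.loc[dup_mask & first_seen, "_row"]:
            row_errors.append((int(rownum), "duplicate (line, treatment, subline, rep) key"))
        valid = valid[~(dup_mask & first_seen)]

    if row_errors and errors == "raise":
        raise ValidationError(sorted(row_errors))

    # normalize dtypes / categories
    for c in KEY_COLUMNS:
        valid[c] = valid[c].astype(str)
    valid["fitness"] = valid["fitness"].str.strip().str.lower()
    valid["treatment"] = valid["treatment"].str.strip().str.lower()
    valid["gmax"] = valid["gmax"].astype(np.int64)
    for c in day_cols:
        valid[c] = valid[c].fillna(0).astype(np.int64)
    for c in surv_cols:
        valid[c] = valid[c].astype(bool)

    ma_gmax = valid.loc[valid["treatment"] == "ma", "gmax"].unique()
    if len(ma_gmax) > 1:
        raise ValidationError(
            [(-1, f"MA rows carry mixed gmax values {sorted(ma_gmax)}; one t per assay")]
        )
    t = int(ma_gmax[0]) if len(ma_gmax) == 1 else 0

    keep = [*KEY_COLUMNS, "gmax", *day_cols, *surv_cols]
    table = AssayTable(valid[keep].reset_index(drop=True), ages=ages, t=t, assay_id=assay_id)
    if errors == "collect":
        rejected = df[df["_row"].isin({r for r, _ in row_errors})].copy()
        reasons = {}
        for r, m in row_errors:
            reasons.setdefault(r, m)
        rejected["reason"] = rejected["_row"].map(reasons)
        return table, rejected
    return table


def read_assay_table(
    path: str | Path,
    format_config: FormatConfig | None = None,
    ages: Sequence[float] = DEFAULT_AGES,
    assay_id: str | None = None,
    errors: str = "raise",
) -> AssayTable | tuple[AssayTable, pd.DataFrame]:
    """Read and validate a delimited assay table (CSV/TSV, UTF-8).

    Raises :class:`ConfigError` when required columns are missing and
    :class:`ValidationError` (naming 1-based file line numbers) when rows
    fail validation; ``errors='collect'`` returns the rejected rows instead
    of raising.
    """
    cfg = format_config or FormatConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = cfg.delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=delim, encoding="utf-8")
    missing = [c for c in cfg.required_file_columns() if c not in raw.columns]
    if missing:
        raise ConfigError(f"file {path} is missing columns {missing} (delimiter {delim!r})")

    n_days = len(cfg.day_columns)
    if n_days != len(ages):
        raise ConfigError(
            f"day_columns ({n_days}) and ages ({len(ages)}) must have equal length"
        )
    rename = {v: k for k, v in cfg.columns.items()}
    rename.update({c: f"day{i + 1}" for i, c in enumerate(cfg.day_columns)})
    if cfg.survived_columns is not None:
        rename.update({c: f"surv{i + 1}" for i, c in enumerate(cfg.survived_columns)})
    df = raw.rename(columns=rename)
    df["_row"] = np.arange(2, len(df) + 2)  # 1-based file lines, header = 1
    return build_assay_table(
        df, ages=ages, assay_id=assay_id or path.stem, errors=errors
    )


def write_assay_table(
    table: AssayTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write an AssayTable to delimited text using the default header.

    Columns: ``line,fitness,treatment,subline,rep,d1..dN,gmax,s1..sN``.
    Round-trips exactly through :func:`read_assay_table` with the matching
    :class:`FormatConfig`.
    """
    out = table.data.copy()
    day_names = [f"d{i + 1}" for i in range(table.n_days)]
    surv_names = [f"s{i + 1}" for i in range(table.n_days)]
    out = out.rename(
        columns={
            **{f"day{i + 1}": day_names[i] for i in range(table.n_days)},
            **{f"surv{i + 1}": surv_names[i] for i in range(table.n_days)},
        }
    )
    for c in surv_names:
        out[c] = out[c].astype(int)
    cols = [*KEY_COLUMNS, *day_names, "gmax", *surv_names]
    out[cols].to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def default_format_config(n_days: int = 3) -> FormatConfig:
    """FormatConfig matching :func:`write_assay_table`'s default header."""
    return FormatConfig(
        delimiter=None,
        day_columns=tuple(f"d{i + 1}" for i in range(n_days)),
        survived_columns=tuple(f"s{i + 1}" for i in range(n_days)),
    )


def summarize_design(table: AssayTable) -> pd.DataFrame:
    """Per-line nesting summary: pseudoline/subline counts and replication.

    Unbalanced designs are reported as-is, never rejected.  Returns one row
    per first-order line with columns ``n_control_pseudolines``,
    ``n_ma_sublines``, ``replicates_min``, ``replicates_max``,
    ``n_individuals``.
    """
    if len(table.data) == 0:
        return pd.DataFrame(
            columns=[
                "line",
                "n_control_pseudolines",
                "n_ma_sublines",
                "replicates_min",
                "replicates_max",
                "n_individuals",
            ]
        ).set_index("line")
    df = table.data
    rows = []
    for line, sub in df.groupby("line", sort=True):
        reps = sub.groupby(["treatment", "subline"], sort=False).size()
        rows.append(
            {
                "line": line,
                "n_control_pseudolines": sub.loc[sub["treatment"] == "control", "subline"].nunique(),
                "n_ma_sublines": sub.loc[sub["treatment"] == "ma", "subline"].nunique(),
                "replicates_min": int(reps.min()),
                "replicates_max": int(reps.max()),
                "n_individuals": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("line")


def merge_reassay_tag(table: AssayTable, assay_id: str) -> AssayTable:
    """Return a copy of ``table`` tagged with a distinct assay id.

    A re-assayed line is encoded as its own assay table; merging happens at
    the estimate level (see :func:`mutacc.mutational_inference.group_summary`).
    """
    return replace(table, assay_id=assay_id)
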