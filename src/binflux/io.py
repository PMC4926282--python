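"""Readers and writers for the pipeline's tabular formats.

All canonical tables are tab-separated UTF-8 text with a single header
row; lines starting with ``#`` are comments. Readers validate schemas
and referential integrity and fail hard (with row numbers) rather than
silently coercing malformed input. Report writers emit a deterministic
column and row order with floats at 6 significant digits so outputs are
diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("binflux")

PERIODS = ("I", "II", "III")
EXPERIMENTAL_SETS = ("non_acclimatized", "acclimatized")
DOSES = (0.0, 2.0, 3.0)

DESIGN_COLUMNS = [
    "sample_id",
    "experimental_set",
    "reactor_id",
    "replicate",
    "lcfa_dose",
    "period",
    "day",
    "aligned_reads",
]

PROCESS_COLUMNS = [
    "reactor_id",
    "day",
    "methane_yield",
    "total_vfa",
    "acetate",
    "propionate",
    "butyrate",
    "ph",
]


class SchemaError(ValueError):
    """Raised when an input table violates its schema or invariants."""


@dataclass
class CoverageMatrix:
    """Per-scaffold mean depth per sample plus sample metadata.

    Attributes
    ----------
    scaffolds : pd.DataFrame
        Columns ``scaffold_id`` (unique), ``length_bp`` (>= 1); same row
        order as ``depth``.
    samples : pd.DataFrame
        Design table (one row per sample, see :func:`read_design`); its
        ``sample_id`` order defines the column order of ``depth``.
    depth : pd.DataFrame
        Nonnegative mean per-base coverage, scaffold x sample, indexed
        by ``scaffold_id`` with columns ``sample_id``.
    """

    scaffolds: pd.DataFrame
    samples: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.depth.index) != list(self.scaffolds["scaffold_id"]):
            raise SchemaError("depth row index does not match scaffold list")
        if list(self.depth.columns) != list(self.samples["sample_id"]):
            raise SchemaError("depth columns do not match sample list")
        if self.scaffolds["scaffold_id"].duplicated().any():
            dup = self.scaffolds["scaffold_id"][
                self.scaffolds["scaffold_id"].duplicated()
            ].iloc[0]
            raise SchemaError(f"duplicate scaffold_id {dup!r}")
        if (self.scaffolds["length_bp"] < 1).any():
            raise SchemaError("scaffold length_bp must be >= 1")
        vals = self.depth.to_numpy()
        if np.isnan(vals).any():
            raise SchemaError("coverage matrix contains NaN")
        if (vals < 0).any():
            raise SchemaError("coverage matrix contains negative depth")

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffolds)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a canonical TSV: tab-separated, UTF-8, '#' comments ignored.

    All cells come back as strings (dtype object); callers cast and
    validate per schema so malformed numerics are rejected, not coerced.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        na_values=[],
        encoding="utf-8",
    )
    return df


def _to_float(series: pd.Series, column: str, path: str | Path) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(
            f"{path}: malformed numeric value {series[bad].iloc[0]!r} "
            f"in column {column!r} at row {row}"
        )
    return out.astype(float)


def _to_int(series: pd.Series, column: str, path: str | Path) -> pd.Series:
    out = _to_float(series, column, path)
    if not np.allclose(out, np.round(out), atol=0, rtol=0, equal_nan=True):
        raise SchemaError(f"{path}: column {column!r} must be integer-valued")
    return out.astype(int)


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the experimental design (sample metadata) table.

    Canonical form is TSV with columns ``sample_id, experimental_set,
    reactor_id, replicate, lcfa_dose, period, day, aligned_reads``.  A
    YAML document holding a list of records with the same keys (under a
    top-level ``samples`` key or as a bare list) is accepted as a
    convenience mirror of the TSV schema.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        records = doc["samples"] if isinstance(doc, dict) else doc
        df = pd.DataFrame(records).astype(str)
    else:
        df = _read_tsv(path)
    _require_columns(df, DESIGN_COLUMNS, path)
    df = df[DESIGN_COLUMNS].copy()
    df["replicate"] = _to_int(df["replicate"], "replicate", path)
    df["lcfa_dose"] = _to_float(df["lcfa_dose"], "lcfa_dose", path)
    df["day"] = _to_int(df["day"], "day", path)
    df["aligned_reads"] = _to_int(df["aligned_reads"], "aligned_reads", path)

    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    bad_set = ~df["experimental_set"].isin(EXPERIMENTAL_SETS)
    if bad_set.any():
        raise SchemaError(
            f"{path}: unknown experimental_set {df['experimental_set'][bad_set].iloc[0]!r}"
        )
    bad_period = ~df["period"].isin(PERIODS)
    if bad_period.any():
        raise SchemaError(f"{path}: unknown period {df['period'][bad_period].iloc[0]!r}")
    bad_dose = ~df["lcfa_dose"].isin(DOSES)
    if bad_dose.any():
        raise SchemaError(
            f"{path}: lcfa_dose must be one of {DOSES}, "
            f"got {df['lcfa_dose'][bad_dose].iloc[0]}"
        )
    if (df["aligned_reads"] < 0).any():
        raise SchemaError(f"{path}: aligned_reads must be nonnegative")

    # days must be monotone across periods within each reactor+set
    order = {p: i for i, p in enumerate(PERIODS)}
    for (eset, reactor), grp in df.groupby(["experimental_set", "reactor_id"]):
        grp = grp.sort_values("day", kind="stable")
        codes = grp["period"].map(order).to_numpy()
        if (np.diff(codes) < 0).any():
            raise SchemaError(
                f"{path}: days not monotone across periods for reactor "
                f"{reactor!r} in set {eset!r}"
            )
    return df.reset_index(drop=True)


def read_coverage_table(path: str | Path, design: pd.DataFrame) -> CoverageMatrix:
    """Read a per-scaffold mean-coverage TSV against a design table.

    The TSV header is ``scaffold_id, length_bp, <sample_id...>``; sample
    columns must match the design's sample_ids exactly.  The returned
    matrix's columns follow the design order, not the file order.  Empty
    depth cells become 0 with one logged warning per file.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ["scaffold_id", "length_bp"], path)
    file_samples = [c for c in df.columns if c not in ("scaffold_id", "length_bp")]
    design_samples = list(design["sample_id"])
    orphan = sorted(set(file_samples) - set(design_samples))
    if orphan:
        raise SchemaError(f"{path}: sample column {orphan[0]!r} not in design")
    absent = sorted(set(design_samples) - set(file_samples))
    if absent:
        raise SchemaError(f"{path}: design sample {absent[0]!r} missing from coverage table")

    if df["scaffold_id"].duplicated().any():
        dup = df["scaffold_id"][df["scaffold_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate scaffold_id {dup!r}")
    lengths = _to_int(df["length_bp"], "length_bp", path)
    if (lengths < 1).any():
        row = int(np.flatnonzero((lengths < 1).to_numpy())[0]) + 2
        raise SchemaError(f"{path}: length_bp < 1 at row {row}")

    blank_seen = False
    depth_cols: dict[str, pd.Series] = {}
    for col in file_samples:
        raw = df[col]
        blanks = raw.astype(str).str.strip() == ""
        if blanks.any():
            blank_seen = True
            raw = raw.where(~blanks, "0")
        vals = _to_float(raw, col, path)
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise SchemaError(f"{path}: negative depth in column {col!r} at row {row}")
        depth_cols[col] = vals
    if blank_seen:
        logger.warning("%s: empty depth cells treated as 0", path)

    depth = pd.DataFrame(depth_cols)[design_samples]
    depth.index = pd.Index(df["scaffold_id"], name="scaffold_id")
    scaffolds = pd.DataFrame(
        {"scaffold_id": df["scaffold_id"].to_numpy(), "length_bp": lengths.to_numpy()}
    )
    carrying = depth.sum(axis=0) > 0
    zero_reads = design.set_index("sample_id")["aligned_reads"].reindex(depth.columns) == 0
    offenders = depth.columns[carrying.to_numpy() & zero_reads.to_numpy()]
    if len(offenders):
        raise SchemaError(
            f"{path}: sample {offenders[0]!r} carries coverage but has 0 aligned reads"
        )
    return CoverageMatrix(scaffolds=scaffolds, samples=design.reset_index(drop=True), depth=depth)


def read_interval_depth(path: str | Path, scaffolds: pd.DataFrame) -> pd.Series:
    """Mean per-base depth per scaffold from a 4-column BED-style file.

    Rows are ``scaffold  start  end  depth`` with 0-based half-open
    coordinates; positions not covered by any interval count as depth 0.
    Overlapping intervals and intervals past the scaffold end are hard
    errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["scaffold_id", "start", "end", "depth"],
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    if df.shape[1] != 4:
        raise SchemaError(f"{path}: expected 4 columns")
    start = _to_int(df["start"], "start", path)
    end = _to_int(df["end"], "end", path)
    depth = _to_float(df["depth"], "depth", path)
    if (depth < 0).any():
        raise SchemaError(f"{path}: negative depth value")
    if (end <= start).any():
        row = int(np.flatnonzero((end <= start).to_numpy())[0]) + 1
        raise SchemaError(f"{path}: empty or inverted interval at row {row}")

    lengths = scaffolds.set_index("scaffold_id")["length_bp"]
    unknown = ~df["scaffold_id"].isin(lengths.index)
    if unknown.any():
        raise SchemaError(
            f"{path}: unknown scaffold {df['scaffold_id'][unknown].iloc[0]!r}"
        )

    totals = pd.Series(0.0, index=lengths.index)
    for sid, grp_idx in df.groupby("scaffold_id").groups.items():
        s = start.loc[grp_idx].to_numpy()
        e = end.loc[grp_idx].to_numpy()
        d = depth.loc[grp_idx].to_numpy()
        L = int(lengths.loc[sid])
        if (e > L).any():
            raise SchemaError(f"{path}: interval exceeds length of scaffold {sid!r}")
        order = np.argsort(s, kind="stable")
        if (s[order][1:] < e[order][:-1]).any():
            raise SchemaError(f"{path}: overlapping intervals on scaffold {sid!r}")
        totals.loc[sid] = float(np.sum(d * (e - s)))
    mean = totals / lengths.astype(float)
    mean.name = "mean_depth"
    return mean


def read_scaffold_bins(path: str | Path) -> dict[str, str]:
    """Read the scaffold-to-bin assignment TSV (``scaffold_id  bin_id``)."""
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ["scaffold_id", "bin_id"], path)
    if df["scaffold_id"].duplicated().any():
        dup = df["scaffold_id"][df["scaffold_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: scaffold {dup!r} assigned to multiple bins")
    return dict(zip(df["scaffold_id"], df["bin_id"]))


def read_gene_annotations(
    path: str | Path, bin_universe: set[str] | None = None
) -> pd.DataFrame:
    """Read the gene annotation TSV (``gene_id  bin_id  category_id``).

    One gene may map to multiple categories but (gene_id, category_id)
    pairs must be unique, and a gene belongs to exactly one bin.  If
    ``bin_universe`` is given, rows naming a bin outside it are rejected.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "bin_id", "category_id"], path)
    df = df[["gene_id", "bin_id", "category_id"]].copy()
    dup = df.duplicated(subset=["gene_id", "category_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise SchemaError(f"{path}: duplicate (gene_id, category_id) pair at row {row}")
    multi_bin = df.groupby("gene_id")["bin_id"].nunique() > 1
    if multi_bin.any():
        gene = multi_bin[multi_bin].index[0]
        raise SchemaError(f"{path}: gene {gene!r} assigned to multiple bins")
    if bin_universe is not None:
        unknown = ~df["bin_id"].isin(bin_universe)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
            raise SchemaError(
                f"{path}: bin {df['bin_id'][unknown].iloc[0]!r} at row {row} "
                "not in scaffold-to-bin universe"
            )
    return df.reset_index(drop=True)


def read_process_table(path: str | Path) -> pd.DataFrame:
    """Read the reactor process-trait table (one row per reactor-day)."""
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, PROCESS_COLUMNS, path)
    df = df[PROCESS_COLUMNS].copy()
    df["day"] = _to_int(df["day"], "day", path)
    for col in PROCESS_COLUMNS[2:]:
        df[col] = _to_float(df[col], col, path)
        if col != "ph" and (df[col] < 0).any():
            row = int(np.flatnonzero((df[col] < 0).to_numpy())[0]) + 2
            raise SchemaError(f"{path}: negative {col} at row {row}")
    if ((df["ph"] < 0) | (df["ph"] > 14)).any():
        raise SchemaError(f"{path}: ph outside [0, 14]")
    if df.duplicated(subset=["reactor_id", "day"]).any():
        raise SchemaError(f"{path}: duplicate (reactor_id, day) record")
    return df.reset_index(drop=True)


def format_float(x: float) -> str:
    """Render a float with 6 significant digits (canonical report form)."""
    if isinstance(x, float) and float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return format(float(x), ".6g")


def write_report(table: pd.DataFrame, path: str | Path, sort: bool = True) -> None:
    """Write a report TSV with deterministic column and row order.

    Rows are sorted by the first column (then the remaining columns) so
    repeated runs produce byte-identical, diffable files; floats are
    rendered with 6 significant digits.
    """
    path = Path(path)
    df = table.copy()
    if sort and len(df):
        df = df.sort_values(list(df.columns), kind="stable")
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(format_float)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
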