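"""Plate-level fluorescence I/O, the genotype matrix, and report writing.

Fluorescence tables are plain CSV/TSV with one row per (individual, assay):
two channel readings (``f1`` = robusta-specific dye, ``f2`` =
intestinalis-specific dye) plus plate metadata and positive-control flags.

The genotype matrix is the pipeline's central table: individuals × markers
with robusta-allele dosage in each cell (0/1/2, NaN = missing) and
per-individual metadata (population, period, species class, hybrid index).
Its on-disk layout mirrors a deposited multi-locus genotype table; because
allele encodings vary between deposits, the reader takes a declarative
dialect (missing tokens, allele→species map) rather than hardcoding one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel

logger = logging.getLogger("introkasp")

__all__ = [
    "FLUOR_COLUMNS",
    "CONTROL_CLASSES",
    "read_fluorescence",
    "validate_fluorescence",
    "GenotypeDialect",
    "GenotypeMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "write_report",
]

#: required columns of a fluorescence table
FLUOR_COLUMNS = [
    "individual_id",
    "population_id",
    "period",
    "run_id",
    "assay_id",
    "f1",
    "f2",
    "is_control",
    "control_class",
]

#: recognised positive-control classes (one robusta, one plain intestinalis,
#: two introgressed intestinalis wells per run in the routine design)
CONTROL_CLASSES = ("robusta", "intestinalis_plain", "intestinalis_introgressed")

MULTIPLEX_ASSAY = "multiplex"


def validate_fluorescence(df: pd.DataFrame, panel: Panel | None = None) -> pd.DataFrame:
    """Validate a fluorescence record table and flag failed wells.

    Rows with ``f1 + f2 = 0`` are kept but marked ``failed=True`` (a silent
    drop would bias call rates).  Negative fluorescence or an assay id
    unknown to the panel is a hard error.
    """
    df = df.copy()
    missing = [c for c in FLUOR_COLUMNS if c not in df.columns and c != "control_class"]
    if missing:
        raise ValueError(f"fluorescence table missing column(s): {missing}")
    if "control_class" not in df.columns:
        df["control_class"] = pd.NA
    df["f1"] = pd.to_numeric(df["f1"])
    df["f2"] = pd.to_numeric(df["f2"])
    if (df["f1"] < 0).any() or (df["f2"] < 0).any():
        bad = df.loc[(df["f1"] < 0) | (df["f2"] < 0), "individual_id"].tolist()
        raise ValueError(f"negative fluorescence for individual(s) {bad[:5]}")
    df["is_control"] = df["is_control"].astype(bool)
    ctl = df["is_control"]
    bad_class = ctl & ~df["control_class"].isin(CONTROL_CLASSES)
    if bad_class.any():
        raise ValueError(
            "control record(s) without a recognised control_class: "
            f"{df.loc[bad_class, 'individual_id'].tolist()[:5]}"
        )
    if panel is not None:
        valid = set(panel.simplex_assay_ids) | {MULTIPLEX_ASSAY}
        unknown = sorted(set(df["assay_id"]) - valid)
        if unknown:
            raise ValueError(f"unknown assay_id(s): {unknown}")
    df["failed"] = (df["f1"] + df["f2"]) == 0
    n_failed = int(df["failed"].sum())
    if n_failed:
        logger.warning("flagged %d fluorescence record(s) with zero total signal", n_failed)
    return df


def read_fluorescence(path: str | Path, panel: Panel | None = None) -> pd.DataFrame:
    """Read a plate fluorescence CSV/TSV into a validated record table."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_fluorescence(df, panel)


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass(frozen=True)
class GenotypeDialect:
    """Declarative encoding of a genotype table's cell values.

    ``robusta_symbol``/``intestinalis_symbol`` name the two species alleles
    as written in the table (e.g. ``R``/``I``); a cell is the unordered
    two-character allele pair for diploid markers.  Tokens in
    ``missing_tokens`` map to a missing dosage.
    """

    robusta_symbol: str = "R"
    intestinalis_symbol: str = "I"
    missing_tokens: tuple[str, ...] = ("NA", "", "--", "NN", ".")

    def to_dosage(self, cell: object) -> float:
        """Robusta-allele dosage of one genotype cell (NaN if unknown)."""
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        text = str(cell).strip()
        if text in self.missing_tokens:
            return np.nan
        alleles = [a for a in text if a not in "/|"]
        if len(alleles) != 2 or any(
            a not in (self.robusta_symbol, self.intestinalis_symbol) for a in alleles
        ):
            return np.nan  # unknown encoding: missing, counted by the caller
        return float(sum(a == self.robusta_symbol for a in alleles))

    def from_dosage(self, dosage: float) -> str:
        if np.isnan(dosage):
            return self.missing_tokens[0]
        r, i = self.robusta_symbol, self.intestinalis_symbol
        return {0: i + i, 1: r + i, 2: r + r}[int(dosage)]


_META_COLUMNS = ["population_id", "period", "species_class", "hybrid_index"]


@dataclass
class GenotypeMatrix:
    """Individuals × markers dosage table with per-individual metadata.

    ``dosage`` is a DataFrame indexed by individual_id with one column per
    marker (values 0/1/2/NaN = robusta-allele count); ``meta`` is indexed
    identically and carries population_id, period, species_class and
    hybrid_index.
    """

    dosage: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.dosage.index, columns=_META_COLUMNS)
        for col in _META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = pd.NA
        if not self.meta.index.equals(self.dosage.index):
            self.meta = self.meta.reindex(self.dosage.index)

    @property
    def individuals(self) -> pd.Index:
        return self.dosage.index

    @property
    def marker_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def subset(self, mask: pd.Series) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[mask], self.meta.loc[mask])

    def natives(self) -> "GenotypeMatrix":
        """Restrict to individuals classified as (pure) *C. intestinalis*."""
        return self.subset(self.meta["species_class"] == "pure_intestinalis")

    def __len__(self) -> int:
        return len(self.dosage)


def read_genotype_table(
    path: str | Path,
    panel: Panel,
    dialect: GenotypeDialect | None = None,
) -> GenotypeMatrix:
    """Read a multi-locus genotype table (one row per individual).

    Marker columns absent from the panel are a hard error (listed); cells
    with unrecognised encodings become missing, with a logged count.
    """
    dialect = dialect or GenotypeDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "individual_id" not in df.columns:
        raise ValueError("genotype table must have an individual_id column")
    df = df.set_index("individual_id")
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    marker_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [c for c in marker_cols if c not in panel]
    if unknown:
        raise ValueError(f"genotype table column(s) not in panel: {unknown}")
    dosage = df[marker_cols].map(dialect.to_dosage)
    n_unknown = int(
        (dosage.isna() & ~df[marker_cols].isin(dialect.missing_tokens) & df[marker_cols].notna()).sum().sum()
    )
    if n_unknown:
        logger.warning("%d genotype cell(s) with unrecognised encoding set to missing", n_unknown)
    meta = df[meta_cols].copy() if meta_cols else None
    if meta is not None and "hybrid_index" in meta.columns:
        meta["hybrid_index"] = pd.to_numeric(meta["hybrid_index"], errors="coerce")
    return GenotypeMatrix(dosage.astype(float), meta)


def write_genotype_table(
    matrix: GenotypeMatrix,
    path: str | Path,
    dialect: GenotypeDialect | None = None,
) -> None:
    """Write a GenotypeMatrix in the layout ``read_genotype_table`` reads."""
    dialect = dialect or GenotypeDialect()
    out = matrix.meta.copy()
    for col in matrix.dosage.columns:
        out[col] = matrix.dosage[col].map(dialect.from_dosage)
    out.index.name = "individual_id"
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# reports


def write_report(results: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write result tables as TSVs with fixed column order.

    ``results`` maps a table name (e.g. ``freqs``, ``tests``, ``ld_delta``)
    to a DataFrame; each becomes ``<outdir>/<name>.tsv``.  Output is
    deterministic given inputs: rows and columns are written in their
    existing order and floats with repr-round-tripping precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        written.append(path)
    return written
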