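"""Readers and writers for quantification tables, designs, KSR and FASTA.

Two TSV dialects are accepted for intensity tables:

* ``generic`` — a ``feature_id`` (or ``site_id``/``protein_id``) column
  plus one intensity column per sample in the design;
* ``maxquant`` — the MaxQuant flavor: contaminant/reverse rows (``CON__``,
  ``REV__`` prefixes or ``+`` marker columns) are dropped with counts
  logged, and phosphosite multiplicity columns (``<sample>___1/2/3``) are
  collapsed by summation.

All files are UTF-8 tab-separated with ``.`` decimals; every reader logs
how many rows it read, kept and dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (KSRTable, PhosphoSites, QuantMatrix, SampleDesign,
                   SchemaError, ValidationError, SITE_META_COLUMNS)

logger = logging.getLogger("phosphodyn")

DIALECTS = ("generic", "maxquant")

_MAXQUANT_MARKERS = ("Reverse", "Potential contaminant", "Contaminant")
_MAXQUANT_PREFIXES = ("CON__", "REV__")


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t")
    design = SampleDesign.from_frame(frame)
    logger.info("design: %d samples over %d stages", len(design.samples),
                design.n_stages)
    return design


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def _id_column(frame: pd.DataFrame, candidates: tuple[str, ...]) -> str:
    for c in candidates:
        if c in frame.columns:
            return c
    raise SchemaError(f"no feature id column; expected one of {candidates}")


def _drop_maxquant_artifacts(frame: pd.DataFrame, id_col: str
                             ) -> tuple[pd.DataFrame, int]:
    drop = pd.Series(False, index=frame.index)
    for col in _MAXQUANT_MARKERS:
        if col in frame.columns:
            drop |= frame[col].astype(str).str.strip() == "+"
    ids = frame[id_col].astype(str)
    for prefix in _MAXQUANT_PREFIXES:
        drop |= ids.str.startswith(prefix)
    return frame.loc[~drop], int(drop.sum())


def read_quant_table(path: str | Path, design: SampleDesign,
                     dialect: str = "generic") -> QuantMatrix:
    """Read a protein quantification table into a validated QuantMatrix."""
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t")
    n_read = len(frame)
    id_col = _id_column(frame, ("feature_id", "protein_id", "Protein IDs",
                                "Majority protein IDs", "id"))
    dropped = 0
    if dialect == "maxquant":
        frame, dropped = _drop_maxquant_artifacts(frame, id_col)
        if dropped:
            logger.info("%s: dropped %d contaminant/reverse rows", path, dropped)
    missing = [s for s in design.samples if s not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing sample columns {missing}")
    values = frame.set_index(frame[id_col].astype(str))[list(design.samples)]
    qm = QuantMatrix(values, design)
    logger.info("%s: read %d rows, kept %d, dropped %d", path, n_read,
                qm.n_features, dropped)
    return qm


def write_quant_table(matrix: QuantMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def _collapse_multiplicity(frame: pd.DataFrame, design: SampleDesign
                           ) -> pd.DataFrame:
    """Sum MaxQuant ``<sample>___k`` multiplicity columns into one per sample."""
    collapsed = frame.copy()
    any_found = False
    for s in design.samples:
        parts = [c for c in frame.columns
                 if c == s or (c.startswith(s + "___"))]
        multi = [c for c in parts if "___" in c]
        if multi:
            any_found = True
            collapsed[s] = frame[parts].apply(
                pd.to_numeric, errors="coerce").fillna(0).sum(axis=1)
            collapsed = collapsed.drop(columns=multi)
    if any_found:
        logger.info("site table: multiplicity columns collapsed by summation")
    return collapsed


_SITE_ALIASES = {
    "Protein": "protein_id", "Proteins": "protein_id",
    "Amino acid": "residue", "Position": "position",
    "Localization prob": "loc_prob", "Sequence window": "window",
}


def read_site_table(path: str | Path, design: SampleDesign,
                    dialect: str = "generic") -> PhosphoSites:
    """Read a phosphosite table (no localization filtering happens here)."""
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t")
    n_read = len(frame)
    dropped = 0
    if dialect == "maxquant":
        frame = frame.rename(columns=_SITE_ALIASES)
        id_col = _id_column(frame, ("site_id", "protein_id"))
        frame, dropped = _drop_maxquant_artifacts(frame, id_col)
        frame = _collapse_multiplicity(frame, design)
        if dropped:
            logger.info("%s: dropped %d contaminant/reverse rows", path, dropped)
    if "site_id" not in frame.columns:
        if {"protein_id", "residue", "position"}.issubset(frame.columns):
            frame = frame.assign(site_id=frame["protein_id"].astype(str)
                                 + "_" + frame["residue"].astype(str)
                                 + frame["position"].astype(int).astype(str))
        else:
            raise SchemaError(f"{path}: cannot determine site ids")
    keep = [c for c in SITE_META_COLUMNS if c in frame.columns]
    if "window" in frame.columns:
        keep.append("window")
    missing = [c for c in SITE_META_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing site columns {missing}")
    missing = [s for s in design.samples if s not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing sample columns {missing}")
    sites = PhosphoSites(frame[keep + list(design.samples)], design)
    logger.info("%s: read %d rows, kept %d, dropped %d", path, n_read,
                len(sites), dropped)
    return sites


def write_site_table(sites: PhosphoSites, path: str | Path) -> None:
    sites.records.to_csv(path, sep="\t", index=False)


def read_ksr_table(path: str | Path) -> KSRTable:
    """Read a kinase-substrate relation table (kinase, site key, tier)."""
    frame = pd.read_csv(path, sep="\t")
    table = KSRTable(frame)
    logger.info("%s: read %d kinase-substrate edges", path, len(table))
    return table


def write_ksr_table(ksr: KSRTable, path: str | Path) -> None:
    ksr.edges.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; duplicate ids are an error."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"duplicate FASTA id {record.id!r}")
        out[record.id] = str(record.seq)
    logger.info("%s: read %d sequences", path, len(out))
    return out


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
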