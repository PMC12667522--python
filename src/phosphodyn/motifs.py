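"""Descriptive sequence statistics of a phosphoproteome.

Residue-class composition (pS/pT/pY), the sites-per-protein histogram,
centered sequence windows around each site, and position frequency /
information-content matrices for sequence-logo rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PhosphoSites, ValidationError

logger = logging.getLogger("phosphodyn")

PAD = "_"
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def residue_class_fractions(sites: PhosphoSites | pd.DataFrame
                            ) -> dict[str, float]:
    """Fractions of phosphoserine, -threonine and -tyrosine sites."""
    recs = sites.records if isinstance(sites, PhosphoSites) else sites
    if len(recs) == 0:
        raise ValidationError("no sites; residue fractions undefined")
    counts = recs["residue"].value_counts()
    total = len(recs)
    return {res: float(counts.get(res, 0)) / total for res in ("S", "T", "Y")}


def sites_per_protein_hist(sites: PhosphoSites | pd.DataFrame, cap: int = 6
                           ) -> dict[int, int]:
    """Histogram of phosphosite counts per protein.

    Keys are 1 .. cap-1 for exact counts; the key ``cap`` aggregates all
    proteins with >= cap sites.  Proteins absent from the site table do
    not appear (the denominator is phosphoproteins, not the proteome).
    """
    recs = sites.records if isinstance(sites, PhosphoSites) else sites
    if len(recs) == 0:
        return {}
    per_protein = recs.groupby("protein_id").size()
    hist: dict[int, int] = {}
    for n, count in per_protein.value_counts().sort_index().items():
        key = min(int(n), cap)
        hist[key] = hist.get(key, 0) + int(count)
    return hist


def extract_window(sequence: str, position: int, w: int) -> str:
    """Centered window of length 2w+1 around a 1-based ``position``.

    Positions beyond either end of the protein are padded with ``_``.
    """
    if not (1 <= position <= len(sequence)):
        raise ValidationError(
            f"position {position} outside sequence of length {len(sequence)}")
    if w < 0:
        raise ValidationError("window half-width must be >= 0")
    chars = []
    for i in range(position - 1 - w, position + w):
        chars.append(sequence[i] if 0 <= i < len(sequence) else PAD)
    return "".join(chars)


def truncate_windows(windows, w_to: int) -> list[str]:
    """Symmetrically trim centered windows to half-width ``w_to``."""
    out = []
    for win in windows:
        if len(win) % 2 == 0:
            raise ValidationError("windows must have odd length")
        half = len(win) // 2
        if w_to > half:
            raise ValidationError("cannot widen a window by truncation")
        out.append(win[half - w_to: half + w_to + 1])
    return out


def frequency_matrix(windows, small_sample_correction: bool = False
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Position frequency matrix and per-position information content.

    Rows are positions -w..+w relative to the phosphosite, columns the 20
    amino acids.  Padding (and any non-standard character) is excluded
    from each position's denominator.  Information content in bits:
    R = log2(20) - H, optionally minus the small-sample correction
    e_n = 19 / (2 ln 2 n) applied per position.
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("no windows")
    length = len(windows[0])
    if length % 2 == 0 or any(len(x) != length for x in windows):
        raise ValidationError("windows must share one odd length")
    w = length // 2
    positions = list(range(-w, w + 1))
    freq = pd.DataFrame(0.0, index=positions, columns=list(AMINO_ACIDS))
    ic = pd.Series(0.0, index=positions, name="information_bits")
    arr = np.array([list(x) for x in windows])
    for i, pos in enumerate(positions):
        col = arr[:, i]
        counts = pd.Series(col).value_counts()
        counts = counts[counts.index.isin(AMINO_ACIDS)]
        n = int(counts.sum())
        if n == 0:
            continue
        f = counts / n
        freq.loc[pos, f.index] = f.to_numpy()
        h = float(-(f * np.log2(f)).sum())
        r = np.log2(20.0) - h
        if small_sample_correction:
            r -= 19.0 / (2.0 * np.log(2.0) * n)
        ic[pos] = max(r, 0.0)
    return freq, ic


@dataclass
class MotifSummary:
    """Bundle of the descriptive statistics for one site collection."""

    residue_fractions: dict[str, float]
    sites_per_protein: dict[int, int]
    windows: list[str]
    frequencies: pd.DataFrame
    information: pd.Series
    w: int


def summarize_motifs(sites: PhosphoSites, sequences: dict[str, str] | None = None,
                     w: int = 10, cap: int = 6,
                     small_sample_correction: bool = False) -> MotifSummary:
    """Compute the full motif summary for a site table.

    Windows come from ``sequences`` (FASTA map) when given; otherwise a
    precomputed ``window`` column is honored.  Sites whose protein lacks a
    sequence are skipped with a log entry.
    """
    recs = sites.records
    windows: list[str] = []
    skipped = 0
    if sequences is not None:
        for _, row in recs.iterrows():
            seq = sequences.get(row["protein_id"])
            if seq is None or not (1 <= row["position"] <= len(seq)):
                skipped += 1
                continue
            if seq[row["position"] - 1] != row["residue"]:
                raise ValidationError(
                    f"site {row['site_id']}: residue {row['residue']} does not "
                    f"match sequence at position {row['position']}")
            windows.append(extract_window(seq, int(row["position"]), w))
    elif "window" in recs.columns:
        for win in recs["window"].astype(str):
            half = len(win) // 2
            if len(win) % 2 == 0 or half < w:
                skipped += 1
                continue
            windows.append(win if half == w else
                           win[half - w: half + w + 1])
    else:
        raise ValidationError("need sequences or a precomputed window column")
    if skipped:
        logger.info("motif summary: skipped %d sites without usable windows",
                    skipped)
    if not windows:
        raise ValidationError("no usable sequence windows")
    freq, ic = frequency_matrix(windows, small_sample_correction)
    return MotifSummary(
        residue_fractions=residue_class_fractions(sites),
        sites_per_protein=sites_per_protein_hist(sites, cap=cap),
        windows=windows, frequencies=freq, information=ic, w=w)
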