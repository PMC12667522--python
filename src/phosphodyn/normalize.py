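"""Protein-calibrated relative abundance of phosphosites.

The quantification model: every intensity row (protein or site) is
mean-scaled to its across-sample mean, and each phosphosite is then
divided, sample-wise, by the mean-scaled abundance of its parent protein:

    r(s, j) = [x(s,j) / mean_j x(s,.)] / [p(g(s),j) / mean_j p(g(s),.)]

so that r is unit-free and protein-abundance changes cancel.  Zeros in the
protein matrix are replaced, before scaling, by the smallest non-zero value
of the whole protein dataset so the division stays defined; sites whose
protein was not quantified keep their mean-scaled values and are flagged
``site-only``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PhosphoSites, QuantMatrix, ValidationError

logger = logging.getLogger("phosphodyn")

#: provenance codes for calibrated cells
PROTEIN_CALIBRATED = "protein-calibrated"
SITE_ONLY = "site-only"
ZERO_REPLACED = "zero-replaced"


@dataclass
class RelativeAbundance:
    """Calibrated site abundances r(s, j) plus per-row provenance.

    ``r`` is sites x samples; ``provenance`` holds one code per row
    (protein-calibrated or site-only); ``zero_replaced`` marks cells whose
    protein denominator came from the zero-replacement rule; ``meta``
    carries the site metadata; ``dropped_all_zero`` lists sites removed
    because every intensity was zero.
    """

    r: pd.DataFrame
    provenance: pd.Series
    zero_replaced: pd.DataFrame
    meta: pd.DataFrame
    design: object
    dropped_all_zero: list

    def log2(self, eps: float | None = None) -> pd.DataFrame:
        """log2(r + eps) with eps = (smallest positive r) * 1e-3 by default."""
        vals = self.r.to_numpy()
        if eps is None:
            pos = vals[vals > 0]
            if pos.size == 0:
                raise ValidationError("no positive relative abundances")
            eps = float(pos.min()) * 1e-3
        return np.log2(self.r + eps)


def filter_localized(sites: PhosphoSites, threshold: float = 0.75
                     ) -> PhosphoSites:
    """Keep sites with localization probability strictly above ``threshold``.

    The class-I convention: probabilities *over* 0.75 are high confidence,
    so the comparison is strict (0.75 itself is removed).
    """
    if not (0 <= threshold <= 1):
        raise ValidationError("localization threshold must lie in [0, 1]")
    keep = sites.records["loc_prob"].to_numpy(dtype=float) > threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("localization filter (> %.2f): removed %d of %d sites",
                    threshold, removed, len(sites))
    return sites.subset(keep)


def replace_zeros(matrix: QuantMatrix) -> tuple[QuantMatrix, pd.DataFrame]:
    """Replace zero intensities by the global minimum non-zero of the dataset.

    Returns the patched matrix and a boolean mask of replaced cells.
    Raises if the matrix contains no non-zero value at all.
    """
    vals = matrix.values.to_numpy(dtype=float)
    mask = vals == 0
    n = int(mask.sum())
    if n == vals.size:
        raise ValidationError("all intensities are zero; nothing to scale to")
    if n:
        floor = float(vals[vals > 0].min())
        vals = np.where(mask, floor, vals)
        logger.info("zero replacement: %d cells set to global minimum %.6g",
                    n, floor)
    out = matrix.copy_with(
        pd.DataFrame(vals, index=matrix.values.index,
                     columns=matrix.values.columns))
    return out, pd.DataFrame(mask, index=matrix.values.index,
                             columns=matrix.values.columns)


def mean_scale(matrix: QuantMatrix) -> QuantMatrix:
    """Divide every row by its across-sample mean (row means become 1)."""
    vals = matrix.values
    means = vals.mean(axis=1)
    if (means <= 0).any():
        bad = means.index[means <= 0]
        raise ValidationError(
            f"rows with non-positive mean cannot be mean-scaled: "
            f"{list(bad)[:5]} (apply zero replacement first)")
    return matrix.copy_with(vals.div(means, axis=0))


def _mean_scale_frame(frame: pd.DataFrame) -> pd.DataFrame:
    means = frame.mean(axis=1)
    return frame.div(means, axis=0)


def calibrate_sites(sites: PhosphoSites, protein_matrix: QuantMatrix,
                    protein_zero_mask: pd.DataFrame | None = None
                    ) -> RelativeAbundance:
    """Calibrate mean-scaled site intensities to mean-scaled protein levels.

    ``protein_matrix`` must already be zero-replaced and mean-scaled.
    Sites with an all-zero intensity row cannot be mean-scaled and are
    dropped (logged); zero intensities in other rows stay zero (r = 0).
    """
    inten = sites.intensities
    all_zero = inten.sum(axis=1) == 0
    dropped = list(inten.index[all_zero])
    if dropped:
        logger.info("calibration: dropped %d all-zero site rows", len(dropped))
    inten = inten.loc[~all_zero]
    meta_cols = [c for c in sites.records.columns
                 if c not in sites.design.samples and c != "site_id"]
    meta = sites.records.set_index("site_id").loc[inten.index, meta_cols]

    site_scaled = _mean_scale_frame(inten)

    prot = protein_matrix.values
    gids = meta["protein_id"]
    present = gids.isin(prot.index).to_numpy()
    provenance = pd.Series(
        np.where(present, PROTEIN_CALIBRATED, SITE_ONLY),
        index=inten.index, name="provenance")
    n_site_only = int((~present).sum())
    if n_site_only:
        logger.info("calibration: %d sites lack a quantified protein "
                    "(site-only normalization)", n_site_only)

    r = site_scaled.copy()
    zero_rep = pd.DataFrame(False, index=inten.index, columns=inten.columns)
    if present.any():
        idx = inten.index[present]
        denom = prot.loc[gids[present].to_numpy()].to_numpy(dtype=float)
        r.loc[idx] = site_scaled.loc[idx].to_numpy() / denom
        if protein_zero_mask is not None:
            zmask = protein_zero_mask.loc[gids[present].to_numpy()].to_numpy()
            zero_rep.loc[idx] = zmask
    return RelativeAbundance(r=r, provenance=provenance,
                             zero_replaced=zero_rep, meta=meta,
                             design=sites.design, dropped_all_zero=dropped)


def calibrate(sites: PhosphoSites, proteins: QuantMatrix,
              localization_threshold: float = 0.75) -> RelativeAbundance:
    """Full calibration chain: localization filter, protein zero replacement
    and mean scaling, then site calibration."""
    localized = filter_localized(sites, localization_threshold)
    patched, zero_mask = replace_zeros(proteins)
    scaled = mean_scale(patched)
    return calibrate_sites(localized, scaled, zero_mask)
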