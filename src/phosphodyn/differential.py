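"""Differential screening of relative phosphosite abundances.

Two modes mirror the two experimental designs:

* multi-group (stage series): one-way ANOVA with Tukey's post hoc test,
  Benjamini-Hochberg FDR control across features, and a fold change
  defined as max(group means) / min(group means).  A feature is called
  significantly regulated when P.adjust < alpha and FC > fc_cut (both
  strict), with pairwise calls from Tukey-adjusted p and pairwise FC.
* two-group (knockout vs control): two-tailed Student's t-test (pooled
  variance), FC gate in either direction, and an ``Intensity_1 > 0``
  filter requiring signal in the first-listed condition.

Statistics run by default on log2(r + eps); fold changes are always
computed on the raw relative-abundance scale, since FC is a ratio.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._sturange import studentized_range_sf
from .core import ValidationError
from .normalize import RelativeAbundance

logger = logging.getLogger("phosphodyn")

#: smallest positive subnormal double; the p-value floor for zero-variance
#: rows with unequal means (the F statistic diverges there)
P_FLOOR = 5e-324


def _validate_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in arrs:
        if g.size < 2:
            raise ValidationError("every group needs at least 2 values")
        if not np.isfinite(g).all():
            raise ValidationError("non-finite values in a group")
    return arrs


def _anova_rows(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise classical one-way ANOVA over per-group (rows x reps) blocks.

    Returns (F, p, zero_variance_flag).  Rows where the within-group sum of
    squares is exactly zero are patched: equal means give F=0, p=1; unequal
    means give a diverging F with p floored at the machine minimum.
    """
    ns = np.array([m.shape[1] for m in mats])
    n_total = int(ns.sum())
    k = len(mats)
    means = np.stack([m.mean(axis=1) for m in mats], axis=1)     # rows x k
    grand = sum(m.sum(axis=1) for m in mats) / n_total
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((m - m.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              for m in mats)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = scipy.stats.f.sf(F, k - 1, n_total - k)
    zero_var = ssw == 0
    equal_means = zero_var & (ssb == 0)
    F = np.where(equal_means, 0.0, F)
    p = np.where(equal_means, 1.0, p)
    diverged = zero_var & ~equal_means
    F = np.where(diverged, np.inf, F)
    p = np.where(diverged, P_FLOOR, p)
    return F, p, zero_var


def anova_oneway(groups) -> tuple[float, float]:
    """Classical (pooled-variance) one-way ANOVA F test.

    Degenerate inputs follow the zero-noise conventions: all groups
    identical in every value give (F=0, p=1); zero within-group variance
    with unequal means gives (inf, machine-minimum p).
    """
    arrs = _validate_groups(groups)
    F, p, _ = _anova_rows([g[None, :] for g in arrs])
    return float(F[0]), float(p[0])


def tukey_hsd(groups) -> dict[tuple[int, int], float]:
    """Tukey HSD pairwise p-values (studentized range, pooled variance).

    Returns a map from group-index pairs (i, j), i < j, to the adjusted
    two-sided p.  Unbalanced designs use the Tukey-Kramer form with the
    pairwise harmonic mean of group sizes.
    """
    arrs = _validate_groups(groups)
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    pairs = list(itertools.combinations(range(k), 2))
    if ssw == 0:
        return {(i, j): (1.0 if arrs[i].mean() == arrs[j].mean() else P_FLOOR)
                for i, j in pairs}
    df = int(ns.sum()) - k
    msw = ssw / df
    means = np.array([g.mean() for g in arrs])
    q = np.array([abs(means[i] - means[j])
                  / np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                  for i, j in pairs])
    p = studentized_range_sf(q, k, df)
    return {pair: float(pv) for pair, pv in zip(pairs, p)}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (``P.adjust``)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_maxmin(group_means) -> float:
    """FC = max(group means) / min(group means); requires positive means."""
    m = np.asarray(group_means, dtype=float)
    if m.size == 0 or (m <= 0).any():
        raise ValidationError("fold change needs strictly positive group means")
    return float(m.max() / m.min())


def _analysis_frame(rel: RelativeAbundance, scale: str) -> pd.DataFrame:
    if scale == "log2":
        return rel.log2()
    if scale == "raw":
        return rel.r
    raise ValidationError(f"unknown scale {scale!r}; use 'log2' or 'raw'")


def screen_multigroup(rel: RelativeAbundance, fc_cut: float = 2.0,
                      alpha: float = 0.05, scale: str = "log2"
                      ) -> pd.DataFrame:
    """Screen all sites across >=3 stages (or 2; then ANOVA equals a t-test).

    Output columns: per-stage means of r, ``fc`` (max/min), ``F``,
    ``pvalue``, ``p_adjust``, ``significant``, per-pair Tukey p and pairwise
    significance flags, and a ``zero_variance`` marker for degenerate rows.
    """
    design = rel.design
    stages = design.stages
    Y = _analysis_frame(rel, scale)
    raw = rel.r
    mats = [Y[design.samples_in(g)].to_numpy(dtype=float) for g in stages]
    F, p, zero_var = _anova_rows(mats)
    p_adj = bh_adjust(p)

    group_means = {g: raw[design.samples_in(g)].mean(axis=1) for g in stages}
    means = pd.DataFrame(group_means)
    if (means.to_numpy() <= 0).any():
        raise ValidationError("non-positive group means; zero replacement or "
                              "all-zero-site dropping failed upstream")
    fc = means.max(axis=1) / means.min(axis=1)

    out = pd.DataFrame(index=raw.index)
    for g in stages:
        out[f"mean_{g}"] = means[g]
    out["fc"] = fc
    out["F"] = F
    out["pvalue"] = p
    out["p_adjust"] = p_adj
    out["zero_variance"] = zero_var
    out["significant"] = (p_adj < alpha) & (fc > fc_cut)

    # pairwise Tukey-Kramer p and pairwise FC gates, vectorized per pair
    k = len(stages)
    ns = np.array([m.shape[1] for m in mats])
    df = int(ns.sum()) - k
    ssw = sum(((m - m.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              for m in mats)
    with np.errstate(divide="ignore", invalid="ignore"):
        msw = ssw / df
    scale_means = np.stack([m.mean(axis=1) for m in mats], axis=1)
    pairs = list(itertools.combinations(range(k), 2))
    tk = {}
    for i, j in pairs:
        delta = np.abs(scale_means[:, i] - scale_means[:, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            q = delta / np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        pvals = np.full(len(raw), 1.0)
        ok = ~zero_var
        if ok.any():
            pvals[ok] = studentized_range_sf(q[ok], k, df)
        pvals[zero_var & (delta > 0)] = P_FLOOR
        tk[(i, j)] = pvals
    for i, j in pairs:
        gi, gj = stages[i], stages[j]
        pair_fc = np.maximum(means[gi] / means[gj], means[gj] / means[gi])
        out[f"tukey_p.{gi}.vs.{gj}"] = tk[(i, j)]
        out[f"pair_significant.{gi}.vs.{gj}"] = (
            (tk[(i, j)] < alpha) & (pair_fc > fc_cut))

    logger.info("multi-group screen: %d of %d sites significant "
                "(P.adjust < %g, FC > %g)", int(out["significant"].sum()),
                len(out), alpha, fc_cut)
    return out


def screen_twogroup(rel: RelativeAbundance, fc_cut: float = 1.5,
                    alpha: float = 0.05, scale: str = "log2",
                    raw_intensities: pd.DataFrame | None = None,
                    require_intensity1: bool = True) -> pd.DataFrame:
    """Two-group (e.g. knockout vs control) differential screen.

    The first-listed stage is the reference condition ("Intensity_1"):
    when ``require_intensity1`` is set, a feature must have positive summed
    raw intensity there.  Gates: two-tailed Student's t p < alpha and fold
    change > fc_cut in either direction (both strict).
    """
    design = rel.design
    if len(design.stages) != 2:
        raise ValidationError("two-group screening needs exactly 2 stages")
    g1, g2 = design.stages
    Y = _analysis_frame(rel, scale)
    a = Y[design.samples_in(g1)].to_numpy(dtype=float)
    b = Y[design.samples_in(g2)].to_numpy(dtype=float)

    ssw = (((a - a.mean(1, keepdims=True)) ** 2).sum(1)
           + ((b - b.mean(1, keepdims=True)) ** 2).sum(1))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a scipy precision warning; those rows
        # are overwritten by the explicit zero-variance rules below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=True)
    zero_var = ssw == 0
    equal = zero_var & (a.mean(1) == b.mean(1))
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    diverged = zero_var & ~equal
    with np.errstate(invalid="ignore"):
        t = np.where(diverged, np.sign(a.mean(1) - b.mean(1)) * np.inf, t)
    p = np.where(diverged, P_FLOOR, p)

    raw = rel.r
    m1 = raw[design.samples_in(g1)].mean(axis=1)
    m2 = raw[design.samples_in(g2)].mean(axis=1)
    if (m1 <= 0).any() or (m2 <= 0).any():
        raise ValidationError("non-positive group means in two-group screen")
    ratio = m1 / m2                       # reference over test condition
    fc_effect = np.maximum(ratio, 1.0 / ratio)

    out = pd.DataFrame(index=raw.index)
    out[f"mean_{g1}"] = m1
    out[f"mean_{g2}"] = m2
    out["fold_change"] = ratio
    out["fc_effect"] = fc_effect
    out["direction"] = np.where(m2 < m1, "down", np.where(m2 > m1, "up", "flat"))
    out["t"] = t
    out["pvalue"] = p
    out["p_adjust"] = bh_adjust(p)
    out["zero_variance"] = zero_var

    if require_intensity1:
        if raw_intensities is None:
            raise ValidationError("raw_intensities required for the "
                                  "Intensity_1 > 0 filter")
        inten1 = raw_intensities.loc[raw.index, design.samples_in(g1)].sum(axis=1)
        out["intensity1_positive"] = inten1 > 0
    else:
        out["intensity1_positive"] = True

    out["significant"] = ((out["pvalue"] < alpha) & (fc_effect > fc_cut)
                          & out["intensity1_positive"])
    logger.info("two-group screen: %d of %d sites significant "
                "(p < %g, FC > %g), %d down / %d up",
                int(out["significant"].sum()), len(out), alpha, fc_cut,
                int((out["significant"] & (out["direction"] == "down")).sum()),
                int((out["significant"] & (out["direction"] == "up")).sum()))
    return out
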