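"""Kinase-substrate enrichment of temporal modules.

For every (kinase, module) pair a 2x2 table compares the kinase's
substrate sites inside the module against the background population of
quantified, localization-passing sites that are neither significant nor
assigned to any module:

                     substrate   non-substrate
        in module        a            b
        background       c            d

Fisher's exact test (two-sided, minimum-likelihood convention) scores the
association and the sample odds ratio (a d)/(b c) gives its direction:
OR > 1 hyperrepresentation (high inferred kinase activity in the module),
OR < 1 hyporepresentation.  A kinase is called significant for a module
when OR > or_cut or OR < 1/or_cut with p < alpha (strict comparisons, no
multiplicity adjustment across kinase-module pairs).

The exact test is computed with exact integer combinatorics: the p-value
is the ratio of two integers (the summed hypergeometric numerators of all
tables no more likely than the observed one, over the total), converted to
float only at the end, so it matches exhaustive enumeration to rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .core import KSRTable, ValidationError

logger = logging.getLogger("phosphodyn")

HYPER = "hyperrepresented"
HYPO = "hyporepresented"
NOT_SIG = "not significant"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) with a+b the module size, c+d the background size."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError("contingency counts must be "
                                      "non-negative integers")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_contingency(substrates: set, module_sites: set,
                      background_sites: set) -> ContingencyTable:
    """Count a kinase's substrates inside a module vs the background.

    ``module_sites`` and ``background_sites`` must be disjoint; sites with
    no kinase annotation simply count as non-substrates.
    """
    overlap = module_sites & background_sites
    if overlap:
        raise ValidationError(
            f"module and background overlap on {len(overlap)} sites")
    a = len(substrates & module_sites)
    c = len(substrates & background_sites)
    return ContingencyTable(a=a, b=len(module_sites) - a,
                            c=c, d=len(background_sites) - c)


def _counts(table) -> tuple[int, int, int, int]:
    if isinstance(table, ContingencyTable):
        return table.as_tuple()
    flat = np.asarray(table).ravel()
    if flat.size != 4:
        raise ValidationError("a 2x2 table has exactly four counts")
    vals = [int(v) for v in flat]
    if any(f != v for f, v in zip(flat, vals)) or any(v < 0 for v in vals):
        raise ValidationError("contingency counts must be non-negative integers")
    return tuple(vals)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums the conditional (hypergeometric) probabilities of every table
    with the observed margins whose probability does not exceed that of
    the observed table.  Exact integer arithmetic throughout; the result
    is the correctly rounded float of the exact rational p.
    """
    a, b, c, d = _counts(table)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValidationError("empty table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table is possible
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    numerator = sum(w for w in weights if w <= w_obs)
    return float(Fraction(numerator, comb(n, c1)))


def odds_ratio(table) -> tuple[float, bool]:
    """Sample odds ratio (a d)/(b c), Haldane-Anscombe corrected on zeros.

    Returns (OR, corrected): when any cell is zero, 0.5 is added to all
    four cells and the correction is flagged.
    """
    a, b, c, d = _counts(table)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    return (a * d) / (b * c), corrected


def classify_kinase(or_value: float, p: float, or_cut: float = 1.2,
                    alpha: float = 0.05) -> str:
    """Direction call from OR and p with strict thresholds."""
    if or_cut <= 1:
        raise ValidationError("or_cut must exceed 1")
    if p < alpha:
        if or_value > or_cut:
            return HYPER
        if or_value < 1.0 / or_cut:
            return HYPO
    return NOT_SIG


def enrich_all(module_map: dict[object, set], background: set,
               ksr: KSRTable, or_cut: float = 1.2, alpha: float = 0.05
               ) -> pd.DataFrame:
    """Score every (kinase, module) pair against the frozen background.

    ``module_map`` maps module labels to site-key sets.  Kinases with no
    substrate resolved anywhere in the analyzed site universe are dropped
    (logged).  Returns one row per pair, sorted by p.
    """
    universe = set().union(background, *module_map.values()) if module_map \
        else set(background)
    subs_by_kinase = ksr.substrates_by_kinase(universe)
    if not subs_by_kinase:
        logger.warning("kinase enrichment: no kinase has a resolved substrate")
    rows = []
    for kinase, subs in sorted(subs_by_kinase.items()):
        for module, sites in module_map.items():
            tab = build_contingency(subs, sites, background)
            p = fisher_exact_two_sided(tab)
            orv, corrected = odds_ratio(tab)
            rows.append({
                "kinase": kinase, "module": module,
                "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                "odds_ratio": orv, "or_corrected": corrected,
                "pvalue": p,
                "class": classify_kinase(orv, p, or_cut, alpha),
            })
    out = pd.DataFrame(rows, columns=["kinase", "module", "a", "b", "c", "d",
                                      "odds_ratio", "or_corrected", "pvalue",
                                      "class"])
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
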