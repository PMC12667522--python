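"""Temporal module discovery by fuzzy c-means on z-scored stage means.

Each significant phosphosite is summarized by its vector of per-stage mean
relative abundances, standardized across stages (mean 0, SD 1 with the
sample SD convention).  Bezdek's fuzzy c-means then recovers soft module
memberships:

    u(i,k) = 1 / sum_j (d(i,k) / d(i,j))^(2/(m-1))
    c(k)   = sum_i u(i,k)^m x_i / sum_i u(i,k)^m
    J      = sum_{i,k} u(i,k)^m d(i,k)^2

with Euclidean distances and a fuzzifier m either fixed or estimated from
the data dimensions by the published empirical formula (the `mestimate`
rule).  The objective J is non-increasing across iterations; the
implementation is seeded (k-means++-style initialization) with
multi-restart keeping the lowest J.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .normalize import RelativeAbundance

logger = logging.getLogger("phosphodyn")


def zscore_stage_means(rel_or_frame, design=None, ddof: int = 1
                       ) -> tuple[pd.DataFrame, list]:
    """Per-feature z-scored stage-mean trajectories.

    Accepts a :class:`RelativeAbundance` or a raw (features x samples)
    frame plus a design.  Returns (trajectory matrix with one column per
    stage, list of features excluded for zero variance across stages).
    """
    if isinstance(rel_or_frame, RelativeAbundance):
        frame, design = rel_or_frame.r, rel_or_frame.design
    else:
        frame = rel_or_frame
        if design is None:
            raise ValidationError("a design is required with a raw frame")
    if design.n_stages < 2:
        raise ValidationError("need at least 2 stages for trajectories")
    means = pd.DataFrame(
        {g: frame[design.samples_in(g)].mean(axis=1) for g in design.stages})
    sd = means.std(axis=1, ddof=ddof)
    constant = sd == 0
    dropped = list(means.index[constant])
    if dropped:
        logger.info("trajectories: excluded %d constant rows", len(dropped))
    means = means.loc[~constant]
    z = means.sub(means.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return z, dropped


def estimate_fuzzifier(n_features: int, n_dims: int) -> float:
    """Empirical fuzzifier estimate m(N, D) for fuzzy c-means.

    The Schwaemmle & Jensen rule used by Mfuzz's mestimate:
    m = 1 + (1418/N + 22.05) D^-2
          + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134).
    """
    if n_features < 2 or n_dims < 1:
        raise ValidationError("need n_features >= 2 and n_dims >= 1")
    N, D = float(n_features), float(n_dims)
    return (1.0
            + (1418.0 / N + 22.05) * D ** -2.0
            + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134))


@dataclass
class ModuleAssignment:
    """Result of a fuzzy c-means run.

    ``membership`` is features x clusters (rows sum to 1), ``centroids``
    clusters x stages, ``m`` the fuzzifier, ``objective`` the per-iteration
    J trace of the winning restart, ``n_iter`` its iteration count.
    """

    membership: pd.DataFrame
    centroids: pd.DataFrame
    m: float
    objective: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def hard_labels(self, membership_floor: float = 0.0) -> pd.Series:
        return assign_modules(self, membership_floor)


def _init_centroids(X: np.ndarray, c: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """k-means++-style seeding: spread initial centroids by D^2 sampling."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, c):
        d2 = np.min(((X[:, None, :] - X[idx][None, :, :]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total == 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
    return X[idx].copy()


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update; points coinciding with a centroid get a one-hot row."""
    coincide = d2 <= 0
    u = np.empty_like(d2)
    regular = ~coincide.any(axis=1)
    if regular.any():
        power = d2[regular] ** (-1.0 / (m - 1.0))
        u[regular] = power / power.sum(axis=1, keepdims=True)
    if (~regular).any():
        rows = np.where(~regular)[0]
        u[rows] = 0.0
        for i in rows:
            hits = np.where(coincide[i])[0]
            u[i, hits] = 1.0 / hits.size
    return u


def _fcm_single(X: np.ndarray, c: int, m: float, tol: float, max_iter: int,
                rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, list, bool]:
    centroids = _init_centroids(X, c, rng)
    trace: list[float] = []
    converged = False
    u = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        u = _memberships(d2, m)
        um = u ** m
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        displacement = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        trace.append(float((um * d2).sum()))
        if displacement < tol:
            converged = True
            break
    return u, centroids, trace, converged


def fuzzy_cmeans(X: pd.DataFrame, c: int = 5, m: float | str = "auto",
                 tol: float = 1e-6, max_iter: int = 1000,
                 seed: int | None = None, restarts: int = 5
                 ) -> ModuleAssignment:
    """Fuzzy c-means over trajectory rows; deterministic given ``seed``.

    ``m="auto"`` applies :func:`estimate_fuzzifier` to the data shape.
    ``restarts`` independent seeded initializations are run and the one
    with the lowest final objective is kept (FCM is non-convex).
    """
    if c < 2:
        raise ValidationError("need at least 2 clusters")
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < c:
        raise ValidationError("need a 2-D matrix with at least c rows")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite trajectory values")
    if m == "auto":
        m = estimate_fuzzifier(arr.shape[0], arr.shape[1])
    m = float(m)
    if m <= 1:
        raise ValidationError("fuzzifier m must exceed 1")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        u, centroids, trace, converged = _fcm_single(
            arr, c, m, tol, max_iter, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (u, centroids, trace, converged)
    u, centroids, trace, converged = best

    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(arr))
    cols = (X.columns if isinstance(X, pd.DataFrame)
            else pd.RangeIndex(arr.shape[1]))
    membership = pd.DataFrame(u, index=index,
                              columns=[f"module{k + 1}" for k in range(c)])
    cent = pd.DataFrame(centroids, index=membership.columns, columns=cols)
    logger.info("fcm: c=%d, m=%.4f, J=%.6g after %d iterations (converged=%s)",
                c, m, trace[-1], len(trace), converged)
    return ModuleAssignment(membership=membership, centroids=cent, m=m,
                            objective=np.asarray(trace), n_iter=len(trace),
                            converged=converged)


def assign_modules(assignment: ModuleAssignment,
                   membership_floor: float = 0.0) -> pd.Series:
    """Hard module labels by argmax membership (1-based; 0 = unassigned).

    Ties break toward the lowest cluster index (logged); features whose
    maximum membership falls below ``membership_floor`` are unassigned.
    """
    u = assignment.membership.to_numpy()
    labels = u.argmax(axis=1) + 1
    umax = u.max(axis=1)
    ties = (u == umax[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("module assignment: %d exact membership ties broken "
                    "toward the lowest cluster index", int(ties.sum()))
    labels = np.where(umax < membership_floor, 0, labels)
    return pd.Series(labels, index=assignment.membership.index, name="module")


def centroid_correlations(assignment: ModuleAssignment) -> pd.DataFrame:
    """Pairwise Pearson correlations between cluster centroids.

    The merge report: with more clusters than true temporal patterns,
    redundant clusters show near-unit centroid correlation, making any
    cluster-merging step explicit and auditable.
    """
    return assignment.centroids.T.corr()


def match_clusters(assignment: ModuleAssignment,
                   reference: pd.DataFrame) -> dict[str, object]:
    """Greedy 1:1 matching of clusters to reference trajectories.

    ``reference`` is reference-pattern x stage.  Pairs are matched in
    decreasing order of Pearson correlation between centroid and reference
    rows; returns cluster label -> (reference label, correlation).
    """
    cent = assignment.centroids
    scores = []
    for ck in cent.index:
        for rk in reference.index:
            rho = np.corrcoef(cent.loc[ck].to_numpy(dtype=float),
                              reference.loc[rk].to_numpy(dtype=float))[0, 1]
            scores.append((rho, ck, rk))
    scores.sort(key=lambda t: -t[0])
    used_c, used_r, out = set(), set(), {}
    for rho, ck, rk in scores:
        if ck in used_c or rk in used_r:
            continue
        out[ck] = (rk, float(rho))
        used_c.add(ck)
        used_r.add(rk)
    return out
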