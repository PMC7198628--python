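"""Alpha and beta diversity statistics.

Implements the survey workflow's statistics directly: Chao1 richness
(bias-corrected by default), rarefaction without replacement (multivariate
hypergeometric subsampling), its closed-form expected richness, one-way
ANOVA on per-sample alpha values, Jaccard distances on presence/absence,
classical PCoA, and rank-based ANOSIM with permutation p-values.

Conventions: ANOSIM uses average ranks on tied distances and the add-one
permutation p-value p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations), so
the smallest attainable p is 1/(n_permutations + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .io import MeiodivError, OtuTable, ValidationError

__all__ = [
    "Chao1Result",
    "DistanceMatrix",
    "AnosimResult",
    "PcoaResult",
    "chao1",
    "rarefy",
    "rarefy_table",
    "expected_richness",
    "anova_alpha",
    "jaccard_matrix",
    "pcoa",
    "anosim",
    "pairwise_anosim",
]


@dataclass(frozen=True)
class Chao1Result:
    """Observed richness plus the Chao1 extrapolation from rare species."""

    s_obs: int
    f1: int  # singletons
    f2: int  # doubletons
    estimate: float


def chao1(counts, bias_corrected: bool = True) -> Chao1Result:
    """Chao1 richness estimate for one sample's count vector.

    Bias-corrected form (default): S_obs + F1*(F1-1) / (2*(F2+1)).
    Classic form (``bias_corrected=False``): S_obs + F1^2 / (2*F2), defined
    only when F2 > 0; with F2 = 0 the bias-corrected form is used instead.
    """
    c = np.asarray(counts)
    if c.size == 0 or not np.any(c > 0):
        raise ValidationError("chao1 requires at least one positive count")
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    s_obs = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        est = s_obs + f1 * f1 / (2.0 * f2)
    return Chao1Result(s_obs=s_obs, f1=f1, f2=f2, estimate=est)


def rarefy(counts, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A multivariate-hypergeometric draw: the result sums exactly to
    ``depth``.  ``seed`` may be an int or a numpy Generator.
    """
    c = np.asarray(counts, dtype=np.int64)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    total = int(c.sum())
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth > total:
        raise ValidationError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return c.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def rarefy_table(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Rarefy every sample of an OTU table to a common depth (one draw each)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = [rarefy(table.counts.loc[s].to_numpy(), depth, rng) for s in table.sample_ids]
    counts = pd.DataFrame(rows, index=table.sample_ids, columns=table.otu_ids)
    return OtuTable(counts=counts, marker=table.marker)


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected species count of a rarefied draw.

    E[S] = sum_i (1 - C(N - n_i, depth) / C(N, depth)).  Exact rational
    arithmetic for small totals; log-gamma otherwise.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds total {total}")
    if total <= 2000:
        acc = Fraction(0)
        denom = math.comb(total, depth)
        for n_i in c:
            acc += 1 - Fraction(math.comb(total - int(n_i), depth), denom)
        return float(acc)
    lg = math.lgamma

    def log_comb(n, k):
        if k < 0 or k > n:
            return -math.inf
        return lg(n + 1) - lg(k + 1) - lg(n - k + 1)

    log_denom = log_comb(total, depth)
    return float(sum(1.0 - math.exp(log_comb(total - int(n_i), depth) - log_denom)
                     for n_i in c))


def anova_alpha(values_by_group: dict[str, list[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over per-sample alpha-diversity values.

    Returns (F, p) with p from the upper tail of the F distribution.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValidationError(f"group {g!r} has no observations")
    n = sum(v.size for v in groups.values())
    k = len(groups)
    if n - k < 1:
        raise ValidationError("not enough residual degrees of freedom")
    grand = sum(v.sum() for v in groups.values()) / n
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ssw == 0:
        if ssb == 0:
            raise ValidationError("zero variance within and between groups")
        return math.inf, 0.0
    f_stat = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return float(f_stat), p


@dataclass
class DistanceMatrix:
    """Symmetric, hollow sample-by-sample dissimilarity matrix."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(d < -1e-12):
            raise ValidationError("negative distances")
        self.data = d

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(sample_ids=list(ids), data=self.data[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.data[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def jaccard_matrix(table: OtuTable) -> DistanceMatrix:
    """Jaccard distances between samples on presence/absence.

    d(a, b) = 1 - |A & B| / |A | B|; two empty samples are at distance 0.
    """
    if table.n_samples == 0:
        raise ValidationError("empty table")
    pres = table.presence().to_numpy().astype(bool)
    inter = (pres[:, None, :] & pres[None, :, :]).sum(axis=2).astype(float)
    union = (pres[:, None, :] | pres[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sample_ids=table.sample_ids, data=d)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis (classical MDS).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Negative eigenvalues are
    reported but their axes dropped; no Lingoes/Cailliez correction.
    """
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0)) if n else 0.0
    pos = vals > tol
    neg = vals < -tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_vals = vals[pos]
    total = pos_vals.sum()
    props = pos_vals / total if total > 0 else pos_vals
    return PcoaResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=pos_vals,
        proportion_explained=props,
        negative_eigenvalues=vals[neg],
    )


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic R with its permutation p-value."""

    r: float
    p_value: float
    n_permutations: int
    group_labels: tuple[str, ...]


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / denom)


def anosim(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_permutations: int | str = 999,
    seed=None,
) -> AnosimResult:
    """Analysis of similarities over locality groups.

    Pairwise distances are ranked (average ranks on ties) and
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    The p-value permutes group labels; ``n_permutations="all"`` enumerates
    every label permutation exactly (p = proportion of permutations,
    identity included, with R >= observed).
    """
    labels = np.asarray([groups[s] for s in dm.sample_ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    for g, c in zip(uniq, counts):
        if c < 2:
            raise ValidationError(f"group {g!r} has a single sample")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.data[iu, ju])
    m = n * (n - 1) / 2
    denom = m / 2.0  # = n(n-1)/4
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, denom)

    if n_permutations == "all":
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pl = labels[list(perm)]
            w = pl[iu] == pl[ju]
            if _anosim_r(ranks, w, denom) >= r_obs - 1e-12:
                hits += 1
            total += 1
        return AnosimResult(r=r_obs, p_value=hits / total,
                            n_permutations=total, group_labels=tuple(uniq))

    nperm = int(n_permutations)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.argsort(rng.random((nperm, n)), axis=1)
    pl = labels[perms]  # nperm x n
    w = pl[:, iu] == pl[:, ju]  # nperm x m
    rb = np.where(w, 0.0, ranks).sum(axis=1) / np.maximum((~w).sum(axis=1), 1)
    rw = np.where(w, ranks, 0.0).sum(axis=1) / np.maximum(w.sum(axis=1), 1)
    r_perm = (rb - rw) / denom
    p = (1 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1 + nperm)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=nperm,
                        group_labels=tuple(uniq))


def pairwise_anosim(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_permutations: int | str = 999,
    seed=None,
) -> list[AnosimResult]:
    """ANOSIM for every unordered pair of groups, on that pair's sub-matrix.

    No multiplicity adjustment is applied; raw p-values are reported.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for s in dm.sample_ids:
        by_group.setdefault(groups[s], []).append(s)
    out = []
    for g1, g2 in itertools.combinations(sorted(by_group), 2):
        ids = by_group[g1] + by_group[g2]
        sub = dm.submatrix(ids)
        out.append(anosim(sub, groups, n_permutations=n_permutations, seed=rng))
    return out


def anosim_table(results: list[AnosimResult]) -> pd.DataFrame:
    """Pairwise ANOSIM results shaped as (Group1, Group2, R, p)."""
    return pd.DataFrame(
        [
            {"group1": r.group_labels[0], "group2": r.group_labels[1],
             "R": r.r, "p": r.p_value}
            for r in results
        ]
    )


def alpha_by_locality(
    table: OtuTable, meta, metric: str = "chao1"
) -> dict[str, list[float]]:
    """Per-sample alpha diversity grouped by locality (chao1 or observed)."""
    out: dict[str, list[float]] = {}
    for s in table.sample_ids:
        counts = table.counts.loc[s].to_numpy()
        if metric == "chao1":
            val = chao1(counts).estimate
        elif metric == "observed":
            val = float((counts > 0).sum())
        else:
            raise MeiodivError(f"unknown alpha metric {metric!r}")
        out.setdefault(meta.locality_of(s), []).append(val)
    return out
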