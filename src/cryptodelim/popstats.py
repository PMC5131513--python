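"""Diversity and differentiation statistics for codominant markers.

Diversity per genetic cluster:

* ``He`` — gene diversity corrected for sample size,
  ``He = n/(n-1) * (1 - sum p_a^2)`` with ``n`` gene copies;
* ``NAe`` — effective number of alleles, ``1 / sum p_a^2``;
* ``AR_k`` — allelic richness rarefied to ``k`` gene copies by hypergeometric
  subsampling, ``sum_a [1 - C(n - n_a, k) / C(n, k)]``;
* ``Npl`` — proportion of loci polymorphic within the cluster.

Differentiation between clusters:

* ``F_ST`` — Weir & Cockerham's theta from per-locus, per-allele variance
  components (among populations / among individuals within / within
  individuals), combined as a ratio of sums over loci and alleles;
* ``D_S`` — Nei's standard genetic distance with the small-sample correction
  of the within-group gene identities;
* ``(delta mu)^2`` — Goldstein's squared difference in mean microsatellite
  allele size (repeat units), averaged over SSR loci; its expectation under
  the stepwise mutation model is ``2 mu T``, which makes it usable for
  divergence dating.

Marker-set comparisons: Wilcoxon matched-pairs signed-rank |Z| (normal
approximation, average ranks on ties, no continuity correction) and Pearson
correlation with an ordinary least-squares fit.

Multilocus combining follows the conventions of the classical population
genetics packages: ratio of sums for theta, unweighted locus means for
He/NAe/AR and the gene-identity terms of D_S.  Missing genotypes are
handled by pairwise deletion per locus; loci monomorphic within a group are
kept (He = 0), not dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .geno_io import (
    SNP,
    SSR,
    GenotypeDataset,
    LabeledDistanceMatrix,
    ValidationError,
)

__all__ = [
    "LocusFrequencies",
    "DiversityStats",
    "locus_frequencies",
    "gene_diversity",
    "effective_alleles",
    "allelic_richness",
    "prop_polymorphic",
    "diversity_stats",
    "fst_wc",
    "nei_ds",
    "delta_mu_sq",
    "pairwise_matrix",
    "wilcoxon_signed_rank_z",
    "pearson_ols",
]


@dataclass
class LocusFrequencies:
    """Per group x locus allele counts (gene copies) with pairwise deletion."""

    groups: list[str]
    locus_names: list[str]
    # counts[group][locus_index] = {allele_code: gene_copy_count}
    counts: dict[str, list[dict[int, int]]]

    def n_copies(self, group: str, locus_index: int) -> int:
        return sum(self.counts[group][locus_index].values())

    def frequencies(self, group: str, locus_index: int) -> dict[int, float]:
        c = self.counts[group][locus_index]
        n = sum(c.values())
        return {a: k / n for a, k in c.items()} if n else {}

    def homozygosity(self, group: str, locus_index: int) -> float:
        """sum of squared allele frequencies (expected gene identity)."""
        freqs = self.frequencies(group, locus_index)
        return sum(p * p for p in freqs.values())


def _groups_of(g: GenotypeDataset, groups: Optional[Mapping[str, str]]) -> dict[str, list[str]]:
    mapping = groups if groups is not None else g.group_labels
    if mapping is None:
        raise ValidationError("no group labels available")
    by_group: dict[str, list[str]] = {}
    for ind in g.individuals:
        if ind in mapping:
            by_group.setdefault(mapping[ind], []).append(ind)
    return by_group


def locus_frequencies(
    g: GenotypeDataset,
    groups: Optional[Mapping[str, str]] = None,
    marker_type: Optional[str] = None,
    locus_indices: Optional[Sequence[int]] = None,
) -> LocusFrequencies:
    """Tabulate gene-copy counts per group and locus.

    ``groups`` maps individual -> group label; it defaults to the dataset's
    own labels.  Individuals absent from the map are excluded.
    """
    by_group = _groups_of(g, groups)
    if locus_indices is None:
        locus_indices = g.locus_indices(marker_type)
    names = [g.loci[l].name for l in locus_indices]
    counts: dict[str, list[dict[int, int]]] = {}
    for grp in sorted(by_group):
        inds = by_group[grp]
        counts[grp] = [dict(g.allele_counts(l, inds)) for l in locus_indices]
    return LocusFrequencies(sorted(by_group), names, counts)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def _per_locus_mean(values: list[float]) -> float:
    if not values:
        raise ValidationError("no locus with sufficient data")
    return float(np.mean(values))


def gene_diversity(f: LocusFrequencies) -> dict[str, float]:
    """Multilocus mean of He = n/(n-1) (1 - sum p^2) per group."""
    out = {}
    for grp in f.groups:
        per_locus = []
        for l in range(len(f.locus_names)):
            n = f.n_copies(grp, l)
            if n < 2:
                warnings.warn(
                    f"gene_diversity: locus {f.locus_names[l]} in group {grp} "
                    f"has n={n} gene copies; excluded"
                )
                continue
            per_locus.append(n / (n - 1) * (1.0 - f.homozygosity(grp, l)))
        out[grp] = _per_locus_mean(per_locus)
    return out


def effective_alleles(f: LocusFrequencies) -> dict[str, float]:
    """Multilocus mean of NAe = 1 / sum p^2 per group."""
    out = {}
    for grp in f.groups:
        per_locus = []
        for l in range(len(f.locus_names)):
            if f.n_copies(grp, l) < 2:
                warnings.warn(
                    f"effective_alleles: locus {f.locus_names[l]} in group {grp} "
                    "has <2 gene copies; excluded"
                )
                continue
            per_locus.append(1.0 / f.homozygosity(grp, l))
        out[grp] = _per_locus_mean(per_locus)
    return out


def _rarefied_richness(counts: dict[int, int], k: int) -> float:
    n = sum(counts.values())
    if k > n:
        raise ValidationError(f"rarefaction k={k} exceeds gene-copy count n={n}")
    denom = math.comb(n, k)
    return sum(1.0 - math.comb(n - na, k) / denom for na in counts.values())


def allelic_richness(f: LocusFrequencies, k: Optional[int] = None) -> tuple[dict[str, float], int]:
    """Allelic richness rarefied to ``k`` gene copies (hypergeometric).

    By default each locus is rarefied to the smallest gene-copy count over
    groups at that locus, so groups are compared at a common depth locus by
    locus.  An explicit ``k`` applies everywhere and must not exceed any
    group's gene-copy count.  Returns the per-group multilocus means and the
    smallest depth actually used.
    """
    n_loci = len(f.locus_names)
    if k is None:
        ks = [min(f.n_copies(grp, l) for grp in f.groups) for l in range(n_loci)]
    else:
        if k < 1:
            raise ValidationError("rarefaction k must be >= 1")
        ks = [k] * n_loci
    out = {}
    for grp in f.groups:
        per_locus = [_rarefied_richness(f.counts[grp][l], ks[l]) for l in range(n_loci)]
        out[grp] = _per_locus_mean(per_locus)
    return out, min(ks)


def prop_polymorphic(f: LocusFrequencies) -> dict[str, float]:
    """Fraction of loci with at least two observed alleles within the group."""
    if not f.locus_names:
        raise ValidationError("prop_polymorphic: no loci")
    return {
        grp: float(
            np.mean([len(f.counts[grp][l]) >= 2 for l in range(len(f.locus_names))])
        )
        for grp in f.groups
    }


@dataclass
class DiversityStats:
    """Per-group diversity summary at one marker type."""

    group: str
    NAe: float
    AR: float
    He: float
    Npl: float
    k_used: int


def diversity_stats(
    g: GenotypeDataset,
    groups: Optional[Mapping[str, str]] = None,
    marker_type: Optional[str] = None,
    rarefy_k: Optional[int] = None,
) -> list[DiversityStats]:
    f = locus_frequencies(g, groups, marker_type)
    he = gene_diversity(f)
    nae = effective_alleles(f)
    ar, k_used = allelic_richness(f, rarefy_k)
    npl = prop_polymorphic(f)
    return [
        DiversityStats(grp, nae[grp], ar[grp], he[grp], npl[grp], k_used)
        for grp in f.groups
    ]


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


def fst_wc(
    g: GenotypeDataset,
    groups: Optional[Mapping[str, str]] = None,
    pair: Optional[tuple[str, str]] = None,
    marker_type: Optional[str] = None,
    locus_indices: Optional[Sequence[int]] = None,
) -> float:
    """Weir & Cockerham's theta over the given groups (all, or one pair).

    Per locus and allele, the variance components are

    * ``a`` — among populations,
    * ``b`` — among individuals within populations,
    * ``c`` — within individuals (from observed heterozygote frequencies),

    and theta is ``sum a / sum (a + b + c)`` over loci and alleles.  Small
    negative estimates are legitimate for an unbiased estimator and are not
    clamped.  A dataset monomorphic at every included locus is an error.
    """
    by_group = _groups_of(g, groups)
    if pair is not None:
        by_group = {k: by_group[k] for k in pair}
    names = sorted(by_group)
    if len(names) < 2:
        raise ValidationError("fst_wc: need at least two groups")
    if locus_indices is None:
        locus_indices = g.locus_indices(marker_type)
    pos = {ind: i for i, ind in enumerate(g.individuals)}
    r = len(names)
    sum_a = 0.0
    sum_abc = 0.0
    for l in locus_indices:
        # per-group individuals with data, allele frequencies and het counts
        n_i = []
        freqs: list[dict[int, float]] = []
        hets: list[dict[int, float]] = []
        alleles: set[int] = set()
        for grp in names:
            calls = [g.calls[pos[ind]][l] for ind in by_group[grp]]
            calls = [c for c in calls if c is not None]
            ni = len(calls)
            n_i.append(ni)
            cnt: dict[int, int] = {}
            het: dict[int, int] = {}
            for a_, b_ in calls:
                cnt[a_] = cnt.get(a_, 0) + 1
                cnt[b_] = cnt.get(b_, 0) + 1
                if a_ != b_:
                    het[a_] = het.get(a_, 0) + 1
                    het[b_] = het.get(b_, 0) + 1
            freqs.append({a: c / (2 * ni) for a, c in cnt.items()} if ni else {})
            hets.append({a: c / ni for a, c in het.items()} if ni else {})
            alleles.update(cnt)
        if any(ni < 2 for ni in n_i) or len(alleles) < 2:
            continue
        n_arr = np.array(n_i, dtype=float)
        n_bar = n_arr.mean()
        n_c = (r * n_bar - (n_arr**2).sum() / (r * n_bar)) / (r - 1)
        if n_c <= 0:
            continue
        for allele in alleles:
            p_i = np.array([fr.get(allele, 0.0) for fr in freqs])
            h_i = np.array([ht.get(allele, 0.0) for ht in hets])
            p_bar = (n_arr * p_i).sum() / (r * n_bar)
            s2 = (n_arr * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_arr * h_i).sum() / (r * n_bar)
            a_comp = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
            )
            b_comp = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c_comp = h_bar / 2.0
            sum_a += a_comp
            sum_abc += a_comp + b_comp + c_comp
    if sum_abc == 0.0:
        raise ValidationError(
            "fst_wc: undefined (all loci monomorphic across the chosen groups)"
        )
    return sum_a / sum_abc


def nei_ds(
    f: LocusFrequencies,
    pair: tuple[str, str],
    locus_indices: Optional[Sequence[int]] = None,
) -> float:
    """Nei's standard genetic distance with sample-size correction.

    Per locus, the unbiased within-group gene identity for a group with
    ``n`` diploid individuals (``2n`` gene copies) is
    ``J_X = (2n sum p^2 - 1) / (2n - 1)``; the between-group identity is
    ``J_XY = sum_a p_Xa p_Ya``.  Identities are averaged arithmetically over
    loci and ``D_S = -ln( mean J_XY / sqrt(mean J_X mean J_Y) )``.  Returns
    ``+inf`` when the groups share no alleles at any locus.
    """
    x, y = pair
    if x == y:
        return 0.0  # self-distance by convention (the correction would not cancel)
    if locus_indices is None:
        locus_indices = range(len(f.locus_names))
    jx, jy, jxy = [], [], []
    for l in locus_indices:
        cx, cy = f.n_copies(x, l), f.n_copies(y, l)
        if cx < 2 or cy < 2:
            continue
        px = f.frequencies(x, l)
        py = f.frequencies(y, l)
        jx.append((cx * sum(p * p for p in px.values()) - 1) / (cx - 1))
        jy.append((cy * sum(p * p for p in py.values()) - 1) / (cy - 1))
        jxy.append(sum(p * py.get(a, 0.0) for a, p in px.items()))
    if not jx:
        raise ValidationError(f"nei_ds: groups {x!r}, {y!r} share no usable locus")
    jx_m, jy_m, jxy_m = np.mean(jx), np.mean(jy), np.mean(jxy)
    if jxy_m <= 0:
        return float("inf")
    return float(-np.log(jxy_m / np.sqrt(jx_m * jy_m)))


def delta_mu_sq(
    g: GenotypeDataset,
    groups: Optional[Mapping[str, str]] = None,
    pair: Optional[tuple[str, str]] = None,
    locus_indices: Optional[Sequence[int]] = None,
) -> float:
    """Goldstein's (delta mu)^2: mean squared difference in mean allele size.

    Defined for SSR loci only (allele codes in repeat units); calling it on
    SNP loci is an error because nucleotide codes carry no size information.
    """
    by_group = _groups_of(g, groups)
    if pair is None:
        names = sorted(by_group)
        if len(names) != 2:
            raise ValidationError("delta_mu_sq: give a pair or exactly two groups")
        pair = (names[0], names[1])
    if locus_indices is None:
        locus_indices = g.locus_indices(SSR)
        if not locus_indices:
            raise ValidationError("delta_mu_sq: dataset has no SSR loci")
    for l in locus_indices:
        if g.loci[l].marker_type != SSR:
            raise ValidationError(
                f"delta_mu_sq: locus {g.loci[l].name!r} is not an SSR "
                "(allele size undefined for SNPs)"
            )
    x, y = pair
    diffs = []
    for l in locus_indices:
        cx = g.allele_counts(l, by_group[x])
        cy = g.allele_counts(l, by_group[y])
        if not cx or not cy:
            continue
        mx = sum(a * c for a, c in cx.items()) / sum(cx.values())
        my = sum(a * c for a, c in cy.items()) / sum(cy.values())
        diffs.append((mx - my) ** 2)
    if not diffs:
        raise ValidationError(f"delta_mu_sq: no shared SSR data for {x!r}, {y!r}")
    return float(np.mean(diffs))


_METRICS = ("FST", "DS", "DELTA_MU_SQ")


def pairwise_matrix(
    g: GenotypeDataset,
    groups: Optional[Mapping[str, str]] = None,
    metric: str = "DS",
    marker_type: Optional[str] = None,
    locus_indices: Optional[Sequence[int]] = None,
) -> LabeledDistanceMatrix:
    """All pairwise distances between groups, plus a global value.

    The global value is the multi-group theta for ``FST`` (all groups pooled
    into one estimate) and the mean over pairs for ``DS`` and
    ``DELTA_MU_SQ``; it is stored on the returned matrix as
    ``global_value``.
    """
    if metric not in _METRICS:
        raise ValidationError(f"metric must be one of {_METRICS}")
    by_group = _groups_of(g, groups)
    labels = sorted(by_group)
    n = len(labels)
    if n < 2:
        raise ValidationError("pairwise_matrix: need at least two groups")
    if metric == "DELTA_MU_SQ" and locus_indices is None:
        locus_indices = g.locus_indices(SSR)
    if metric != "FST":
        f = locus_frequencies(g, groups, marker_type, locus_indices)
    values = np.zeros((n, n))
    pair_values = []
    for i in range(n):
        for j in range(i + 1, n):
            pr = (labels[i], labels[j])
            if metric == "FST":
                v = fst_wc(g, groups, pr, marker_type, locus_indices)
            elif metric == "DS":
                v = nei_ds(f, pr)
            else:
                v = delta_mu_sq(g, groups, pr, locus_indices)
            values[i, j] = values[j, i] = v
            pair_values.append(v)
    if metric == "FST":
        global_value = fst_wc(g, groups, None, marker_type, locus_indices)
    else:
        global_value = float(np.mean(pair_values))
    return LabeledDistanceMatrix(labels, values, metric, global_value)


# ---------------------------------------------------------------------------
# marker-set comparison statistics
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank_z(x: Sequence[float], y: Sequence[float]) -> dict:
    """Wilcoxon matched-pairs signed-rank test, normal approximation.

    Zero differences are dropped; |d| are ranked with average ranks on ties;
    ``W = min(W+, W-)`` and ``|Z| = (n(n+1)/4 - W) / sqrt(n(n+1)(2n+1)/24)``
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("wilcoxon: x and y must have equal length")
    if len(x) < 6:
        raise ValidationError("wilcoxon: need at least 6 pairs")
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("wilcoxon: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    mean_w = n * (n + 1) / 4.0
    sd_w = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return {"abs_z": float((mean_w - w) / sd_w), "W": float(w), "n": n}


def pearson_ols(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson r with the least-squares slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("pearson_ols: need paired vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("pearson_ols: x is constant")
    res = sps.linregress(x, y)
    return {
        "r": float(res.rvalue),
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
    }
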