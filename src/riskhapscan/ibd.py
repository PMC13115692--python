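"""Interval-based IBD-sharing summaries, founder-dating heuristic,
KING-robust pairwise kinship, and the carrier-relatedness contrast.

IBD segments are consumed from a file (or from simulator truth), never
detected here: detection belongs to the external haplotype-IBD tool. The
overlap rule is the inclusive interval rule ``segment end >= interval start
and segment start <= interval end``. Founder age uses the rough heuristic
g ~= 50 / L_cM applied to the median per-pair maximum overlapping segment
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import IBDSegmentSet

__all__ = [
    "overlaps_interval",
    "class_ibd_summary",
    "IBDIntervalSummary",
    "tmrca_heuristic",
    "king_robust",
    "KinshipMatrix",
    "carrier_pair_contrast",
    "CarrierPairContrast",
]


def overlaps_interval(seg_start: int, seg_end: int,
                      interval_start: int, interval_end: int) -> bool:
    """Inclusive interval-overlap rule (both endpoints count)."""
    return seg_end >= interval_start and seg_start <= interval_end


@dataclass
class IBDIntervalSummary:
    """Within-class IBD sharing over a focal interval.

    ``per_pair_max_cM`` maps a canonical haplotype pair to the maximum cM
    length among its segments overlapping the interval. The generations
    estimate applies g = 50/L to the median of those per-pair maxima.
    """

    interval: tuple
    n_class_haplotypes: int
    n_possible_pairs: int
    n_sharing_pairs: int
    proportion_sharing: float
    median_max_cM: float
    generations_raw: float
    generations: float
    per_pair_max_cM: dict

    @property
    def has_sharing(self) -> bool:
        return self.n_sharing_pairs > 0


def class_ibd_summary(segments: IBDSegmentSet, class_haplotypes,
                      interval: tuple) -> IBDIntervalSummary:
    """Summarize IBD sharing over ``interval`` among the haplotypes in
    ``class_haplotypes`` (iterable of ``(dog_id, side)``).

    For each of the n(n-1)/2 within-class pairs: the maximum cM length of
    any overlapping segment; the proportion of pairs with at least one such
    segment; the median of per-pair maxima among sharing pairs; and the
    founder-age heuristic applied to that median.
    """
    chrom, start, end = interval
    members = {(str(d), int(s)) for d, s in class_haplotypes}
    n = len(members)
    if n < 2:
        raise ValueError("class must contain at least 2 haplotypes")
    df = segments.segments
    per_pair: dict = {}
    for row in df.itertuples(index=False):
        if str(row.chromosome) != str(chrom):
            continue
        a = (str(row.dog_a), int(row.side_a))
        b = (str(row.dog_b), int(row.side_b))
        if a not in members or b not in members:
            continue
        if not overlaps_interval(row.start_bp, row.end_bp, start, end):
            continue
        key = (a, b) if a <= b else (b, a)
        cur = per_pair.get(key)
        if cur is None or row.length_cM > cur:
            per_pair[key] = float(row.length_cM)
    n_pairs = n * (n - 1) // 2
    n_sharing = len(per_pair)
    if n_sharing:
        med = float(np.median(list(per_pair.values())))
        g_raw, g = tmrca_heuristic(med)
    else:
        med, g_raw, g = float("nan"), float("nan"), float("nan")
    return IBDIntervalSummary(
        interval=(chrom, start, end), n_class_haplotypes=n,
        n_possible_pairs=n_pairs, n_sharing_pairs=n_sharing,
        proportion_sharing=n_sharing / n_pairs,
        median_max_cM=med, generations_raw=g_raw, generations=g,
        per_pair_max_cM=per_pair,
    )


def tmrca_heuristic(length_cM: float) -> tuple:
    """Approximate generations to the common ancestor, g = 50 / L_cM.

    Returns ``(raw, rounded-to-nearest-integer)``. Only meaningful for
    L > 0; local recombination-rate variation and IBD-calling thresholds
    shift these estimates, so they are order-of-magnitude guides.
    """
    if not length_cM > 0:
        raise ValueError("segment length must be positive")
    g = 50.0 / float(length_cM)
    return g, float(round(g))


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    dog_ids: list
    phi: np.ndarray
    n_markers_used: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.dog_ids.index(a), self.dog_ids.index(b)
        return float(self.phi[i, j])


def king_robust(dosages, dog_ids=None, maf_min: float = 0.05,
                miss_max: float = 0.05) -> KinshipMatrix:
    """KING-robust pairwise kinship from a dogs x markers dosage matrix.

    Dosages are 0/1/2 alt-allele counts with negative values marking missing
    calls. Markers are filtered to MAF >= ``maf_min`` and missing rate <=
    ``miss_max`` (LD pruning, when wanted, is an upstream marker-list
    decision). For each pair,

        phi = (N_het,het - 2 N_opp-hom) / (N_het,i + N_het,j)

    counted over markers non-missing in both dogs. The estimator is robust
    to population structure and is negative for between-population pairs;
    the self-comparison diagonal equals 0.5 by the duplicate formula. Pairs
    with no heterozygous markers are undefined (NaN).
    """
    D = np.asarray(dosages, dtype=float)
    n, m = D.shape
    if n < 2:
        raise ValueError("need at least 2 dogs")
    if dog_ids is None:
        dog_ids = [f"D{i + 1}" for i in range(n)]
    obs = D >= 0
    with np.errstate(invalid="ignore"):
        miss_rate = 1.0 - obs.mean(axis=0)
        alt = np.where(obs, D, 0.0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        freq = np.divide(alt, denom, out=np.zeros(m), where=denom > 0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & (miss_rate <= miss_max)
    D = D[:, keep]
    obs = obs[:, keep]

    het = (D == 1) & obs
    aa = (D == 0) & obs
    bb = (D == 2) & obs
    Hf = het.astype(np.float64)
    Of = obs.astype(np.float64)
    n_hh = Hf @ Hf.T
    n_opp = aa.astype(np.float64) @ bb.astype(np.float64).T
    n_opp = n_opp + n_opp.T
    # per-pair heterozygote counts restricted to jointly observed markers
    het_i = Hf @ Of.T          # het in i among markers observed in j
    het_j = het_i.T
    used = Of @ Of.T
    denom = het_i + het_j
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    return KinshipMatrix(list(dog_ids), phi, used.astype(np.int64))


@dataclass
class CarrierPairContrast:
    categories: dict          # category -> kinship value array
    statistic: float          # rank-sum W of carrier-carrier (first-named group)
    p_value: float
    medians: dict

    @property
    def n_pairs(self) -> dict:
        return {k: len(v) for k, v in self.categories.items()}


def carrier_pair_contrast(kinship: KinshipMatrix, carrier_flags) -> CarrierPairContrast:
    """Compare carrier-carrier vs noncarrier-noncarrier kinship.

    Pairs are assigned to carrier-carrier, carrier-noncarrier, or
    noncarrier-noncarrier by the two dogs' carrier flags (dosage >= 1 at the
    lead marker). The two homogeneous categories are contrasted with a
    two-sided Wilcoxon rank-sum test (normal approximation with tie
    correction; exact for tiny samples). The reported W is the
    Mann-Whitney U of the carrier-carrier group, so its orientation is
    "carrier-carrier first".
    """
    flags = np.asarray(carrier_flags, dtype=bool)
    n = len(flags)
    if kinship.phi.shape != (n, n):
        raise ValueError("carrier flags do not match the kinship matrix")
    iu = np.triu_indices(n, k=1)
    vals = kinship.phi[iu]
    ci, cj = flags[iu[0]], flags[iu[1]]
    cats = {
        "carrier-carrier": vals[ci & cj],
        "carrier-noncarrier": vals[ci ^ cj],
        "noncarrier-noncarrier": vals[~ci & ~cj],
    }
    cc = cats["carrier-carrier"][~np.isnan(cats["carrier-carrier"])]
    nn = cats["noncarrier-noncarrier"][~np.isnan(cats["noncarrier-noncarrier"])]
    if len(cc) < 2 or len(nn) < 2:
        raise ValueError("need at least 2 pairs in each contrasted category")
    method = "exact" if max(len(cc), len(nn)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(cc, nn, alternative="two-sided", method=method)
    return CarrierPairContrast(
        categories=cats,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        medians={k: float(np.nanmedian(v)) if len(v) else float("nan")
                 for k, v in cats.items()},
    )
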