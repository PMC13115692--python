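"""Haplotype-sharing statistics around a focal allele.

Phased chromosomes are partitioned into risk and non-risk classes by the
allele carried at the lead marker. Within each class the module computes:

* pairwise shared-tract lengths — the maximal interval around the focal
  marker over which two haplotypes are identical at every typed marker, and
  the per-haplotype median over all within-class pairs;
* the EHH decay curve — EHH(x) is the probability that two haplotypes drawn
  at random from the class are identical at every marker from the focal
  position out to x, computed independently left and right (unpolarized);
* integrated haplotype homozygosity (iES, trapezoidal area under EHH) and
  the unstandardized cross-class statistic xpehh = log(iES_a / iES_b);
* half-decay spans (first crossing of EHH below a threshold, linearly
  interpolated between markers);
* seeded down-sampling of a class for sample-size sensitivity checks.

Tract boundaries use the position of the farthest *matching* marker (a
conservative, marker-supported length); a mismatch-midpoint alternative is
available behind a flag. Tracts reaching the region edge are flagged as
censored. iES integration is discarded (NaN, flagged) when the EHH curve
has not fallen below a cutoff before the region border, mirroring the
discard-at-border convention of selection-scan software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FocalMarkerSpec, MarkerMap, PhasedHaplotypeSet

__all__ = [
    "AllelePartition",
    "SharedTractSummary",
    "EHHCurve",
    "IESContrast",
    "partition_by_focal_allele",
    "shared_tract_length",
    "median_shared_tracts",
    "ehh_curve",
    "ies",
    "xpehh_unstandardized",
    "half_decay_span",
    "downsample_class",
]


@dataclass
class AllelePartition:
    """Risk/non-risk haplotype indices at the focal marker."""

    risk_indices: np.ndarray
    nonrisk_indices: np.ndarray
    focal_index: int
    risk_allele_code: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.risk_indices) + len(self.nonrisk_indices)


def partition_by_focal_allele(haps: PhasedHaplotypeSet,
                              focal: FocalMarkerSpec) -> AllelePartition:
    """Assign every haplotype to the risk or non-risk class by its allele at
    the lead-marker column. The focal marker must be polymorphic."""
    idx = focal.validate(haps.map)
    code = focal.risk_code(haps.map)
    col = haps.alleles[:, idx]
    risk = np.flatnonzero(col == code)
    nonrisk = np.flatnonzero(col != code)
    if len(risk) == 0 or len(nonrisk) == 0:
        raise ValueError("focal marker is monomorphic in this sample")
    return AllelePartition(risk, nonrisk, idx, code)


# ---------------------------------------------------------------------------
# Shared tracts
# ---------------------------------------------------------------------------

def _pair_extents(h1, h2, focal_index):
    """Indices of the farthest matching marker left/right of the focal
    (inclusive scan stopping at the first mismatch)."""
    mism = h1 != h2
    if mism[focal_index]:
        return None  # alleles differ at the focal marker itself
    left = focal_index
    right = focal_index
    before = np.flatnonzero(mism[:focal_index])
    left = before[-1] + 1 if len(before) else 0
    after = np.flatnonzero(mism[focal_index + 1:])
    right = focal_index + after[0] if len(after) else len(h1) - 1
    return left, right


def shared_tract_length(h1, h2, focal_index: int, mm: MarkerMap,
                        boundary: str = "match") -> dict:
    """Shared-tract length (bp) around the focal marker for one pair.

    With ``boundary="match"`` the tract runs from the farthest matching
    marker on the left to the farthest matching marker on the right; with
    ``boundary="midpoint"`` each end extends to the midpoint between the
    last match and the first mismatch. A side that reaches the region edge
    without mismatching is censored at the edge position.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    ext = _pair_extents(h1, h2, focal_index)
    pos = mm.position_bp
    if ext is None:
        return {"length_bp": 0, "left_bp": int(pos[focal_index]),
                "right_bp": int(pos[focal_index]),
                "censored_left": False, "censored_right": False,
                "focal_mismatch": True}
    left, right = ext
    censored_left = left == 0
    censored_right = right == len(h1) - 1
    lb, rb = float(pos[left]), float(pos[right])
    if boundary == "midpoint":
        if not censored_left:
            lb = (pos[left - 1] + pos[left]) / 2.0
        if not censored_right:
            rb = (pos[right] + pos[right + 1]) / 2.0
    elif boundary != "match":
        raise ValueError("boundary must be 'match' or 'midpoint'")
    return {"length_bp": float(rb - lb), "left_bp": lb, "right_bp": rb,
            "censored_left": censored_left, "censored_right": censored_right,
            "focal_mismatch": False}


def _pairwise_lengths(alleles, focal_index, positions):
    """Vectorized within-class pairwise tract lengths (match-boundary).

    Returns (lengths_bp, censored) with shape (n, n); the diagonal is the
    full focal-anchored span of a haplotype against itself.
    """
    A = np.asarray(alleles, dtype=np.uint8)
    n, M = A.shape
    lengths = np.zeros((n, n))
    censored = np.zeros((n, n), dtype=bool)
    last = M - 1
    for i in range(n):
        diff = A[i] != A[i:]
        # left: index of last mismatch before focal, else -1
        seg = diff[:, :focal_index]
        anyl = seg.any(axis=1)
        lastmism = np.where(anyl, focal_index - 1 - np.argmax(seg[:, ::-1], axis=1), -1)
        lefts = np.where(anyl, lastmism + 1, 0)
        seg = diff[:, focal_index + 1:]
        anyr = seg.any(axis=1)
        firstmism = np.where(anyr, focal_index + 1 + np.argmax(seg, axis=1), M)
        rights = np.where(anyr, firstmism - 1, last)
        L = positions[rights] - positions[lefts]
        lengths[i, i:] = L
        lengths[i:, i] = L
        c = (~anyl) | (~anyr)
        censored[i, i:] = c
        censored[i:, i] = c
    return lengths, censored


@dataclass
class SharedTractSummary:
    """Per-haplotype median shared-tract lengths within one allele class."""

    class_label: str
    haplotype_indices: np.ndarray
    per_hap_median_bp: np.ndarray
    per_hap_median_censor_free_bp: np.ndarray
    panel_median_bp: float
    panel_mean_bp: float

    @property
    def per_hap_median_mb(self) -> np.ndarray:
        return self.per_hap_median_bp / 1e6

    @property
    def panel_median_mb(self) -> float:
        return self.panel_median_bp / 1e6


def median_shared_tracts(haps: PhasedHaplotypeSet, indices, focal_index: int,
                         class_label: str = "") -> SharedTractSummary:
    """Per-haplotype median pairwise shared-tract length within a class
    (diagonal excluded), plus the panel median and mean across haplotypes.

    Border-censored tracts are included at their observed (edge-truncated)
    lengths; a censor-free alternative that drops fully censored pairs per
    haplotype is reported alongside, since either treatment is defensible.
    """
    idx = np.asarray(indices)
    if len(idx) < 2:
        raise ValueError("class must contain at least 2 haplotypes")
    A = haps.alleles[idx]
    pos = haps.map.position_bp.astype(float)
    lengths, censored = _pairwise_lengths(A, focal_index, pos)
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    med = np.array([np.median(lengths[i][off[i]]) for i in range(n)])
    medcf = np.empty(n)
    for i in range(n):
        keep = off[i] & ~censored[i]
        medcf[i] = np.median(lengths[i][keep]) if keep.any() else np.nan
    return SharedTractSummary(
        class_label=class_label, haplotype_indices=idx,
        per_hap_median_bp=med, per_hap_median_censor_free_bp=medcf,
        panel_median_bp=float(np.median(med)), panel_mean_bp=float(np.mean(med)),
    )


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

@dataclass
class EHHCurve:
    """EHH values at marker positions around the focal marker for one class.

    ``positions_bp``/``ehh`` run left-to-right over all markers; the focal
    marker has EHH 1. ``nhaplo`` is the contributing haplotype count.
    ``border_left/right`` flag whether EHH was still above ``border_cutoff``
    at the region edge.
    """

    positions_bp: np.ndarray
    ehh: np.ndarray
    focal_index: int
    n_haplotypes: int
    nhaplo: np.ndarray
    border_cutoff: float
    class_label: str = ""

    @property
    def offsets_mb(self) -> np.ndarray:
        return (self.positions_bp - self.positions_bp[self.focal_index]) / 1e6

    @property
    def border_left(self) -> bool:
        return bool(self.ehh[0] >= self.border_cutoff)

    @property
    def border_right(self) -> bool:
        return bool(self.ehh[-1] >= self.border_cutoff)


def ehh_curve(haps: PhasedHaplotypeSet, indices, focal_index: int,
              border_cutoff: float = 0.05, class_label: str = "") -> EHHCurve:
    """EHH at every marker for the class given by ``indices``.

    At marker x, haplotypes are grouped by their allele sequence over the
    inclusive span [focal..x]; EHH(x) = sum_g C(n_g, 2) / C(n, 2). Computed
    independently leftward and rightward from the focal marker.
    """
    idx = np.asarray(indices)
    n = len(idx)
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    A = haps.alleles[idx]
    M = A.shape[1]
    denom = n * (n - 1) / 2.0
    ehh = np.empty(M)
    nhap = np.full(M, n)
    ehh[focal_index] = 1.0

    for direction in (+1, -1):
        groups = np.zeros(n, dtype=np.int64)
        rng_idx = (range(focal_index + 1, M) if direction > 0
                   else range(focal_index - 1, -1, -1))
        for j in rng_idx:
            # refine groups by the allele at marker j
            key = groups * 2 + A[:, j]
            _, groups = np.unique(key, return_inverse=True)
            counts = np.bincount(groups)
            ehh[j] = float(np.sum(counts * (counts - 1) / 2.0) / denom)
    return EHHCurve(
        positions_bp=haps.map.position_bp.astype(float).copy(), ehh=ehh,
        focal_index=int(focal_index), n_haplotypes=n, nhaplo=nhap,
        border_cutoff=border_cutoff, class_label=class_label,
    )


def _integrate_side(pos, e, cutoff):
    """Trapezoidal area under EHH from the focal marker outward, truncated at
    the interpolated crossing below ``cutoff``; positions ordered outward."""
    area = 0.0
    for k in range(1, len(pos)):
        p0, p1 = pos[k - 1], pos[k]
        e0, e1 = e[k - 1], e[k]
        if e1 < cutoff <= e0:
            # interpolate the crossing and stop
            if e0 == e1:
                px = p1
            else:
                px = p0 + (p1 - p0) * (e0 - cutoff) / (e0 - e1)
            area += 0.5 * (e0 + cutoff) * abs(px - p0)
            return area
        area += 0.5 * (e0 + e1) * abs(p1 - p0)
    return area


def ies(curve: EHHCurve, cutoff: float | None = None,
        discard_at_border: bool = True) -> dict:
    """Integrated EHH (area in Mb) over both sides of the focal marker.

    With ``discard_at_border`` (the convention used for locus-centered
    scans), the integral is NaN when EHH has not fallen below ``cutoff``
    before either region border.
    """
    cutoff = curve.border_cutoff if cutoff is None else cutoff
    j = curve.focal_index
    pos = curve.positions_bp / 1e6
    right = _integrate_side(pos[j:], curve.ehh[j:], cutoff)
    left = _integrate_side(pos[j::-1], curve.ehh[j::-1], cutoff)
    discarded = bool(curve.ehh[0] >= cutoff or curve.ehh[-1] >= cutoff)
    value = np.nan if (discarded and discard_at_border) else left + right
    return {"ies": float(value), "left": float(left), "right": float(right),
            "border_discarded": discarded}


@dataclass
class IESContrast:
    ies_a: float
    ies_b: float

    @property
    def xpehh(self) -> float:
        return float(np.log(self.ies_a / self.ies_b))


def xpehh_unstandardized(ies_a: float, ies_b: float) -> float:
    """log(iES_a / iES_b); positive when class a carries longer homozygous
    haplotypes. Antisymmetric under swapping the classes."""
    if not (ies_a > 0 and ies_b > 0):
        return float("nan")
    return float(np.log(ies_a / ies_b))


def half_decay_span(curve: EHHCurve, threshold: float = 0.5) -> dict:
    """First positions where EHH drops below ``threshold`` on each side.

    Crossings are linearly interpolated between the flanking markers. A side
    where EHH never crosses before the border is reported as None (censored).
    """
    j = curve.focal_index
    pos = curve.positions_bp

    def crossing(p, e):
        for k in range(1, len(p)):
            if e[k] < threshold:
                if e[k - 1] == e[k] or e[k - 1] < threshold:
                    return float(p[k - 1] if e[k - 1] < threshold else p[k])
                frac = (e[k - 1] - threshold) / (e[k - 1] - e[k])
                return float(p[k - 1] + (p[k] - p[k - 1]) * frac)
        return None

    right = crossing(pos[j:], curve.ehh[j:])
    left = crossing(pos[j::-1], curve.ehh[j::-1])
    span = (right - left) if (left is not None and right is not None) else None
    return {"left_bp": left, "right_bp": right, "span_bp": span}


def downsample_class(indices, n_haplotypes: int, seed: int) -> np.ndarray:
    """Seeded uniform subsample of a haplotype class without replacement."""
    idx = np.asarray(indices)
    if n_haplotypes > len(idx):
        raise ValueError("cannot down-sample beyond the class size")
    if n_haplotypes == len(idx):
        return idx.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=n_haplotypes, replace=False))
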