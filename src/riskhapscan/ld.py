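"""LD profiling of a region relative to the lead marker.

r-squared is the squared Pearson correlation of per-dog dosages (0/1/2),
computed blockwise for large regions; monomorphic markers have undefined
r-squared and are reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDProfile", "ld_to_lead", "ld_bins", "DEFAULT_BINS"]

DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class LDProfile:
    marker_id: np.ndarray
    r2: np.ndarray
    lead_index: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker_id": self.marker_id, "r2": self.r2})


def ld_to_lead(dosages, lead_index: int, marker_ids=None,
               block_size: int = 512) -> LDProfile:
    """r^2 between every marker's dosage and the lead marker's dosage.

    ``dosages`` is dogs x markers. Blockwise evaluation is numerically
    identical to the whole-matrix computation. The lead marker must be
    polymorphic; monomorphic markers yield NaN.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValueError("need a dogs x markers matrix with >= 2 dogs")
    n, m = D.shape
    lead = D[:, lead_index]
    lead_c = lead - lead.mean()
    ss_lead = float(lead_c @ lead_c)
    if ss_lead == 0:
        raise ValueError("lead marker is monomorphic")
    if marker_ids is None:
        marker_ids = np.arange(m)
    r2 = np.empty(m)
    for a in range(0, m, block_size):
        b = min(a + block_size, m)
        block = D[:, a:b] - D[:, a:b].mean(axis=0)
        ss = np.einsum("ij,ij->j", block, block)
        cov = lead_c @ block
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[a:b] = np.where(ss > 0, (cov * cov) / (ss * ss_lead), np.nan)
    r2 = np.clip(r2, 0.0, 1.0, out=r2)
    return LDProfile(np.asarray(marker_ids, dtype=object), r2, int(lead_index))


def ld_bins(profile: LDProfile, breakpoints=DEFAULT_BINS) -> np.ndarray:
    """Half-open LD bins ``[b_i, b_{i+1})`` with the top bin closed at 1.

    Returns string labels per marker (``None`` for missing r^2).
    """
    bp = np.asarray(breakpoints, dtype=float)
    if np.any(np.diff(bp) <= 0) or bp[0] < 0 or bp[-1] > 1:
        raise ValueError("breakpoints must be increasing within [0, 1]")
    labels = np.array(
        [f"[{bp[i]:g},{bp[i + 1]:g})" for i in range(len(bp) - 2)]
        + [f"[{bp[-2]:g},{bp[-1]:g}]"],
        dtype=object,
    )
    out = np.full(len(profile.r2), None, dtype=object)
    ok = ~np.isnan(profile.r2)
    idx = np.searchsorted(bp, profile.r2[ok], side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    out[ok] = labels[idx]
    return out
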