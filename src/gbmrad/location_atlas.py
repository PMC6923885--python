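"""Per-subtype spatial distribution atlases and the 16 location features.

For each subtype an atlas pair (P⁺, P⁻) holds the voxelwise frequency of
tumor-core occupancy among subjects of that subtype (P⁺) versus all other
subjects (P⁻).  A new tumor is scored by the mean and max of each map over
its own tumor-core voxels, combined into four relative values per subtype:

    L1 = mean⁺ − mean⁻        L2 = max⁺ − max⁻
    L3 = (mean⁺ + ε) / (mean⁻ + ε)
    L4 = (max⁺ + ε) / (max⁻ + ε)

with ε = 1e-6 guarding division by zero.  Four subtypes × four values give
16 location features.  Atlases must be built from training subjects only;
the scored subject's mask never contributes to the pair scoring it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SUBTYPES, SubjectRecord

__all__ = [
    "EPSILON",
    "AtlasPair",
    "build_atlas_pair",
    "build_all_atlases",
    "location_features_one",
    "all_location_features",
    "location_feature_names",
]

EPSILON = 1e-6


@dataclass(frozen=True)
class AtlasPair:
    """Tumor-core occupancy frequency maps for one subtype vs the rest."""

    subtype: str
    p_plus: np.ndarray
    p_minus: np.ndarray
    n_plus: int
    n_minus: int

    def __post_init__(self) -> None:
        for name, p in (("p_plus", self.p_plus), ("p_minus", self.p_minus)):
            arr = np.asarray(p)
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(f"{name} frequencies outside [0, 1]")
        if self.p_plus.shape != self.p_minus.shape:
            raise ValueError("atlas maps on different grids")


def build_atlas_pair(records: list[SubjectRecord], subtype: str) -> AtlasPair:
    """Superimpose TC masks of ``subtype`` subjects (P⁺) and of all other
    subjects (P⁻) into occupancy-fraction maps on the common grid."""
    plus = [r for r in records if r.subtype == subtype]
    minus = [r for r in records if r.subtype != subtype]
    if not plus or not minus:
        raise ValueError(
            f"need >= 1 subject in each group for {subtype!r}: "
            f"{len(plus)} positive, {len(minus)} negative"
        )
    shape = plus[0].mask.labels.shape
    for r in plus + minus:
        if r.mask.labels.shape != shape:
            raise ValueError(f"subject {r.subject_id!r} not on the common atlas grid")
    p_plus = np.mean([r.mask.region("TC") for r in plus], axis=0)
    p_minus = np.mean([r.mask.region("TC") for r in minus], axis=0)
    return AtlasPair(
        subtype=subtype,
        p_plus=p_plus,
        p_minus=p_minus,
        n_plus=len(plus),
        n_minus=len(minus),
    )


def build_all_atlases(records: list[SubjectRecord]) -> dict[str, AtlasPair]:
    """One atlas pair per subtype, in canonical order."""
    return {s: build_atlas_pair(records, s) for s in SUBTYPES}


def location_features_one(
    tc_mask: np.ndarray, pair: AtlasPair, eps: float = EPSILON
) -> tuple[float, float, float, float]:
    """(L1, L2, L3, L4) of one subject's TC against one atlas pair.

    Means and maxima are taken over exactly the subject's TC voxels,
    including voxels where an atlas is zero.
    """
    tc = np.asarray(tc_mask, dtype=bool)
    if not tc.any():
        raise ValueError("empty tumor core")
    plus = pair.p_plus[tc]
    minus = pair.p_minus[tc]
    mean_p, mean_m = float(plus.mean()), float(minus.mean())
    max_p, max_m = float(plus.max()), float(minus.max())
    l1 = mean_p - mean_m
    l2 = max_p - max_m
    l3 = (mean_p + eps) / (mean_m + eps)
    l4 = (max_p + eps) / (max_m + eps)
    return l1, l2, l3, l4


def location_feature_names() -> list[str]:
    """The 16 location feature names in canonical subtype × L order."""
    return [f"loc_{s}_L{k}" for s in SUBTYPES for k in (1, 2, 3, 4)]


def all_location_features(
    tc_mask: np.ndarray, pairs: dict[str, AtlasPair]
) -> pd.Series:
    """All 16 location features, keyed by canonical subtype order regardless
    of the order pairs are supplied in."""
    missing = [s for s in SUBTYPES if s not in pairs]
    if missing:
        raise ValueError(f"missing atlas pairs for {missing}")
    values = {}
    for subtype in SUBTYPES:
        l1, l2, l3, l4 = location_features_one(tc_mask, pairs[subtype])
        for k, v in zip((1, 2, 3, 4), (l1, l2, l3, l4)):
            values[f"loc_{subtype}_L{k}"] = v
    return pd.Series(values).reindex(location_feature_names())
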