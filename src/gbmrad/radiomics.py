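"""Radiomic feature extraction over tumor sub-regions and MRI channels.

Feature families: region volumetrics (volumes, brain-volume ratios, surface
areas), first-order intensity moments, 5-bin histogram percentages, GLCM
texture (contrast, correlation, energy, homogeneity; unit radius, 13 unique
3-D directions, pooled symmetric matrix), 2-D morphology on the axial slice
with the largest tumor-core area, minimum distances to the ventricles, and
the tumor core's proportions across the 9-region lobe parcellation.

Conventions (fixed for reproducibility, configurable where noted):

- moments are population moments; kurtosis is non-excess (3 for a Gaussian);
- histogram bin edges are equal-width between the 1st and 99th within-region
  percentiles, computed per subject; out-of-range voxels land in end bins;
- GLCM gray levels default to 32, min–max scaled within the region;
- surface area counts exposed voxel faces; perimeter counts exposed pixel
  edges (both exactly hand-computable, not mesh/Crofton estimates);
- 2-D moment axes treat each pixel as a uniform square patch, so a filled
  w×h rectangle has an exact major/minor axis ratio of w/h.

Empty sub-regions yield 0 for geometric features and NaN (flagged) for
intensity/texture features; flagged values are imputed downstream from
training-fold medians only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.morphology import convex_hull_image

from .io_core import (
    CHANNELS,
    LOBE_NAMES,
    AnatomyContext,
    SegmentationMask,
    SubjectRecord,
)

__all__ = [
    "GLCM_OFFSETS",
    "GlcmSpec",
    "MorphologySlice",
    "region_volumes",
    "surface_area",
    "first_order_stats",
    "histogram_bins",
    "histogram_edges",
    "glcm_matrix",
    "glcm_features",
    "select_morphology_slice",
    "morphology_2d",
    "ventricle_distance",
    "lobe_proportions",
    "extract_features",
    "extract_cohort_features",
    "feature_schema",
]

_REGIONS = ("ED", "ET", "NET")
_MORPH_REGIONS = ("ED", "ET", "NET", "TC")


def _unit_radius_offsets() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique displacement directions at Chebyshev radius 1.

    All 26 neighbors of a voxel, with antiparallel duplicates removed by
    keeping only vectors whose first nonzero component is positive.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                v = (dx, dy, dz)
                if v == (0, 0, 0):
                    continue
                first = next(c for c in v if c != 0)
                if first > 0:
                    offsets.append(v)
    return tuple(offsets)


GLCM_OFFSETS = _unit_radius_offsets()


@dataclass(frozen=True)
class GlcmSpec:
    """Gray-level co-occurrence accumulation parameters."""

    n_gray_levels: int = 32
    offsets: tuple = GLCM_OFFSETS

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if len(self.offsets) != 13:
            raise ValueError("expected the 13 unique unit-radius directions")


@dataclass(frozen=True)
class MorphologySlice:
    """Axial slice chosen for 2-D morphology: argmax of TC pixel count."""

    z_index: int
    region_masks: dict  # region name → 2-D boolean mask


# ---------------------------------------------------------------------------
# Volumetrics


def region_volumes(
    mask: SegmentationMask, brain_mask: np.ndarray | None, spacing
) -> dict[str, float]:
    """Volumes (mm³) of ED/ET/NET/TC/WT and, when a brain mask is given,
    their ratios over the brain volume."""
    voxel = float(np.prod(spacing))
    out = {}
    for region in ("ED", "ET", "NET", "TC", "WT"):
        out[f"volume_{region}"] = float(np.count_nonzero(mask.region(region))) * voxel
    if brain_mask is not None:
        n_brain = int(np.count_nonzero(brain_mask))
        if n_brain == 0:
            raise ValueError("empty brain mask")
        brain_volume = n_brain * voxel
        for region in ("ED", "ET", "NET", "TC", "WT"):
            out[f"ratio_{region}"] = out[f"volume_{region}"] / brain_volume
    return out


def surface_area(region: np.ndarray, spacing) -> float:
    """Exposed-face surface area (mm²) of a binary region.

    Every voxel face adjoining a non-region voxel (or the grid boundary)
    contributes the physical area of that face.  Empty region → 0.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return 0.0
    padded = np.pad(region, 1).astype(np.int8)
    sx, sy, sz = (float(s) for s in spacing)
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    area = 0.0
    for axis in range(3):
        area += np.count_nonzero(np.diff(padded, axis=axis)) * face[axis]
    return float(area)


# ---------------------------------------------------------------------------
# First-order statistics


def first_order_stats(values: np.ndarray) -> dict[str, float]:
    """Population mean/variance/skewness/kurtosis of a 1-D intensity sample.

    Kurtosis is non-excess.  A constant sample gets skewness and kurtosis 0
    by convention (degenerate standardization).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    mean = float(v.mean())
    var = float(v.var())  # population (ddof=0)
    if var == 0.0:
        return {"mean": mean, "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    c = v - mean
    skew = float((c**3).mean() / var**1.5)
    kurt = float((c**4).mean() / var**2)
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}


# ---------------------------------------------------------------------------
# Histogram percentages


def histogram_edges(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width bin edges between the 1st and 99th percentiles."""
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1.0  # degenerate spread: all mass falls in bin 1
    return np.linspace(lo, hi, n_bins + 1)


def histogram_bins(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Percentage of voxels per bin; out-of-range values clamp to end bins.

    Exactly ``len(bin_edges) - 1`` percentages, summing to 100.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    clipped = np.clip(v, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / v.size * 100.0


# ---------------------------------------------------------------------------
# GLCM texture


def _quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.intp)
    return np.minimum(q, n_levels - 1)


def glcm_matrix(image: np.ndarray, region: np.ndarray, spec: GlcmSpec) -> np.ndarray | None:
    """Pooled, symmetrized, normalized co-occurrence matrix over all offsets.

    Pairs are counted only when both voxels lie inside the region.  Returns
    None (missing-feature flag) when fewer than 2 pairs exist.
    """
    region = np.asarray(region, dtype=bool)
    n = spec.n_gray_levels
    quant = np.zeros(image.shape, dtype=np.intp)
    if region.any():
        quant[region] = _quantize(np.asarray(image, dtype=np.float64)[region], n)

    counts = np.zeros((n, n), dtype=np.float64)
    n_pairs = 0
    for off in spec.offsets:
        src = tuple(
            slice(max(0, -o), dim - max(0, o)) for o, dim in zip(off, image.shape)
        )
        dst = tuple(
            slice(max(0, o), dim - max(0, -o)) for o, dim in zip(off, image.shape)
        )
        valid = region[src] & region[dst]
        if not valid.any():
            continue
        a = quant[src][valid]
        b = quant[dst][valid]
        counts += np.bincount(a * n + b, minlength=n * n).reshape(n, n)
        n_pairs += a.size
    if n_pairs < 2:
        return None
    counts += counts.T  # symmetrize
    return counts / counts.sum()


def glcm_features(
    image: np.ndarray, region: np.ndarray, spec: GlcmSpec | None = None
) -> dict[str, float] | None:
    """Haralick contrast, correlation, energy, homogeneity from the pooled
    matrix; a constant region has correlation 1 by convention.  Returns None
    when the region supports fewer than 2 co-occurrence pairs."""
    spec = spec or GlcmSpec()
    p = glcm_matrix(image, region, spec)
    if p is None:
        return None
    n = spec.n_gray_levels
    i = np.arange(n)[:, None].astype(np.float64)
    j = np.arange(n)[None, :].astype(np.float64)
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i == 0.0 or var_j == 0.0:
        correlation = 1.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


# ---------------------------------------------------------------------------
# 2-D morphology


def select_morphology_slice(mask: SegmentationMask) -> MorphologySlice:
    """Axial slice (fixed-z plane) maximizing TC pixel count; ties take the
    smallest z."""
    tc = mask.region("TC")
    per_slice = tc.sum(axis=(0, 1))
    if per_slice.sum() == 0:
        raise ValueError("empty tumor core: no morphology slice")
    z = int(np.argmax(per_slice))  # argmax returns first maximum
    region_masks = {r: mask.region(r)[:, :, z] for r in _MORPH_REGIONS}
    return MorphologySlice(z_index=z, region_masks=region_masks)


def morphology_2d(region: np.ndarray, pixel_spacing) -> dict[str, float]:
    """2-D shape descriptors of a binary pixel region.

    area = pixel count × pixel area; perimeter = exposed pixel-edge length;
    extent = area / bounding-box area; solidity = area / convex-hull area
    (pixelized hull); axis lengths from the second-order central moments of
    the region treated as a union of uniform square patches (full lengths,
    4·√eigenvalue); eccentricity_ratio = major/minor ≥ 1.  A single-pixel
    region takes axes equal to the pixel sides (flagged upstream).
    """
    region = np.asarray(region, dtype=bool)
    px, py = (float(s) for s in pixel_spacing)
    n = int(np.count_nonzero(region))
    if n == 0:
        return {k: 0.0 for k in (
            "area", "perimeter", "extent", "solidity",
            "major_axis", "minor_axis", "eccentricity_ratio",
        )}
    area = n * px * py

    padded = np.pad(region, 1).astype(np.int8)
    perimeter = (
        np.count_nonzero(np.diff(padded, axis=0)) * py
        + np.count_nonzero(np.diff(padded, axis=1)) * px
    )

    rows, cols = np.nonzero(region)
    bbox_area = (np.ptp(rows) + 1) * px * (np.ptp(cols) + 1) * py
    extent = area / bbox_area

    hull = convex_hull_image(region)
    solidity = n / int(np.count_nonzero(hull))

    if n == 1:
        # degenerate single-pixel region: axes = pixel sides, ratio 1
        return {
            "area": float(area),
            "perimeter": float(perimeter),
            "extent": float(extent),
            "solidity": float(solidity),
            "major_axis": float(max(px, py)),
            "minor_axis": float(min(px, py)),
            "eccentricity_ratio": 1.0,
        }
    else:
        x = rows * px
        y = cols * py
        cov = np.cov(np.stack([x, y]), ddof=0)
        cov[0, 0] += px**2 / 12.0  # pixel-as-square patch moments
        cov[1, 1] += py**2 / 12.0
        eigvals = np.sort(np.linalg.eigvalsh(cov))
        major = 4.0 * np.sqrt(eigvals[1])
        minor = 4.0 * np.sqrt(max(eigvals[0], 0.0))
    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "extent": float(extent),
        "solidity": float(solidity),
        "major_axis": float(major),
        "minor_axis": float(minor),
        "eccentricity_ratio": float(major / minor),
    }


# ---------------------------------------------------------------------------
# Location-adjacent scalar features


def ventricle_distance(
    region: np.ndarray, ventricle_mask: np.ndarray, spacing
) -> float | None:
    """Minimum Euclidean distance (mm) between voxel centers of the region
    and the ventricles; 0 when they overlap; None for an empty region."""
    region = np.asarray(region, dtype=bool)
    vent = np.asarray(ventricle_mask, dtype=bool)
    if not vent.any():
        raise ValueError("empty ventricle mask")
    if not region.any():
        return None
    dt = distance_transform_edt(~vent, sampling=spacing)
    return float(dt[region].min())


def lobe_proportions(
    tc_mask: np.ndarray, parcellation: np.ndarray, n_lobes: int = 9
) -> np.ndarray:
    """Fraction of TC voxels per lobe code 1..n_lobes.

    TC voxels outside the parcellation (code 0) are dropped with
    renormalization over in-brain voxels.
    """
    tc = np.asarray(tc_mask, dtype=bool)
    if not tc.any():
        raise ValueError("empty tumor core")
    codes = np.rint(np.asarray(parcellation)).astype(np.int64)[tc]
    in_brain = codes[codes > 0]
    if in_brain.size == 0:
        raise ValueError("tumor core entirely outside parcellation")
    counts = np.bincount(in_brain, minlength=n_lobes + 1)[1 : n_lobes + 1]
    return counts / in_brain.size


# ---------------------------------------------------------------------------
# Assembly


def feature_schema(n_lobes: int = 9) -> list[str]:
    """Deterministic ordered names of all non-location features."""
    names = []
    for region in ("ED", "ET", "NET", "TC", "WT"):
        names.append(f"volume_{region}")
    for region in ("ED", "ET", "NET", "TC", "WT"):
        names.append(f"ratio_{region}")
    for region in ("ED", "ET", "NET", "TC", "WT"):
        names.append(f"surface_{region}")
    for region in _REGIONS:
        for ch in CHANNELS:
            for stat in ("mean", "variance", "skewness", "kurtosis"):
                names.append(f"firstorder_{region}_{ch}_{stat}")
    for region in _REGIONS:
        for ch in CHANNELS:
            for b in range(1, 6):
                names.append(f"histogram_{region}_{ch}_bin{b}")
    for region in _REGIONS:
        for ch in CHANNELS:
            for stat in ("contrast", "correlation", "energy", "homogeneity"):
                names.append(f"glcm_{region}_{ch}_{stat}")
    for region in _MORPH_REGIONS:
        for stat in (
            "area", "perimeter", "extent", "solidity",
            "major_axis", "minor_axis", "eccentricity_ratio",
        ):
            names.append(f"morph2d_{region}_{stat}")
    names += ["ventdist_ED", "ventdist_TC"]
    names += [f"lobe_{name}" for name in LOBE_NAMES[:n_lobes]]
    return names


def extract_features(
    subject: SubjectRecord,
    anatomy: AnatomyContext,
    glcm_spec: GlcmSpec | None = None,
    n_hist_bins: int = 5,
) -> tuple[pd.Series, list[str]]:
    """Extract the full non-location feature vector for one subject.

    Returns (features, flags): ``features`` follows :func:`feature_schema`
    exactly; ``flags`` lists feature names that are missing (NaN) because
    their sub-region was empty or degenerate.
    """
    glcm_spec = glcm_spec or GlcmSpec()
    mask = subject.mask
    spacing = mask.spacing
    brain = anatomy.brain_mask.values.astype(bool)
    flags: list[str] = []
    feats: dict[str, float] = {}

    feats.update(region_volumes(mask, brain, spacing))
    for region in ("ED", "ET", "NET", "TC", "WT"):
        feats[f"surface_{region}"] = surface_area(mask.region(region), spacing)

    for region in _REGIONS:
        rmask = mask.region(region)
        empty = not rmask.any()
        for ch in CHANNELS:
            values = subject.study.channels[ch].values[rmask]
            prefix = f"{region}_{ch}"
            if empty:
                for stat in ("mean", "variance", "skewness", "kurtosis"):
                    feats[f"firstorder_{prefix}_{stat}"] = np.nan
                    flags.append(f"firstorder_{prefix}_{stat}")
                for b in range(1, n_hist_bins + 1):
                    feats[f"histogram_{prefix}_bin{b}"] = np.nan
                    flags.append(f"histogram_{prefix}_bin{b}")
            else:
                feats.update(
                    {f"firstorder_{prefix}_{k}": v
                     for k, v in first_order_stats(values).items()}
                )
                edges = histogram_edges(values, n_hist_bins)
                pct = histogram_bins(values, edges)
                for b in range(1, n_hist_bins + 1):
                    feats[f"histogram_{prefix}_bin{b}"] = float(pct[b - 1])
            tex = None if empty else glcm_features(
                subject.study.channels[ch].values, rmask, glcm_spec
            )
            if tex is None:
                for stat in ("contrast", "correlation", "energy", "homogeneity"):
                    feats[f"glcm_{prefix}_{stat}"] = np.nan
                    flags.append(f"glcm_{prefix}_{stat}")
            else:
                feats.update({f"glcm_{prefix}_{k}": v for k, v in tex.items()})

    mslice = select_morphology_slice(mask)
    pixel_spacing = (spacing[0], spacing[1])
    for region in _MORPH_REGIONS:
        morph = morphology_2d(mslice.region_masks[region], pixel_spacing)
        for stat, value in morph.items():
            feats[f"morph2d_{region}_{stat}"] = value

    vent = anatomy.ventricle_mask.values.astype(bool)
    for region in ("ED", "TC"):
        d = ventricle_distance(mask.region(region), vent, spacing)
        name = f"ventdist_{region}"
        if d is None:
            feats[name] = np.nan
            flags.append(name)
        else:
            feats[name] = d

    props = lobe_proportions(mask.region("TC"), anatomy.lobe_parcellation.values)
    for name, p in zip(LOBE_NAMES, props):
        feats[f"lobe_{name}"] = float(p)

    schema = feature_schema()
    vector = pd.Series({name: feats[name] for name in schema}, name=subject.subject_id)
    return vector, flags


def extract_cohort_features(
    records: list[SubjectRecord],
    anatomy: AnatomyContext,
    glcm_spec: GlcmSpec | None = None,
) -> "pd.DataFrame":
    """Stack per-subject vectors into a subjects × features frame
    (manifest order preserved)."""
    vectors = [extract_features(r, anatomy, glcm_spec)[0] for r in records]
    return pd.DataFrame(vectors)
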