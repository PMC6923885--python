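"""Synthetic labeled cohort generator.

Each subject carries a nested-ellipsoid tumor (NET core, ET shell, ED outer
shell) placed inside a shared ellipsoidal brain mask, with per-(region,
channel) Gaussian intensities.  Class-conditional effects — intensity
multipliers, region size multipliers, axis-ratio (eccentricity) changes, and
placement shifts — inject a known, auditable imaging signature per subtype,
so the downstream extraction/selection/classification stages can be tested
for signal recovery against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (
    CHANNELS,
    LABEL_CODES,
    LOBE_NAMES,
    SUBTYPES,
    AnatomyContext,
    MpMRIStudy,
    SegmentationMask,
    SubjectRecord,
    VolumeGrid,
)

__all__ = [
    "SubtypeEffect",
    "SimulationConfig",
    "default_config",
    "zero_effect_config",
    "make_anatomy",
    "generate_subject",
    "generate_cohort",
    "effect_audit",
]

_TUMOR_REGIONS = ("NET", "ET", "ED")


class NestingError(RuntimeError):
    """Sampled tumor geometry could not satisfy NET ⊂ ET ⊂ ED."""


@dataclass(frozen=True)
class SubtypeEffect:
    """Class-conditional modifiers applied on top of the shared priors.

    intensity
        (region, channel) → multiplicative factor on the region mean.
    size
        region → multiplicative factor on the region's mean semi-axes.
    axis_ratio
        region → desired major/minor axis ratio in the axial plane
        (overrides the config-wide default for that region).
    center_shift_mm
        Mean displacement of the tumor center from the brain center,
        realizing a subtype-specific placement prior.
    """

    intensity: dict = field(default_factory=dict)
    size: dict = field(default_factory=dict)
    axis_ratio: dict = field(default_factory=dict)
    center_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # mean semi-axis (mm) and per-axis sampling sd (mm), per tumor region
    semiaxes_mean: dict = field(
        default_factory=lambda: {"NET": 6.0, "ET": 11.0, "ED": 18.0}
    )
    semiaxes_sd: dict = field(default_factory=lambda: {"NET": 0.8, "ET": 1.2, "ED": 1.8})
    # default major/minor ratio in the axial plane, per region
    axis_ratio: dict = field(default_factory=lambda: {"NET": 1.3, "ET": 1.3, "ED": 1.0})
    # (region, channel) → intensity mean; "BRAIN" covers healthy tissue
    intensity_mean: dict = field(
        default_factory=lambda: {
            ("BRAIN", "T1"): 100.0,
            ("BRAIN", "T1GD"): 100.0,
            ("BRAIN", "T2"): 100.0,
            ("BRAIN", "FLAIR"): 100.0,
            ("NET", "T1"): 80.0,
            ("NET", "T1GD"): 90.0,
            ("NET", "T2"): 140.0,
            ("NET", "FLAIR"): 130.0,
            ("ET", "T1"): 90.0,
            ("ET", "T1GD"): 170.0,
            ("ET", "T2"): 120.0,
            ("ET", "FLAIR"): 120.0,
            ("ED", "T1"): 90.0,
            ("ED", "T1GD"): 95.0,
            ("ED", "T2"): 150.0,
            ("ED", "FLAIR"): 160.0,
        }
    )
    noise_sd: float = 10.0
    center_jitter_mm: float = 4.0
    effects: dict = field(default_factory=dict)  # subtype → SubtypeEffect
    max_retries: int = 10

    def effect(self, subtype: str) -> SubtypeEffect:
        return self.effects.get(subtype, SubtypeEffect())


def default_config(**overrides) -> SimulationConfig:
    """Config whose effects realize the published per-subtype directions.

    Injected signature (relative to the shared baseline):

    - proneural: lower ET signal on T1-Gd; antero-lateral placement prior.
    - neural: higher ED signal on T2-FLAIR; lower NET eccentricity.
    - mesenchymal: lower ED signal on T2-FLAIR and T2; bigger ED/ET (hence
      WT) volume; lower ET eccentricity; higher NET eccentricity.
    - classical: smaller ED (hence smaller ED and WT surface area).

    Effect magnitudes are simulator choices (the source directions carry no
    magnitudes) tuned so the full pipeline separates the classes.
    """
    effects = {
        "proneural": SubtypeEffect(
            intensity={("ET", "T1GD"): 0.70},
            center_shift_mm=(-14.0, -10.0, 0.0),
        ),
        "neural": SubtypeEffect(
            intensity={("ED", "FLAIR"): 1.30},
            axis_ratio={"NET": 1.0},
            center_shift_mm=(14.0, -10.0, 0.0),
        ),
        "mesenchymal": SubtypeEffect(
            intensity={("ED", "FLAIR"): 0.70, ("ED", "T2"): 0.80},
            size={"ED": 1.22, "ET": 1.25},
            axis_ratio={"ET": 1.0, "NET": 1.9},
            center_shift_mm=(-14.0, 10.0, 0.0),
        ),
        "classical": SubtypeEffect(
            size={"ED": 0.75},
            center_shift_mm=(14.0, 10.0, 0.0),
        ),
    }
    return replace(SimulationConfig(effects=effects), **overrides)


def zero_effect_config(**overrides) -> SimulationConfig:
    """Config with no class-conditional effect: all four classes identical."""
    return replace(SimulationConfig(effects={}), **overrides)


# ---------------------------------------------------------------------------
# Anatomy


def _coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    xx, yy, zz = _coords_mm(shape, spacing)
    q = (
        ((xx - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((yy - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((zz - center_mm[2]) / semiaxes_mm[2]) ** 2
    )
    return q <= 1.0


def make_anatomy(config: SimulationConfig) -> AnatomyContext:
    """Brain ellipsoid, two ventricle ellipsoids, and a 3×3 geometric
    parcellation of the brain into the nine named regions."""
    shape, spacing = config.shape, config.spacing
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]
    brain = _ellipsoid(shape, spacing, center, [0.45 * e for e in extent])
    vent_semi = (4.0, 12.0, 10.0)
    vent = _ellipsoid(
        shape, spacing, (center[0] - 8.0, center[1], center[2]), vent_semi
    ) | _ellipsoid(shape, spacing, (center[0] + 8.0, center[1], center[2]), vent_semi)
    vent &= brain

    # 3×3 (x, y) sectors over the full z range; codes 1..9 partition the brain
    xx, yy, _ = _coords_mm(shape, spacing)
    x_bins = np.digitize(xx, [center[0] - extent[0] / 8, center[0] + extent[0] / 8])
    y_bins = np.digitize(yy, [center[1] - extent[1] / 8, center[1] + extent[1] / 8])
    lobes = np.where(brain, 3 * x_bins + y_bins + 1, 0).astype(np.int16)

    return AnatomyContext(
        brain_mask=VolumeGrid(brain.astype(np.uint8), spacing),
        ventricle_mask=VolumeGrid(vent.astype(np.uint8), spacing),
        lobe_parcellation=VolumeGrid(lobes, spacing),
    )


# ---------------------------------------------------------------------------
# Subject generation


def _sample_semiaxes(config: SimulationConfig, effect: SubtypeEffect, rng) -> dict:
    """Sample per-region semi-axes (mm); raises NestingError after retries."""
    for _ in range(config.max_retries):
        axes = {}
        for region in _TUMOR_REGIONS:
            mean = config.semiaxes_mean[region] * effect.size.get(region, 1.0)
            ratio = effect.axis_ratio.get(region, config.axis_ratio[region])
            r = np.sqrt(ratio)
            target = np.array([mean * r, mean / r, mean])
            axes[region] = rng.normal(target, config.semiaxes_sd[region])
        ok = (
            np.all(axes["NET"] > 0.5)
            and np.all(axes["ET"] > axes["NET"] + 0.5)
            and np.all(axes["ED"] > axes["ET"] + 0.5)
        )
        if ok:
            return axes
    raise NestingError(
        "could not sample nested NET ⊂ ET ⊂ ED semi-axes within retry budget"
    )


def generate_subject(
    config: SimulationConfig,
    subtype: str,
    seed,
    anatomy: AnatomyContext | None = None,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Generate one subject; bit-reproducible from (config, subtype, seed)."""
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    if anatomy is None:
        anatomy = make_anatomy(config)
    effect = config.effect(subtype)
    rng = np.random.default_rng(seed)
    shape, spacing = config.shape, config.spacing
    brain = anatomy.brain_mask.values.astype(bool)
    extent = [n * s for n, s in zip(shape, spacing)]
    brain_center = np.array([e / 2 for e in extent])

    axes = _sample_semiaxes(config, effect, rng)
    # placement prior: subtype shift + jitter, center constrained inside brain
    for _ in range(config.max_retries):
        center = brain_center + np.array(effect.center_shift_mm)
        center = center + rng.normal(0.0, config.center_jitter_mm, size=3)
        idx = tuple(int(round(c / s)) for c, s in zip(center, spacing))
        if all(0 <= i < n for i, n in zip(idx, shape)) and brain[idx]:
            break
    else:
        center = brain_center + np.array(effect.center_shift_mm)

    net_full = _ellipsoid(shape, spacing, center, axes["NET"])
    et_full = _ellipsoid(shape, spacing, center, axes["ET"])
    ed_full = _ellipsoid(shape, spacing, center, axes["ED"])
    net = net_full & brain
    et = et_full & ~net_full & brain
    ed = ed_full & ~et_full & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[ed] = LABEL_CODES["ED"]
    labels[net] = LABEL_CODES["NET"]
    labels[et] = LABEL_CODES["ET"]

    region_masks = {"NET": net, "ET": et, "ED": ed}
    channels = {}
    for ch in CHANNELS:
        img = np.zeros(shape, dtype=np.float64)
        img[brain] = config.intensity_mean[("BRAIN", ch)]
        for region in _TUMOR_REGIONS:
            mult = effect.intensity.get((region, ch), 1.0)
            img[region_masks[region]] = config.intensity_mean[(region, ch)] * mult
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=shape)
            img[brain] += noise[brain]
        channels[ch] = VolumeGrid(img, spacing)

    sid = subject_id or f"{subtype}-{int(np.random.default_rng(seed).integers(1 << 31)):010d}"
    return SubjectRecord(
        subject_id=sid,
        study=MpMRIStudy(subject_id=sid, channels=channels),
        mask=SegmentationMask(labels=labels, spacing=spacing),
        subtype=subtype,
    )


def _subject_seed(master_seed: int, index: int):
    # per-subject seed from (master seed, index): insertion-order independent
    return np.random.SeedSequence(entropy=(int(master_seed), int(index)))


def generate_cohort(
    config: SimulationConfig, n_per_class: int, seed: int
) -> tuple[list[SubjectRecord], AnatomyContext]:
    """Generate a balanced labeled cohort sharing one AnatomyContext."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    anatomy = make_anatomy(config)
    records = []
    index = 0
    for subtype in SUBTYPES:
        for i in range(n_per_class):
            sid = f"{subtype}-{i:03d}"
            records.append(
                generate_subject(
                    config,
                    subtype,
                    _subject_seed(seed, index),
                    anatomy=anatomy,
                    subject_id=sid,
                )
            )
            index += 1
    return records, anatomy


# ---------------------------------------------------------------------------
# Ground-truth audit


def _region_mean_intensity(record: SubjectRecord, region: str, channel: str) -> float:
    m = record.mask.region(region)
    return float(record.study.channels[channel].values[m].mean()) if m.any() else np.nan


def _audited_quantities(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(quantity, effect subtype, direction) rows implied by the config."""
    rows = []
    for subtype in SUBTYPES:
        eff = config.effect(subtype)
        for (region, channel), mult in sorted(eff.intensity.items()):
            if mult != 1.0:
                direction = "lower" if mult < 1.0 else "higher"
                rows.append((f"intensity_{region}_{channel}", subtype, direction))
        for region, mult in sorted(eff.size.items()):
            if mult != 1.0:
                direction = "lower" if mult < 1.0 else "higher"
                rows.append((f"volume_{region}", subtype, direction))
                rows.append((f"surface_{region}", subtype, direction))
    return rows


def effect_audit(records: list[SubjectRecord], config: SimulationConfig) -> pd.DataFrame:
    """Realized group means for every injected effect, with recovery flags.

    Returns one row per injected effect (or a single all-null row when the
    config injects nothing), with the four group means, the intended
    direction, and whether the extreme group matches the intended subtype.
    Invariant to the order of ``records``.
    """
    from .radiomics import region_volumes, surface_area

    by_subtype = {
        s: sorted(
            (r for r in records if r.subtype == s), key=lambda r: r.subject_id
        )
        for s in SUBTYPES
    }
    rows = _audited_quantities(config)
    if not rows:
        return pd.DataFrame(
            [{"quantity": "none", "effect_subtype": None, "direction": "null",
              "recovered": True}]
        )

    def quantity_value(record: SubjectRecord, quantity: str) -> float:
        kind, rest = quantity.split("_", 1)
        if kind == "intensity":
            region, channel = rest.rsplit("_", 1)
            return _region_mean_intensity(record, region, channel)
        if kind == "volume":
            vols = region_volumes(record.mask, None, record.mask.spacing)
            return vols[f"volume_{rest}"]
        if kind == "surface":
            return surface_area(record.mask.region(rest), record.mask.spacing)
        raise KeyError(quantity)

    out = []
    for quantity, subtype, direction in rows:
        means = {
            s: float(np.mean([quantity_value(r, quantity) for r in group]))
            for s, group in by_subtype.items()
            if group
        }
        extreme = min(means, key=means.get) if direction == "lower" else max(means, key=means.get)
        out.append(
            {
                "quantity": quantity,
                "effect_subtype": subtype,
                "direction": direction,
                **{f"mean_{s}": means.get(s, np.nan) for s in SUBTYPES},
                "recovered": extreme == subtype,
            }
        )
    return pd.DataFrame(out)


def cohort_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    """Manifest skeleton (paths filled in by the CLI writer)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "subtype": [r.subtype for r in records],
        }
    )
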