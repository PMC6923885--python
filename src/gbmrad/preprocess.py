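"""Intensity histogram matching against a reference subject.

A monotone quantile map carries each channel's within-brain intensity
distribution onto the corresponding channel of a chosen reference subject;
voxels outside the brain mask pass through unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_core import (
    CHANNELS,
    MpMRIStudy,
    RegistrationError,
    SubjectRecord,
    VolumeGrid,
)

__all__ = ["histogram_match", "match_cohort"]


def histogram_match(
    moving: VolumeGrid,
    reference: VolumeGrid,
    brain_mask: np.ndarray,
    n_quantiles: int = 256,
) -> VolumeGrid:
    """Map ``moving``'s within-mask distribution onto ``reference``'s.

    The map is piecewise-linear between ``n_quantiles`` matched quantile
    landmarks (including the 0th and 100th percentiles), hence monotone
    non-decreasing; output values stay within the reference's within-mask
    range.  A constant moving image (zero spread) returns unchanged with a
    warning.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    mov = moving.values[mask]
    ref = reference.values[mask]
    if mov.size == 0 or ref.size == 0:
        raise ValueError("no voxels within mask")
    if np.ptp(mov) == 0:
        warnings.warn("constant moving image: histogram match is the identity")
        return moving
    q = np.linspace(0.0, 1.0, n_quantiles)
    src = np.quantile(mov, q)
    dst = np.quantile(ref, q)
    out = moving.values.astype(np.float64).copy()
    out[mask] = np.interp(mov, src, dst)
    return VolumeGrid(out, moving.spacing)


def match_cohort(
    records: list[SubjectRecord],
    brain_mask: np.ndarray,
    reference_subject_id: str,
    n_quantiles: int = 256,
) -> list[SubjectRecord]:
    """Match every subject's channels to the reference subject's, channel-wise.

    The reference subject is returned unchanged (its quantile map is the
    identity up to interpolation).
    """
    by_id = {r.subject_id: r for r in records}
    if reference_subject_id not in by_id:
        raise KeyError(f"reference subject {reference_subject_id!r} not in cohort")
    reference = by_id[reference_subject_id]
    for ch in CHANNELS:
        if ch not in reference.study.channels:
            raise RegistrationError(f"reference missing channel {ch}")

    out = []
    for record in records:
        matched = {
            ch: histogram_match(
                record.study.channels[ch],
                reference.study.channels[ch],
                brain_mask,
                n_quantiles=n_quantiles,
            )
            for ch in CHANNELS
        }
        out.append(
            SubjectRecord(
                subject_id=record.subject_id,
                study=MpMRIStudy(subject_id=record.subject_id, channels=matched),
                mask=record.mask,
                subtype=record.subtype,
            )
        )
    return out
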