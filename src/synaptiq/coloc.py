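"""Signaling-to-antigen colocalization measures.

Relates a clustered signaling channel (e.g. pCD79, pSyk, pCD19) to the
clustered antigen on the same cell: the signaling-per-antigen intensity
ratio, the masked Manders overlap fraction (intensity-weighted fraction of
the signal channel's clustered fluorescence lying within the reference
channel's mask), and the absolute signal intensity within the reference
features.  Both channels are assumed registered; background subtraction uses
the median intensity outside the signal mask, with negative values clipped
to zero so fractions stay in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import IntensityImage

__all__ = [
    "OverlapResult",
    "signaling_per_ag",
    "manders_fraction",
    "signal_within_reference",
    "overlap_result",
]


@dataclass(frozen=True)
class OverlapResult:
    """Masked-Manders overlap of one signal channel with a reference mask."""

    manders_fraction: float
    signal_total: float
    signal_in_reference: float


def signaling_per_ag(signal_total: float, ag_total: float) -> float:
    """Clustered signaling intensity normalized to clustered antigen.

    Raises
    ------
    ValueError
        If ``ag_total`` is not positive (such cells are excluded upstream).
    """
    if not ag_total > 0:
        raise ValueError("ag_total must be positive; cell excluded")
    return signal_total / ag_total


def _masked_signal(
    signal: IntensityImage, signal_mask: np.ndarray
) -> np.ndarray:
    signal_mask = np.asarray(signal_mask, dtype=bool)
    if signal_mask.shape != signal.shape:
        raise ValueError("signal_mask shape must match signal image")
    if not signal_mask.any():
        raise ValueError("signal_mask is empty")
    background = float(np.median(signal.pixels[~signal_mask]))
    corrected = signal.pixels - background
    corrected[~signal_mask] = 0.0
    np.clip(corrected, 0.0, None, out=corrected)
    return corrected


def manders_fraction(
    signal: IntensityImage, signal_mask: np.ndarray, reference_mask: np.ndarray
) -> float:
    """Fraction of clustered signal fluorescence inside the reference mask.

    The signal image is background-subtracted (median outside its own mask),
    zeroed outside its mask and negative-clipped; the returned value is the
    masked Manders coefficient M = sum(signal in signal_mask ∩ reference) /
    sum(signal in signal_mask), in [0, 1].
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != signal.shape:
        raise ValueError("reference_mask shape must match signal image")
    corrected = _masked_signal(signal, signal_mask)
    denom = corrected.sum()
    if denom <= 0:
        raise ValueError("zero clustered signal; Manders fraction undefined")
    return float(corrected[reference_mask].sum() / denom)


def signal_within_reference(
    signal: IntensityImage, signal_mask: np.ndarray, reference_mask: np.ndarray
) -> float:
    """Absolute clustered signal intensity inside the reference mask (the
    numerator of :func:`manders_fraction`, in intensity units)."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != signal.shape:
        raise ValueError("reference_mask shape must match signal image")
    corrected = _masked_signal(signal, signal_mask)
    return float(corrected[reference_mask].sum())


def overlap_result(
    signal: IntensityImage, signal_mask: np.ndarray, reference_mask: np.ndarray
) -> OverlapResult:
    """All three overlap quantities in one pass."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != signal.shape:
        raise ValueError("reference_mask shape must match signal image")
    corrected = _masked_signal(signal, signal_mask)
    total = float(corrected.sum())
    if total <= 0:
        raise ValueError("zero clustered signal; overlap undefined")
    inside = float(corrected[reference_mask].sum())
    return OverlapResult(inside / total, total, inside)
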