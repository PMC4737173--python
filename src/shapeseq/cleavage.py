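"""Cleavage QC: dual-channel spike detection in raw fragment distributions.

A genuine chemical modification produces excess stops in the (+) channel
only; an RNase cleavage event truncates the RNA itself and therefore
produces a coincident spike in *both* the (+) and (-) fragment
distributions.  Sites are flagged with a robust z-score (median/MAD,
which tolerates the heavy-tailed stop distributions genuine reactivity
creates) combined with a minimum read-fraction requirement, and a call
is emitted only when both channels pass both criteria.  Full-length
counts are excluded from the background statistics — they are a
structurally different outcome, not a stop site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

from .counts import FragmentCounts


@dataclass(frozen=True)
class SpikeCall:
    """A candidate double-stranded RNase cleavage site."""

    target: str
    position: int  # 1-based
    z_plus: float
    z_minus: float
    fraction_plus: float
    fraction_minus: float


def _robust_z_and_fraction(counts: FragmentCounts) -> tuple[np.ndarray, np.ndarray]:
    X = counts.X.astype(float)
    med = np.median(X)
    scale = median_abs_deviation(X, scale="normal")
    # a degenerate (near-constant) background still deserves a finite z;
    # one count is the smallest meaningful deviation unit
    scale = max(scale, 1.0)
    z = (X - med) / scale
    total = counts.total
    fraction = X / total if total else np.zeros_like(X)
    return z, fraction


def detect_spikes(
    plus: FragmentCounts,
    minus: FragmentCounts,
    z_threshold: float = 5.0,
    min_fraction: float = 0.05,
) -> list[SpikeCall]:
    """Coincident-spike calls over a target's probed region.

    A position is called when its robust z-score is at least
    ``z_threshold`` *and* it carries at least ``min_fraction`` of the
    channel's reads, in both channels.  Calls are sorted by position.
    """
    if plus.n != minus.n:
        raise ValueError("channel count vectors must have equal length")
    if plus.total == 0 or minus.total == 0:
        raise ValueError("spike detection needs reads in both channels")
    z_p, f_p = _robust_z_and_fraction(plus)
    z_m, f_m = _robust_z_and_fraction(minus)
    hits = (
        (z_p >= z_threshold)
        & (z_m >= z_threshold)
        & (f_p >= min_fraction)
        & (f_m >= min_fraction)
    )
    return [
        SpikeCall(
            target=plus.target,
            position=int(k + 1),
            z_plus=float(z_p[k]),
            z_minus=float(z_m[k]),
            fraction_plus=float(f_p[k]),
            fraction_minus=float(f_m[k]),
        )
        for k in np.flatnonzero(hits)
    ]


def spike_positions(calls: list[SpikeCall]) -> set[int]:
    """Positions to annotate as cleavage-confounded in reactivity output."""
    return {c.position for c in calls}
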