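"""Neural encoding layer: motion retrieval and phase coding.

Grayscale video is turned into ON/OFF spike trains in three steps:

1. *Frame differencing* — the luminance change ``P(x, y, f) = L(f) - L(f-1)``
   carries all motion information; static scenes encode to silence.
2. *Half-wave rectification* — brightness increments flow into the ON channel
   and decrements into the OFF channel.  A small residual coefficient
   ``alpha1`` lets a fraction of the previous frame's channel activity leak
   into the current frame, mimicking temporal persistence of the
   photoreceptor response.
3. *Phase coding with weighted spikes* — each channel value is normalised to
   [0, 1) and expanded into an 8-bit binary spike pattern, one bit per phase
   tick.  Phase ``i`` of a period carries weight ``2**-(i+1)``, so the most
   significant information travels in the earliest spikes of every period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHASES_PER_FRAME",
    "INTENSITY_SCALE",
    "MotionChannels",
    "phase_weight",
    "frame_difference",
    "split_on_off",
    "phase_encode",
    "phase_decode",
]

logger = logging.getLogger(__name__)

#: Number of phase ticks per encoded video frame.
PHASES_PER_FRAME = 8

#: Full-scale normalisation constant for 8-bit luminance changes.
INTENSITY_SCALE = 256.0


def phase_weight(t):
    """Weight ``omega(t) = 2**-(1 + t mod 8)`` of phase tick ``t``.

    The weight is strictly decreasing within each 8-phase period, from
    ``2**-1`` at the first phase down to ``2**-8`` at the last, and is
    periodic across periods.  Accepts scalars or arrays of non-negative
    integers.
    """
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("phase time must be non-negative")
    w = np.ldexp(1.0, -(1 + np.mod(t, PHASES_PER_FRAME)).astype(int))
    return float(w) if w.ndim == 0 else w


def frame_difference(frames):
    """Per-frame luminance change ``P`` of a frame stack.

    Parameters
    ----------
    frames : (F, H, W) array-like
        Grayscale intensities.  At least two frames are required.

    Returns
    -------
    (F, H, W) float64 array; ``P[0]`` is identically zero (no predecessor).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least two frames")
    p = np.zeros_like(frames)
    p[1:] = frames[1:] - frames[:-1]
    return p


@dataclass
class MotionChannels:
    """Running state of the ON/OFF half-wave rectifiers.

    ``p_on``/``p_off`` hold the rectified channel fields of the most recent
    frame, including the ``alpha1`` residual of earlier frames.  Both are
    non-negative by construction; with ``alpha1 = 0`` at most one of them is
    nonzero at any pixel.
    """

    alpha1: float = 0.1
    p_on: np.ndarray | None = field(default=None, repr=False)
    p_off: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.alpha1 < 1.0:
            raise ValueError("alpha1 must lie in [0, 1)")

    def step(self, p):
        """Feed one signed change field ``P`` and return ``(p_on, p_off)``."""
        p = np.asarray(p, dtype=np.float64)
        if self.p_on is None:
            self.p_on = np.zeros_like(p)
            self.p_off = np.zeros_like(p)
        self.p_on = np.maximum(p, 0.0) + self.alpha1 * self.p_on
        self.p_off = np.maximum(-p, 0.0) + self.alpha1 * self.p_off
        return self.p_on, self.p_off


def split_on_off(p_fields, alpha1=0.1):
    """Rectify a stack of change fields into ON/OFF channel stacks.

    Implements the recursions ``P_on(f) = [P(f)]+ + alpha1 * P_on(f-1)`` and
    ``P_off(f) = [P(f)]- + alpha1 * P_off(f-1)`` with zero state before the
    first field.
    """
    chans = MotionChannels(alpha1=alpha1)
    on, off = [], []
    for p in np.asarray(p_fields, dtype=np.float64):
        a, b = chans.step(p)
        on.append(a.copy())
        off.append(b.copy())
    return np.stack(on), np.stack(off)


def phase_encode(channel_field, scale=INTENSITY_SCALE):
    """Expand one channel field into its 8 binary phase slices.

    The field is normalised by ``scale`` and quantised to 8 fixed-point
    bits, most significant bit first: phase ``i`` carries
    ``floor(v * 2**(i+1)) mod 2``.  Values at or above ``scale`` (possible
    after residual accumulation) are clipped to the largest representable
    code; the number of clipped pixels is logged.

    Returns an ``(8, H, W)`` uint8 array of 0/1 spikes.
    """
    v = np.asarray(channel_field, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("channel fields must be non-negative")
    q = np.floor(v / scale * 256.0)
    n_clip = int(np.count_nonzero(q > 255))
    if n_clip:
        logger.warning("phase_encode: clipped %d saturated pixels", n_clip)
    q = np.minimum(q, 255).astype(np.uint8)
    shifts = np.arange(PHASES_PER_FRAME - 1, -1, -1, dtype=np.uint8)
    bits = (q[None, ...] >> shifts[:, None, None]) & 1
    return bits.astype(np.uint8)


def phase_decode(bits):
    """Inverse of :func:`phase_encode` up to quantisation.

    Sums the phase weights of the set bits; the result equals the normalised
    channel value to within ``2**-8``.
    """
    bits = np.asarray(bits, dtype=np.float64)
    w = phase_weight(np.arange(PHASES_PER_FRAME))
    return np.tensordot(w, bits, axes=(0, 0))
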