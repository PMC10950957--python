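"""Spiking interaction layer: delayed-inhibition competition at S-cells.

Grid spikes generate two post-synaptic currents per polarity channel: a
prompt excitatory current (EPSC) spread by a small 3x3 Gaussian kernel, and
an inhibitory current (IPSC) built from spikes ``epsilon`` phase ticks in
the past, spread by a wider 9x9 kernel.  Because the phase weight
``omega(t)`` halves at every tick within a period, a delayed spike carries
``2**epsilon`` times the weight of a prompt one — the temporal competition
that, combined with the spatial kernels, makes expanding edges the only
stimuli that consistently escape inhibition.

The net current ``G = E - I`` (signed) charges one summation S-cell per
grid location; S-cells are LIF units whose threshold and reset scale with
``omega(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .encoding import PHASES_PER_FRAME, phase_weight

__all__ = [
    "KernelSet",
    "DelayBuffer",
    "make_kernels",
    "epsc",
    "ipsc",
    "summation",
    "s_cell_update",
]

MAX_DELAY = PHASES_PER_FRAME  # largest investigated phase delay


def _gaussian_kernel(size, sigma, normalize=True):
    """Centered Gaussian kernel; ``sigma`` is in units of the half-support.

    Expressing sigma relative to the kernel's own half-width keeps the three
    network kernels on one convention: the 3x3 excitatory kernel has an
    effective spread of one cell, the 9x9 inhibitory kernel of two cells
    (wider than the excitation, as the competition requires), and the
    grid-sized readout map covers the whole field with a central emphasis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    s = sigma * half if half > 0 else sigma
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * s**2))
    return g / g.sum() if normalize else g


@dataclass(frozen=True)
class KernelSet:
    """The three Gaussian connection kernels of the network.

    ``w1`` (3x3) spreads prompt excitation, ``w2`` (9x9) spreads delayed
    inhibition, and ``w3`` (grid-sized) is the full-connection weight map
    from S-cells onto the polarity readout neurons.  All kernels are
    reflection-symmetric; by default each is normalised to unit sum so that
    currents stay bounded by ``omega(t) * rho``.
    """

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray


def make_kernels(dl, sigma1=1.0, sigma2=0.5, sigma3=1.0, normalize=True) -> KernelSet:
    """Build the kernel set for a ``dl x dl`` grid.

    All sigmas are in units of the respective kernel's half-support (see
    :func:`_gaussian_kernel`).  ``normalize`` controls whether the local
    ``w1``/``w2`` kernels are scaled to unit sum or keep absolute synaptic
    gains (peak 1); the default network runs with absolute gains so that
    temporally aligned inhibition can fully cancel excitation.  The global
    readout map ``w3`` is always unit-sum: it is a weight distribution over
    the population, not a synaptic gain.
    """
    return KernelSet(
        w1=_gaussian_kernel(3, sigma1, normalize),
        w2=_gaussian_kernel(9, sigma2, normalize),
        w3=_gaussian_kernel(dl, sigma3, True),
    )


class DelayBuffer:
    """Ring buffer holding one frame (``MAX_DELAY`` phases) of grid fields.

    Phases before the start of the clip read as all-zero fields, so delayed
    currents are identically zero for ``t < epsilon``.  With the standard
    one-frame history, a delay of a full period reads the slot the current
    phase has just rewritten: inhibition delayed by 8 therefore coincides
    with the excitation exactly as a delay of 0 does, which is why the two
    extreme delays behave identically (both abolish every response).  Pass
    ``depth=MAX_DELAY + 1`` for a buffer that serves a true one-frame lag.
    """

    def __init__(self, shape, depth=MAX_DELAY):
        self._buf = np.zeros((depth,) + tuple(shape), dtype=np.uint8)
        self._depth = depth
        self._t = -1

    def push(self, spikes, t):
        if t != self._t + 1:
            raise ValueError("delay buffer must be fed consecutive phases")
        self._t = t
        self._buf[t % self._depth] = spikes

    def delayed(self, t, epsilon):
        """Field at phase ``t - epsilon`` (zeros if that precedes the clip)."""
        if epsilon == 0:
            src = t
        else:
            src = t - epsilon
        if src < 0 or src > self._t:
            return np.zeros_like(self._buf[0])
        return self._buf[src % self._depth]


def epsc(grid_spikes, w1, t, rho=0.9):
    """Prompt excitatory current ``E = omega(t) * (S * w1) * rho``.

    The 3x3 neighbourhood sum is zero-padded at the borders.
    """
    s = np.asarray(grid_spikes, dtype=np.float64)
    return phase_weight(t) * ndimage.convolve(s, w1, mode="constant") * rho


def ipsc(delayed_spikes, w2, t, rho=0.9, epsilon=2):
    """Delayed inhibitory current ``I = omega(t - eps) * (S(t-eps) * w2) * rho``.

    ``delayed_spikes`` is the grid field from ``epsilon`` ticks ago (the
    caller's history buffer); the current is identically zero while
    ``t < epsilon``.  Delays outside the investigated range [0, 8] are
    rejected.
    """
    if not 0 <= epsilon <= MAX_DELAY:
        raise ValueError(f"phase delay must lie in [0, {MAX_DELAY}]")
    s = np.asarray(delayed_spikes, dtype=np.float64)
    if t < epsilon:
        return np.zeros_like(s)
    return phase_weight(t - epsilon) * ndimage.convolve(s, w2, mode="constant") * rho


def summation(e_field, i_field):
    """Net current ``G = E - I`` at the summation sub-layer (may be negative)."""
    e = np.asarray(e_field, dtype=np.float64)
    i = np.asarray(i_field, dtype=np.float64)
    if e.shape != i.shape:
        raise ValueError("EPSC and IPSC shapes differ")
    return e - i


def s_cell_update(g_field, state, t):
    """One phase tick of the S-cell population.

    ``state`` is a :class:`~spikeloom.eccentric.LIFArrayState` with one unit
    per grid location; firing follows the omega-scaled threshold contract.
    Returns a binary field shaped like ``g_field``.
    """
    g = np.asarray(g_field, dtype=np.float64)
    return state.step_scaled(g.ravel(), t).reshape(g.shape)
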