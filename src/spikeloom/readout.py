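"""Readout: feed-forward inhibition, polarity LIF neurons, output neuron.

The population firing rate of the (delayed) grid field gates each polarity
channel: when a large fraction of the visual field is active inside a tiny
time window — a whole-field luminance event rather than a localised looming
edge — the channel's input current is blocked outright (feed-forward
inhibition, FFI).  Ungated S-cell spikes are pooled through the global
Gaussian weight map ``w3`` into one ON-type and one OFF-type LIF neuron,
whose spikes are linearly mixed (coefficients ``theta1``, ``theta2``) at the
single output neuron.  With equal mixing the detector fires for both bright
and dark looming objects (LGMD1-like); biasing the OFF channel yields
dark-looming selectivity (LGMD2-like).
"""

from __future__ import annotations

import numpy as np

from .encoding import phase_weight

__all__ = ["ffi_rate", "gate_and_pool", "channel_lif", "output_neuron"]


def ffi_rate(delayed_spikes, t, epsilon=2):
    """Weighted population firing rate of the delayed grid field.

    ``F(t) = omega(t - epsilon) * (active units) / units``; zero while
    ``t < epsilon``.  Bounded by ``omega(t - epsilon)``.
    """
    if t < epsilon:
        return 0.0
    s = np.asarray(delayed_spikes)
    return float(phase_weight(t - epsilon) * np.count_nonzero(s) / s.size)


def gate_and_pool(s_cell_spikes, w3, f_rate, s_th=0.1, t=0, rho=0.9):
    """FFI-gated channel input current.

    If the population rate reaches the gate threshold (``f_rate >= s_th``,
    inclusive) the channel receives no input this phase; otherwise the
    S-cell spikes are pooled through the full-connection map ``w3``:
    ``I = omega(t) * sum(S * w3) * rho``.
    """
    if f_rate >= s_th:
        return 0.0
    s = np.asarray(s_cell_spikes, dtype=np.float64)
    if s.shape != np.shape(w3):
        raise ValueError("S-cell field and w3 shapes differ")
    return float(phase_weight(t) * np.vdot(s, w3) * rho)


def channel_lif(current, state, t):
    """One tick of a polarity (ON- or OFF-type) LIF neuron.

    ``state`` is a 1-unit :class:`~spikeloom.eccentric.LIFArrayState`;
    returns the binary spike.
    """
    return int(state.step_scaled(np.array([current]), t)[0])


def output_neuron(s_bar_on, s_bar_off, state, t, theta1=0.5, theta2=0.5):
    """Combine polarity spikes and tick the single output neuron.

    ``I(t) = omega(t) * (theta1 * S_on + theta2 * S_off)`` feeds a final
    omega-scaled LIF unit; returns its binary spike.
    """
    if theta1 < 0 or theta2 < 0:
        raise ValueError("mixing coefficients must be non-negative")
    current = phase_weight(t) * (theta1 * s_bar_on + theta2 * s_bar_off)
    return int(state.step_scaled(np.array([current]), t)[0])
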