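"""EPSC/IPSC generation, delay buffering and S-cell competition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeloom.eccentric import LIFArrayState
from spikeloom.encoding import phase_weight
from spikeloom.interaction import (
    DelayBuffer,
    epsc,
    ipsc,
    make_kernels,
    s_cell_update,
    summation,
)


@pytest.fixture(scope="module")
def kernels():
    return make_kernels(5, normalize=True)


class TestKernels:
    def test_unit_sum_when_normalised(self, kernels):
        for w in (kernels.w1, kernels.w2, kernels.w3):
            assert w.sum() == pytest.approx(1.0)

    def test_reflection_symmetric_with_central_peak(self, kernels):
        for w in (kernels.w1, kernels.w2, kernels.w3):
            assert np.allclose(w, w[::-1, ::-1])
            assert w.max() == w[w.shape[0] // 2, w.shape[1] // 2]

    def test_flat_limit_for_large_sigma(self):
        ks = make_kernels(5, sigma1=1e3, normalize=True)
        assert np.allclose(ks.w1, 1.0 / 9, atol=1e-5)

    def test_absolute_gain_mode_keeps_unit_peak(self):
        ks = make_kernels(5, normalize=False)
        assert ks.w1.max() == 1.0 and ks.w2.max() == 1.0
        assert ks.w3.sum() == pytest.approx(1.0)  # readout map stays a weight map

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_kernels(5, sigma1=0.0)


class TestCurrents:
    def test_silent_grid_produces_no_current(self, kernels):
        z = np.zeros((5, 5))
        assert not epsc(z, kernels.w1, t=3).any()
        assert not ipsc(z, kernels.w2, t=5).any()

    def test_epsc_interior_value_for_full_activity(self, kernels):
        # unit-sum kernel, all units active, t=0: E = omega(0) * 1 * rho = 0.45
        e = epsc(np.ones((5, 5)), kernels.w1, t=0, rho=0.9)
        assert e[2, 2] == pytest.approx(0.45)

    def test_epsc_single_spike_stamps_kernel(self, kernels):
        s = np.zeros((5, 5))
        s[2, 2] = 1
        e = epsc(s, kernels.w1, t=0, rho=0.9)
        assert np.allclose(e[1:4, 1:4], 0.45 * kernels.w1)

    def test_ipsc_zero_before_delay_elapses(self, kernels):
        i = ipsc(np.ones((5, 5)), kernels.w2, t=1, epsilon=2)
        assert not i.any()

    def test_ipsc_interior_value_uses_delayed_weight(self, kernels):
        # at t=6 with epsilon=2 the delayed weight is omega(4) = 2**-5; the
        # grid must be large enough that the 9x9 support is not clipped
        i = ipsc(np.ones((20, 20)), kernels.w2, t=6, rho=0.9, epsilon=2)
        assert i[10, 10] == pytest.approx(phase_weight(4) * 0.9)

    def test_delay_out_of_range_rejected(self, kernels):
        with pytest.raises(ValueError):
            ipsc(np.zeros((5, 5)), kernels.w2, t=0, epsilon=9)
        with pytest.raises(ValueError):
            ipsc(np.zeros((5, 5)), kernels.w2, t=0, epsilon=-1)

    def test_summation_is_signed_difference(self):
        e = np.full((3, 3), 0.45)
        i = np.full((3, 3), 0.1)
        g = summation(e, i)
        assert np.allclose(g, 0.35)
        assert np.allclose(summation(e, e), 0.0)
        assert np.allclose(summation(e, np.zeros((3, 3))), e)

    def test_brute_force_oracle_small_grid(self, kernels):
        # exact quadruple-loop evaluation of the convolution sums on a 5x5
        # grid over 3 phases, zero padding at the borders
        rng = np.random.default_rng(11)
        spikes = rng.integers(0, 2, (3, 5, 5)).astype(float)
        rho, eps = 0.9, 2
        for t in range(3):
            e = epsc(spikes[t], kernels.w1, t, rho)
            delayed = spikes[t - eps] if t - eps >= 0 else np.zeros((5, 5))
            i_f = ipsc(delayed, kernels.w2, t, rho, eps)
            for y in range(5):
                for x in range(5):
                    acc_e = 0.0
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < 5 and 0 <= xx < 5:
                                acc_e += spikes[t, yy, xx] * kernels.w1[1 + dy, 1 + dx]
                    assert e[y, x] == pytest.approx(
                        phase_weight(t) * acc_e * rho
                    )
                    acc_i = 0.0
                    if t >= eps:
                        for dy in range(-4, 5):
                            for dx in range(-4, 5):
                                yy, xx = y + dy, x + dx
                                if 0 <= yy < 5 and 0 <= xx < 5:
                                    acc_i += (
                                        spikes[t - eps, yy, xx]
                                        * kernels.w2[4 + dy, 4 + dx]
                                    )
                        assert i_f[y, x] == pytest.approx(
                            phase_weight(t - eps) * acc_i * rho
                        )
                    else:
                        assert i_f[y, x] == 0.0


class TestDelayBuffer:
    def test_history_shift_contract(self):
        rng = np.random.default_rng(3)
        fields = rng.integers(0, 2, (12, 4, 4)).astype(np.uint8)
        buf = DelayBuffer((4, 4))
        for t in range(12):
            buf.push(fields[t], t)
            for eps in (0, 1, 2, 7):
                want = fields[t - eps] if t - eps >= 0 else np.zeros((4, 4))
                assert np.array_equal(buf.delayed(t, eps), want)

    def test_full_period_delay_coincides_with_present(self):
        # a one-frame buffer serves delay 8 from the slot the current phase
        # just rewrote, so the extreme delays 0 and 8 read the same field
        rng = np.random.default_rng(8)
        fields = rng.integers(0, 2, (10, 3, 3)).astype(np.uint8)
        buf = DelayBuffer((3, 3))
        for t in range(10):
            buf.push(fields[t], t)
            if t >= 8:
                assert np.array_equal(buf.delayed(t, 8), buf.delayed(t, 0))

    def test_non_consecutive_push_rejected(self):
        buf = DelayBuffer((2, 2))
        buf.push(np.zeros((2, 2)), 0)
        with pytest.raises(ValueError):
            buf.push(np.zeros((2, 2)), 2)

    @given(st.integers(min_value=0, max_value=6))
    @settings(max_examples=7, deadline=None, derandomize=True)
    def test_shifting_input_shifts_output(self, shift):
        # feeding the same spike history `shift` phases later reproduces the
        # same delayed reads, shifted — linearity of the buffer
        rng = np.random.default_rng(4)
        fields = rng.integers(0, 2, (6, 3, 3)).astype(np.uint8)
        a, b = DelayBuffer((3, 3)), DelayBuffer((3, 3))
        for t in range(shift):
            b.push(np.zeros((3, 3), dtype=np.uint8), t)
        for t in range(6):
            a.push(fields[t], t)
            b.push(fields[t], t + shift)
            assert np.array_equal(a.delayed(t, 2), b.delayed(t + shift, 2))


class TestSCells:
    def test_subthreshold_current_accumulates(self):
        state = LIFArrayState(n=1)
        g = np.array([[0.1]])
        assert s_cell_update(g, state, 0)[0, 0] == 0
        assert state.membrane[0] == pytest.approx(0.1)

    def test_matched_current_fires_at_period_start(self):
        # sustained G = 0.45 equals omega(0)*rho at phase 0: immediate spike
        state = LIFArrayState(n=1)
        assert s_cell_update(np.array([[0.45]]), state, 0)[0, 0] == 1

    def test_inhibition_never_fires_nor_hyperpolarises(self):
        state = LIFArrayState(n=1)
        for t in range(8):
            assert s_cell_update(np.array([[-1.0]]), state, t)[0, 0] == 0
        assert state.membrane[0] == 0.0
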