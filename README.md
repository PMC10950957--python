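# spikeloom

A feed-forward spiking neural network for **looming perception** — detecting
objects that approach on a collision course — from ordinary grayscale video.
It is aimed at researchers in bio-inspired vision and neuromorphic collision
avoidance who want a frame-camera-compatible spiking model of the
LGMD-style looming detectors found in locusts and of the foveated sampling
found in mammalian retinas.

## The model

Video frames `L(x, y, f)` pass through five stages, all spiking:

1. **ON/OFF motion retrieval.** The luminance change
   `P = L(f) − L(f−1)` is half-wave rectified into parallel channels,
   `P_on = [P]⁺ + α₁ P_on(f−1)` and `P_off = [P]⁻ + α₁ P_off(f−1)`,
   with a small residual coefficient α₁ = 0.1 carrying a trace of earlier
   motion.
2. **Phase coding with weighted spikes.** Each channel value, normalised to
   [0, 1), becomes an 8-bit binary spike pattern: one phase tick per bit,
   most significant bit first, phase *i* carrying weight
   `ω = 2^−(i+1)`. Early spikes matter most; a frame becomes 8 ticks.
3. **Eccentric down-sampling (EC).** A foveated layout of square
   receptive-field (RF) rings — 10-px RFs at the periphery shrinking
   linearly to single pixels in the fovea — pools pixel spikes through one
   leaky integrate-and-fire (LIF) neuron per RF, then onto a 58×58 output
   grid delineated by the ring corners. Peripheral RFs need more coincident
   input to fire; the fovea responds at full resolution.
4. **Delayed-inhibition competition.** Grid spikes generate a prompt
   excitatory current (3×3 Gaussian spread) and an inhibitory current from
   spikes ε = 2 ticks in the past (9×9 spread, wider than the
   excitation). Because ω halves every tick, the delayed inhibition arrives
   with 2^ε times the weight of the excitation it competes with at the
   summation (S) cells. With ε = 0 — or a full 8-tick period, which
   coincides with the present phase again — inhibition cancels excitation
   exactly and the network falls silent.
5. **Gated readout.** A feed-forward inhibition (FFI) gate blocks a
   channel whenever the delayed population firing rate exceeds
   `S_th = 0.1` (whole-field events such as flashes); surviving S-cell
   spikes are pooled through a global Gaussian weight map into one ON-type
   and one OFF-type LIF neuron, mixed as `θ₁·S̄_on + θ₂·S̄_off` at the
   single output neuron. Equal mixing responds to both bright and dark
   objects (LGMD1-like); weighting OFF more (θ = 0.3/0.7) biases the
   detector toward dark objects (LGMD2-like).

No learning is involved; every parameter is fixed in `ModelConfig`.

## Worked example

```python
import spikeloom as sl

config = sl.ModelConfig()                      # reference parameters
spec   = sl.standard_suite()["looming_dark_hi"]  # dark square, 10→80 px, 90 frames
trace  = sl.run_model(config, sl.make_stimulus(spec))
print(sl.summarize(trace))
```

prints (abridged):

```
{
  "detected": true,
  "n_phases": 712,
  "first_output_spike": 31,
  "channel_spike_counts": {"on": 0, "off": 66},
  "s_cell_spike_counts": {"on": 0, "off": 47459}
}
```

A dark object approaching on a bright background darkens pixels, so all
activity runs through the OFF channel; 89 encoded frames make 712 phase
ticks; the output neuron first fires at tick 31 (during the fourth video
frame) and the clip is scored as a detection. Setting
`epsilon=0` in the config silences the network completely — the
phase-delayed competition, not raw motion energy, drives the response.

The same pipeline is available from the shell:

```bash
spikeloom gen clips/                    # write the synthetic stimulus suite
spikeloom run looming_dark_hi           # run a suite member, print a summary
spikeloom sweep-delay --stimulus looming_dark_hi --stimulus receding_dark_hi
spikeloom ablate --stimulus looming_dark_hi
spikeloom raster looming_dark_hi s_cell events.csv
```

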