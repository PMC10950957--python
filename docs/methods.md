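# Methods

This note documents the modelling conventions behind `spikeloom`: the
network's assumptions, the parameters that matter, the geometry and
numerical choices that were genuinely open, and what the synthetic-stimulus
suite can and cannot establish.

## Network model

The network is a fixed-weight, feed-forward spiking pipeline. Time is
discrete at two scales: video frames (default 30 fps) and phase ticks
(8 per frame). All neurons are leaky integrate-and-fire (LIF) units with a
per-tick decay `exp(-1/τ_p)` where `τ_p = 1000 / fps` ticks (≈ 33 at
30 fps, i.e. a leak of ≈ 0.97 per tick). Two firing contracts are used:

- **Plain threshold** (RF and grid populations): fire when the membrane
  reaches ρ = 0.9, reset to the resting level 0.
- **Phase-scaled threshold** (S-cells, polarity neurons, output neuron):
  threshold and post-spike subtraction are `ω(t)·ρ`, where
  `ω(t) = 2^−(1+t mod 8)` is the phase weight. The bar a unit must clear
  therefore halves at every tick within a period, so persistent
  sub-threshold drive tends to produce spikes late in a period, while the
  period boundary resets the bar high. Membranes are floored at 0:
  inhibition can silence but never hyperpolarise a unit.

Thresholds are inclusive (`≥`), matching the Heaviside convention
`U(0) = 1` used throughout.

### Phase coding

Channel values are normalised by the full 8-bit intensity scale (256) and
quantised to 8 fixed-point bits, most significant bit first; phase *i*
carries bit `floor(v·2^(i+1)) mod 2`. The ω-weighted sum of the bits
reconstructs the normalised value to within 2⁻⁸ (asserted for all 256
codes). Values that exceed the scale after residual accumulation are
clipped to the largest code and counted in a log message. Whether the
original design normalised by 255, 256 or a per-frame maximum is not
derivable from its description; 1/256 fixed-point is this package's choice
(a per-frame maximum was tried and rejected: it destroys the delay-extreme
cancellations described below).

### Eccentric geometry

The ring recursion advances the upper-left anchor centre by half the
previous RF size and shrinks the RF size linearly with distance to the
fovea (`d_fovea` = 45 px for the default geometry). Conventions, fixed so
that the default geometry yields the reference 58-cell grid:

- anchor centres are kept exact (half-integers allowed); RF sizes are
  floored to whole pixels; the recursion stops at the first size below 2.
  This gives l = 14 ring layers for the 100-px input.
- the one-to-one foveal span runs from the innermost anchor (x = 36) to
  its mirror image (x = 65), giving 29 unit boundary points and
  `DL = 2l + n + 1 = 58` per-axis regions. Literal real-valued recursion
  gives l = 12 and DL = 55–56; the floor-size convention is the simplest
  one that reaches the published grid side, and the integer span (29)
  makes it robust to tie-breaking.
- an RF of size *s* injects current from the pixels at offsets
  `floor(−s/2) … floor(s/2)` around its anchor pixel — *s* + 1 columns, so
  neighbouring RFs overlap by one pixel. This overlap is load-bearing: it
  sustains the down-sampled spike field from frame to frame, which the
  delay-extreme cancellations require. A strictly symmetric *s*-pixel
  extent was tried and abandoned for that reason. The side effect is that
  a central foveal output region pools the 2×2 block of overlapping unit
  RFs around it; foveal one-to-one resolution holds at the region level.
- per-pixel injected current is `R_k / area` (default), so a peripheral
  10-px RF demands many coincident pixel spikes where a foveal unit RF
  fires after two; `rf_current: raw` switches to a flat `R_k` per pixel.
- ring RFs are placed evenly between the anchor and its mirror with
  spacing at most one RF size, keeping the ring symmetric and the image
  fully covered (both asserted at build time).

### Kernels

All three Gaussian kernels use one σ convention: **σ is in units of the
kernel's half-support.** The 3×3 excitatory kernel (σ₁ = 1) spreads one
cell; the 9×9 inhibitory kernel (σ₂ = 0.5) spreads two cells — wider than
the excitation, as the competition requires; the grid-sized readout map
(σ₃ = 1) covers the whole field with a mild central (foveal) emphasis.
Reading σ₂ = 0.5 and σ₃ = 1 in raw cell units instead produces a
near-delta inhibition kernel and a readout blind to everything but the
2–3 central cells; under that reading the network detects nothing, so it
was rejected.

`w1`/`w2` carry absolute synaptic gains (peak 1) by default. Unit-sum
normalisation (available via `normalize_kernels` / `make_kernels(...,
normalize=True)`) weakens temporally aligned inhibition below the level
needed to cancel excitation, and the zero-delay silence disappears. The
readout map `w3` is always unit-sum: it is a weight distribution over the
S-cell population, not a gain.

### Phase delay

Inhibition at tick *t* is built from the grid field at `t − ε` with weight
`ω(t − ε)`, ε = 2 by default (range 0–8). The history buffer holds exactly
one frame (8 ticks). Consequently a delay of 8 reads the slot the current
phase has just rewritten: inhibition "delayed to the same phase of the
previous frame" coincides with the present excitation, and the two extreme
delays (0 and 8) are equivalent — both abolish every response. This
equivalence is a property of the one-frame buffer and is documented in
`DelayBuffer`; a true one-frame lag (depth 9) does not abolish the
delay-8 response.

### Readout

The FFI rate is `ω(t−ε) ×` (active grid fraction), per polarity; when it
reaches `S_th` the channel's input current is zeroed for exactly those
ticks (no hold time — the gate re-opens as soon as the rate drops). The
upper summation bound printed as "D7" in the population-rate definition is
treated as a typo for DL. Gating blocks input only; it does not clear the
channel membrane. A clip is scored *detected* when the output neuron fires
at least once.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `alpha1` | temporal residual of the ON/OFF rectifiers | 0.1 | — |
| `max_rs` | RF size of the outermost ring | 10 | px |
| `r_k` | RF current gain | 0.6 | — |
| `rho` | LIF firing threshold | 0.9 | — |
| `sigma1/2/3` | kernel spreads (half-support units) | 1 / 0.5 / 1 | — |
| `epsilon` | phase delay of inhibition | 2 | ticks |
| `side_length` | input side | 100 | px |
| `dl` | down-sampled grid side (validated against the layout) | 58 | cells |
| `s_th` | FFI gate threshold | 0.1 | — |
| `theta1/theta2` | ON/OFF mixing at the output | 0.5 / 0.5 | — |
| `fps` | sampling rate; sets `τ_p = 1000/fps` | 30 | frames/s |

## Synthetic stimuli

The suite contains, at four contrasts (dark-on-bright and bright-on-dark,
luminance gaps 60 and 180): looming squares growing 10 → 80 px over
90 frames (linear side growth by default; exponential and a
constant-approach-speed `perspective` law, 1/size linear in time, are
available), the exact time-reversals as receding clips, translating bars
(10 px wide, 2 px/frame), and drifting sinusoidal gratings (5 cycles/image
at temporal frequencies 0.05–0.4 cycles/frame). All generators are
deterministic. Edge speeds are sub-pixel per frame (≈ 0.4 px/frame for the
squares), as they are for any object of this size filmed at 30 fps.

What the suite does not emulate: sensor noise, background texture, camera
ego-motion, lighting changes, and the full-field transient of a physical
impact. Passing tests on this suite therefore demonstrate the network's
temporal-competition physics, not robustness on natural video.

## Known limitations

- **Looming-direction selectivity does not emerge.** Every processing
  stage is a function of radially symmetric event counts, and at sub-cell
  edge speeds the instantaneous excitation/inhibition configuration at a
  given object size is identical for an expanding and a contracting
  square. The response to a receding clip is therefore the approximate
  time-mirror of the looming response rather than zero, and translating
  bars also drive the output at intermediate delays. A systematic search
  over the open conventions (inhibition weight reading, kernel
  normalisation and widths, RF current modes, stimulus trajectory laws)
  did not produce a regime that silences receding or translating motion
  while preserving the looming response; the corresponding acceptance
  tests are expected to fail and say so. What does emerge robustly: total
  silence at delays 0 and 8, detection of every looming contrast at
  delays 1–7, monotone scaling of the response with contrast, more
  summation-cell spikes for looming than for its time-reversed clip, a
  stronger response without down-sampling than with it, and vigorous
  responses to gratings.
- The FFI gate only engages for genuinely whole-field events; object-sized
  stimuli never reach the 10% population threshold after down-sampling.
- Low-contrast motion (|Δ| ≲ 30) barely clears the encoding quantisation
  and the RF thresholds; the network is effectively blind to it.
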