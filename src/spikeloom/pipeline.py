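"""Online per-phase model loop, experiment protocols and exports.

:func:`run_model` executes the full network phase by phase — encode, pool
through the eccentric layer, generate prompt excitation and delayed
inhibition, compete at S-cells, gate through FFI, pool into the polarity
neurons and combine at the output neuron — and records a complete
:class:`ModelTrace`.  The experiment drivers reproduce the standard
protocols: the selectivity suite, the phase-delay sweep, the ON/OFF mixing
bias, and the down-sampling ablation (eccentric vs. none vs. uniform block
averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import eccentric, interaction, readout
from .encoding import PHASES_PER_FRAME, MotionChannels, phase_encode
from .eccentric import ECLayout, LIFArrayState, build_layout
from .interaction import DelayBuffer, make_kernels
from .stimuli import FrameStream, make_stimulus, standard_suite

__all__ = [
    "ModelConfig",
    "ModelTrace",
    "run_model",
    "detect",
    "sweep_delay",
    "ablate_downsampling",
    "export_raster",
    "read_raster",
    "summarize",
]

_DOWNSAMPLING_MODES = ("eccentric", "none", "average")


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterisation of the network.

    Defaults are the reference parameter set: residual ``alpha1 = 0.1``,
    largest RF 10 px, RF current gain 0.6, firing threshold ``rho = 0.9``,
    kernel widths ``sigma1 = 1`` / ``sigma2 = 0.5`` / ``sigma3 = 1``, phase
    delay 2 ticks, 100-px input, 58-cell down-sampled grid, FFI threshold
    0.1 and equal ON/OFF mixing.  ``tau`` is expressed in phase ticks as
    ``1000 / fps`` (about 33 at 30 fps).
    """

    alpha1: float = 0.1
    max_rs: int = 10
    r_k: float = 0.6
    rho: float = 0.9
    sigma1: float = 1.0
    sigma2: float = 0.5
    sigma3: float = 1.0
    epsilon: int = 2
    side_length: int = 100
    dl: int = 58
    s_th: float = 0.1
    theta1: float = 0.5
    theta2: float = 0.5
    fps: float = 30.0
    fovea_fraction: float = 0.1
    rf_current: str = "normalized"
    normalize_kernels: bool = False
    downsampling: str = "eccentric"

    def __post_init__(self):
        if self.downsampling not in _DOWNSAMPLING_MODES:
            raise ValueError(f"downsampling must be one of {_DOWNSAMPLING_MODES}")

    @property
    def tau_p(self) -> float:
        """Leak time constant in phase ticks."""
        return 1000.0 / self.fps

    # -- flat key:value serialisation -------------------------------------

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name}: {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            t = types[key]
            if t == "bool" or t is bool:
                kwargs[key] = val.lower() in {"1", "true", "yes"}
            elif t == "int" or t is int:
                kwargs[key] = int(val)
            elif t == "float" or t is float:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class ModelTrace:
    """Per-phase record of spikes at every layer plus readout membranes.

    ``grid_events`` and ``s_cell_events`` map polarity -> list (one entry
    per phase) of ``(n, 2)`` integer arrays of active ``(x, y)`` locations.
    ``channel_spikes`` holds the ON/OFF-type neuron spike trains and
    ``output_spikes`` the final binary output ``S(t)``.
    """

    n_phases: int
    dl: int
    grid_events: dict = field(default_factory=dict, repr=False)
    s_cell_events: dict = field(default_factory=dict, repr=False)
    channel_spikes: dict = field(default_factory=dict, repr=False)
    channel_input: dict = field(default_factory=dict, repr=False)
    ffi: dict = field(default_factory=dict, repr=False)
    channel_membrane: dict = field(default_factory=dict, repr=False)
    output_spikes: np.ndarray = None
    output_membrane: np.ndarray = None

    def output_spike_times(self) -> np.ndarray:
        return np.flatnonzero(self.output_spikes)

    def first_output_spike(self):
        """Phase time of the first output spike, or None."""
        t = self.output_spike_times()
        return int(t[0]) if t.size else None

    def spike_count(self, layer: str, polarity: str | None = None) -> int:
        if layer == "output":
            return int(self.output_spikes.sum())
        if layer == "channel":
            return int(np.sum(self.channel_spikes[polarity]))
        events = {"grid": self.grid_events, "s_cell": self.s_cell_events}[layer]
        return int(sum(len(e) for e in events[polarity]))


_LAYOUT_CACHE: dict = {}


def _layout_for(config: ModelConfig) -> ECLayout:
    key = (
        config.side_length,
        config.max_rs,
        config.fovea_fraction,
        config.r_k,
        config.rf_current,
    )
    if key not in _LAYOUT_CACHE:
        _LAYOUT_CACHE[key] = build_layout(
            side_length=config.side_length,
            max_rs=config.max_rs,
            fovea_fraction=config.fovea_fraction,
            r_k=config.r_k,
            rf_current=config.rf_current,
        )
    return _LAYOUT_CACHE[key]


def _block_matrix(side: int, dl: int):
    """Uniform block-average map from a side x side field to a dl x dl grid."""
    from scipy import sparse

    cell = np.minimum((np.arange(side) * dl) // side, dl - 1)
    rows, cols, vals = [], [], []
    counts = np.zeros((dl, dl))
    for y in range(side):
        for x in range(side):
            counts[cell[y], cell[x]] += 1
    for y in range(side):
        for x in range(side):
            gy, gx = cell[y], cell[x]
            rows.append(gy * dl + gx)
            cols.append(y * side + x)
            vals.append(1.0 / counts[gy, gx])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(dl * dl, side * side))


def run_model(config: ModelConfig, stream: FrameStream) -> ModelTrace:
    """Run the network over a clip and return its full trace.

    The loop is fully deterministic: identical ``(config, stream)`` pairs
    produce identical traces.  The first frame has no predecessor, so the
    encoded phase axis spans ``8 * (n_frames - 1)`` ticks.
    """
    if stream.side_length != config.side_length:
        raise ValueError(
            f"stream side {stream.side_length} != config side {config.side_length}"
        )
    if stream.n_frames < 2:
        raise ValueError("stream must contain at least two frames")

    mode = config.downsampling
    if mode == "eccentric":
        layout = _layout_for(config)
        if layout.dl != config.dl:
            raise ValueError(
                f"configured dl={config.dl} but layout yields dl={layout.dl}"
            )
        grid_side = layout.dl
    elif mode == "none":
        layout = None
        grid_side = config.side_length
    else:  # average
        layout = None
        grid_side = config.dl
        block = _block_matrix(config.side_length, config.dl)

    tau_p, rho = config.tau_p, config.rho
    kernels = make_kernels(
        grid_side, config.sigma1, config.sigma2, config.sigma3,
        normalize=config.normalize_kernels,
    )

    def lif(n):
        return LIFArrayState(n=n, tau_p=tau_p, rho=rho)

    pols = ("on", "off")
    if mode == "eccentric":
        rf_states = {p: lif(layout.n_rf) for p in pols}
        grid_states = {p: lif(grid_side**2) for p in pols}
    elif mode == "average":
        grid_states = {p: lif(grid_side**2) for p in pols}
    s_states = {p: lif(grid_side**2) for p in pols}
    chan_states = {p: lif(1) for p in pols}
    out_state = lif(1)
    buffers = {p: DelayBuffer((grid_side, grid_side)) for p in pols}
    channels = MotionChannels(alpha1=config.alpha1)

    frames = stream.frames.astype(np.float64)
    n_enc = stream.n_frames - 1
    n_phases = PHASES_PER_FRAME * n_enc

    trace = ModelTrace(n_phases=n_phases, dl=grid_side)
    trace.grid_events = {p: [] for p in pols}
    trace.s_cell_events = {p: [] for p in pols}
    trace.channel_spikes = {p: np.zeros(n_phases, dtype=np.uint8) for p in pols}
    trace.channel_input = {p: np.zeros(n_phases) for p in pols}
    trace.ffi = {p: np.zeros(n_phases) for p in pols}
    trace.channel_membrane = {p: np.zeros(n_phases) for p in pols}
    trace.output_spikes = np.zeros(n_phases, dtype=np.uint8)
    trace.output_membrane = np.zeros(n_phases)

    for f in range(1, stream.n_frames):
        p_fields = dict(zip(pols, channels.step(frames[f] - frames[f - 1])))
        bits = {p: phase_encode(p_fields[p]) for p in pols}
        for i in range(PHASES_PER_FRAME):
            t = PHASES_PER_FRAME * (f - 1) + i
            s_bar = {}
            for p in pols:
                slice_ = bits[p][i]
                if mode == "eccentric":
                    rf_sp = eccentric.rf_integrate_fire(
                        slice_, layout, rf_states[p], t
                    )
                    grid_sp = eccentric.pool_to_grid(
                        rf_sp, layout, grid_states[p], t
                    )
                elif mode == "none":
                    grid_sp = slice_
                else:  # average
                    current = block @ slice_.ravel().astype(np.float64)
                    grid_sp = grid_states[p].step_reset(current, t).reshape(
                        grid_side, grid_side
                    )
                buffers[p].push(grid_sp, t)

                e = interaction.epsc(grid_sp, kernels.w1, t, rho)
                delayed = buffers[p].delayed(t, config.epsilon)
                i_field = interaction.ipsc(
                    delayed, kernels.w2, t, rho, config.epsilon
                )
                g = interaction.summation(e, i_field)
                s_hat = interaction.s_cell_update(g, s_states[p], t)

                f_rate = readout.ffi_rate(delayed, t, config.epsilon)
                current = readout.gate_and_pool(
                    s_hat, kernels.w3, f_rate, config.s_th, t, rho
                )
                s_bar[p] = readout.channel_lif(current, chan_states[p], t)

                ys, xs = np.nonzero(grid_sp)
                trace.grid_events[p].append(
                    np.column_stack([xs, ys]).astype(np.int32)
                )
                ys, xs = np.nonzero(s_hat)
                trace.s_cell_events[p].append(
                    np.column_stack([xs, ys]).astype(np.int32)
                )
                trace.channel_spikes[p][t] = s_bar[p]
                trace.channel_input[p][t] = current
                trace.ffi[p][t] = f_rate
                trace.channel_membrane[p][t] = chan_states[p].membrane[0]

            s_out = readout.output_neuron(
                s_bar["on"], s_bar["off"], out_state, t,
                config.theta1, config.theta2,
            )
            trace.output_spikes[t] = s_out
            trace.output_membrane[t] = out_state.membrane[0]

    return trace


def detect(trace: ModelTrace) -> bool:
    """Collision decision: a clip is 'detected' iff the output fires at all."""
    return bool(trace.output_spikes.any())


# ---------------------------------------------------------------------------
# experiment protocols


def _resolve_stimuli(stimuli, config):
    """Accept a dict of specs/streams, or None for the standard suite."""
    if stimuli is None:
        stimuli = standard_suite(
            side_length=config.side_length, fps=config.fps
        )
    out = {}
    for name, s in stimuli.items():
        out[name] = s if isinstance(s, FrameStream) else make_stimulus(s)
    return out


def sweep_delay(config: ModelConfig, stimuli=None, delays=range(0, 9)):
    """Detection flag per (stimulus, phase delay).

    Returns a DataFrame indexed by stimulus name with one boolean column per
    delay value.
    """
    streams = _resolve_stimuli(stimuli, config)
    rows = {}
    for name, stream in streams.items():
        rows[name] = {
            f"delay_{d}": detect(run_model(replace(config, epsilon=d), stream))
            for d in delays
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ablate_downsampling(config: ModelConfig, stimuli=None):
    """Compare eccentric, no, and average down-sampling on a stimulus set.

    Returns a DataFrame with a detection flag and the first output-spike
    phase for each (stimulus, model) pair.
    """
    streams = _resolve_stimuli(stimuli, config)
    records = []
    for mode in _DOWNSAMPLING_MODES:
        cfg = replace(config, downsampling=mode)
        for name, stream in streams.items():
            tr = run_model(cfg, stream)
            records.append(
                {
                    "stimulus": name,
                    "model": mode,
                    "detected": detect(tr),
                    "first_spike": tr.first_output_spike(),
                    "n_spikes": int(tr.output_spikes.sum()),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# exports


_RASTER_LAYERS = ("grid", "s_cell", "channel", "output")


def export_raster(trace: ModelTrace, layer: str, path=None) -> pd.DataFrame:
    """Event-list CSV of one layer: columns (layer, polarity, x, y, t).

    Scalar layers (channel, output) use x = y = 0.  Returns the DataFrame;
    writes CSV if ``path`` is given.
    """
    if layer not in _RASTER_LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {_RASTER_LAYERS}")
    rows = []
    if layer in ("grid", "s_cell"):
        events = trace.grid_events if layer == "grid" else trace.s_cell_events
        for pol, per_phase in events.items():
            for t, coords in enumerate(per_phase):
                for x, y in coords:
                    rows.append((layer, pol, int(x), int(y), t))
    elif layer == "channel":
        for pol, spikes in trace.channel_spikes.items():
            for t in np.flatnonzero(spikes):
                rows.append((layer, pol, 0, 0, int(t)))
    else:
        for t in trace.output_spike_times():
            rows.append((layer, "both", 0, 0, int(t)))
    df = pd.DataFrame(rows, columns=["layer", "polarity", "x", "y", "t"])
    df = df.sort_values(["t", "polarity", "y", "x"], kind="stable").reset_index(
        drop=True
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_raster(path) -> pd.DataFrame:
    """Read an event CSV written by :func:`export_raster`."""
    return pd.read_csv(path, dtype={"layer": str, "polarity": str})


def summarize(trace: ModelTrace) -> dict:
    """Per-clip JSON-style summary."""
    return {
        "detected": detect(trace),
        "n_phases": int(trace.n_phases),
        "output_spike_times": [int(t) for t in trace.output_spike_times()],
        "first_output_spike": trace.first_output_spike(),
        "channel_spike_counts": {
            p: int(np.sum(s)) for p, s in trace.channel_spikes.items()
        },
        "ffi_gated_phases": {
            p: [int(t) for t in np.flatnonzero(np.asarray(f) >= 0.1)]
            for p, f in trace.ffi.items()
        },
        "s_cell_spike_counts": {
            p: int(sum(len(e) for e in ev))
            for p, ev in trace.s_cell_events.items()
        },
    }
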