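"""Synthetic visual stimuli and frame I/O.

Generates the computer-simulated movement classes used to probe looming
selectivity — approaching/receding squares at several contrasts, translating
bars, and drifting sinusoidal gratings — plus lossless reading/writing of
image-sequence directories so every experiment runs without external data.

All generators are deterministic: a stimulus is fully described by its
:class:`StimulusSpec`, and a looming clip reversed in time is exactly the
receding clip of the mirrored spec.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FrameStream",
    "StimulusSpec",
    "make_square_motion",
    "make_translating_bar",
    "make_grating",
    "make_stimulus",
    "standard_suite",
    "read_frames",
    "write_frames",
]

#: Rec.601 luma weights used when colour frames are read from disk.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStream:
    """An ordered stack of grayscale frames with its sampling rate.

    ``frames`` is an ``(F, H, W)`` uint8 array with intensities in [0, 255];
    every frame shares the same dimensions.  ``fps`` is the sampling
    frequency in frames per second.
    """

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (F, H, W) stack")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def side_length(self) -> int:
        return self.frames.shape[2]

    def reversed(self) -> "FrameStream":
        """Time-reversed copy of the stream."""
        return FrameStream(self.frames[::-1].copy(), self.fps)


@dataclass
class StimulusSpec:
    """Declarative description of one synthetic clip.

    ``kind`` selects the generator; ``speed`` is pixels/frame for a
    translating bar and cycles/frame (temporal frequency) for a grating.
    ``growth`` chooses the size trajectory of looming/receding squares
    (``linear`` by default, ``exponential`` optional).
    """

    kind: str = "looming"
    side_length: int = 100
    n_frames: int = 90
    fps: float = 30.0
    object_intensity: int = 40
    background_intensity: int = 220
    start_size: float = 10.0
    end_size: float = 80.0
    speed: float = 2.0
    bar_width: int = 10
    spatial_frequency: float = 5.0
    growth: str = "linear"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"looming", "receding", "translating", "grating"}:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        for name in ("object_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.n_frames < 2:
            raise ValueError("a clip needs at least two frames")

    @property
    def contrast(self) -> int:
        """Signed object-background luminance difference."""
        return self.object_intensity - self.background_intensity


def _size_trajectory(spec: StimulusSpec) -> np.ndarray:
    s0, s1 = spec.start_size, spec.end_size
    if spec.kind == "receding":
        s0, s1 = max(s0, s1), min(s0, s1)
    else:
        s0, s1 = min(s0, s1), max(s0, s1)
    u = np.linspace(0.0, 1.0, spec.n_frames)
    if spec.growth == "linear":
        sizes = s0 + (s1 - s0) * u
    elif spec.growth == "exponential":
        sizes = s0 * (s1 / s0) ** u
    elif spec.growth == "perspective":
        # constant approach/departure speed in depth: 1/size linear in time,
        # so an approaching edge accelerates toward collision
        sizes = 1.0 / (1.0 / s0 + (1.0 / s1 - 1.0 / s0) * u)
    else:
        raise ValueError(f"unknown growth law {spec.growth!r}")
    return sizes


def _render_square(side_length, size, obj, bg):
    # pixel centre coordinates; square of side `size` centred on the image
    c = side_length / 2.0
    ax = np.arange(side_length) + 0.5
    half = size / 2.0
    inside = (np.abs(ax - c) < half)[:, None] & (np.abs(ax - c) < half)[None, :]
    frame = np.full((side_length, side_length), bg, dtype=np.uint8)
    frame[inside] = obj
    return frame


def make_square_motion(spec: StimulusSpec) -> FrameStream:
    """Centered square whose side grows (looming) or shrinks (receding).

    The side length follows a linear trajectory by default.  Reversing a
    looming spec in time yields the receding clip frame-for-frame.
    """
    if spec.kind not in {"looming", "receding"}:
        raise ValueError("spec.kind must be 'looming' or 'receding'")
    if max(spec.start_size, spec.end_size) > spec.side_length:
        raise ValueError(
            f"square size {max(spec.start_size, spec.end_size)} exceeds "
            f"frame side {spec.side_length}"
        )
    sizes = _size_trajectory(spec)
    frames = np.stack(
        [
            _render_square(
                spec.side_length, s, spec.object_intensity, spec.background_intensity
            )
            for s in sizes
        ]
    )
    return FrameStream(frames, spec.fps)


def make_translating_bar(spec: StimulusSpec) -> FrameStream:
    """Vertical bar entering at the left edge and crossing at constant speed.

    The bar's left edge at frame ``f`` sits at ``-bar_width + speed * f``;
    after leaving the frame the clip continues with pure background.
    """
    if spec.kind != "translating":
        raise ValueError("spec.kind must be 'translating'")
    if spec.speed == 0:
        raise ValueError("translating bar needs nonzero speed")
    L, w = spec.side_length, spec.bar_width
    frames = np.full((spec.n_frames, L, L), spec.background_intensity, dtype=np.uint8)
    xs = np.arange(L) + 0.5
    for f in range(spec.n_frames):
        left = -w + spec.speed * f
        cols = (xs > left) & (xs < left + w)
        frames[f, :, cols] = spec.object_intensity
    return FrameStream(frames, spec.fps)


def make_grating(spec: StimulusSpec) -> FrameStream:
    """Horizontally drifting sinusoidal luminance grating.

    Mean luminance is the midpoint of object/background intensities and the
    amplitude is half their gap; ``spatial_frequency`` is in cycles per image
    width and ``speed`` is the temporal frequency in cycles per frame.
    """
    if spec.kind != "grating":
        raise ValueError("spec.kind must be 'grating'")
    if spec.spatial_frequency <= 0:
        raise ValueError("spatial_frequency must be positive")
    L = spec.side_length
    mid = (spec.object_intensity + spec.background_intensity) / 2.0
    amp = abs(spec.object_intensity - spec.background_intensity) / 2.0
    x = np.arange(L) / L
    frames = np.empty((spec.n_frames, L, L), dtype=np.uint8)
    for f in range(spec.n_frames):
        phase = 2.0 * np.pi * (spec.spatial_frequency * x - spec.speed * f)
        row = np.clip(np.rint(mid + amp * np.sin(phase)), 0, 255).astype(np.uint8)
        frames[f] = row[None, :]
    return FrameStream(frames, spec.fps)


_GENERATORS = {
    "looming": make_square_motion,
    "receding": make_square_motion,
    "translating": make_translating_bar,
    "grating": make_grating,
}


def make_stimulus(spec: StimulusSpec) -> FrameStream:
    """Dispatch a spec to its generator."""
    return _GENERATORS[spec.kind](spec)


def standard_suite(side_length=100, n_frames=90, fps=30.0):
    """The standard synthetic selectivity suite.

    Four contrasts (dark-on-bright and bright-on-dark at luminance gaps 60
    and 180) for looming, receding and translating clips, plus a drifting
    grating at four temporal frequencies.  Returns a name -> StimulusSpec
    mapping in a deterministic order.
    """
    base = dict(
        side_length=side_length,
        n_frames=n_frames,
        fps=fps,
        start_size=round(0.1 * side_length),
        end_size=round(0.8 * side_length),
        bar_width=max(2, round(0.1 * side_length)),
    )
    contrasts = {
        "dark_hi": dict(object_intensity=40, background_intensity=220),
        "dark_lo": dict(object_intensity=100, background_intensity=160),
        "white_hi": dict(object_intensity=220, background_intensity=40),
        "white_lo": dict(object_intensity=160, background_intensity=100),
    }
    suite = {}
    for kind in ("looming", "receding", "translating"):
        for cname, cvals in contrasts.items():
            kw = dict(base)
            if kind == "receding":
                kw["start_size"], kw["end_size"] = kw["end_size"], kw["start_size"]
            if kind == "translating":
                kw.pop("start_size"), kw.pop("end_size")
            suite[f"{kind}_{cname}"] = StimulusSpec(kind=kind, **kw, **cvals)
    for tf in (0.05, 0.1, 0.2, 0.4):
        kw = {k: v for k, v in base.items() if k not in ("start_size", "end_size", "bar_width")}
        suite[f"grating_tf{tf}"] = StimulusSpec(
            kind="grating",
            speed=tf,
            object_intensity=218,
            background_intensity=38,
            **kw,
        )
    return suite


# ---------------------------------------------------------------------------
# frame I/O


def write_frames(stream: FrameStream, path) -> None:
    """Write a stream as a PNG image-sequence directory.

    A sidecar ``meta.txt`` records fps and side length.  The round trip
    through :func:`read_frames` is lossless for 8-bit grayscale.
    """
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(stream.n_frames)))
    for f in range(stream.n_frames):
        iio.imwrite(path / f"frame_{f:0{width}d}.png", stream.frames[f])
    (path / "meta.txt").write_text(
        f"fps: {stream.fps}\nside_length: {stream.side_length}\n"
        f"n_frames: {stream.n_frames}\n"
    )


def read_frames(path, fps=None) -> FrameStream:
    """Read a lexicographically ordered PNG/PGM image-sequence directory.

    Colour frames are converted to luminance with Rec.601 weights.  Mixed
    frame sizes or unreadable files raise errors naming the offending frame.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a frame directory: {path}")
    names = sorted(
        p for p in os.listdir(path) if re.search(r"\.(png|pgm)$", p, re.IGNORECASE)
    )
    if not names:
        raise ValueError(f"no PNG/PGM frames found in {path}")
    frames = []
    for name in names:
        try:
            img = iio.imread(path / name)
        except Exception as exc:  # pragma: no cover - backend specific
            raise ValueError(f"unreadable frame {name!r}: {exc}") from exc
        if img.ndim == 3:
            img = np.rint(img[..., :3].astype(float) @ _LUMA).astype(np.uint8)
        if frames and img.shape != frames[0].shape:
            raise ValueError(
                f"frame {name!r} has size {img.shape}, expected {frames[0].shape}"
            )
        frames.append(img.astype(np.uint8))
    if fps is None:
        fps = 30.0
        meta = path / "meta.txt"
        if meta.exists():
            m = re.search(r"fps:\s*([\d.]+)", meta.read_text())
            if m:
                fps = float(m.group(1))
    return FrameStream(np.stack(frames), fps)
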