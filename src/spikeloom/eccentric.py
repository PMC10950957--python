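"""Foveated (eccentric) down-sampling implemented as a local LIF network.

The retina-like layout covers the square image with concentric square rings
of receptive fields (RFs) whose size shrinks linearly from ``max_rs`` pixels
at the periphery to single pixels in the central fovea.  Each RF is a leaky
integrate-and-fire (LIF) neuron that pools the phase-coded pixel spikes it
contains; a second LIF population pools RF spikes onto a coarse ``DL x DL``
output grid whose per-axis regions are delineated by the ring corners.

Geometry conventions
--------------------
The ring recursion advances the upper-left anchor centre by half the
previous ring's RF size and shrinks the RF size linearly with distance to
the fovea::

    Rc(i) = Rc(i-1) + Rs(i-1) / 2
    Rs(i) = max_rs - (max_rs / d_fovea) * Rc(i)

with ``Rc(0) = max_rs / 2`` and ``Rs(0) = max_rs``.  Anchor centres are kept
exact (half-integers allowed) while RF sizes are floored to whole pixels;
the recursion stops at the first layer whose floored size falls below 2
pixels.  The one-to-one foveal block then fills the span between the
innermost ring anchor and its mirror image.  For the default geometry
(side 100, ``max_rs`` 10, foveal dimension 10% of the side) this produces
l = 14 ring layers, a 29-pixel fovea and a 58-cell output grid per axis.

A pixel may belong to several RFs: consecutive rings advance by half an RF
size, so neighbouring rings overlap by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .encoding import phase_weight

__all__ = [
    "ECLayout",
    "LIFArrayState",
    "build_layout",
    "rf_integrate_fire",
    "pool_to_grid",
]


# ---------------------------------------------------------------------------
# LIF populations


@dataclass
class LIFArrayState:
    """Membrane state of a population of LIF units.

    ``tau_p`` is the leak time constant in phase ticks; each tick the
    membrane decays by ``exp(-1/tau_p)``.  ``rho`` is the firing threshold.
    Two firing contracts are used in the network:

    * :meth:`step_reset` — plain threshold at ``rho`` with reset to the
      resting level 0 on firing (RF and grid populations).
    * :meth:`step_scaled` — threshold and reset are scaled by the phase
      weight ``omega(t)`` (summation cells and readout neurons), so a unit
      whose membrane persists within a period meets an ever-lower bar at
      later, lightly-weighted phases.
    """

    n: int
    tau_p: float = 1000.0 / 30.0
    rho: float = 0.9
    membrane: np.ndarray = field(default=None, repr=False)
    last_spike_t: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.membrane is None:
            self.membrane = np.zeros(self.n)
        if self.last_spike_t is None:
            self.last_spike_t = np.full(self.n, -1, dtype=np.int64)
        self._leak = math.exp(-1.0 / self.tau_p)

    def step_reset(self, current, t):
        """Integrate ``current`` at phase ``t``; fire at ``rho``, reset to 0."""
        current = np.asarray(current, dtype=np.float64)
        if current.shape != self.membrane.shape:
            raise ValueError(
                f"current shape {current.shape} != state shape {self.membrane.shape}"
            )
        self.membrane = self.membrane * self._leak + current
        spikes = self.membrane >= self.rho
        self.membrane[spikes] = 0.0
        self.last_spike_t[spikes] = t
        return spikes.astype(np.uint8)

    def step_scaled(self, current, t):
        """Integrate signed ``current``; fire at ``omega(t) * rho``.

        On firing the membrane drops by ``omega(t) * rho``; it is floored at
        the resting level 0, so inhibition can silence but never
        hyperpolarise a unit.
        """
        current = np.asarray(current, dtype=np.float64)
        if current.shape != self.membrane.shape:
            raise ValueError(
                f"current shape {current.shape} != state shape {self.membrane.shape}"
            )
        thr = phase_weight(t) * self.rho
        v = self.membrane * self._leak + current
        spikes = v >= thr
        v = v - thr * spikes
        self.membrane = np.maximum(v, 0.0)
        self.last_spike_t[spikes] = t
        return spikes.astype(np.uint8)


# ---------------------------------------------------------------------------
# layout construction


@dataclass
class ECLayout:
    """Eccentric receptive-field geometry and its pooling matrices."""

    side_length: int
    max_rs: int
    fovea_fraction: float
    d_fovea: float
    l: int                      # index of the last ring layer
    n_fovea: int                # one-to-one foveal dimension (boundary points)
    ring_sizes: np.ndarray      # floored RF size per ring layer, (l+1,)
    ring_centers: np.ndarray    # exact anchor centre per ring layer, (l+1,)
    rf_centers: np.ndarray      # (m, 2) exact RF centres (x, y)
    rf_sizes: np.ndarray        # (m,) integer RF sizes
    rf_layer: np.ndarray        # (m,) ring layer, -1 for foveal RFs
    boundaries: np.ndarray      # (dl + 1,) per-axis region edges (sets B, C, D)
    dl: int                     # output grid side
    pixel_matrix: sparse.csr_matrix = field(repr=False)  # (m, side**2) currents
    grid_matrix: sparse.csr_matrix = field(repr=False)   # (dl**2, m) RF pooling

    @property
    def n_rf(self) -> int:
        return self.rf_centers.shape[0]

    def to_table(self):
        """Text-table export: one row per RF plus the region edges."""
        lines = ["k\tlayer\tcenter_x\tcenter_y\tsize"]
        for k in range(self.n_rf):
            cx, cy = self.rf_centers[k]
            lines.append(
                f"{k}\t{self.rf_layer[k]}\t{cx:g}\t{cy:g}\t{self.rf_sizes[k]}"
            )
        lines.append("# region edges: " + " ".join(f"{b:g}" for b in self.boundaries))
        return "\n".join(lines) + "\n"


def _ring_recursion(side_length, max_rs, fovea_fraction):
    """Run the anchor recursion; returns exact centres and floored sizes."""
    fovea_dim = fovea_fraction * side_length
    d_fovea = (side_length - fovea_dim) / 2.0
    centers = [max_rs / 2.0]
    sizes = [int(max_rs)]
    raw_sizes = [float(max_rs)]
    while True:
        c = centers[-1] + sizes[-1] / 2.0
        raw = max_rs - (max_rs / d_fovea) * c
        s = math.floor(raw)
        if s < 2:
            break
        centers.append(c)
        sizes.append(s)
        raw_sizes.append(raw)
        if c > side_length:  # degenerate geometry guard
            raise ValueError("ring recursion escaped the image")
    return np.array(centers), np.array(sizes, dtype=int), np.array(raw_sizes), d_fovea


def _pixel_extent(center, size):
    """Integer pixel extent of an RF's input field along one axis.

    Follows the floor-bound summation limits of the RF integration rule:
    pixel offsets run from ``floor(-size/2)`` to ``floor(size/2)`` around
    the anchor pixel, so an RF of size ``s`` pools ``s + 1`` pixel columns.
    Neighbouring RFs therefore overlap by one pixel, which gives the
    down-sampled spike field its frame-to-frame persistence.  The anchor
    rounding introduces a half-pixel offset for half-integer centres.
    """
    c = int(math.floor(center + 0.5))
    lo = c + math.floor(-size / 2.0)
    hi = c + math.floor(size / 2.0)
    return lo, hi


def _ring_rf_positions(center, size, side_length):
    """Evenly spaced RF centres along the perimeter of one square ring."""
    span = side_length - 2.0 * center
    m = max(2, int(math.ceil(span / size)) + 1)  # spacing <= size
    pos = np.linspace(center, side_length - center, m)
    pts = []
    for x in pos:
        pts.append((x, pos[0]))       # top
        pts.append((x, pos[-1]))      # bottom
    for y in pos[1:-1]:
        pts.append((pos[0], y))       # left
        pts.append((pos[-1], y))      # right
    return pts


def build_layout(
    side_length=100,
    max_rs=10,
    fovea_fraction=0.1,
    r_k=0.6,
    rf_current="normalized",
) -> ECLayout:
    """Construct the eccentric layout for a square image.

    Parameters
    ----------
    side_length : int
        Image side in pixels.
    max_rs : int
        RF size of the outermost ring; must satisfy ``side_length >= 2*max_rs``.
    fovea_fraction : float in (0, 1)
        Nominal foveal dimension as a fraction of the image side; sets the
        periphery-to-fovea distance ``d_fovea`` of the size recursion.
    r_k : float
        RF current gain ("percentage area of the RF").
    rf_current : {"normalized", "raw"}
        Per-pixel injected current: ``r_k / area`` (default, so larger
        peripheral RFs demand more coincident stimulation) or ``r_k`` flat.

    Raises ``ValueError`` on degenerate geometry.
    """
    if max_rs < 2:
        raise ValueError("max_rs must be at least 2 pixels")
    if not 0.0 < fovea_fraction < 1.0:
        raise ValueError("fovea_fraction must lie in (0, 1)")
    if side_length < 2 * max_rs:
        raise ValueError("image side must be at least twice max_rs")
    if rf_current not in {"normalized", "raw"}:
        raise ValueError("rf_current must be 'normalized' or 'raw'")

    centers, sizes, _, d_fovea = _ring_recursion(side_length, max_rs, fovea_fraction)
    l = len(centers) - 1

    # boundary points: B (ring upper-left corners), C (foveal diagonal), D (mirror)
    b_pts = [0.0] + [centers[i] - sizes[i] / 2.0 for i in range(1, l + 1)]
    fovea_lo = centers[l]
    mirror = side_length - b_pts[-1]
    n_fovea = int(round(mirror - fovea_lo))
    if n_fovea < 1:
        raise ValueError("fovea collapsed; geometry is degenerate")
    c_pts = [fovea_lo + i for i in range(n_fovea)]
    d_pts = [side_length - x for x in reversed(b_pts)]
    boundaries = np.array(b_pts + c_pts + d_pts)
    dl = len(boundaries) - 1  # = 2 l + n_fovea + 1

    # receptive fields: ring perimeters + one-to-one fovea
    rf_centers, rf_sizes, rf_layer = [], [], []
    for i in range(l + 1):
        for (x, y) in _ring_rf_positions(centers[i], sizes[i], side_length):
            rf_centers.append((x, y))
            rf_sizes.append(sizes[i])
            rf_layer.append(i)
    f0 = int(math.floor(fovea_lo + 0.5))
    f1 = int(math.floor(side_length - fovea_lo + 0.5))
    for y in range(f0, f1):
        for x in range(f0, f1):
            rf_centers.append((x + 0.5, y + 0.5))
            rf_sizes.append(1)
            rf_layer.append(-1)
    rf_centers = np.array(rf_centers)
    rf_sizes = np.array(rf_sizes, dtype=int)
    rf_layer = np.array(rf_layer, dtype=int)
    m = len(rf_sizes)

    # pixel -> RF current matrix
    rows, cols, vals = [], [], []
    covered = np.zeros((side_length, side_length), dtype=bool)
    for k in range(m):
        cx, cy = rf_centers[k]
        s = rf_sizes[k]
        x0, x1 = _pixel_extent(cx, s)
        y0, y1 = _pixel_extent(cy, s)
        x0, x1 = max(x0, 0), min(x1, side_length - 1)
        y0, y1 = max(y0, 0), min(y1, side_length - 1)
        area = (x1 - x0 + 1) * (y1 - y0 + 1)
        w = r_k / area if rf_current == "normalized" else r_k
        for y in range(y0, y1 + 1):
            for x in range(x0, x1 + 1):
                rows.append(k)
                cols.append(y * side_length + x)
                vals.append(w)
            covered[y, x0 : x1 + 1] = True
    if not covered.all():
        raise ValueError("internal error: RF set does not cover the image")
    pixel_matrix = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(m, side_length * side_length)
    )

    # RF -> output-grid mapping: RF joins every region its pixel field
    # overlaps.  Because neighbouring RF fields overlap by one pixel, a
    # foveal region pools the small block of unit RFs around it — the
    # one-to-one resolution of the fovea is at the region level, while the
    # overlap sustains the down-sampled field across frames.
    grows, gcols = [], []
    extents = np.empty((m, 4))
    for k in range(m):
        cx, cy = rf_centers[k]
        s = rf_sizes[k]
        x0, x1 = _pixel_extent(cx, s)
        y0, y1 = _pixel_extent(cy, s)
        extents[k] = (max(x0, 0), min(x1 + 1, side_length),
                      max(y0, 0), min(y1 + 1, side_length))
    for k in range(m):
        x0, x1, y0, y1 = extents[k]
        xi0 = np.searchsorted(boundaries, x0, side="right") - 1
        xi1 = np.searchsorted(boundaries, x1, side="left") - 1
        yi0 = np.searchsorted(boundaries, y0, side="right") - 1
        yi1 = np.searchsorted(boundaries, y1, side="left") - 1
        for yi in range(max(yi0, 0), min(yi1, dl - 1) + 1):
            for xi in range(max(xi0, 0), min(xi1, dl - 1) + 1):
                grows.append(yi * dl + xi)
                gcols.append(k)
    grid_matrix = sparse.csr_matrix(
        (np.ones(len(grows)), (grows, gcols)), shape=(dl * dl, m)
    )

    return ECLayout(
        side_length=side_length,
        max_rs=max_rs,
        fovea_fraction=fovea_fraction,
        d_fovea=d_fovea,
        l=l,
        n_fovea=n_fovea,
        ring_sizes=sizes,
        ring_centers=centers,
        rf_centers=rf_centers,
        rf_sizes=rf_sizes,
        rf_layer=rf_layer,
        boundaries=boundaries,
        dl=dl,
        pixel_matrix=pixel_matrix,
        grid_matrix=grid_matrix,
    )


# ---------------------------------------------------------------------------
# LIF stages


def rf_integrate_fire(pixel_spikes, layout: ECLayout, state: LIFArrayState, t):
    """One phase tick of the RF population.

    ``pixel_spikes`` is a binary ``(side, side)`` phase slice; each RF
    integrates the weighted current of its pixels and fires at ``rho`` with
    reset to rest.  Returns a binary ``(n_rf,)`` spike vector.
    """
    if state.n != layout.n_rf:
        raise ValueError("state size does not match layout RF count")
    current = layout.pixel_matrix @ np.asarray(
        pixel_spikes, dtype=np.float64
    ).ravel()
    return state.step_reset(current, t)


def pool_to_grid(rf_spikes, layout: ECLayout, state: LIFArrayState, t):
    """One phase tick of the down-sampled output grid.

    Each output neuron integrates the spike count of the RFs mapped to its
    region and thresholds at ``rho``.  Returns a binary ``(dl, dl)`` field.
    """
    if state.n != layout.dl**2:
        raise ValueError("state size does not match layout grid size")
    current = layout.grid_matrix @ np.asarray(rf_spikes, dtype=np.float64)
    return state.step_reset(current, t).reshape(layout.dl, layout.dl)
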