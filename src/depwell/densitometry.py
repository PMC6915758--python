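"""Well-image densitometry: from frame stacks to a polarisability index.

The instrument illuminates each cylindrical well from below and images it
once per second.  Cells redistribute radially according to the sign of
Re[f_CM] at the applied frequency — outward (towards the wall electrodes)
under positive DEP, inward under negative DEP — which changes the light
absorbance in different zones of the well.  Absorbance is monitored over
ten concentric annular rings; the per-ring rates of change, scaled by ring
area, combine into a single scalar proportional to Re[f_CM].

The index here uses fractional absorbance (I(0) - I(t)) / I(0) per ring:
cells accumulating in a ring attenuate more light, so its absorbance rises.
Outer-half rings enter with sign +1 and inner-half rings with -1, making
the index positive for positive DEP (accumulation at the wall).  The
response is close to linear in time for roughly the first ten seconds and
saturates beyond, so the standard analysis window is 10 s.

A seeded particle-drift simulator renders synthetic sequences so the whole
image pipeline is testable without the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectric import CellModel, Medium, clausius_mossotti

__all__ = [
    "WellGeometry",
    "WellImageSequence",
    "RingProfile",
    "ring_masks",
    "ring_intensity_series",
    "polarisability_index",
    "simulate_well_sequence",
]


@dataclass(frozen=True)
class WellGeometry:
    """Axisymmetric well footprint in image coordinates.

    ``centre`` is (row, col) in floating-point pixels with the origin at
    the top-left; ``radius`` is in pixels; ``frame_shape`` is the (rows,
    cols) shape of each frame.  The well disc must lie inside the frame and
    each of the ``n_rings`` equal-width annuli must be at least one pixel
    wide.
    """

    centre: tuple[float, float]
    radius: float
    frame_shape: tuple[int, int]
    n_rings: int = 10

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("need at least one ring")
        if self.radius < self.n_rings:
            raise ValueError("radius must allow >= 1 pixel per ring")
        r0, c0 = self.centre
        nr, nc = self.frame_shape
        if not (0 <= r0 < nr and 0 <= c0 < nc):
            raise ValueError("well centre must lie inside the frame")
        if (r0 - self.radius < -0.5 or r0 + self.radius > nr - 0.5
                or c0 - self.radius < -0.5 or c0 + self.radius > nc - 0.5):
            raise ValueError("well disc must lie inside the frame")


@dataclass(frozen=True)
class WellImageSequence:
    """Timestamped grayscale frames of one well (nominally 1 frame/s)."""

    frames: np.ndarray  # (n_frames, rows, cols), float intensities
    timestamps: np.ndarray  # seconds, strictly increasing
    geometry: WellGeometry

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("need >= 2 frames of constant shape")
        if t.shape != (frames.shape[0],) or np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing, one per frame")
        if frames.shape[1:] != tuple(self.geometry.frame_shape):
            raise ValueError("frame shape does not match geometry")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", t)


@dataclass(frozen=True)
class RingProfile:
    """Per-ring mean intensity time series plus ring geometry fractions."""

    ring_bounds: np.ndarray      # n_rings+1 radii fractions of well radius
    rel_areas: np.ndarray        # fraction of disc pixels per ring, sums to 1
    intensity_series: np.ndarray  # (n_rings, n_frames)
    timestamps: np.ndarray


def ring_masks(geometry: WellGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the concentric equal-width annuli of a well.

    Pixel membership is decided by the pixel-centre radius with half-open
    bins [r_k, r_{k+1}); the union of the masks is the well disc and the
    masks are pairwise disjoint.  Returns (masks, rel_areas) where
    ``masks`` has shape (n_rings, rows, cols) and ``rel_areas`` are pixel
    counts normalised by the disc total.
    """
    nr, nc = geometry.frame_shape
    r0, c0 = geometry.centre
    rows = np.arange(nr)[:, None] - r0
    cols = np.arange(nc)[None, :] - c0
    rho = np.hypot(rows, cols)
    edges = np.linspace(0.0, geometry.radius, geometry.n_rings + 1)
    masks = np.stack([
        (rho >= edges[k]) & (rho < edges[k + 1])
        for k in range(geometry.n_rings)
    ])
    counts = masks.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise ValueError("well radius too small: empty ring mask")
    return masks, counts / counts.sum()


def ring_intensity_series(sequence: WellImageSequence, masks: np.ndarray) -> RingProfile:
    """Mean intensity of every ring in every frame."""
    if masks.shape[1:] != tuple(sequence.geometry.frame_shape):
        raise ValueError("masks do not match the sequence geometry")
    counts = masks.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise ValueError("empty ring mask")
    flat = sequence.frames.reshape(sequence.frames.shape[0], -1)
    series = np.stack([
        flat[:, masks[k].ravel()].mean(axis=1) for k in range(masks.shape[0])
    ])
    n = masks.shape[0]
    return RingProfile(
        ring_bounds=np.linspace(0.0, 1.0, n + 1),
        rel_areas=counts / counts.sum(),
        intensity_series=series,
        timestamps=sequence.timestamps,
    )


def polarisability_index(profile: RingProfile, window: float = 10.0) -> float:
    """Area-scaled, signed sum of ring absorbance changes over a window.

    For each ring the least-squares slope of fractional absorbance
    (I(0) - I(t)) / I(0) over the first ``window`` seconds is computed and
    multiplied by the window span (the fitted net change), scaled by the
    ring's relative area, and summed with sign +1 for the outer half of
    the rings and -1 for the inner half.  The result is proportional to
    Re[f_CM] of the suspended cells: positive for positive DEP
    (accumulation at the wall), negative for negative DEP.  While the
    redistribution is in its linear regime the index grows proportionally
    with the window; it saturates for long windows.
    """
    t = profile.timestamps
    in_window = t <= t[0] + window
    if in_window.sum() < 3:
        raise ValueError("need at least 3 frames inside the analysis window")
    tw = t[in_window]
    span = tw[-1] - tw[0]
    n_rings = profile.intensity_series.shape[0]
    signs = np.where(np.arange(n_rings) >= n_rings / 2.0, 1.0, -1.0)
    index = 0.0
    for k in range(n_rings):
        series = profile.intensity_series[k, in_window]
        i0 = profile.intensity_series[k, 0]
        if i0 == 0:
            raise ValueError("zero initial intensity in ring")
        absorbance = (i0 - series) / i0
        slope = np.polyfit(tw - tw[0], absorbance, 1)[0]
        index += signs[k] * profile.rel_areas[k] * slope * span
    return float(index)


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def simulate_well_sequence(
    cell: CellModel,
    medium: Medium,
    frequency: float,
    n_cells: int = 2000,
    duration: float = 10.0,
    seed: int = 0,
    geometry: WellGeometry | None = None,
    v0_fraction: float = 0.005,
    footprint_sigma: float = 1.5,
    particle_depth: float = 0.05,
    render_noise_sd: float = 0.0,
    wall_margin: float | None = None,
    n_substeps: int = 10,
) -> WellImageSequence:
    """Simulate the radial redistribution of cells in one well.

    Particles start uniformly distributed over the well disc and drift
    radially with velocity v(rho) = v0 * Re[f_CM] * rho / R, the simplest
    axisymmetric field-gradient profile (zero on the axis, maximal at the
    wall); v0 = ``v0_fraction`` * R per second.  Boundaries reflect, with a
    small ``wall_margin`` (default 2 * footprint_sigma) keeping particle
    footprints inside the disc.  Frames are rendered once per second as
    Beer-Lambert attenuation of a uniform unit background: each particle
    contributes a Gaussian optical-depth footprint of width
    ``footprint_sigma`` pixels and peak depth ``particle_depth``.  Optional
    additive Gaussian render noise; everything is driven by ``seed`` and
    bit-reproducible.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if geometry is None:
        geometry = WellGeometry(centre=(64.0, 64.0), radius=60.0,
                                frame_shape=(128, 128))
    if wall_margin is None:
        wall_margin = 2.0 * footprint_sigma
    R = geometry.radius
    r_max = R - wall_margin
    if r_max <= 0:
        raise ValueError("wall margin leaves no room for particles")

    fcm = float(np.real(clausius_mossotti(cell, medium, frequency)))
    v0 = v0_fraction * R  # px/s at the wall for |Re f_CM| = 1

    rng = np.random.default_rng(seed)
    rho = r_max * np.sqrt(rng.uniform(size=n_cells))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_cells)

    n_frames = int(np.floor(duration)) + 1
    timestamps = np.arange(n_frames, dtype=float)
    nr, nc = geometry.frame_shape
    frames = np.empty((n_frames, nr, nc))

    half = int(np.ceil(3.0 * footprint_sigma))
    span = np.arange(-half, half + 1)
    dt = 1.0 / n_substeps

    def render() -> np.ndarray:
        depth = np.zeros((nr, nc))
        rr = geometry.centre[0] + rho * np.sin(theta)
        cc = geometry.centre[1] + rho * np.cos(theta)
        for pr, pc in zip(rr, cc):
            ir, ic = int(round(pr)), int(round(pc))
            dr = ir + span - pr
            dc = ic + span - pc
            stamp = particle_depth * np.outer(
                np.exp(-0.5 * (dr / footprint_sigma) ** 2),
                np.exp(-0.5 * (dc / footprint_sigma) ** 2),
            )
            r_lo, r_hi = ir - half, ir + half + 1
            c_lo, c_hi = ic - half, ic + half + 1
            sr_lo, sr_hi = max(0, -r_lo), 2 * half + 1 - max(0, r_hi - nr)
            sc_lo, sc_hi = max(0, -c_lo), 2 * half + 1 - max(0, c_hi - nc)
            depth[max(r_lo, 0):min(r_hi, nr), max(c_lo, 0):min(c_hi, nc)] += \
                stamp[sr_lo:sr_hi, sc_lo:sc_hi]
        frame = np.exp(-depth)
        if render_noise_sd > 0:
            frame = frame + rng.normal(0.0, render_noise_sd, size=frame.shape)
        return frame

    frames[0] = render()
    for i in range(1, n_frames):
        for _ in range(n_substeps):
            rho = rho + dt * v0 * fcm * (rho / R)
            rho = np.abs(rho)                      # reflect at the axis
            over = rho > r_max
            rho[over] = 2.0 * r_max - rho[over]    # reflect at the wall
            rho = np.clip(rho, 0.0, r_max)
        frames[i] = render()

    return WellImageSequence(frames=frames, timestamps=timestamps,
                             geometry=geometry)
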