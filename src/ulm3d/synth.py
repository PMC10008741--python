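"""Ground-truthed synthetic 4-D scenes.

Emulates the statistical structure of a rodent-brain microbubble
acquisition: a branching vessel tree with Murray's-law radii, Poiseuille
bubble flow, an anisotropic point-spread function, bright temporally
coherent clutter and additive noise, sampled at a fixed volume rate.
Every generator is deterministic under a fixed seed and exports its ground
truth so downstream recovery tests never have to re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImagingGrid, ProbeGeometry, VolumeSequence, wavelength_um

__all__ = [
    "VesselSegment",
    "BubbleTruth",
    "PSFModel",
    "SceneNoiseModel",
    "build_vessel_tree",
    "simulate_bubbles",
    "render_bmode",
    "simulate_rf",
    "make_demo_scene",
    "make_parallel_vessel_scene",
    "make_two_vessel_tree",
]

#: Murray's law radius ratio for a symmetric bifurcation.
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)


@dataclass
class VesselSegment:
    """One straight vessel segment of a binary tree.

    ``centerline`` is an ordered (N≥2, 3) array of (z, x, y) points in mm;
    flow runs from the first point to the last.  ``peak_speed_mm_s`` is the
    Poiseuille centerline speed.  ``children`` holds indices into the tree
    list (empty for terminal segments).
    """

    centerline: np.ndarray
    radius_mm: float
    peak_speed_mm_s: float
    flow_direction: int = 1
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline needs >= 2 points of 3 coordinates")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.peak_speed_mm_s < 0:
            raise ValueError("peak_speed_mm_s must be non-negative")

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))

    @property
    def mean_speed_mm_s(self) -> float:
        """Cross-section-averaged Poiseuille speed = peak / 2."""
        return self.peak_speed_mm_s / 2.0

    @property
    def volumetric_flow(self) -> float:
        """π R² × mean speed (mm³/s)."""
        return math.pi * self.radius_mm**2 * self.mean_speed_mm_s

    def point_at(self, arclength_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Centerline point and unit tangent at an arc length along the segment."""
        deltas = np.diff(self.centerline, axis=0)
        seg_len = np.linalg.norm(deltas, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(arclength_mm, 0.0, cum[-1])
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seg_len) - 1)
        frac = (s - cum[i]) / seg_len[i]
        point = self.centerline[i] + frac * deltas[i]
        tangent = deltas[i] / seg_len[i]
        return point, tangent


@dataclass
class BubbleTruth:
    """Per-frame ground-truth bubble records.

    ``records`` columns: bubble (id), frame, z_mm, x_mm, y_mm, rho
    (fractional radial offset in [0, 1)), speed_mm_s (true instantaneous
    speed).
    """

    records: pd.DataFrame
    frame_rate: float
    n_frames: int

    def positions(self, frame: int) -> np.ndarray:
        sub = self.records[self.records["frame"] == frame]
        return sub[["z_mm", "x_mm", "y_mm"]].to_numpy()

    def counts_per_frame(self) -> np.ndarray:
        counts = np.zeros(self.n_frames, dtype=int)
        got = self.records.groupby("frame").size()
        counts[got.index.to_numpy()] = got.to_numpy()
        return counts


@dataclass(frozen=True)
class PSFModel:
    """Anisotropic Gaussian point-spread function, FWHM per axis in mm."""

    fwhm_axial_mm: float
    fwhm_lateral_mm: float
    fwhm_elevation_mm: float

    def __post_init__(self) -> None:
        if min(self.fwhm_axial_mm, self.fwhm_lateral_mm, self.fwhm_elevation_mm) <= 0:
            raise ValueError("all FWHMs must be positive")

    @classmethod
    def from_frequency(cls, center_frequency_hz: float = 7.81e6) -> "PSFModel":
        """Diffraction-limit defaults: axial λ/2, lateral/elevation 1.5 λ."""
        lam_mm = wavelength_um(center_frequency_hz) * 1e-3
        return cls(lam_mm / 2.0, 1.5 * lam_mm, 1.5 * lam_mm)

    @property
    def fwhm_mm(self) -> tuple[float, float, float]:
        return (self.fwhm_axial_mm, self.fwhm_lateral_mm, self.fwhm_elevation_mm)

    @property
    def sigma_mm(self) -> tuple[float, float, float]:
        k = 2.0 * math.sqrt(2.0 * math.log(2.0))
        return tuple(f / k for f in self.fwhm_mm)


@dataclass(frozen=True)
class SceneNoiseModel:
    """Clutter + noise model for the synthetic B-mode sequence.

    ``clutter_amplitude`` is relative to a unit-amplitude bubble; the
    default ~31.6 puts the clutter 30 dB above a dim bubble — bright enough
    that localization without clutter filtering is hopeless, which is the
    regime SVD filtering targets.

    Tissue/skull clutter in vivo is not a single frozen pattern: pulsation,
    breathing and slow drift give it a spectrum of strong temporal modes,
    and that effective rank is precisely what removing 15–20% of singular
    values assumes.  The model therefore adds, on top of a static bright
    field, ``clutter_rank − 1`` smooth spatial modes with slowly varying
    temporal weights (smoothness set by ``clutter_decorrelation_time_s``)
    and geometrically decaying amplitudes
    (``clutter_fluctuation × clutter_mode_decay^k`` relative to the static
    field).  ``clutter_decorrelation_time_s = inf`` collapses to purely
    static (rank-one) clutter.
    """

    clutter_amplitude: float = 31.6
    clutter_rank: int = 30
    clutter_fluctuation: float = 0.15
    clutter_mode_decay: float = 0.93
    clutter_decorrelation_time_s: float = 0.02
    noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clutter_amplitude < 0 or self.noise_std < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.clutter_rank < 1:
            raise ValueError("clutter_rank must be >= 1")


def _perpendicular_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, tangent)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(tangent, helper)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(tangent, n1)
    return n1, n2


def build_vessel_tree(
    n_generations: int,
    root_radius_mm: float = 0.15,
    branch_angle_deg: float = 35.0,
    seed: int = 0,
    root_start_mm: tuple[float, float, float] = (1.5, -2.0, 0.0),
    root_direction: tuple[float, float, float] = (0.0, 1.0, 0.0),
    root_length_mm: float = 1.8,
    root_peak_speed_mm_s: float = 20.0,
    length_ratio: float = 0.75,
) -> list[VesselSegment]:
    """Binary vessel tree obeying Murray's law.

    Child radius = parent × 2^(-1/3); child peak speed is set so the
    volumetric flow of the two children sums to the parent's (for the
    symmetric split this is also a factor 2^(-1/3) per child).  Branch
    planes are rotated pseudo-randomly (seeded) so the tree is genuinely
    3-D.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    start = np.asarray(root_start_mm, dtype=float)
    direction = np.asarray(root_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    segments: list[VesselSegment] = []

    def add(start, direction, length, radius, peak, parent, gen) -> int:
        end = start + direction * length
        idx = len(segments)
        segments.append(
            VesselSegment(
                centerline=np.stack([start, end]),
                radius_mm=radius,
                peak_speed_mm_s=peak,
                parent=parent,
            )
        )
        if parent is not None:
            segments[parent].children.append(idx)
        if gen < n_generations:
            n1, n2 = _perpendicular_basis(direction)
            phi = rng.uniform(0.0, math.pi)
            branch_normal = math.cos(phi) * n1 + math.sin(phi) * n2
            theta = math.radians(branch_angle_deg)
            for sign in (+1, -1):
                child_dir = math.cos(theta) * direction + sign * math.sin(theta) * branch_normal
                child_dir = child_dir / np.linalg.norm(child_dir)
                add(
                    end,
                    child_dir,
                    length * length_ratio,
                    radius * MURRAY_RATIO,
                    peak * MURRAY_RATIO,
                    idx,
                    gen + 1,
                )
        return idx

    add(start, direction, root_length_mm, root_radius_mm, root_peak_speed_mm_s, None, 0)
    return segments


def make_two_vessel_tree(
    separation_mm: float = 0.060,
    radius_mm: float = 0.008,
    peak_speed_mm_s: float = 10.0,
    length_mm: float = 2.0,
    center_mm: tuple[float, float, float] = (1.5, 0.0, 0.0),
) -> list[VesselSegment]:
    """Two parallel straight vessels separated laterally by ``separation_mm``.

    The canonical separability phantom: with a 60 µm center-to-center gap
    the pair is resolvable on a λ/20 grid but not at the λ/2 diffraction
    scale.  Both vessels are roots (no branching), flowing along +y.
    """
    cz, cx, cy = center_mm
    half = separation_mm / 2.0
    segs = []
    for dx in (-half, +half):
        p0 = np.array([cz, cx + dx, cy - length_mm / 2.0])
        p1 = np.array([cz, cx + dx, cy + length_mm / 2.0])
        segs.append(
            VesselSegment(
                centerline=np.stack([p0, p1]),
                radius_mm=radius_mm,
                peak_speed_mm_s=peak_speed_mm_s,
            )
        )
    return segs


def _roots(tree: list[VesselSegment]) -> list[int]:
    return [i for i, s in enumerate(tree) if s.parent is None]


def _sample_path(tree: list[VesselSegment], rng: np.random.Generator) -> list[int]:
    """Random root-to-leaf path, branching with probability ∝ child flow."""
    roots = _roots(tree)
    flows = np.array([tree[r].volumetric_flow for r in roots])
    if flows.sum() > 0:
        idx = int(rng.choice(len(roots), p=flows / flows.sum()))
    else:
        idx = int(rng.integers(len(roots)))
    path = [roots[idx]]
    while tree[path[-1]].children:
        kids = tree[path[-1]].children
        w = np.array([tree[k].volumetric_flow for k in kids])
        if w.sum() > 0:
            k = int(rng.choice(len(kids), p=w / w.sum()))
        else:
            k = int(rng.integers(len(kids)))
        path.append(kids[k])
    return path


def _residence_time(tree: list[VesselSegment], path: list[int], rho: float) -> float:
    t = 0.0
    for i in path:
        v = tree[i].peak_speed_mm_s * (1.0 - rho**2)
        t += math.inf if v <= 0 else tree[i].length_mm / v
    return t


def simulate_bubbles(
    tree: list[VesselSegment],
    duration_s: float,
    frame_rate: float,
    mean_bubbles_in_view: float,
    seed: int = 0,
    radial_mode: str = "poiseuille",
    rho_max: float = 0.85,
) -> BubbleTruth:
    """Poiseuille bubble transport through the tree, sampled per frame.

    Bubbles enter at the tree root as a Poisson process whose rate is
    calibrated (by seeded Monte-Carlo estimation of the mean residence
    time) so the expected number of bubbles in view equals
    ``mean_bubbles_in_view``.  Each bubble keeps a fixed fractional radial
    offset ρ and azimuth; it advances by v(ρ)·Δt per frame with
    v(ρ) = peak_speed × (1 − ρ²), and picks a child branch with
    probability proportional to branch flow.

    ``radial_mode``: ``"poiseuille"`` samples ρ uniformly over the vessel
    cross-section (capped at ``rho_max`` so near-wall bubbles do not stall
    forever); ``"centerline"`` pins ρ = 0, so each bubble moves at its
    segment's centerline speed — convenient when a recovery test needs a
    single known speed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if radial_mode not in {"poiseuille", "centerline"}:
        raise ValueError(f"unknown radial_mode {radial_mode!r}")
    rng = np.random.default_rng(seed)

    def draw_rho() -> float:
        if radial_mode == "centerline":
            return 0.0
        return rho_max * math.sqrt(rng.uniform())

    # Calibrate the Poisson arrival rate against the mean residence time.
    cal = [
        _residence_time(tree, _sample_path(tree, rng), draw_rho()) for _ in range(256)
    ]
    cal = [t for t in cal if math.isfinite(t)]
    mean_residence = float(np.mean(cal)) if cal else 0.0
    if mean_residence <= 0 or mean_bubbles_in_view <= 0:
        rate = 0.0
    else:
        rate = mean_bubbles_in_view / mean_residence
    warmup = 1.2 * max(cal) if cal else 0.0

    n_frames = int(round(duration_s * frame_rate))
    dt = 1.0 / frame_rate

    rows: list[tuple] = []
    n_arrivals = rng.poisson(rate * (duration_s + warmup)) if rate > 0 else 0
    arrivals = np.sort(rng.uniform(-warmup, duration_s, size=n_arrivals))
    for bubble_id, t0 in enumerate(arrivals):
        path = _sample_path(tree, rng)
        rho = draw_rho()
        phi = rng.uniform(0.0, 2.0 * math.pi)
        # Cumulative entry times into each segment of the path.
        seg_enter = [0.0]
        for i in path:
            v = tree[i].peak_speed_mm_s * (1.0 - rho**2)
            seg_enter.append(seg_enter[-1] + (math.inf if v <= 0 else tree[i].length_mm / v))
        first_frame = max(0, int(math.ceil(t0 * frame_rate)))
        for frame in range(first_frame, n_frames):
            age = frame * dt - t0
            if age < 0:
                continue
            if age >= seg_enter[-1]:
                break  # bubble has exited the tree
            k = int(np.searchsorted(seg_enter, age, side="right") - 1)
            seg = tree[path[k]]
            v = seg.peak_speed_mm_s * (1.0 - rho**2)
            s = (age - seg_enter[k]) * v
            point, tangent = seg.point_at(s)
            n1, n2 = _perpendicular_basis(tangent)
            offset = rho * seg.radius_mm * (math.cos(phi) * n1 + math.sin(phi) * n2)
            pos = point + offset
            rows.append((bubble_id, frame, pos[0], pos[1], pos[2], rho, v))

    records = pd.DataFrame(
        rows, columns=["bubble", "frame", "z_mm", "x_mm", "y_mm", "rho", "speed_mm_s"]
    )
    return BubbleTruth(records=records, frame_rate=frame_rate, n_frames=n_frames)


def _splat_gaussians(
    volume: np.ndarray,
    grid: ImagingGrid,
    positions_mm: np.ndarray,
    amplitudes: np.ndarray,
    sigma_mm: tuple[float, float, float],
) -> None:
    """Add one anisotropic Gaussian per position, in place, windowed at 3σ."""
    spacing = np.asarray(grid.spacing_mm)
    sigma_vox = np.asarray(sigma_mm) / spacing
    half = np.maximum(1, np.ceil(3.0 * sigma_vox).astype(int))
    shape = np.asarray(grid.shape)
    for pos, amp in zip(positions_mm, amplitudes):
        cidx = grid.mm_to_index(pos)
        lo = np.maximum(0, np.floor(cidx - half).astype(int))
        hi = np.minimum(shape, np.ceil(cidx + half).astype(int) + 1)
        if np.any(lo >= hi):
            continue
        axes = [
            np.exp(-0.5 * ((np.arange(lo[a], hi[a]) - cidx[a]) / sigma_vox[a]) ** 2)
            for a in range(3)
        ]
        volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            amp * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        )


def render_bmode(
    truth: BubbleTruth,
    psf: PSFModel,
    noise: SceneNoiseModel,
    grid: ImagingGrid,
    amplitude_range: tuple[float, float] = (1.0, 10.0),
) -> VolumeSequence:
    """Render an envelope-like non-negative intensity sequence.

    Each bubble contributes an anisotropic 3-D Gaussian (peak value = its
    amplitude) centered at its true sub-voxel position.  Per-bubble
    amplitudes are drawn log-uniform over ``amplitude_range`` — a mix of
    dim and bright bubbles is exactly what motivates the dual-threshold
    localization strategy downstream.  Clutter is a bright smooth random
    field (static, or decorrelating with the configured time constant) and
    noise is additive white Gaussian; the final magnitude is returned.
    """
    rng = np.random.default_rng(noise.seed)
    n_frames = truth.n_frames
    frames = np.zeros((n_frames,) + tuple(grid.shape), dtype=np.float64)

    ids = (
        truth.records["bubble"].unique() if len(truth.records) else np.array([], dtype=int)
    )
    lo, hi = amplitude_range
    amp_by_id = {
        int(b): float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for b in np.sort(ids)
    }

    sigma = psf.sigma_mm
    for frame, sub in truth.records.groupby("frame"):
        pos = sub[["z_mm", "x_mm", "y_mm"]].to_numpy()
        amps = np.array([amp_by_id[int(b)] for b in sub["bubble"]])
        _splat_gaussians(frames[int(frame)], grid, pos, amps, sigma)

    if noise.clutter_amplitude > 0:
        def smooth_field() -> np.ndarray:
            g = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=4.0)
            return g / np.sqrt(np.mean(g**2))

        frames += noise.clutter_amplitude * np.abs(smooth_field())[None]
        n_modes = noise.clutter_rank - 1
        tau = noise.clutter_decorrelation_time_s
        if n_modes > 0 and noise.clutter_fluctuation > 0 and not math.isinf(tau):
            modes = np.stack([smooth_field() for _ in range(n_modes)])
            weights = ndimage.gaussian_filter1d(
                rng.standard_normal((n_modes, n_frames)),
                sigma=max(tau * truth.frame_rate, 1.0),
                axis=1,
            )
            weights /= np.sqrt(np.mean(weights**2, axis=1))[:, None]
            amps = (
                noise.clutter_amplitude
                * noise.clutter_fluctuation
                * noise.clutter_mode_decay ** np.arange(n_modes)
            )
            frames += np.einsum("m,mzxy,mt->tzxy", amps, modes, weights)

    if noise.noise_std > 0:
        frames += noise.noise_std * rng.standard_normal(frames.shape)

    np.abs(frames, out=frames)
    return VolumeSequence(frames=frames, grid=grid, frame_rate=truth.frame_rate)


def simulate_rf(
    scatterers_mm: np.ndarray,
    amplitudes: np.ndarray,
    probe: ProbeGeometry,
    angles_deg: list[tuple[float, float]],
    sound_speed_m_s: float = 1540.0,
    sample_rate_hz: float | None = None,
    n_samples: int = 1024,
):
    """Single-scattering plane-wave RF channel data.

    For each (angle, element) pair the trace is a sum over scatterers of a
    one-cycle Hann-tapered sinusoid at the probe center frequency, delayed
    by the plane-wave transmit time plus the element receive time, with
    amplitude proportional to the scatterer amplitude (no spreading loss —
    the simulator targets localization-grade geometry, not calibrated
    echo amplitudes).
    """
    from .beamform import RFDataSet, transmit_delay  # local import: beamform owns the type

    scatterers_mm = np.atleast_2d(np.asarray(scatterers_mm, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), scatterers_mm.shape[:1])
    if sample_rate_hz is None:
        sample_rate_hz = 4.0 * probe.center_frequency_hz

    elements = probe.element_positions()
    f0 = probe.center_frequency_hz
    period = 1.0 / f0
    data = np.zeros((len(angles_deg), probe.n_elements, n_samples), dtype=np.float64)
    t = np.arange(n_samples) / sample_rate_hz

    for ai, angle in enumerate(angles_deg):
        tau_tx = transmit_delay(scatterers_mm, angle, sound_speed_m_s)
        for si in range(scatterers_mm.shape[0]):
            dist_mm = np.linalg.norm(scatterers_mm[si] - elements, axis=1)
            delays = tau_tx[si] + dist_mm * 1e-3 / sound_speed_m_s
            # center the one-cycle pulse on the geometric delay so the
            # envelope peak (not the onset) encodes the echo time
            lo = np.searchsorted(t, delays - period / 2)
            hi = np.searchsorted(t, delays + period / 2)
            for ei in range(probe.n_elements):
                if lo[ei] >= n_samples:
                    continue
                tt = t[lo[ei] : hi[ei]] - delays[ei] + period / 2
                pulse = np.sin(2 * np.pi * f0 * tt) * 0.5 * (1 - np.cos(2 * np.pi * f0 * tt))
                data[ai, ei, lo[ei] : hi[ei]] += amplitudes[si] * pulse
    return RFDataSet(
        data=data,
        probe=probe,
        angles_deg=list(angles_deg),
        sample_rate_hz=float(sample_rate_hz),
        sound_speed_m_s=float(sound_speed_m_s),
    )


def make_demo_scene(
    seed: int = 0,
    n_frames: int = 500,
    frame_rate: float = 500.0,
    mean_bubbles_in_view: float = 20.0,
    radial_mode: str = "centerline",
    noise: SceneNoiseModel | None = None,
    n_generations: int = 5,
):
    """Packaged small scene: a branching vessel tree on a 32×48×48 λ/2 grid.

    Returns ``(tree, truth, sequence, grid, psf)``.  The grid spacing is
    the λ/2 beamforming voxel at 7.81 MHz (98.6 µm); the default duration
    is one second at 500 volumes/s with ~20 bubbles in view.  Five
    generations pack ~20 mm of vessel into the volume so the in-view
    bubbles stay mostly separated by more than a PSF — the sparsity regime
    localization microscopy relies on.
    """
    lam_mm = wavelength_um(7.81e6) * 1e-3
    spacing = lam_mm / 2.0
    grid = ImagingGrid(
        origin_mm=(0.0, -48 / 2 * spacing, -48 / 2 * spacing),
        spacing_mm=(spacing, spacing, spacing),
        shape=(32, 48, 48),
    )
    tree = build_vessel_tree(
        n_generations=n_generations,
        root_radius_mm=0.12,
        branch_angle_deg=45.0,
        seed=seed,
        root_start_mm=(1.6, -2.1, 0.0),
        root_direction=(0.0, 1.0, 0.0),
        root_length_mm=1.2,
        root_peak_speed_mm_s=20.0,
        length_ratio=0.7,
    )
    truth = simulate_bubbles(
        tree,
        duration_s=n_frames / frame_rate,
        frame_rate=frame_rate,
        mean_bubbles_in_view=mean_bubbles_in_view,
        seed=seed + 1,
        radial_mode=radial_mode,
    )
    psf = PSFModel.from_frequency(7.81e6)
    if noise is None:
        noise = SceneNoiseModel(seed=seed + 2)
    seq = render_bmode(truth, psf, noise, grid)
    return tree, truth, seq, grid, psf


def make_parallel_vessel_scene(
    seed: int = 0,
    n_frames: int = 500,
    frame_rate: float = 500.0,
    mean_bubbles_in_view: float = 20.0,
    peak_speed_mm_s: float = 20.0,
    radius_mm: float = 0.02,
    noise: SceneNoiseModel | None = None,
):
    """Parameter-recovery scene: eight parallel vessels, one known speed.

    Eight straight vessels run along the lateral axis at mutually distant
    (z, y) positions (≥ 1.2 mm apart, beyond any PSF overlap), all with
    the same Poiseuille centerline speed; bubbles are injected on the
    centerline, so every bubble moves at exactly ``peak_speed_mm_s``.
    With ~20 bubbles spread over ~36 mm of vessel the scene stays in the
    sparse regime localization microscopy assumes, which makes it the
    reference configuration for localization-error and speed-recovery
    measurements.  Defaults carry no clutter: the clutter/SVD interaction
    is validated separately, and adding bright clutter here would couple
    the two stages' errors.

    Returns ``(tree, truth, sequence, grid, psf)`` like
    :func:`make_demo_scene`.
    """
    lam_mm = wavelength_um(7.81e6) * 1e-3
    spacing = lam_mm / 2.0
    grid = ImagingGrid(
        origin_mm=(0.0, -48 / 2 * spacing, -48 / 2 * spacing),
        spacing_mm=(spacing, spacing, spacing),
        shape=(32, 48, 48),
    )
    zy = [
        (0.55, -1.6), (0.55, 0.55), (1.25, -0.55), (1.25, 1.6),
        (1.95, -1.6), (1.95, 0.55), (2.65, -0.55), (2.65, 1.6),
    ]
    half_len = 2.25
    tree = [
        VesselSegment(
            centerline=np.array([[z, -half_len, y], [z, +half_len, y]]),
            radius_mm=radius_mm,
            peak_speed_mm_s=peak_speed_mm_s,
        )
        for z, y in zy
    ]
    truth = simulate_bubbles(
        tree,
        duration_s=n_frames / frame_rate,
        frame_rate=frame_rate,
        mean_bubbles_in_view=mean_bubbles_in_view,
        seed=seed + 1,
        radial_mode="centerline",
    )
    psf = PSFModel.from_frequency(7.81e6)
    if noise is None:
        noise = SceneNoiseModel(clutter_amplitude=0.0, noise_std=0.05, seed=seed + 2)
    seq = render_bmode(truth, psf, noise, grid)
    return tree, truth, seq, grid, psf
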