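"""Synthetic-data generators with known ground truth.

Raw microscopy of the original strains is not available, so every analysis
stage in this package is exercised against simulated inputs:

* **tethered tracks** — a locus confined to the surface of a spherical
  nuclear envelope performs a persistence-correlated tangential random walk
  with exponential step lengths, occasionally punctuated by larger "dash"
  steps; the observable is the orthographic XY projection (thru-focus
  acquisition) plus localization noise;
* **pairing time courses** — the true paired fraction ramps linearly from a
  somatic baseline, and the observed percentage is a binomial draw of
  ``n_cells`` per hourly timepoint;
* **collision-trap populations** — two independent tethered loci per cell;
  a collision (3D separation below the capture radius) is absorbing with
  tetramerizing lacI and reversible, with an unbinding hazard, with
  dimerizing lacI;
* **rendered nuclei** — three-channel 3D stacks (telomere, spindle-pole
  body, DNA) with telomere foci drawn from a von Mises–Fisher distribution
  of tunable concentration κ around a chosen direction on the nuclear
  surface.

All generators draw from a single ``numpy`` Generator seeded from their
config, so identical configs reproduce outputs bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .bouquet import NucleusImage
from .pairing import CellSpotObservation, PairingTimecourse
from .rpm import SpotTrack

__all__ = [
    "SimulationConfig",
    "NucleusRenderConfig",
    "ACTIVITY_PRESETS",
    "simulate_tethered_track",
    "simulate_tethered_tracks",
    "isotropic_planar_tracks",
    "simulate_pairing_timecourse",
    "simulate_collision_population",
    "render_nucleus",
    "sample_vmf",
]


@dataclass
class SimulationConfig:
    """Free parameters of the tethered-walk and population generators.

    Lengths are µm, times are seconds.  ``persistence`` in [0, 1) sets how
    strongly each step direction correlates with the previous one (0 is a
    memoryless walk).  ``capture_radius_um`` holds the <0.2 µm proximity
    criterion used to score two loci as paired / collided.  Localization
    noise is truncated at ±3 s.d. so that noisy projected positions stay
    within ``nucleus_radius + 3·loc_noise`` of the center.
    """

    nucleus_radius_um: float = 1.0
    n_frames: int = 120
    dt_s: float = 1.0
    step_scale_um: float = 0.10
    persistence: float = 0.0
    dash_prob: float = 0.0
    dash_scale_um: float = 0.40
    loc_noise_um: float = 0.0
    capture_radius_um: float = 0.2
    trap_mode: str = "tetramer"
    unpair_rate_per_s: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "nucleus_radius_um",
            "dt_s",
            "dash_scale_um",
            "capture_radius_um",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        for name in ("step_scale_um", "loc_noise_um", "unpair_rate_per_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative and finite")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if not 0.0 <= self.dash_prob <= 1.0:
            raise ValueError("dash_prob must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.trap_mode not in ("dimer", "tetramer"):
            raise ValueError("trap_mode must be 'dimer' or 'tetramer'")

    def rng(self, seed: int | None = None) -> np.random.Generator:
        s = seed if seed is not None else self.seed
        return np.random.default_rng(s)


# Graded activity presets, ordered from the most to the least mobile
# genotype.  Parameter values are package choices that reproduce the
# qualitative activity ordering wild-type > mps3-dCC > mps3-dAR > ndj1Δ >
# csm4Δ on simulated medians; they are not calibrated to the experimental
# medians.
ACTIVITY_PRESETS: dict[str, SimulationConfig] = {
    "wild_type": SimulationConfig(step_scale_um=0.16, persistence=0.45, dash_prob=0.05),
    "mps3-dCC": SimulationConfig(step_scale_um=0.13, persistence=0.38, dash_prob=0.04),
    "mps3-dAR": SimulationConfig(step_scale_um=0.10, persistence=0.30, dash_prob=0.03),
    "ndj1": SimulationConfig(step_scale_um=0.07, persistence=0.20, dash_prob=0.02),
    "csm4": SimulationConfig(step_scale_um=0.045, persistence=0.10, dash_prob=0.0),
}


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_tangents(rng: np.random.Generator, points: np.ndarray) -> np.ndarray:
    """Unit vectors tangent to the sphere at each point, isotropic in the
    tangent plane."""
    normals = points / np.linalg.norm(points, axis=1, keepdims=True)
    v = rng.standard_normal(points.shape)
    v -= np.einsum("ij,ij->i", v, normals)[:, None] * normals
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a standard normal draw is almost surely non-degenerate; guard anyway
    bad = norms[:, 0] < 1e-12
    if bad.any():
        v[bad] = np.cross(normals[bad], [0.0, 0.0, 1.0])
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def _walk_on_sphere(
    cfg: SimulationConfig, n_tracks: int, rng: np.random.Generator
) -> np.ndarray:
    """3D positions of ``n_tracks`` independent tethered walks,
    shape (n_tracks, n_frames, 3)."""
    R = cfg.nucleus_radius_um
    pos = _random_unit_vectors(rng, n_tracks) * R
    prev_dir = _random_tangents(rng, pos)
    out = np.empty((n_tracks, cfg.n_frames, 3))
    out[:, 0] = pos
    for i in range(1, cfg.n_frames):
        normals = pos / R
        # carry the previous direction into the current tangent plane
        par = prev_dir - np.einsum("ij,ij->i", prev_dir, normals)[:, None] * normals
        norms = np.linalg.norm(par, axis=1, keepdims=True)
        fresh = _random_tangents(rng, pos)
        par = np.where(norms > 1e-12, par / np.where(norms > 0, norms, 1.0), fresh)
        d = cfg.persistence * par + (1.0 - cfg.persistence) * fresh
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        lengths = rng.exponential(cfg.step_scale_um, n_tracks)
        if cfg.dash_prob > 0:
            dash = rng.random(n_tracks) < cfg.dash_prob
            lengths[dash] = rng.exponential(cfg.dash_scale_um, int(dash.sum()))
        pos = pos + d * lengths[:, None]
        pos *= R / np.linalg.norm(pos, axis=1, keepdims=True)
        prev_dir = d
        out[:, i] = pos
    return out


def _project_with_noise(
    walk3d: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Orthographic XY projection plus truncated Gaussian localization
    noise."""
    xy = walk3d[..., :2].copy()
    if cfg.loc_noise_um > 0:
        noise = rng.standard_normal(xy.shape)
        np.clip(noise, -3.0, 3.0, out=noise)
        xy += cfg.loc_noise_um * noise
    return xy


def simulate_tethered_tracks(
    config: SimulationConfig,
    n_tracks: int,
    *,
    seed: int | None = None,
    genotype: str = "",
    timepoint_h: float | None = None,
    paired: bool | None = None,
) -> list[SpotTrack]:
    """Simulate ``n_tracks`` independent envelope-tethered spot tracks."""
    if n_tracks < 1:
        raise ValueError("n_tracks must be positive")
    rng = config.rng(seed)
    xy = _project_with_noise(_walk_on_sphere(config, n_tracks, rng), config, rng)
    return [
        SpotTrack(
            positions=xy[i],
            dt_s=config.dt_s,
            cell_id=f"cell{i:05d}",
            spot_id="a",
            genotype=genotype,
            timepoint_h=timepoint_h,
            paired=paired,
        )
        for i in range(n_tracks)
    ]


def simulate_tethered_track(
    config: SimulationConfig, *, seed: int | None = None
) -> SpotTrack:
    """Single-track convenience wrapper around ``simulate_tethered_tracks``."""
    return simulate_tethered_tracks(config, 1, seed=seed)[0]


def isotropic_planar_tracks(
    n_tracks: int,
    n_positions: int = 120,
    step_scale_um: float = 0.1,
    *,
    dt_s: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Unconfined planar random walks: the null model for the bias measure.

    Step directions are i.i.d. uniform on [0, 2π) and step lengths i.i.d.
    exponential, so successive displacements are independent and the
    expected per-track bias (mean turning-angle cosine) is exactly 0.
    Returns positions of shape (n_tracks, n_positions, 2) in µm.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, (n_tracks, n_positions - 1))
    lengths = rng.exponential(step_scale_um, (n_tracks, n_positions - 1))
    steps = lengths[..., None] * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    pos = np.zeros((n_tracks, n_positions, 2))
    np.cumsum(steps, axis=1, out=pos[:, 1:])
    return pos


def simulate_pairing_timecourse(
    config: SimulationConfig,
    n_cells: int,
    hours: Sequence[float],
    true_rate_pct_per_h: float,
    *,
    baseline_pct: float = 20.0,
    onset_h: float = 3.0,
    seed: int | None = None,
    genotype: str = "",
    locus: str = "",
) -> PairingTimecourse:
    """Binomially sampled pairing time course around a linear true ramp.

    The true paired fraction is ``baseline + rate·(t − onset)`` clamped to
    [0, 100]; at each timepoint the observed percentage is a binomial draw
    of ``n_cells`` scored cells.  The ground-truth rate is recorded on the
    returned time course.
    """
    if len(hours) == 0:
        raise ValueError("hours must be non-empty")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    if not np.isfinite(true_rate_pct_per_h):
        raise ValueError("true_rate_pct_per_h must be finite")
    hours = np.asarray(sorted(hours), dtype=float)
    rng = config.rng(seed)
    true_pct = np.clip(baseline_pct + true_rate_pct_per_h * (hours - onset_h), 0.0, 100.0)
    observed = rng.binomial(n_cells, true_pct / 100.0) / n_cells * 100.0
    return PairingTimecourse(
        genotype=genotype,
        locus=locus,
        hours=hours.tolist(),
        percent_paired=observed.tolist(),
        n_cells=[n_cells] * len(hours),
        true_rate_pct_per_h=true_rate_pct_per_h,
    )


def simulate_collision_population(
    config: SimulationConfig,
    n_cells: int,
    duration_s: float,
    *,
    seed: int | None = None,
    genotype: str = "",
    locus_pair: str = "",
    stage: str = "zip1_spots",
) -> list[CellSpotObservation]:
    """Collision-trap experiment: two tethered loci per cell.

    Both loci start uniformly on the nuclear surface and perform
    independent tethered walks.  A collision occurs when their 3D
    separation falls below the capture radius.  With ``trap_mode
    "tetramer"`` the collision is absorbing: the pair moves jointly ever
    after and the cell scores one spot.  With ``"dimer"`` a collided pair
    also moves jointly but unbinds with hazard ``unpair_rate_per_s``, after
    which the loci walk independently again.  The final observation scores
    one spot if the pair is bound or closer than the capture radius at the
    observation time.  ``duration_s = 0`` reduces to the chance-overlap
    baseline of independent initial placement.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    rng = config.rng(seed)
    n_steps = int(round(duration_s / config.dt_s))
    cfg = replace(config, n_frames=max(n_steps + 1, 2), seed=None)
    walk_a = _walk_on_sphere(cfg, n_cells, rng)
    walk_b = _walk_on_sphere(cfg, n_cells, rng)

    # a bound pair moves jointly, following locus A's walk
    bound = np.zeros(n_cells, dtype=bool)
    sep = np.linalg.norm(walk_a[:, 0] - walk_b[:, 0], axis=1)
    bound |= sep < config.capture_radius_um
    p_unbind = (
        1.0 - math.exp(-config.unpair_rate_per_s * config.dt_s)
        if config.trap_mode == "dimer"
        else 0.0
    )
    # positions of B, rewritten to follow A while bound
    pos_b = walk_b[:, 0].copy()
    drift_b = np.diff(walk_b, axis=1)  # B's own increments
    for i in range(1, n_steps + 1):
        if p_unbind > 0 and bound.any():
            unbind = bound & (rng.random(n_cells) < p_unbind)
            bound &= ~unbind
        free = ~bound
        pos_b[free] += drift_b[free, i - 1]
        R = config.nucleus_radius_um
        pos_b[free] *= (R / np.linalg.norm(pos_b[free], axis=1))[:, None]
        pos_b[bound] = walk_a[bound, i]
        sep = np.linalg.norm(walk_a[:, i] - pos_b, axis=1)
        hits = sep < config.capture_radius_um
        bound |= hits
        pos_b[bound] = walk_a[bound, i]
    final_sep = np.linalg.norm(walk_a[:, n_steps] - pos_b, axis=1)
    single = bound | (final_sep < config.capture_radius_um)
    return [
        CellSpotObservation(
            cell_id=f"cell{i:05d}",
            n_spots=1 if single[i] else 2,
            spot_separation_um=None if single[i] else float(final_sep[i]),
            stage=stage,
            trap=config.trap_mode,
            genotype=genotype,
            locus_pair=locus_pair,
        )
        for i in range(n_cells)
    ]


# ---------------------------------------------------------------------------
# 3D nucleus rendering


@dataclass
class NucleusRenderConfig:
    """Geometry and optics of the rendered three-channel nucleus.

    The stack covers ``n_slices`` z-planes at ``z_step_um`` spacing
    (defaults 64 × 0.2 µm) and ``n_xy`` × ``n_xy`` pixels of
    ``xy_pixel_um`` in-plane.  The DNA channel is a solid sphere of radius
    ``dapi_radius_um`` at the grid center; the SPB channel is one point on
    the sphere surface along ``spb_direction``; the telomere channel holds
    ``n_foci`` surface points drawn von Mises–Fisher around
    ``cluster_direction`` with concentration κ (κ=0 → uniform on the
    sphere).  All channels are blurred with an isotropic physical-units
    Gaussian of ``psf_sigma_um`` and Gaussian noise of s.d. ``noise_sd`` is
    added.
    """

    n_slices: int = 64
    z_step_um: float = 0.2
    xy_pixel_um: float = 0.1
    n_xy: int = 64
    dapi_radius_um: float = 1.0
    spb_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_foci: int = 32
    cluster_concentration: float = 0.0
    cluster_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    psf_sigma_um: float = 0.15
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_slices * self.z_step_um < 2.0 * self.dapi_radius_um:
            raise ValueError("axial extent n_slices·z_step must cover the DNA sphere")
        if self.n_xy * self.xy_pixel_um < 2.0 * self.dapi_radius_um:
            raise ValueError("lateral extent n_xy·xy_pixel must cover the DNA sphere")
        for name in ("z_step_um", "xy_pixel_um", "dapi_radius_um", "psf_sigma_um"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.cluster_concentration < 0:
            raise ValueError("cluster_concentration (κ) must be ≥ 0")
        if self.n_foci < 1:
            raise ValueError("n_foci must be positive")
        for name in ("spb_direction", "cluster_direction"):
            d = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(d)
            if not np.isfinite(n) or n == 0:
                raise ValueError(f"{name} must be a non-zero 3-vector")
            setattr(self, name, tuple(d / n))


def sample_vmf(
    mean_direction: Sequence[float],
    kappa: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` unit 3-vectors from a von Mises–Fisher distribution.

    Uses the inversion sampler for the S² special case, where the cosine of
    the polar angle w has density ∝ exp(κw): w is sampled by inverting the
    CDF, the azimuth is uniform, and the frame is rotated onto the mean
    direction.  κ=0 reduces to the uniform distribution on the sphere.
    """
    mu = np.asarray(mean_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    u = rng.random(n)
    if kappa < 1e-12:
        w = 2.0 * u - 1.0
    else:
        # inverse CDF of w on [-1, 1]; written to stay stable for large κ
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    local = np.stack([s * np.cos(phi), s * np.sin(phi), w], axis=1)
    # rotate z-axis onto mu
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(mu, z):
        return local
    if np.allclose(mu, -z):
        return local * np.array([1.0, -1.0, -1.0])
    axis = np.cross(z, mu)
    axis /= np.linalg.norm(axis)
    angle = math.acos(float(np.clip(mu @ z, -1.0, 1.0)))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)
    return local @ rot.T


def _splat_points(
    grid: np.ndarray,
    points_zyx: np.ndarray,
    voxel_size_zyx: tuple[float, float, float],
    weight: float = 1.0,
) -> None:
    """Deposit unit masses at physical points with trilinear weights.

    Physical coordinate 0 lies at the center of voxel index 0.  Raises if a
    point falls outside the grid.
    """
    idx = points_zyx / np.asarray(voxel_size_zyx)
    if (idx < 0).any() or (idx > np.asarray(grid.shape) - 1).any():
        raise ValueError("focus outside the rendered grid")
    lo = np.floor(idx).astype(int)
    frac = idx - lo
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                z = np.minimum(lo[:, 0] + dz, grid.shape[0] - 1)
                y = np.minimum(lo[:, 1] + dy, grid.shape[1] - 1)
                x = np.minimum(lo[:, 2] + dx, grid.shape[2] - 1)
                np.add.at(grid, (z, y, x), weight * w)


def render_nucleus(config: NucleusRenderConfig, *, seed: int | None = None) -> NucleusImage:
    """Render a three-channel (TEL, SPB, DNA) 3D stack of one nucleus."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    shape = (config.n_slices, config.n_xy, config.n_xy)
    vs = (config.z_step_um, config.xy_pixel_um, config.xy_pixel_um)
    center = (np.asarray(shape) - 1) / 2.0 * np.asarray(vs)

    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * vs[0] - center[0],
        np.arange(shape[1]) * vs[1] - center[1],
        np.arange(shape[2]) * vs[2] - center[2],
        indexing="ij",
    )
    dna = (zz**2 + yy**2 + xx**2 <= config.dapi_radius_um**2).astype(float)

    # directions are (x, y, z); grid axes are (z, y, x)
    spb_xyz = np.asarray(config.spb_direction) * config.dapi_radius_um
    spb_zyx = center + spb_xyz[::-1]
    spb = np.zeros(shape)
    _splat_points(spb, spb_zyx[None, :], vs)

    foci_dirs = sample_vmf(
        config.cluster_direction, config.cluster_concentration, config.n_foci, rng
    )
    foci_zyx = center[None, :] + (foci_dirs * config.dapi_radius_um)[:, ::-1]
    tel = np.zeros(shape)
    _splat_points(tel, foci_zyx, vs)

    sigma_vox = tuple(config.psf_sigma_um / s for s in vs)
    stack = np.stack(
        [
            ndimage.gaussian_filter(tel, sigma_vox),
            ndimage.gaussian_filter(spb, sigma_vox),
            ndimage.gaussian_filter(dna, sigma_vox),
        ]
    )
    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, stack.shape)
    return NucleusImage(voxels=stack, voxel_size_zyx=vs, provenance="rendered")
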