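"""Synthetic inputs with the statistical structure the analyses assume.

No raw imaging data accompanies the phenotype tables this package analyses,
so every pipeline stage is exercised on simulations built here:

* multinomial phenotype tables (one draw per condition);
* bead trajectories — a rigid counter-clockwise vortex plus diffusion
  (functioning organizer), Brownian motion confined to a reflecting disc
  (failed organizer), or free diffusion;
* those trajectories rendered into noisy fluorescence stacks (Gaussian
  point-spread, Gaussian and/or Poisson noise) with pixel-level ground truth;
* dorsal-forerunner-cell style tracks drifting toward the vegetal pole
  while their spread about the cluster centroid relaxes exponentially.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ImageStack, Track
from .errors import DomainError, ParameterError

__all__ = [
    "BeadSimConfig",
    "RenderConfig",
    "DfcSimConfig",
    "simulate_multinomial_counts",
    "simulate_bead_tracks",
    "render_image_stack",
    "simulate_dfc_tracks",
]


@dataclass
class BeadSimConfig:
    """Bead-motion simulation parameters (um, seconds).

    ``mode`` selects the flow regime.  In ``directed`` mode beads sit on a
    ring of radius ``vortex_radius`` around ``vortex_center`` and are
    advected by a rigid counter-clockwise rotation whose tangential speed at
    that radius is ``tangential_speed`` (``angular_speed`` may be given
    instead), plus isotropic diffusion ``D``.  In ``confined`` mode beads
    diffuse inside a reflecting disc of ``confinement_radius``.  The default
    frame interval matches 4 Hz acquisition.
    """

    mode: str = "directed"  # directed | confined | diffusive
    n_beads: int = 200
    duration: float = 8.0
    dt: float = 0.25
    vortex_center: tuple[float, float] = (32.0, 32.0)
    tangential_speed: float | None = 1.0  # um/s at vortex_radius
    angular_speed: float | None = None  # rad/s; overrides tangential_speed
    vortex_radius: float = 25.0
    radial_jitter: float = 0.1  # fractional spread of starting radii
    D: float = 0.02  # um^2/s
    confinement_radius: float = 5.0
    arena_size: float = 64.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in {"directed", "confined", "diffusive"}:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.dt <= 0 or self.duration < 2 * self.dt:
            raise ParameterError("need dt > 0 and duration >= 2*dt")
        if self.D < 0:
            raise DomainError("D must be non-negative")
        if self.mode == "confined" and self.confinement_radius <= 0:
            raise DomainError("confinement_radius must be positive")

    @property
    def omega(self) -> float:
        """Angular speed of the vortex in rad/s (counter-clockwise > 0)."""
        if self.angular_speed is not None:
            return self.angular_speed
        return (self.tangential_speed or 0.0) / self.vortex_radius


@dataclass
class RenderConfig:
    """Spot-rendering parameters.

    The point-spread is an isotropic Gaussian of ``psf_sigma`` um; the
    default 0.354 um gives an apparent blob diameter of 1.0 um
    (2*sqrt(2)*sigma), the centre of the 0.75-1.25 um detection gate.
    SNR = peak / noise_sd; the defaults give SNR 10.
    """

    pixel_size: float = 0.25
    shape: tuple[int, int] = (256, 256)  # (H, W)
    psf_sigma: float = 0.354
    peak: float = 100.0
    background: float = 10.0
    noise_sd: float = 10.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ParameterError("pixel_size and psf_sigma must be positive")
        if self.noise_sd < 0 or self.peak <= 0:
            raise ParameterError("need peak > 0 and noise_sd >= 0")


@dataclass
class DfcSimConfig:
    """Collective-migration simulation parameters (um, minutes).

    Cells drift toward the vegetal pole (+y) at ``drift_speed`` while their
    offsets from the moving cluster centroid relax exponentially at
    ``convergence_strength`` per minute; observed positions optionally carry
    additive Gaussian noise.  Defaults emulate a 3-hour recording from 50%
    epiboly sampled every 6 minutes with ~20 tracked cells.
    """

    n_cells: int = 20
    drift_speed: float = 1.0  # um/min toward +y
    convergence_strength: float = 0.005  # 1/min
    noise_sd: float = 0.0  # um
    duration: float = 180.0  # min
    dt: float = 6.0  # min
    initial_spread: tuple[float, float] = (60.0, 40.0)  # (x, y) half-extents
    seed: int = 0

    def __post_init__(self):
        if min(self.drift_speed, self.convergence_strength, self.noise_sd) < 0:
            raise DomainError("rates and noise must be non-negative")
        if self.dt <= 0 or self.duration < self.dt:
            raise ParameterError("need dt > 0 and duration >= dt")


def simulate_multinomial_counts(frequencies, n: int, seed: int = 0) -> np.ndarray:
    """One multinomial draw of ``n`` observations over the given frequencies."""
    freq = np.asarray(frequencies, dtype=float)
    if (freq < 0).any():
        raise DomainError("frequencies must be non-negative")
    if n < 1:
        raise DomainError("n must be >= 1")
    if abs(freq.sum() - 1.0) > 1e-9:
        raise DomainError(f"frequencies sum to {freq.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, freq)


def simulate_bead_tracks(config: BeadSimConfig) -> list[Track]:
    """Euler-Maruyama bead trajectories under the configured flow regime."""
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    n = config.n_beads
    dt = config.dt
    sqrt_step = math.sqrt(2.0 * config.D * dt)
    cx, cy = config.vortex_center

    if config.mode == "directed":
        radius = config.vortex_radius * (
            1.0 + config.radial_jitter * (2.0 * rng.random(n) - 1.0)
        )
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        pos = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    elif config.mode == "confined":
        r = config.confinement_radius * np.sqrt(rng.random(n))
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        pos = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    else:
        pos = rng.uniform(0.0, config.arena_size, size=(n, 2))

    # rigid rotation is exactly integrable: advect by the rotation matrix for
    # angle omega*dt (a forward-Euler tangential step would spiral outward)
    ang = config.omega * dt
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    center = np.array([cx, cy])
    traj = np.empty((n_steps + 1, n, 2))
    traj[0] = pos
    for step in range(1, n_steps + 1):
        if config.mode == "directed":
            pos = center + (pos - center) @ rot.T
        if sqrt_step > 0:
            pos = pos + sqrt_step * rng.standard_normal((n, 2))
        if config.mode == "confined":
            pos = _reflect_into_disc(pos, (cx, cy), config.confinement_radius)
        traj[step] = pos

    frames = np.arange(n_steps + 1)
    return [
        Track(
            track_id=i,
            frame=frames,
            t=frames * dt,
            x=traj[:, i, 0].copy(),
            y=traj[:, i, 1].copy(),
        )
        for i in range(n)
    ]


def _reflect_into_disc(pos: np.ndarray, center, radius: float) -> np.ndarray:
    """Radially reflect positions that left a disc back across its boundary."""
    cx, cy = center
    rel = pos - np.array([cx, cy])
    r = np.hypot(rel[:, 0], rel[:, 1])
    out = r > radius
    if out.any():
        # mirror the radial overshoot: r -> 2R - r (caps at the centre for
        # pathological steps longer than 2R, which diffusion never takes)
        r_new = np.clip(2.0 * radius - r[out], 0.0, radius)
        scale = np.where(r[out] > 0, r_new / r[out], 0.0)
        rel[out] *= scale[:, None]
        pos = np.array([cx, cy]) + rel
    return pos


def render_image_stack(
    tracks: list[Track],
    config: RenderConfig,
) -> tuple[ImageStack, list[dict]]:
    """Render tracks as Gaussian spots over background plus noise.

    Returns the stack and a ground-truth table: one record per rendered
    spot with ``frame``, ``track_id`` and the true ``x``/``y`` in um.
    Beads outside the field of view are clipped from the rendering (with a
    warning) but retained in the ground truth of the frames they do occupy.
    """
    h, w = config.shape
    px = config.pixel_size
    sigma_px = config.psf_sigma / px
    support = int(math.ceil(4.0 * sigma_px))
    frames_present = sorted({int(f) for tr in tracks for f in tr.frame})
    if not frames_present:
        raise DomainError("no track points to render")
    n_frames = frames_present[-1] + 1

    clean = np.full((n_frames, h, w), float(config.background))
    truth: list[dict] = []
    clipped = 0
    for tr in tracks:
        for f, x, y in zip(tr.frame, tr.x, tr.y):
            col, row = x / px, y / px
            if not (-0.5 <= col < w - 0.5 and -0.5 <= row < h - 0.5):
                clipped += 1
                continue
            truth.append(
                {"frame": int(f), "track_id": int(tr.track_id), "x": float(x), "y": float(y)}
            )
            c0, c1 = max(0, int(col) - support), min(w, int(col) + support + 1)
            r0, r1 = max(0, int(row) - support), min(h, int(row) + support + 1)
            rows, cols = np.mgrid[r0:r1, c0:c1]
            clean[int(f), r0:r1, c0:c1] += config.peak * np.exp(
                -((rows - row) ** 2 + (cols - col) ** 2) / (2.0 * sigma_px**2)
            )
    if clipped:
        warnings.warn(f"{clipped} bead positions fell outside the field and were clipped",
                      stacklevel=2)

    rng = np.random.default_rng(config.seed)
    noisy = clean
    if config.poisson:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
    if config.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, config.noise_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    stack = ImageStack(
        frames=noisy,
        pixel_size=px,
        frame_interval=0.25,
        meta={"render_config": asdict(config)},
    )
    return stack, truth


def simulate_dfc_tracks(config: DfcSimConfig) -> tuple[list[Track], dict]:
    """Converging, vegetal-ward cell tracks with known ground truth.

    Offsets from the cluster centroid decay as exp(-c t) (applied exactly
    per sampling step), the centroid advances at ``drift_speed`` um/min in
    +y, and observation noise is added to the recorded positions only.
    Returns the tracks (times in minutes) and the generating parameters,
    including the exact offset-extent ratio exp(c*T).
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    sx, sy = config.initial_spread
    offsets = np.column_stack([
        rng.uniform(-sx, sx, config.n_cells),
        rng.uniform(-sy, sy, config.n_cells),
    ])
    decay = np.exp(-config.convergence_strength * times)  # exact relaxation
    centroid_y = config.drift_speed * times

    tracks = []
    for i in range(config.n_cells):
        x = offsets[i, 0] * decay
        y = centroid_y + offsets[i, 1] * decay
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, x.shape)
            y = y + rng.normal(0.0, config.noise_sd, y.shape)
        tracks.append(Track(track_id=i, frame=np.arange(n_steps + 1), t=times, x=x, y=y))

    truth = {
        "drift_speed": config.drift_speed,
        "convergence_strength": config.convergence_strength,
        "expected_extent_ratio": float(math.exp(config.convergence_strength * times[-1])),
        "duration": float(times[-1]),
    }
    return tracks, truth
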