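"""Synthetic subtomogram generator.

Emulates the statistical regime the segmentation model assumes: small cubic
patches containing a few non-overlapping particles of N classes against a
zero background, additive Gaussian noise at a controlled signal-to-noise
ratio (SNR, defined throughout this package as the *variance ratio*
var(signal)/var(noise); other conventions such as amplitude ratios or dB
exist, so this choice is stated prominently), and optionally a Fourier-space
missing wedge mimicking the limited tilt range of the microscope stage.

Particles are solid (mildly anisotropic) ellipsoids with class-specific
mean intensity, not density maps of real macromolecules: the point of the
generator is that every downstream stage is testable without any download,
and its acceptance surface is label/parameter recovery rather than
biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volumes import LabelVolume, Volume

__all__ = [
    "SimulationConfig",
    "Particle",
    "simulate_patch",
    "simulate_dataset",
    "add_noise",
    "apply_missing_wedge",
    "toy_simulation_config",
]


@dataclass(frozen=True)
class Particle:
    """One particle record: class (1-based), center (voxels), nominal radius."""

    class_id: int
    center: tuple[float, float, float]
    radius: float


@dataclass
class SimulationConfig:
    """Generator settings.

    snr is the variance-ratio signal-to-noise level; ``float("inf")``
    disables noise.  ``missing_wedge_halfangle`` is the tilt half-angle in
    degrees (None disables the wedge).  All geometry is in voxels.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_classes: int = 1
    particles_per_patch: tuple[int, int] = (1, 3)
    radius_range: tuple[float, float] = (3.0, 6.0)
    snr: float = float("inf")
    missing_wedge_halfangle: float | None = None
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        lo, hi = self.particles_per_patch
        if not 1 <= lo <= hi:
            raise ValueError(f"bad particles_per_patch range {self.particles_per_patch}")
        rlo, rhi = self.radius_range
        if not 0 < rlo <= rhi:
            raise ValueError(f"bad radius_range {self.radius_range}")
        if rhi * 2 + 2 > min(self.shape):
            raise ValueError(
                f"max radius {rhi} too large for volume shape {self.shape}"
            )
        if not self.snr > 0:
            raise ValueError("snr must be positive (use float('inf') for noiseless)")


class CapacityError(RuntimeError):
    """Raised when non-overlapping particle placement fails repeatedly."""


def _class_intensity(class_id: int, n_classes: int) -> float:
    # distinct positive mean intensity per class, bounded away from background 0
    return 0.5 + 0.5 * class_id / n_classes


def simulate_patch(cfg: SimulationConfig, seed: int | None = None):
    """Generate one ``(Volume, LabelVolume, list[Particle])`` triple.

    Particles are placed without overlap (center distance > sum of radii)
    and entirely inside the volume; deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = cfg.shape
    n = int(rng.integers(cfg.particles_per_patch[0], cfg.particles_per_patch[1] + 1))
    # place large particles first (standard packing order); a greedy
    # sequential placement can still deadlock (an early central particle
    # may leave no room), so on failure all centers are redrawn while the
    # radii are kept
    radii = np.sort(rng.uniform(*cfg.radius_range, size=n))[::-1]
    for r in radii:
        if any(s - 2 * (r + 1.0) <= 0 for s in shape):
            raise CapacityError(f"radius {r} cannot fit inside volume shape {shape}")
    placed: list[tuple[np.ndarray, float]] = []
    tries_per_particle = 50
    restarts = max(1, cfg.max_place_tries // tries_per_particle)
    for _restart in range(restarts):
        placed = []
        failed = False
        for r in radii:
            r = float(r)
            margin = r + 1.0
            for _try in range(tries_per_particle):
                c = np.array([rng.uniform(margin, s - margin) for s in shape])
                if all(np.linalg.norm(c - c0) > r + r0 for c0, r0 in placed):
                    placed.append((c, r))
                    break
            else:
                failed = True
                break
        if not failed:
            break
    else:
        raise CapacityError(
            f"could not place {n} non-overlapping particles of radii "
            f"{np.round(radii, 2).tolist()} in {shape} after {restarts} restarts "
            "(volume too crowded)"
        )
    particles = [
        Particle(int(rng.integers(1, cfg.n_classes + 1)),
                 tuple(float(v) for v in c), r)
        for c, r in placed
    ]

    vol = np.zeros(shape, dtype=np.float32)
    lab = np.zeros(shape, dtype=np.int64)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    for p, (c, r) in zip(particles, placed):
        # axis-aligned ellipsoid with semi-axes in [0.8 r, r]: stays inside
        # the nominal sphere, so the recorded radius bounds the particle
        semi = rng.uniform(0.8, 1.0, size=3) * r
        q = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, semi))
        inside = q <= 1.0
        vol[inside] = _class_intensity(p.class_id, cfg.n_classes)
        lab[inside] = p.class_id
    volume = Volume(vol)
    if cfg.missing_wedge_halfangle is not None:
        volume = apply_missing_wedge(volume, cfg.missing_wedge_halfangle)
    if np.isfinite(cfg.snr):
        noise_seed = int(rng.integers(0, 2**31 - 1))
        volume = add_noise(volume, cfg.snr, noise_seed)
    return volume, LabelVolume(lab, cfg.n_classes), particles


def simulate_dataset(cfg: SimulationConfig, n_patches: int, seed: int | None = None):
    """Generate ``n_patches`` independent triples, deterministic given seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_patches)
    return [simulate_patch(cfg, int(s)) for s in seeds]


def toy_simulation_config(seed: int = 0, snr: float = 0.05) -> SimulationConfig:
    """Desk-scale study conditions: 16^3 patches, one foreground class,
    1-2 particles of radius 2.5-4 voxels (the largest radii whose
    non-overlap placement is geometrically feasible in a 16^3 box), heavy
    noise at variance-ratio SNR 0.05 by default."""
    return SimulationConfig(
        shape=(16, 16, 16),
        n_classes=1,
        particles_per_patch=(1, 2),
        radius_range=(2.5, 4.0),
        snr=snr,
        seed=seed,
    )


def add_noise(volume: Volume, snr: float, seed: int) -> Volume:
    """Additive zero-mean Gaussian noise with variance var(signal)/snr.

    ``snr = inf`` returns the input unchanged.
    """
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    if np.isinf(snr):
        return volume
    sig_var = float(np.var(volume.data))
    if sig_var == 0:
        raise ValueError("signal has zero variance; finite snr is undefined")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(sig_var / snr), size=volume.data.shape)
    return Volume(volume.data + noise.astype(np.float32), volume.voxel_size)


def apply_missing_wedge(volume: Volume, halfangle: float) -> Volume:
    """Zero the Fourier double wedge left unsampled by a +/- ``halfangle``
    (degrees) single-axis tilt series.

    The tilt axis is the canonical W axis (axis 1); the beam axis is D
    (axis 2).  Frequencies whose direction in the (H, D) plane makes an
    angle larger than ``halfangle`` with the H axis are never measured and
    are set to zero.

    On a discrete grid each coefficient is treated as a cell of finite
    angular extent and is attributed the angle of its inner cell edge
    (|k_H| floored at half a frequency step); a cell is zeroed only when
    that angle exceeds ``halfangle``, so the operator approaches the
    identity as ``halfangle -> 90`` on any finite grid.  Output is real.
    """
    if not 0 < halfangle < 90:
        raise ValueError(f"halfangle must be in (0, 90) degrees, got {halfangle}")
    data = volume.data.astype(np.float64)
    spec = np.fft.fftn(data)
    kh = np.fft.fftfreq(data.shape[0])[:, None, None]
    kd = np.fft.fftfreq(data.shape[2])[None, None, :]
    kh_floor = np.maximum(np.abs(kh), 0.5 / data.shape[0])
    angle = np.degrees(np.arctan2(np.abs(kd), kh_floor))
    keep = angle <= halfangle
    spec = spec * keep
    out = np.fft.ifftn(spec).real.astype(np.float32)
    return Volume(out, volume.voxel_size)
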