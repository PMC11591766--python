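"""Skull-stripped brain phantoms with group-dependent texture.

Real structural-MRI cohorts for Alzheimer's staging (CN / MCI / AD) are
access-restricted, so this module generates ellipsoidal "brain" phantoms whose
interior texture statistics and central cavity size vary monotonically across
the three diagnostic groups.  Two handles emulate disease progression:

* texture smoothness — the interior is a uniform-noise field blurred with a
  group-specific Gaussian sigma; less blur means finer, higher-contrast
  texture (disease groups get finer texture, i.e. higher GLCM contrast);
* a central zero-intensity ellipsoidal cavity whose radius grows with disease
  severity, a crude analogue of ventricular enlargement / gross atrophy.

Everything is deterministic given the config (including its seed): each
subject draws from a private RNG stream keyed by ``(seed, subject_counter)``
so enlarging the cohort never reshuffles earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import nibabel as nib
from scipy.ndimage import gaussian_filter

GROUPS = ("CN", "MCI", "AD")

#: brain ellipsoid semi-axes as a fraction of each half-extent
_BRAIN_SEMI_AXIS_FRAC = (0.9, 0.85, 0.9)
#: intensity range the blurred texture is rescaled to inside the mask
_TEXTURE_RANGE = (0.2, 1.0)

# Default group parameters: smoothing sigma falls (texture gets finer/harsher)
# and cavity grows CN -> MCI -> AD; noise rises mildly with severity.
_DEFAULT_SMOOTHNESS = {"CN": 2.5, "MCI": 1.8, "AD": 1.2}
_DEFAULT_NOISE_SD = {"CN": 0.02, "MCI": 0.04, "AD": 0.06}
_DEFAULT_CAVITY_FRAC = {"CN": 0.10, "MCI": 0.18, "AD": 0.28}


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic three-group cohort.

    Parameters
    ----------
    n_per_group
        Subject count per diagnostic group; every listed group needs >= 1.
    volume_shape
        Voxel grid, default 91 x 109 x 91 (2 mm MNI-like grid).
    texture_smoothness
        Gaussian blur sigma (voxels) of the interior texture, per group.
    noise_sd
        SD of additive Gaussian noise (intensity units), per group.
    cavity_radius_frac
        Central cavity semi-axes as a fraction (in [0, 0.8]) of the brain
        ellipsoid semi-axes, per group.
    seed
        Root RNG seed.
    """

    n_per_group: Mapping[str, int]
    volume_shape: tuple[int, int, int] = (91, 109, 91)
    texture_smoothness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SMOOTHNESS))
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    cavity_radius_frac: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CAVITY_FRAC))
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ConfigurationError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if int(n) < 1:
                raise ConfigurationError(f"count for group {g} must be >= 1, got {n}")
        if len(self.volume_shape) != 3 or any(int(s) < 8 for s in self.volume_shape):
            raise ConfigurationError(f"invalid volume_shape {self.volume_shape}")
        for g in self.n_per_group:
            if not self.texture_smoothness[g] > 0:
                raise ConfigurationError(f"texture_smoothness[{g}] must be > 0")
            if not self.noise_sd[g] >= 0:
                raise ConfigurationError(f"noise_sd[{g}] must be >= 0")
            if not 0 <= self.cavity_radius_frac[g] <= 0.8:
                raise ConfigurationError(f"cavity_radius_frac[{g}] must be in [0, 0.8]")

    @classmethod
    def default(cls, n_per_group: Mapping[str, int] | None = None,
                seed: int = 0, effect_scale: float = 1.0,
                **kwargs) -> "CohortConfig":
        """Cohort with the default group effects.

        ``effect_scale`` interpolates every group's parameters between the CN
        values (scale 0, a null cohort) and the defaults (scale 1); a "hard
        mode" uses a scale strictly between 0 and 1.
        """
        if n_per_group is None:
            n_per_group = {"CN": 167, "MCI": 235, "AD": 102}

        def _scaled(params: Mapping[str, float]) -> dict[str, float]:
            base = params["CN"]
            return {g: base + effect_scale * (params[g] - base) for g in GROUPS}

        return cls(
            n_per_group=dict(n_per_group),
            texture_smoothness=_scaled(_DEFAULT_SMOOTHNESS),
            noise_sd=_scaled(_DEFAULT_NOISE_SD),
            cavity_radius_frac=_scaled(_DEFAULT_CAVITY_FRAC),
            seed=seed,
            **kwargs,
        )

    @classmethod
    def null(cls, n_per_group: Mapping[str, int] | None = None,
             seed: int = 0, **kwargs) -> "CohortConfig":
        """Cohort in which all groups share identical parameters (no effect)."""
        return cls.default(n_per_group, seed=seed, effect_scale=0.0, **kwargs)


@dataclass
class BrainVolume:
    """One subject's skull-stripped intensity grid with its group label.

    Invariants: voxels are finite and >= 0, and the background outside the
    brain mask is exactly 0 (the skull-stripped contract).
    """

    subject_id: str
    group: str
    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)


def _ellipsoid_mask(shape: tuple[int, int, int],
                    semi_axes: tuple[float, float, float]) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[[slice(0, s) for s in shape]]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _generate_volume(group: str, config: CohortConfig, rng: np.random.Generator,
                     subject_id: str) -> BrainVolume:
    shape = tuple(int(s) for s in config.volume_shape)
    brain_axes = tuple(f * s / 2.0 for f, s in zip(_BRAIN_SEMI_AXIS_FRAC, shape))
    mask = _ellipsoid_mask(shape, brain_axes)

    texture = gaussian_filter(rng.uniform(0.0, 1.0, size=shape),
                              sigma=config.texture_smoothness[group])
    lo, hi = texture[mask].min(), texture[mask].max()
    span = hi - lo if hi > lo else 1.0
    a, b = _TEXTURE_RANGE
    vox = np.zeros(shape)
    vox[mask] = a + (b - a) * (texture[mask] - lo) / span

    frac = config.cavity_radius_frac[group]
    if frac > 0:
        cavity_axes = tuple(max(frac * ax, 1e-9) for ax in brain_axes)
        vox[_ellipsoid_mask(shape, cavity_axes)] = 0.0

    sd = config.noise_sd[group]
    if sd > 0:
        vox[mask] += rng.normal(0.0, sd, size=int(mask.sum()))
    np.clip(vox, 0.0, None, out=vox)
    vox[~mask] = 0.0
    return BrainVolume(subject_id=subject_id, group=group, voxels=vox,
                       voxel_size_mm=config.voxel_size_mm)


def generate_cohort(config: CohortConfig) -> list[BrainVolume]:
    """Generate the full cohort described by ``config``.

    Returns exactly ``sum(n_per_group.values())`` volumes in a fixed order
    (CN block, MCI block, AD block).  Each subject uses an RNG stream keyed by
    ``(config.seed, global_subject_index)`` so output is a pure function of
    the config and stable under cohort-size changes.
    """
    volumes: list[BrainVolume] = []
    counter = 0
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        for i in range(n):
            rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, counter])
            volumes.append(_generate_volume(group, config, rng,
                                            subject_id=f"{group}{i:03d}"))
            counter += 1
    return volumes


def write_nifti(volume: BrainVolume, path: str | Path) -> Path:
    """Write one volume as a NIfTI-1 file; round-trip preserves voxels exactly."""
    path = Path(path)
    affine = np.diag([*volume.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), affine)
    nib.save(img, str(path))
    return path


def write_cohort(volumes: list[BrainVolume], directory: str | Path) -> Path:
    """Write every volume as ``<subject_id>.nii`` plus a metadata CSV.

    Returns the path of the metadata file (header ``subject_id,group``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["subject_id,group"]
    for v in volumes:
        write_nifti(v, directory / f"{v.subject_id}.nii")
        lines.append(f"{v.subject_id},{v.group}")
    meta = directory / "cohort.csv"
    meta.write_text("\n".join(lines) + "\n")
    return meta
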