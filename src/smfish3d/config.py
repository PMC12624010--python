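"""Pipeline configuration.

A single flat dataclass holds every tunable of the pipeline: acquisition
geometry, PSF priors, detection thresholds, spot-QC ranges, the
transcription-site intensity ratio, segmentation parameters and the
statistical post hoc choice.  Defaults mirror a widefield 100x/1.4NA
acquisition with a 6.5 um sCMOS camera (65 nm lateral pixels) and 200 nm
z-steps over a 12 um optical range.

Configs round-trip through YAML; unknown keys are rejected so typos fail
loudly, and a fully-resolved copy is written next to every pipeline output
for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

log = logging.getLogger("smfish3d")

#: package version echoed in output provenance
__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


def planes_for_range(optical_range_um: float, z_step_nm: float) -> int:
    """Number of z-planes acquired over ``optical_range_um`` at ``z_step_nm`` steps.

    Both endpoints are imaged, so 12 um at 200 nm steps gives 61 planes.
    """
    if optical_range_um <= 0 or z_step_nm <= 0:
        raise ConfigError("optical range and z-step must be positive")
    return int(round(optical_range_um * 1000.0 / z_step_nm)) + 1


@dataclass
class PipelineConfig:
    """Every tunable of the analysis pipeline, with field-typical defaults."""

    # --- acquisition geometry ---
    voxel_size_nm: tuple[float, float, float] = (200.0, 65.0, 65.0)  # (z, y, x)

    # --- PSF prior (anisotropic Gaussian sigma) ---
    psf_sigma_nm: tuple[float, float, float] = (350.0, 130.0, 130.0)

    # --- background subtraction ---
    # rolling-ball (grayscale opening) radius as a multiple of lateral PSF sigma
    ball_radius_factor: float = 10.0
    bg_presmooth_sigma_vox: float = 1.0

    # --- candidate detection ---
    # LoG response threshold = log_threshold_k * robust (MAD-based) noise SD.
    # Noise maxima of the background-subtracted response reach ~7-8 SD over
    # a full field while the weakest detectable spots exceed 30 SD, so 10
    # keeps the blank-field false-positive rate below one per field with a
    # >3x margin to real signals.
    log_threshold_k: float = 10.0

    # --- Gaussian fitting ---
    fit_window_vox: tuple[int, int, int] = (7, 11, 11)  # (z, y, x)

    # --- spot QC ---
    # amplitude_min = amplitude_k * robust noise SD of the background-subtracted
    # stack unless an absolute range is given
    amplitude_k: float = 5.0
    amplitude_range: Optional[tuple[float, float]] = None
    # acceptance band for fitted sigmas, relative to psf_sigma_nm
    sigma_rel_range: tuple[float, float] = (0.45, 1.8)
    residual_max: float = 0.5

    # --- single-molecule reference intensity ---
    reference: str = "cytoplasmic"  # or "all"
    reference_min_spots: int = 10
    reference_trimmed: bool = False  # 10% trimmed mean instead of plain mean

    # --- transcription sites ---
    tsx_ratio_threshold: float = 1.5

    # --- nuclear segmentation ---
    nucleus_diameter_um: float = 6.0
    stitch_threshold: float = 0.25
    min_z_planes: int = 3
    # nucleus volume accepted within these multiples of the expected sphere
    volume_bounds: tuple[float, float] = (0.25, 4.0)

    # --- cell segmentation ---
    cell_diameter_um: float = 9.0

    # --- population statistics ---
    pseudocount: float = 0.5
    posthoc: str = "tukey_ranks"  # or "dunn"

    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ConfigError("voxel sizes must be positive")
        if any(s <= 0 for s in self.psf_sigma_nm):
            raise ConfigError("PSF sigmas must be positive")
        if not 0.0 < self.stitch_threshold < 1.0:
            raise ConfigError("stitch_threshold must be in (0, 1)")
        if self.tsx_ratio_threshold <= 0:
            raise ConfigError("tsx_ratio_threshold must be positive")
        if self.reference not in ("cytoplasmic", "all"):
            raise ConfigError(f"unknown reference policy {self.reference!r}")
        if self.posthoc not in ("tukey_ranks", "dunn"):
            raise ConfigError(f"unknown posthoc method {self.posthoc!r}")
        lo, hi = self.sigma_rel_range
        if not 0 < lo < hi:
            raise ConfigError("sigma_rel_range must satisfy 0 < lo < hi")
        if self.amplitude_range is not None:
            lo, hi = self.amplitude_range
            if not lo < hi:
                raise ConfigError("amplitude_range must satisfy lo < hi")
        lo, hi = self.volume_bounds
        if not 0 < lo < hi:
            raise ConfigError("volume_bounds must satisfy 0 < lo < hi")

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}

    def write_resolved(self, out_dir: str | Path) -> Path:
        """Write the fully-resolved config plus tool version into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.yaml"
        payload = {"smfish3d_version": __version__, **self.to_dict()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path
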