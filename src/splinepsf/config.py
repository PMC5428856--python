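"""Analysis configuration."""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import yaml

__all__ = ["AnalysisConfig"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisConfig:
    """All knobs of the movie-analysis pipeline.

    Thresholds whose values the underlying method leaves open are
    documented at their defaults: the finding threshold is in units of the
    shot-noise standard deviation of the PSF-convolved background (6 sigma),
    the proximity cutoff is 5 px, the background smoothing sigma 8 px, and
    the outer find/fit loop repeats at most 3 times with at most 200
    fitting sweeps per repeat.
    """

    pixel_size: float = 160.0       # nm
    wavelength: float = 600.0       # nm
    spline_path: str | None = None
    threshold: float = 6.0          # finding threshold, background-noise sigmas
    z_planes: tuple = (0.0,)        # nm, convolution planes for finding
    min_distance: float = 5.0       # px, proximity filter cutoff
    max_iterations: int = 200       # fitting sweeps per repeat
    max_repeats: int = 3
    background_sigma: float = 8.0   # px
    fit_roi: int = 12               # px
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "wavelength", "threshold", "min_distance",
                     "background_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_iterations", "max_repeats", "fit_roi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.z_planes = tuple(float(z) for z in self.z_planes)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.spline_path is not None and not pathlib.Path(cfg.spline_path).exists():
            raise FileNotFoundError(f"spline file not found: {cfg.spline_path}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def log_resolved(self) -> None:
        """Log every resolved setting so a run is reproducible from logs."""
        for key, value in dataclasses.asdict(self).items():
            log.info("config: %s = %r", key, value)
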