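"""Pipeline configuration.

Every constant of the analysis (band layout, detector thresholds, window
lengths, statistical alpha, SVM grids) lives here as a default rather than
being hard-coded at call sites, and can be overridden from a YAML file.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class HfoConfig:
    """Time-frequency HFO detector parameters.

    The detector z-scores Hilbert amplitude envelopes in ``n_bands``
    log-spaced frequency bands between ``fmin`` and ``fmax`` Hz, with
    mean/SD estimated per ``stat_window_s``-second statistical window,
    thresholds at ``z_threshold`` SD above the mean, and keeps events
    lasting more than ``min_cycles`` cycles at their peak frequency.
    """

    n_bands: int = 300
    fmin: float = 60.0
    fmax: float = 800.0
    stat_window_s: float = 10.0
    z_threshold: float = 3.0
    min_cycles: float = 4.0
    filter_order: int = 4
    #: half-width of each analysis band as a fraction of its center frequency
    band_halfwidth: float = 0.35
    r_band: tuple[float, float] = (80.0, 250.0)
    fr_band: tuple[float, float] = (250.0, 600.0)
    #: if True, report duration as the span within the peak band only
    peak_band_duration: bool = False
    #: dominant-frequency estimator: "centroid" (z^2-weighted) or "argmax"
    peak_frequency_method: str = "centroid"


@dataclass
class IedConfig:
    """Interictal spike detector parameters (Barkmeier-style two-band scheme).

    ``ref_background_uv`` is the reference median absolute amplitude of the
    1-35 Hz band to which every channel is rescaled before thresholding;
    amplitude/slope thresholds then apply in those scaled units.
    """

    detect_band: tuple[float, float] = (20.0, 50.0)
    scale_band: tuple[float, float] = (1.0, 35.0)
    ref_background_uv: float = 10.0
    amp_threshold: float = 60.0
    slope_threshold: float = 3.0
    refractory_s: float = 0.2
    #: peak-to-trough ("p2t") or baseline-to-peak ("b2p") amplitude measure
    amplitude_measure: str = "p2t"
    screen_threshold_per_10min: float = 50.0


@dataclass
class ConnectivityConfig:
    window_s: float = 1.0
    n_bins: int = 10
    log_base: str = "e"  # "e" (nats) or "2" (bits)


@dataclass
class StatsConfig:
    alpha: float = 0.05
    bh_correction: bool = False


@dataclass
class SvmConfig:
    kernels: Sequence[str] = ("linear", "rbf")
    c_grid: Sequence[float] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    gamma_grid: Sequence[float] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    refine: bool = True


@dataclass
class PipelineConfig:
    hfo: HfoConfig = field(default_factory=HfoConfig)
    ied: IedConfig = field(default_factory=IedConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        h = self.hfo
        if not (0 < h.fmin < h.fmax):
            raise ConfigError(f"need 0 < fmin < fmax, got ({h.fmin}, {h.fmax})")
        if h.n_bands < 2:
            raise ConfigError("n_bands must be >= 2")
        if h.r_band[1] != h.fr_band[0]:
            raise ConfigError(
                "ripple and fast-ripple bands must be contiguous "
                f"(got R upper {h.r_band[1]} != FR lower {h.fr_band[0]})"
            )
        if h.r_band[0] >= h.r_band[1] or h.fr_band[0] >= h.fr_band[1]:
            raise ConfigError("band edges must be increasing")
        if not 0 < self.stats.alpha < 1:
            raise ConfigError(f"alpha must lie in (0,1), got {self.stats.alpha}")
        if self.connectivity.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "hfo": HfoConfig,
            "ied": IedConfig,
            "connectivity": ConnectivityConfig,
            "stats": StatsConfig,
            "svm": SvmConfig,
        }
        kwargs: dict = {}
        for name, klass in sections.items():
            sub = dict(raw.get(name, {}))
            for key in ("r_band", "fr_band", "detect_band", "scale_band"):
                if key in sub and sub[key] is not None:
                    sub[key] = tuple(sub[key])
            kwargs[name] = klass(**sub)
        kwargs["seed"] = int(raw.get("seed", 0))
        return cls(**kwargs).validate()
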