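"""Configuration objects for the simulation and analysis pipeline.

The study design being emulated: healthy volunteers complete a 30-minute
walking stress test on three days, once per ambulatory-load condition
(80 / 100 / 120 % body weight, coded -1 / 0 / +1).  Serum is sampled twice
before (t-1, t0) and three times after (t1, t2, t3) the test, and each
sample is assayed in duplicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigurationError

#: Fixed mapping between percent-body-weight load and the centered load code.
LOAD_PCT_TO_CODE = {80: -1, 100: 0, 120: 1}
LOAD_CODE_TO_PCT = {v: k for k, v in LOAD_PCT_TO_CODE.items()}

TIMEPOINTS = ("t-1", "t0", "t1", "t2", "t3")
POST_TIMEPOINTS = ("t1", "t2", "t3")

MARKERS = (
    "COMP", "MMP-3", "MMP-9", "ADAMTS-4", "PRG-4", "IL-6", "C2C", "CPII",
)
RATIO_MARKER = "CPII/C2C"


@dataclass(frozen=True)
class MarkerSpec:
    """Per-marker generative settings for the concentration simulator.

    Parameters
    ----------
    baseline_median:
        Median resting serum concentration, in the marker's native units.
    baseline_gcv:
        Geometric coefficient of variation of between-subject baselines
        (lognormal spread), as a fraction (0.3 = 30%).
    cv_intra:
        Intra-assay coefficient of variation between duplicate wells, in
        percent, matching how assay precision is conventionally reported.
    detection_limits:
        (lower, upper) assay detection bounds in concentration units;
        simulated values outside are clipped to the bound and flagged.
    log_transform:
        Whether absolute changes for this marker are computed on the
        log10(1+x) scale (used for strongly right-skewed markers).
    """

    baseline_median: float
    baseline_gcv: float = 0.3
    cv_intra: float = 3.0
    detection_limits: tuple[float, float] = (0.0, math.inf)
    log_transform: bool = False


def default_marker_panel() -> dict[str, MarkerSpec]:
    """Marker panel with realistic resting medians (order of magnitude of
    commercial ELISA reference ranges) and the duplicate CVs reported for
    this assay battery."""
    return {
        "COMP": MarkerSpec(800.0, 0.25, 2.2),        # ng/ml
        "MMP-3": MarkerSpec(12.0, 0.40, 2.6),        # ng/ml
        "MMP-9": MarkerSpec(300.0, 0.45, 1.2),       # ng/ml
        "ADAMTS-4": MarkerSpec(0.6, 0.9, 1.3,        # ng/ml, right-skewed
                               detection_limits=(0.03, 40.0),
                               log_transform=True),
        "PRG-4": MarkerSpec(110.0, 0.35, 4.8),       # ng/ml
        "IL-6": MarkerSpec(1.8, 0.5, 2.4),           # pg/ml
        "C2C": MarkerSpec(220.0, 0.25, 8.1),         # ng/ml
        "CPII": MarkerSpec(1000.0, 0.35, 3.0),       # ng/ml
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for synthetic change values and concentration panels.

    The change-scale response of subject ``i`` at load code ``l`` is

        delta_il = alpha_i + beta_i * l + eps_il

    with (alpha_i, beta_i) bivariate normal with means (mu_alpha, mu_beta),
    SDs (sd_alpha, sd_beta) and correlation rho_alpha_beta, and eps i.i.d.
    normal with SD sd_error.  All response parameters are in change-scale
    points (percent of baseline / baseline median).
    """

    n_subjects: int = 24
    load_codes: tuple[int, ...] = (-1, 0, 1)
    timepoints: tuple[str, ...] = TIMEPOINTS
    mu_alpha: float = 5.0
    sd_alpha: float = 5.0
    mu_beta: float = 5.0
    sd_beta: float = 5.0
    rho_alpha_beta: float = 0.0
    sd_error: float = 5.0
    markers: dict[str, MarkerSpec] = field(default_factory=default_marker_panel)
    #: multiplicative weight of the injected response at each post-test
    #: timepoint, emulating the decay of the response after the stress test
    response_profile: dict[str, float] = field(
        default_factory=lambda: {"t1": 1.0, "t2": 0.5, "t3": 0.2})
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects", "need at least 2 subjects")
        codes = tuple(self.load_codes)
        if len(codes) < 2 or any(b <= a for a, b in zip(codes, codes[1:])):
            raise ConfigurationError("load_codes", "must be strictly increasing")
        if abs(sum(codes)) > 1e-12:
            raise ConfigurationError("load_codes", "must be centered on 0")
        for name in ("sd_alpha", "sd_beta", "sd_error"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "standard deviation must be >= 0")
        if not -1.0 <= self.rho_alpha_beta <= 1.0:
            raise ConfigurationError("rho_alpha_beta", "must lie in [-1, 1]")
        for name, spec in self.markers.items():
            if spec.baseline_median <= 0:
                raise ConfigurationError(
                    f"markers[{name}].baseline_median", "must be > 0")
            if spec.cv_intra < 0:
                raise ConfigurationError(
                    f"markers[{name}].cv_intra", "must be >= 0")
        for tp, w in self.response_profile.items():
            if tp not in self.timepoints:
                raise ConfigurationError(
                    "response_profile", f"unknown timepoint {tp!r}")
        return self

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: exactly one of ``input_csv`` (a raw
    concentration panel) or ``scenario`` (a synthetic-data configuration)."""

    input_csv: str | None = None
    scenario: SimulationConfig | None = None
    scales: tuple[str, ...] = ("relative", "absolute")
    gating_scale: str = "relative"
    cap: float = 75.0
    alpha: float = 0.05
    overrides: tuple[tuple[str, str, str], ...] = ()
    n_boot: int = 2000
    out_dir: str = "loadresponse_out"
    seed: int = 0
    compute_correlations: bool = True

    def validate(self) -> "PipelineConfig":
        if (self.input_csv is None) == (self.scenario is None):
            raise ConfigurationError(
                "input_csv/scenario", "exactly one input source required")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha", "must lie in (0, 1)")
        if self.cap <= 0:
            raise ConfigurationError("cap", "must be > 0")
        for s in self.scales:
            if s not in ("relative", "absolute"):
                raise ConfigurationError("scales", f"unknown scale {s!r}")
        return self


def _marker_spec_from_dict(d: dict) -> MarkerSpec:
    if "detection_limits" in d:
        lo, hi = d["detection_limits"]
        d = {**d, "detection_limits": (float(lo),
                                       math.inf if hi in (None, "inf") else float(hi))}
    return MarkerSpec(**d)


def simulation_config_from_yaml(path: str) -> SimulationConfig:
    """Read a SimulationConfig from a nested key-value (YAML) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    markers = raw.pop("markers", None)
    cfg = SimulationConfig(**{k: _coerce(k, v) for k, v in raw.items()})
    if markers is not None:
        cfg = cfg.with_(markers={name: _marker_spec_from_dict(spec)
                                 for name, spec in markers.items()})
    return cfg.validate()


def pipeline_config_from_yaml(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = raw.pop("scenario", None)
    if scenario is not None:
        markers = scenario.pop("markers", None)
        sc = SimulationConfig(**{k: _coerce(k, v) for k, v in scenario.items()})
        if markers is not None:
            sc = sc.with_(markers={name: _marker_spec_from_dict(spec)
                                   for name, spec in markers.items()})
        raw["scenario"] = sc.validate()
    if "overrides" in raw:
        raw["overrides"] = tuple(tuple(o) for o in raw["overrides"])
    for key in ("scales",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw).validate()


def _coerce(key: str, value):
    if key in ("load_codes", "timepoints") and isinstance(value, list):
        return tuple(value)
    return value
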