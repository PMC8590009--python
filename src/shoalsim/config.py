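"""Structured run configuration: loading, validation, serialization.

A :class:`RunConfig` gathers everything a simulation or analysis needs:
per-age kinematic parameters, simulation settings, retina parameters,
response-curve anchors and analysis options.  Configs load from YAML or JSON
(YAML is a superset of JSON here), reject unknown keys, and round-trip
losslessly through :func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .geometry import RetinaParams
from .responses import GroupDeltaCurve, ResponseCurve, WallResponse


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass
class AgeParams:
    arena_diameter_cm: float
    fish_length_cm: float
    fish_height_cm: float
    bout_rate_hz: float
    bout_size_cm: float


@dataclass
class SimulationSettings:
    dt_s: float = 0.02
    duration_s: float = 600.0
    n_agents: int = 5
    n_repetitions: int = 50
    bout_duration_s: float = 0.32
    start_fraction: float = 0.9
    turn_sigma_deg: float = 30.0
    speed_profile: str = "triangular"


@dataclass
class RetinaSettings:
    eye_separation_cm: float = 0.12
    eye_radius_cm: float = 0.045
    eye_height_cm: float = 0.5
    effective_field_deg: float = 163.0
    vergence_deg: float = 36.0
    ray_span_deg: float = 165.0
    n_rays: int = 1000

    def to_params(self) -> RetinaParams:
        return RetinaParams(
            eye_separation=self.eye_separation_cm,
            eye_radius=self.eye_radius_cm,
            eye_height=self.eye_height_cm,
            effective_field_deg=self.effective_field_deg,
            vergence_deg=self.vergence_deg,
        )


@dataclass
class WallSettings:
    p_max: float = 0.8
    chance_distance_bl: float = 3.0
    engage_distance_bl: float = 2.0

    def to_response(self) -> WallResponse:
        return WallResponse(
            p_max=self.p_max,
            chance_distance_bl=self.chance_distance_bl,
            engage_distance_bl=self.engage_distance_bl,
        )


@dataclass
class GroupCurveSettings:
    style: str = ""
    peak_delta_deg: float = 30.0
    peak_p: float = 0.65
    return_to_chance_deg: float = 90.0


@dataclass
class ResponseSettings:
    vr_curves: dict = field(default_factory=dict)
    wall: WallSettings = field(default_factory=WallSettings)
    group_delta_curves: dict = field(default_factory=dict)


@dataclass
class AnalysisSettings:
    bin_width_deg: float = 5.0
    wall_bin_width_bl: float = 1.0
    wall_exclusion_bl: float = 3.0
    ci_method: str = "clopper-pearson"
    log_base: str = "e"
    n_shuffles: int = 1000
    nn_stride: int = 5


@dataclass
class RunConfig:
    ages: dict = field(default_factory=dict)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    retina: RetinaSettings = field(default_factory=RetinaSettings)
    responses: ResponseSettings = field(default_factory=ResponseSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    # -- convenience accessors -------------------------------------------

    def age_params(self, age: int) -> AgeParams:
        try:
            return self.ages[int(age)]
        except KeyError:
            raise ConfigError(f"ages.{age}: no parameters configured") from None

    def response_curve(self, age: int) -> ResponseCurve:
        anchors = self.responses.vr_curves.get(int(age))
        if anchors is None:
            raise ConfigError(f"responses.vr_curves.{age}: no anchors configured")
        return ResponseCurve(age=int(age), anchors=tuple(tuple(a) for a in anchors))

    def group_delta_curve(self, age: int) -> GroupDeltaCurve:
        s = self.responses.group_delta_curves.get(int(age), GroupCurveSettings())
        return GroupDeltaCurve(
            age=int(age),
            style=s.style,
            peak_delta_deg=s.peak_delta_deg,
            peak_p=s.peak_p,
            return_to_chance_deg=s.return_to_chance_deg,
        )

    def wall_response(self) -> WallResponse:
        return self.responses.wall.to_response()

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


# ---------------------------------------------------------------------------
# parsing / validation


def _build(cls, data, path):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown key")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        kwargs[name] = data[name]
    try:
        return cls(**kwargs)
    except TypeError as exc:  # missing required field
        raise ConfigError(f"{path}: {exc}") from None


def _require_positive(value, key):
    if not isinstance(value, (int, float)) or value <= 0:
        raise ConfigError(f"{key}: must be a positive number, got {value!r}")


def _validate(cfg: RunConfig) -> RunConfig:
    for age, ap in cfg.ages.items():
        for name in (
            "arena_diameter_cm",
            "fish_length_cm",
            "fish_height_cm",
            "bout_rate_hz",
            "bout_size_cm",
        ):
            _require_positive(getattr(ap, name), f"ages.{age}.{name}")
    sim = cfg.simulation
    for name in ("dt_s", "duration_s", "bout_duration_s", "turn_sigma_deg"):
        _require_positive(getattr(sim, name), f"simulation.{name}")
    for name in ("n_agents", "n_repetitions"):
        v = getattr(sim, name)
        if not isinstance(v, int) or v < 1:
            raise ConfigError(f"simulation.{name}: must be a positive integer")
    if not 0 < sim.start_fraction <= 1:
        raise ConfigError("simulation.start_fraction: must lie in (0, 1]")
    if sim.speed_profile not in ("triangular", "instant"):
        raise ConfigError(
            "simulation.speed_profile: must be 'triangular' or 'instant'"
        )
    for age, ap in cfg.ages.items():
        if 1.0 / ap.bout_rate_hz <= sim.bout_duration_s:
            raise ConfigError(
                f"ages.{age}.bout_rate_hz: mean inter-bout interval must "
                "exceed simulation.bout_duration_s"
            )
    ret = cfg.retina
    for name in (
        "eye_separation_cm",
        "eye_radius_cm",
        "eye_height_cm",
        "effective_field_deg",
        "vergence_deg",
        "ray_span_deg",
    ):
        _require_positive(getattr(ret, name), f"retina.{name}")
    if ret.n_rays < 2:
        raise ConfigError("retina.n_rays: must be >= 2")
    ana = cfg.analysis
    for name in ("bin_width_deg", "wall_bin_width_bl"):
        _require_positive(getattr(ana, name), f"analysis.{name}")
    if ana.log_base not in ("e", "2", "10"):
        raise ConfigError("analysis.log_base: must be one of 'e', '2', '10'")
    if ana.ci_method not in ("clopper-pearson", "normal", "wilson"):
        raise ConfigError(
            "analysis.ci_method: must be 'clopper-pearson', 'normal' or 'wilson'"
        )
    # constructing the response objects runs their own invariant checks
    for age in cfg.ages:
        try:
            cfg.response_curve(age)
        except (ConfigError, ValueError) as exc:
            raise ConfigError(f"responses.vr_curves.{age}: {exc}") from None
        cfg.group_delta_curve(age)
    cfg.wall_response()
    cfg.retina.to_params()
    return cfg


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - {"ages", "simulation", "retina", "responses", "analysis"}
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown key")
    ages = {}
    for age, sub in (data.get("ages") or {}).items():
        try:
            key = int(age)
        except (TypeError, ValueError):
            raise ConfigError(f"ages.{age}: age keys must be integers (dpf)")
        ages[key] = _build(AgeParams, sub, f"ages.{age}")
    resp_data = dict(data.get("responses") or {})
    unknown = set(resp_data) - {"vr_curves", "wall", "group_delta_curves"}
    if unknown:
        raise ConfigError(f"responses.{sorted(unknown)[0]}: unknown key")
    vr = {
        int(a): [list(pair) for pair in anchors]
        for a, anchors in (resp_data.get("vr_curves") or {}).items()
    }
    wall = _build(WallSettings, resp_data.get("wall") or {}, "responses.wall")
    gdc = {
        int(a): _build(GroupCurveSettings, sub, f"responses.group_delta_curves.{a}")
        for a, sub in (resp_data.get("group_delta_curves") or {}).items()
    }
    cfg = RunConfig(
        ages=ages,
        simulation=_build(
            SimulationSettings, data.get("simulation") or {}, "simulation"
        ),
        retina=_build(RetinaSettings, data.get("retina") or {}, "retina"),
        responses=ResponseSettings(vr_curves=vr, wall=wall, group_delta_curves=gdc),
        analysis=_build(AnalysisSettings, data.get("analysis") or {}, "analysis"),
    )
    return _validate(cfg)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = cfg.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_config() -> RunConfig:
    """The packaged default configuration."""
    text = resources.files("shoalsim.data").joinpath("default_config.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
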