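"""Run configuration: model variant, behavior mode, parameter blocks, presets."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .chemofield import ChemotaxisParams
from .cpm import CPMParams
from .signaling import SignalingParams
from .sproutgraph import MorphParams

MODEL_VARIANTS = ("contact_inhibition", "cell_elongation")
SIGNALING_MODES = ("off", "dll4_notch", "vegf_dll4_notch")
BEHAVIOR_MODES = ("uniform", "differential_adhesion", "differential_chemosensitivity")


@dataclass
class ScenarioConfig:
    """Complete description of one simulation experiment."""

    model_variant: str = "contact_inhibition"
    signaling: str = "off"
    behavior_mode: str = "uniform"
    mosaic_ratio: float = 1.0           # WT fraction
    lattice_shape: tuple = (400, 400)
    spheroid_radius: int = 45
    cell_width: int = 7
    target_length: float = 25.0          # sites; used by the elongation variant
    duration_mcs: int = 30_000
    analysis_window: tuple = (10_000, 30_000)
    sample_stride: int = 20
    min_sprout_frames: int = 4   # sprouts tracked shorter than this (80 MCS)
                                 # are skeleton transients, not statistics
    occupancy_frames: int = 5    # frames at the run end pooled for
                                 # tip-occupancy scoring
    occupancy_spacing: int = 10  # spacing between pooled frames, in sample
                                 # strides (10 x 20 MCS: beyond the leader
                                 # decorrelation time)
    seeds: tuple = (1,)
    cpm: CPMParams = field(default_factory=CPMParams)
    chemotaxis: ChemotaxisParams | None = None
    field_alpha: float | None = None   # per-variant calibrated default
    field_epsilon: float = 1.8e-4
    field_D: float = 1.0e-13
    field_dt: float = 2.0
    field_steps_per_mcs: int = 15
    signaling_params: SignalingParams = field(default_factory=SignalingParams)
    morph: MorphParams | None = None

    def __post_init__(self) -> None:
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        if self.signaling not in SIGNALING_MODES:
            raise ValueError(f"unknown signaling mode {self.signaling!r}")
        if self.behavior_mode not in BEHAVIOR_MODES:
            raise ValueError(f"unknown behavior mode {self.behavior_mode!r}")
        if not (0.0 <= self.mosaic_ratio <= 1.0):
            raise ValueError("mosaic_ratio must be a fraction in [0, 1]")
        if self.duration_mcs < self.analysis_window[1]:
            raise ValueError("duration must cover the analysis window")
        if len(self.seeds) == 0 or len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be nonempty and distinct")
        if self.morph is None:
            self.morph = (MorphParams.contact_model()
                          if self.model_variant == "contact_inhibition"
                          else MorphParams.elongation_model())
        # variant-specific cell behaviors and calibrated base chemoattraction
        if self.model_variant == "contact_inhibition":
            if self.chemotaxis is None:
                self.chemotaxis = ChemotaxisParams(
                    lambda_c={"tip": 10.0, "stalk": 10.0})
            self.chemotaxis.contact_inhibition = True
            self.cpm.lambda_length = {"tip": 0.0, "stalk": 0.0}
            if self.field_alpha is None:
                # calibrated so the rim chemotaxis bias stays comparable to
                # the interfacial energies (order 1-3 at lambda_c = 10)
                self.field_alpha = 3.6e-4
        else:
            if self.chemotaxis is None:
                self.chemotaxis = ChemotaxisParams(
                    lambda_c={"tip": 10.0, "stalk": 10.0})
            self.chemotaxis.contact_inhibition = False
            if all(v == 0 for v in self.cpm.lambda_length.values()):
                self.cpm.lambda_length = {"tip": 1.0, "stalk": 1.0}
            if self.field_alpha is None:
                self.field_alpha = 1.08e-3

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def desk_preset(**overrides) -> ScenarioConfig:
    """Scaled-down configuration for interactive and CI-scale runs.

    200x200 lattice, spheroid radius 25, 6,000 MCS with the analysis
    window 2,000-6,000; statistics are rescaled to the reference window
    internally, so rates remain comparable across presets.
    """
    base = dict(lattice_shape=(200, 200), spheroid_radius=25,
                duration_mcs=6_000, analysis_window=(2_000, 6_000))
    base.update(overrides)
    return ScenarioConfig(**base)


def full_preset(**overrides) -> ScenarioConfig:
    """Full-scale configuration (400x400 lattice, 30,000 MCS)."""
    return ScenarioConfig(**overrides)


_NESTED = {"cpm": CPMParams, "chemotaxis": ChemotaxisParams,
           "signaling_params": SignalingParams, "morph": MorphParams}


def _build_dataclass(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _NESTED and isinstance(val, dict):
            if key == "cpm" and "J" in val:
                val = dict(val)
                val["J"] = {tuple(k.split(",")): v for k, v in val["J"].items()}
            val = _build_dataclass(_NESTED[key], val)
        elif key in ("lattice_shape", "analysis_window", "seeds") and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path) -> ScenarioConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    preset = data.pop("preset", None)
    if preset == "desk":
        cfg = desk_preset()
        base = _to_plain(cfg)
        base.update(data)
        data = base
    return _build_dataclass(ScenarioConfig, _normalize(data))


def _normalize(data: dict) -> dict:
    out = dict(data)
    cpm = out.get("cpm")
    if isinstance(cpm, dict) and isinstance(cpm.get("J"), dict):
        cpm = dict(cpm)
        cpm["J"] = {(k if isinstance(k, str) else ",".join(k)): v
                    for k, v in cpm["J"].items()}
        out["cpm"] = cpm
    return out


def dump_config(cfg: ScenarioConfig, path) -> None:
    data = _to_plain(cfg)
    data["cpm"]["J"] = {",".join(k): v for k, v in cfg.cpm.J.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
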