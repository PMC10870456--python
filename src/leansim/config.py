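"""Run configuration: a strict, JSON/YAML-loadable schema for the pipeline.

The schema is a tree of frozen dataclasses.  Loading rejects unknown keys
and type-checks every field; numeric invariants are enforced when the
corresponding runtime objects (SimConfig, SegmentationConfig, ...) are
built.  ``config_hash`` fingerprints the canonical serialized form so
every output table can record exactly which configuration produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cohort import CohortSpec
from .errors import ConfigError
from .identify import IdentifyOptions
from .plant import DEFAULT_COM_COEFF, default_plant, derive_anthropometry
from .planning import DEFAULT_SCALE_FRACTION
from .segmentation import SegmentationConfig
from .simulate import SimConfig


@dataclass(frozen=True)
class AnthroSection:
    height_m: float = 1.756
    mass_kg: float = 77.28
    com_coeff: float = DEFAULT_COM_COEFF


@dataclass(frozen=True)
class SimSection:
    prep_s: float = 5.0
    tail_s: float = 2.0
    dt: float = 1.0 / 1600.0
    out_hz: float = 80.0
    blend_direction: str = "narrative"
    noise_sd_cm: float = 0.0


@dataclass(frozen=True)
class SegSection:
    baseline_window_s: float = 5.0
    min_apa_duration_s: float = 0.05
    threshold_floor_cm: float = 1e-4
    lowpass_hz: float | None = None
    filter_order: int = 4
    settle_band_frac: float = 0.10


@dataclass(frozen=True)
class IdentifySection:
    kp_min: float = 5.0
    kp_max: float = 300.0
    kff_min: float = 0.0
    kff_max: float = 30.0
    grid: int = 7
    n_refine: int = 6
    tol: float = 1e-2


@dataclass(frozen=True)
class CohortSection:
    n_per_group: int = 24
    cv: float = 0.15
    repetitions: int = 4
    noise_sd_cm: float = 0.05
    targets: tuple[int, ...] = tuple(range(1, 9))
    within_subject_corr: float = 0.7
    rho_kp_updrs: float = 0.6
    rho_kp_frt: float = -0.6
    rho_kff_updrs: float = -0.6
    rho_kff_frt: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    scale_fraction: float = DEFAULT_SCALE_FRACTION
    anthropometry: AnthroSection = field(default_factory=AnthroSection)
    simulation: SimSection = field(default_factory=SimSection)
    segmentation: SegSection = field(default_factory=SegSection)
    identification: IdentifySection = field(default_factory=IdentifySection)
    cohort: CohortSection = field(default_factory=CohortSection)

    # ---- conversion to runtime objects -------------------------------
    def anthro(self):
        return derive_anthropometry(
            height=self.anthropometry.height_m,
            mass=self.anthropometry.mass_kg,
            com_coeff=self.anthropometry.com_coeff,
        )

    def plant(self):
        return default_plant(self.anthro())

    def sim_config(self) -> SimConfig:
        s = self.simulation
        return SimConfig(
            prep_s=s.prep_s,
            tail_s=s.tail_s,
            dt=s.dt,
            out_hz=s.out_hz,
            blend_direction=s.blend_direction,
            noise_sd_cm=s.noise_sd_cm,
            seed=self.seed,
        )

    def seg_config(self) -> SegmentationConfig:
        s = self.segmentation
        return SegmentationConfig(
            baseline_window_s=s.baseline_window_s,
            min_apa_duration_s=s.min_apa_duration_s,
            threshold_floor_cm=s.threshold_floor_cm,
            lowpass_hz=s.lowpass_hz,
            filter_order=s.filter_order,
            settle_band_frac=s.settle_band_frac,
        )

    def identify_options(self) -> IdentifyOptions:
        s = self.identification
        return IdentifyOptions(
            kp_bounds=(s.kp_min, s.kp_max),
            kff_bounds=(s.kff_min, s.kff_max),
            grid_shape=(s.grid, s.grid),
            n_refine=s.n_refine,
            tol=s.tol,
            sim_config=self.sim_config(),
            seg_config=self.seg_config(),
        )

    def cohort_spec(self) -> CohortSpec:
        c = self.cohort
        return CohortSpec(
            n_per_group=c.n_per_group,
            cv=c.cv,
            seed=self.seed,
            within_subject_corr=c.within_subject_corr,
            rho_kp_updrs=c.rho_kp_updrs,
            rho_kp_frt=c.rho_kp_frt,
            rho_kff_updrs=c.rho_kff_updrs,
            rho_kff_frt=c.rho_kff_frt,
            directions=tuple(c.targets),
        )

    # ---- (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


_SECTIONS = {
    "anthropometry": AnthroSection,
    "simulation": SimSection,
    "segmentation": SegSection,
    "identification": IdentifySection,
    "cohort": CohortSection,
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{path}'")
    kwargs = {}
    for key, value in data.items():
        sub = _SECTIONS.get(key) if cls is RunConfig else None
        if sub is not None:
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif key == "targets" and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{path}': {exc}") from exc


def load_config(path_or_text, overrides: dict | None = None) -> RunConfig:
    """Parse a JSON/YAML config file (or literal text) into a RunConfig.

    ``overrides`` are dotted-path updates (e.g. {"seed": 7,
    "cohort.n_per_group": 3}) applied on top of the file, used by CLI
    flags.
    """
    import os

    if isinstance(path_or_text, (str, os.PathLike)) and os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = str(path_or_text)
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    for dotted, value in (overrides or {}).items():
        node = data
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value
    cfg = _build(RunConfig, data, "root")
    # touch the runtime conversions so invariant violations surface at load
    try:
        cfg.sim_config()
        cfg.seg_config()
        cfg.cohort_spec()
        cfg.anthro()
    except Exception as exc:
        raise ConfigError(f"config fails runtime validation: {exc}") from exc
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Canonical JSON text; parse(dump(cfg)) round-trips exactly."""
    return json.dumps(cfg.to_dict(), indent=2, sort_keys=True, default=list)
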