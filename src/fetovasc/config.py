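"""Run configuration: parameter distributions, YAML round-tripping, pipeline.

Every scalar growth input can be a constant, ``Uniform(lo, hi)`` or
``Normal(μ, σ)``; the YAML syntax is ``{dist: normal|uniform|constant,
params: [...]}`` with bare numbers read as constants.  ``run_pipeline``
executes the staged generation (shape → chorionic → placentone/villous →
full) and writes trees, meshes, metrics and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("fetovasc")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Distribution:
    """A constant, uniform or normal sampling distribution."""

    kind: str  # "constant" | "uniform" | "normal"
    params: tuple

    def __post_init__(self) -> None:
        n_expected = {"constant": 1, "uniform": 2, "normal": 2}
        if self.kind not in n_expected:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        if len(self.params) != n_expected[self.kind]:
            raise ConfigError(f"{self.kind} takes {n_expected[self.kind]} parameters")
        if self.kind == "uniform" and self.params[1] < self.params[0]:
            raise ConfigError("uniform requires lo <= hi")
        if self.kind == "normal" and self.params[1] < 0:
            raise ConfigError("normal requires sd >= 0")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "constant":
            return self.params[0] if size is None else np.full(size, self.params[0])
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], size=size)
        return rng.normal(self.params[0], self.params[1], size=size)

    @property
    def mean(self) -> float:
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return float(self.params[0])

    def to_spec(self):
        if self.kind == "constant":
            return float(self.params[0])
        return {"dist": self.kind, "params": [float(p) for p in self.params]}

    @classmethod
    def from_spec(cls, obj) -> "Distribution":
        if isinstance(obj, Distribution):
            return obj
        if isinstance(obj, (int, float)):
            return cls("constant", (float(obj),))
        if isinstance(obj, dict):
            return cls(str(obj["dist"]), tuple(float(p) for p in obj["params"]))
        raise ConfigError(f"cannot interpret {obj!r} as a distribution")


def constant(x: float) -> Distribution:
    return Distribution("constant", (float(x),))


def uniform(lo: float, hi: float) -> Distribution:
    return Distribution("uniform", (float(lo), float(hi)))


def normal(mu: float, sd: float) -> Distribution:
    return Distribution("normal", (float(mu), float(sd)))


def positive_sample(dist: Distribution, rng: np.random.Generator,
                    floor: float = 1e-6) -> float:
    """Sample with rejection of non-positive draws (for diameters, lengths)."""
    for _ in range(64):
        x = float(dist.sample(rng))
        if x > floor:
            return x
    return floor


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

STAGES = ("shape", "chorionic", "placentone", "villous", "full")


@dataclass
class RunConfig:
    """Everything needed to reproduce a generation run."""

    scenario: str | None = None
    seed: int = 0
    output_dir: str = "fetovasc_out"
    stages: tuple = ("shape",)
    shape: dict = field(default_factory=dict)
    chorionic: dict = field(default_factory=dict)
    placentone: dict = field(default_factory=dict)
    villous: dict = field(default_factory=dict)
    collision_multiplier: float | None = None
    seed_density: float | None = None

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the artifact bundle.

    Returns a dict of in-memory artifacts (trees, domains, summaries); files
    are written under ``config.output_dir`` together with a manifest holding
    the config, seed and package version.
    """
    from . import __version__, chorionic, experiments, geometry, trees, villous

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: dict = {}

    preset = experiments.get_preset(config.scenario) if config.scenario else None

    def _dist(section: dict, key: str, default):
        if key in section:
            return Distribution.from_spec(section[key])
        return default

    wants = set(config.stages)
    if "full" in wants:
        wants.update({"shape"})

    if wants & {"shape", "chorionic"}:
        shape_cfg = dict(config.shape)
        base = preset.shape if preset and preset.shape else {}
        params = geometry.PlacentalShapeParams(
            V=float(_dist(shape_cfg, "V", base.get("V", uniform(400, 500))).sample(rng)),
            r_maj=float(_dist(shape_cfg, "r_maj", base.get("r_maj", normal(9.3, 0.455))).sample(rng)),
            E=float(np.clip(_dist(shape_cfg, "E", base.get("E", normal(0.49, 0.17))).sample(rng), 0.0, 0.95)),
            CCI=float(np.clip(_dist(shape_cfg, "CCI", base.get("CCI", normal(0.36, 0.21))).sample(rng), 0.0, 1.0)),
            m_t=float(_dist(shape_cfg, "m_t", base.get("m_t", constant(20.0))).sample(rng)),
        )
        density = config.seed_density or 13.0
        surface = geometry.build_placental_surface(params, target_seed_density=density)
        surface.export(out / "placental_surface.stl")
        artifacts["shape_params"] = params
        artifacts["surface"] = surface

    if "chorionic" in wants or "full" in wants:
        params = artifacts["shape_params"]
        cp = chorionic.ChorionicGrowthParams.from_dict(config.chorionic)
        if config.collision_multiplier is not None:
            cp.collision_multiplier = config.collision_multiplier
        a_chor = geometry.chorionic_area(params.r_maj, params.r_min, params.t_half)
        plate = geometry.extract_chorionic_plate(artifacts["surface"], a_chor)
        insertion = geometry.locate_cord_insertion(plate, params.CCI, params.r_maj,
                                                   params.m_t, rng)
        tree = chorionic.grow_chorionic_tree(plate, insertion, cp, rng)
        artifacts["plate"] = plate
        artifacts["chorionic_tree"] = tree

    if "full" in wants:
        vp = villous.VillousGrowthParams.from_dict(config.villous)
        tree = villous.grow_full_vasculature(
            artifacts["shape_params"],
            chorionic.ChorionicGrowthParams.from_dict(config.chorionic),
            vp, rng, surface=artifacts.get("surface"))
        artifacts["full_tree"] = tree

    if "placentone" in wants or "villous" in wants:
        vp = villous.VillousGrowthParams.from_dict(config.villous)
        pl = dict(config.placentone)
        base = preset.placentone if preset else {}
        dom = geometry.build_placentone(
            V=float(_dist(pl, "V", Distribution.from_spec(base.get("V", 390.0))).sample(rng)),
            thickness=float(_dist(pl, "thickness", Distribution.from_spec(base.get("thickness", 24.0))).sample(rng)),
            n_p=int(_dist(pl, "n_p", Distribution.from_spec(base.get("n_p", 65))).sample(rng)),
            CC_r=float(_dist(pl, "CC_r", Distribution.from_spec(base.get("CC_r", 1.88))).sample(rng)),
            CC_h=float(_dist(pl, "CC_h", Distribution.from_spec(base.get("CC_h", 5.6))).sample(rng)),
        )
        if preset is not None and preset.villous:
            vp = villous.VillousGrowthParams.from_dict({**preset.villous, **config.villous})
        tree = villous.grow_villous_tree(dom, villous.default_stem(dom, vp, rng), vp, rng)
        dom.surface.export(out / "placentone.stl")
        artifacts["placentone"] = dom
        artifacts["villous_tree"] = tree

    # outputs + manifest
    for name in ("chorionic_tree", "villous_tree", "full_tree"):
        if name in artifacts:
            t = artifacts[name]
            trees.write_swc(t, out / f"{name}.swc")
            trees.write_csv(t, out / f"{name}.csv", out / f"{name}.meta.json")
            vol = artifacts["placentone"].volume if name == "villous_tree" and \
                "placentone" in artifacts else artifacts.get("surface").volume() if \
                artifacts.get("surface") is not None else 1e6
            summary = trees.morphometry_summary(t, vol)
            (out / f"{name}.metrics.json").write_text(
                json.dumps(summary.as_dict(), indent=2))
            artifacts[f"{name}_metrics"] = summary

    manifest = {"config": config.to_dict(), "seed": config.seed,
                "version": __version__,
                "preset_hash": experiments.preset_hash(config.scenario)
                if config.scenario else None}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts
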