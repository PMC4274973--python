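"""Pipeline configuration: YAML in, validated dataclasses out.

A :class:`PipelineConfig` gathers every tunable of a full run -- montage
pairs, window schemes, the ASI signal parameters, quiet-sleep tags, the
window-rejection mode, classification settings, seeds and the output
directory.  Every run writes its resolved configuration (and its hash)
beside the outputs so results are attributable to an exact parameter set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .asi import ASIConfig
from .classify import ClassificationConfig
from .errors import ConfigError
from .pipeline import SCHEMES, WindowScheme
from .records import STANDARD_PAIRS, DerivationPair
from .synthetic import BurstModel, CohortSpec, SynchronyPlant

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_PAIRS_BY_NAME = {p.name: p for p in STANDARD_PAIRS}


@dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run."""

    pairs: tuple[DerivationPair, ...] = STANDARD_PAIRS
    schemes: tuple[WindowScheme, ...] = tuple(SCHEMES.values())
    asi: ASIConfig = ASIConfig()
    classification: ClassificationConfig = ClassificationConfig()
    qs_tags: tuple[str, str] = ("QS1", "QS2")
    rejection_mode: str = "strict"
    seed: int = 0
    outdir: Path = Path("neoasi_out")

    def __post_init__(self) -> None:
        if self.rejection_mode not in ("strict", "tolerant"):
            raise ConfigError(f"unknown rejection mode {self.rejection_mode!r}")
        if len(self.qs_tags) != 2:
            raise ConfigError("exactly two quiet-sleep tags are required")
        self.outdir = Path(self.outdir)

    def to_dict(self) -> dict:
        return {
            "pairs": [p.name for p in self.pairs],
            "schemes": [s.scheme_id for s in self.schemes],
            "asi": dataclasses.asdict(self.asi),
            "classification": dataclasses.asdict(self.classification),
            "qs_tags": list(self.qs_tags),
            "rejection_mode": self.rejection_mode,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }

    def dump(self, path: Path) -> None:
        blob = self.to_dict()
        blob["config_hash"] = config_hash(self)
        path.write_text(yaml.safe_dump(blob, sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _parse_pair(name: str) -> DerivationPair:
    if name in _PAIRS_BY_NAME:
        return _PAIRS_BY_NAME[name]
    raise ConfigError(
        f"unknown derivation pair {name!r}; known: {sorted(_PAIRS_BY_NAME)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Every key is optional; omitted keys keep their defaults.  Unknown keys
    raise :class:`ConfigError` rather than being silently ignored.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"pairs", "schemes", "asi", "classification", "qs_tags",
             "rejection_mode", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "pairs" in raw:
        kwargs["pairs"] = tuple(_parse_pair(n) for n in raw["pairs"])
    if "schemes" in raw:
        try:
            kwargs["schemes"] = tuple(SCHEMES[s] for s in raw["schemes"])
        except KeyError as exc:
            raise ConfigError(f"unknown scheme id {exc.args[0]!r}; "
                              f"known: {sorted(SCHEMES)}") from exc
    if "asi" in raw:
        a = dict(raw["asi"])
        if "band" in a:
            a["band"] = tuple(a["band"])
        try:
            kwargs["asi"] = ASIConfig(**a)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad asi settings: {exc}") from exc
    if "classification" in raw:
        try:
            kwargs["classification"] = ClassificationConfig(**raw["classification"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad classification settings: {exc}") from exc
    for key in ("qs_tags", "rejection_mode", "seed", "outdir"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "qs_tags" else raw[key]
    return PipelineConfig(**kwargs)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a synthetic-cohort specification from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for plant_key in ("plant_normal", "plant_abnormal"):
        if plant_key in raw:
            kwargs[plant_key] = SynchronyPlant(**raw.pop(plant_key))
    if "burst_model" in raw:
        b = dict(raw.pop("burst_model"))
        if "burst_band" in b:
            b["burst_band"] = tuple(b["burst_band"])
        kwargs["burst_model"] = BurstModel(**b)
    if "pma_range" in raw:
        kwargs["pma_range"] = tuple(raw.pop("pma_range"))
    try:
        return CohortSpec(**kwargs, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad cohort spec: {exc}") from exc
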