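"""Pipeline configuration: one YAML document, one key per tunable.

Every analysis constant surfaces here with its default: the 100X minimum
depth, the 2%/5%/10% detection thresholds, the quality filter (radius 5 bp,
minimum quality 30), the permissive (0.5/0.8) and stringent (0.95/0.95)
mapping fractions, the secondary-review entry gate (<10% frequency,
<=1500X average depth), the nearly-complete allowance (<=4 positions) and
the QC kinship cutoff. Configurations round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import Optional

import yaml

from .align import DEFAULT_PARAMS, STRICT_PARAMS, MappingParams
from .call import CallThresholds
from .classify import ReviewCriteria
from .qc import DEFAULT_KINSHIP_CUTOFF
from .reference import CircularRegion

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class QCConfig:
    kinship_cutoff: float = DEFAULT_KINSHIP_CUTOFF
    max_passing_phps: int = 4


@dataclass
class PipelineConfig:
    mapping_default: MappingParams = field(default_factory=lambda: DEFAULT_PARAMS)
    mapping_strict: MappingParams = field(default_factory=lambda: STRICT_PARAMS)
    calling: CallThresholds = field(default_factory=CallThresholds)
    classify: ReviewCriteria = field(default_factory=ReviewCriteria)
    qc: QCConfig = field(default_factory=QCConfig)
    report_thresholds: tuple[float, ...] = (0.02, 0.05, 0.10)
    reference_fasta: Optional[str] = None
    numt_catalog: Optional[str] = None
    php_hotspots: Optional[str] = None
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "mapping": {
                "default": asdict(self.mapping_default),
                "strict": asdict(self.mapping_strict),
            },
            "calling": asdict(self.calling),
            "classify": _criteria_to_dict(self.classify),
            "qc": asdict(self.qc),
            "report": {"thresholds": list(self.report_thresholds)},
            "inputs": {
                "reference_fasta": self.reference_fasta,
                "numt_catalog": self.numt_catalog,
                "php_hotspots": self.php_hotspots,
            },
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        mapping = d.get("mapping", {})
        if "default" in mapping:
            cfg.mapping_default = MappingParams(**mapping["default"])
        if "strict" in mapping:
            cfg.mapping_strict = MappingParams(**mapping["strict"])
        if "calling" in d:
            cfg.calling = CallThresholds(**d["calling"])
        if "classify" in d:
            cfg.classify = _criteria_from_dict(d["classify"])
        if "qc" in d:
            cfg.qc = QCConfig(**d["qc"])
        if "report" in d:
            cfg.report_thresholds = tuple(d["report"].get(
                "thresholds", cfg.report_thresholds))
        inputs = d.get("inputs", {})
        cfg.reference_fasta = inputs.get("reference_fasta")
        cfg.numt_catalog = inputs.get("numt_catalog")
        cfg.php_hotspots = inputs.get("php_hotspots")
        cfg.seed = int(d.get("seed", 0))
        return cfg


def _criteria_to_dict(c: ReviewCriteria) -> dict:
    d = asdict(c)
    d["hotspot_regions"] = [str(r) for r in c.hotspot_regions]
    d["low_band"] = list(c.low_band)
    return d


def _criteria_from_dict(d: dict) -> ReviewCriteria:
    kwargs = dict(d)
    if "hotspot_regions" in kwargs:
        kwargs["hotspot_regions"] = tuple(
            CircularRegion.parse(s) if isinstance(s, str)
            else CircularRegion(**s)
            for s in kwargs["hotspot_regions"]
        )
    if "low_band" in kwargs:
        kwargs["low_band"] = tuple(kwargs["low_band"])
    valid = {f.name for f in fields(ReviewCriteria)}
    return ReviewCriteria(**{k: v for k, v in kwargs.items() if k in valid})


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
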