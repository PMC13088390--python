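"""Pipeline and simulation configuration.

Every printed constant of the inference procedure (kinship window, mismatch
cap, confidence level, calibration settings, the >20 parental-pair exclusion,
the Q > 0.75 cluster rule) lives here with its default, so the standard
procedure is the default behaviour and every deviation is explicit in the
config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class MafSpectrum:
    """Per-locus minor-allele-frequency distribution for founder simulation.

    ``uniform`` draws MAF on [lo, hi]; ``fixed`` uses ``lo`` for every locus.
    """

    kind: str = "uniform"
    lo: float = 0.05
    hi: float = 0.5

    def validate(self) -> None:
        if self.kind not in ("uniform", "fixed"):
            raise ConfigurationError(f"unknown maf_spectrum kind {self.kind!r}")
        if not (0 < self.lo <= 0.5) or not (0 < self.hi <= 0.5):
            raise ConfigurationError("MAF bounds must lie in (0, 0.5]")
        if self.kind == "uniform" and self.lo > self.hi:
            raise ConfigurationError("maf_spectrum lo > hi")

    @property
    def mean(self) -> float:
        return self.lo if self.kind == "fixed" else 0.5 * (self.lo + self.hi)


@dataclass
class SimulationConfig:
    """Synthetic panel generator settings.

    Defaults emulate a 96-SNP cultivar panel: intermediate allele
    frequencies, per-call error 0.01, missing rate 0.0028, a diallelic
    self-incompatibility system (G1/G2), maternally inherited chlorotypes and
    cytoplasmic male sterility carried by the E3.1 lineage.
    """

    n_founders: int = 150
    n_loci: int = 96
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    n_generations: int = 2
    crosses_per_generation: int = 40
    offspring_per_cross: int = 2
    error_rate: float = 0.01
    missing_rate: float = 0.0028
    si_group_assignment: float = 0.5  # P(G1) among founders
    chlorotype_labels: dict[str, float] = field(
        default_factory=lambda: {"E1.1": 0.70, "E1.2": 0.15, "E2": 0.05, "E3.1": 0.10}
    )
    cms_chlorotype: str = "E3.1"
    open_pollination_fraction: float = 0.0
    seed: int = 20260311

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        self.maf_spectrum.validate()
        for name in ("error_rate", "missing_rate", "si_group_assignment",
                     "open_pollination_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.si_group_assignment in (0.0, 1.0) and self.n_founders > 0:
            # Both SI groups must be representable among founders.
            raise ConfigurationError(
                "si_group_assignment must leave both SI groups possible"
            )
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.crosses_per_generation < 1 or self.offspring_per_cross < 1:
            raise ConfigurationError("cross counts must be >= 1")
        freqs = self.chlorotype_labels
        if not freqs or abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("chlorotype frequencies must sum to 1")
        if self.cms_chlorotype not in freqs:
            raise ConfigurationError(
                f"cms_chlorotype {self.cms_chlorotype!r} not in chlorotype_labels"
            )


@dataclass
class CalibrationSettings:
    """Monte-Carlo settings for LOD confidence calibration.

    The defaults are the standard recommended simulation settings:
    10,000 offspring, 200 candidate parents, 30% of candidate parents
    sampled, 80% of loci typed, 1% of loci mistyped.
    """

    n_offspring: int = 10_000
    n_candidate_parents: int = 200
    prop_sampled: float = 0.3
    prop_loci_typed: float = 0.8
    error_rate: float = 0.01
    confidence: float = 0.95
    top_m_pair_candidates: int = 10
    seed: int = 1

    def validate(self) -> None:
        if self.n_offspring < 1:
            raise ConfigurationError("n_offspring must be >= 1")
        if self.n_candidate_parents < 1:
            raise ConfigurationError("n_candidate_parents must be >= 1")
        for name in ("prop_sampled", "prop_loci_typed", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not (0.5 <= self.confidence < 1.0):
            raise ConfigurationError("confidence must lie in [0.5, 1)")
        if self.top_m_pair_candidates < 2:
            raise ConfigurationError("top_m_pair_candidates must be >= 2")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full atlas run."""

    genotypes: str | None = None
    metadata: str | None = None
    out_dir: str = "atlas_out"

    kinship_lo: float = 0.177
    kinship_hi: float = 0.354
    min_compared_loci: int = 20
    max_mismatch: int = 2
    max_supported_pairs: int = 20
    q_threshold: float = 0.75
    max_missing_rate_per_locus: float = 0.5

    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if not (self.kinship_lo < self.kinship_hi):
            raise ConfigurationError("kinship window requires lo < hi")
        if not (0 <= self.kinship_lo and self.kinship_hi <= 0.5):
            raise ConfigurationError("kinship window outside [0, 0.5]")
        if self.max_mismatch < 0:
            raise ConfigurationError("max_mismatch must be >= 0")
        if self.max_supported_pairs < 1:
            raise ConfigurationError("max_supported_pairs must be >= 1")
        if not (0 < self.q_threshold < 1):
            raise ConfigurationError("q_threshold must lie in (0, 1)")
        if self.min_compared_loci < 1:
            raise ConfigurationError("min_compared_loci must be >= 1")
        self.calibration.validate()
        if self.simulation is not None:
            self.simulation.validate()


def _build(cls, data: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    if "calibration" in raw:
        raw["calibration"] = _build(CalibrationSettings, raw["calibration"])
    if raw.get("simulation") is not None:
        sim = dict(raw["simulation"])
        if "maf_spectrum" in sim:
            sim["maf_spectrum"] = _build(MafSpectrum, sim["maf_spectrum"])
        raw["simulation"] = _build(SimulationConfig, sim)
    cfg = _build(PipelineConfig, raw)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
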