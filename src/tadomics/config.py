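"""Run configuration: thresholds, sample handling and chromosome filter."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: chromosomes retained by default (autosomes only)
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class RunConfig:
    """Thresholds and switches shared across the pipeline stages.

    Parameters
    ----------
    alpha_event
        BH-adjusted p-value cutoff for calling an event significant.
    lfc_min
        Minimum |logFC| (group-mean difference on the [0, 100] scale) for an
        event call.
    alpha_tad
        Raw upper-tail hypergeometric p cutoff for calling a TAD significant.
    activation_min
        Minimum TAD activation (mean |logFC| over expression events).
    min_marker_n
        Binary metadata markers present in fewer samples than this are dropped.
    sample_mode
        ``"intersect"`` keeps only samples present in every omics layer;
        ``"union"`` keeps all samples and leaves missing cells NaN (excluded
        pairwise from statistics).
    allowed_chromosomes
        Events elsewhere are dropped at load time.
    beta_autoscale
        Multiply a freq layer by 100 when its maximum is <= 1 (methylation
        beta dialect).
    reverse_features
        Gene-feature classes whose methylation values are inverted
        (``100 - value``) by the methylation-normalisation step.
    promoter_upstream / promoter_downstream
        Promoter window around the TSS, in bases, used for sequence
        extraction of expression events.
    cpg_flank
        Flank, in bases, added on each side of point events before motif
        sequence extraction.
    pwm_hit_fraction
        A motif hit requires a log-odds score of at least this fraction of
        the motif's maximum achievable score.
    seed
        Seed for any stochastic step (synthetic data generation).
    """

    alpha_event: float = 0.01
    lfc_min: float = 2.0
    alpha_tad: float = 0.01
    activation_min: float = 2.0
    min_marker_n: int = 5
    sample_mode: str = "intersect"
    allowed_chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    beta_autoscale: bool = True
    reverse_features: tuple[str, ...] = ("promoter", "intergenic")
    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    cpg_flank: int = 50
    pwm_hit_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_event", "lfc_min", "alpha_tad", "activation_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_mode not in ("intersect", "union"):
            raise ValueError(f"unknown sample_mode {self.sample_mode!r}")
        self.allowed_chromosomes = tuple(self.allowed_chromosomes)
        self.reverse_features = tuple(self.reverse_features)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["allowed_chromosomes"] = list(self.allowed_chromosomes)
        data["reverse_features"] = list(self.reverse_features)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
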