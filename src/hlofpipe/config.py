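"""Run configuration: the filter thresholds and mode switches.

Defaults are the thresholds of the published analysis this pipeline
implements: relative position < 0.9, at least 200 called individuals,
50 bp capture padding, HWE excess-homozygote alpha 0.01 with a 5x depth
floor, 20x minimum depth in a homozygote for novel variants, ROH binomial
alpha 0.1, and 1% phenotype-outlier quantiles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    max_relative_position: float = 0.9
    min_called: int = 200
    capture_pad: int = 50
    hwe_alpha: float = 0.01
    min_depth: int = 5
    min_hom_depth: int = 20
    roh_alpha: float = 0.1
    outlier_quantile: float = 0.01
    # "all": the variant must sit before 90% of EVERY transcript in which it
    # is coding; "any": in at least one transcript.
    relative_position_mode: str = "all"
    # "transcript": frame-restoration judged across all homozygous
    # frameshifts of a transcript; "carrier": only frameshift pairs that are
    # homozygous in a common carrier can rescue one another.
    rescue_mode: str = "transcript"
    # count "called" individuals as non-missing genotypes ("called") or as
    # individuals passing the depth floor ("depth").
    min_samples_mode: str = "called"
    # pool carriers across populations for per-variant ROH-bias
    # classification ("pooled") or classify per population ("per_population")
    roh_bias_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_relative_position <= 1:
            raise ValueError("max_relative_position must be in (0, 1]")
        for name in ("hwe_alpha", "roh_alpha", "outlier_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
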