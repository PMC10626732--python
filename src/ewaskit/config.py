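"""Pipeline configuration with lossless YAML/JSON round-trip.

Every threshold defaults to the value the pipeline's stages document:
detection alpha 0.01, probe-SD floor 0.005, purity minimum 0.9,
family-wise alpha 0.05, GSEA sizes [10, 500] with exponent 1, 10,000
gene permutations and 500 outcome-label permutations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection_alpha: float = 0.01
    greedycut_stop_frac: float = 0.05
    sd_min: float = 0.005
    knn_k: int = 10
    run_bmiq: bool = True
    purity_min: float = 0.9
    alpha: float = 0.05
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_exponent: float = 1.0
    n_perm_genes: int = 10_000
    n_perm_labels: int = 500
    run_gsea: bool = True
    run_label_permutation: bool = True
    run_attenuation: bool = True
    n_gene_sets: int = 100
    n_enriched_sets: int = 5
    gene_set_size_range: tuple[int, int] = (10, 50)
    outdir: str = "ewaskit_results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["probes_per_promoter"] = list(
            d["simulation"]["probes_per_promoter"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("probes_per_promoter", "paired_post_time_range",
                        "time_strata_props"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        for key in ("gene_set_size_range",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(simulation=sim, **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load YAML, falling back to JSON."""
        text = Path(path).read_text()
        try:
            d = yaml.safe_load(text)
        except yaml.YAMLError:
            d = json.loads(text)
        return cls.from_dict(d)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()
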