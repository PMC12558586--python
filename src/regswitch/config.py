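"""Run configuration: one declarative file drives every stage.

Every threshold defaults to the workflow's published value (motif p-value
1e-4, similarity cutoffs 0.5, DEG log2FC 0.5 / adjusted p 0.05, ORA
adjusted p 0.01, cluster-marker adjusted p 0.05, 1000 permutations) and
all randomness flows from one top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # input paths
    windows_fasta: str = "windows.fasta"
    motifs_jaspar: str = "motifs.jaspar"
    genotypes: str = "genotypes.tsv"
    pool_variants: str = "pool_variants.tsv"
    patients: str = "patients.tsv"
    ontology_obo: str = "ontology.obo"
    tf_go: str = "tf_go.tsv"
    gene_go: str = "gene_go.tsv"
    curated_terms: str = "curated_terms.txt"
    deg_tables: dict[str, str] = field(
        default_factory=lambda: {"colon": "deg_colon.tsv", "rectum": "deg_rectum.tsv"}
    )
    outdir: str = "results"

    # motif scanning
    pvalue_threshold: float = 1e-4
    pseudocount: float = 0.8
    grid_step: float = 1e-3

    # filter cascade
    reduction_cutoff: float = 0.5
    contrast_cutoff: float = 0.5
    curated_enabled: bool = True
    enrichment_side: str = "disease"

    # enrichment
    deg_log2fc_min: float = 0.5
    deg_adjp_max: float = 0.05
    ora_adjp_max: float = 0.01

    # patients / clustering
    min_dosage: int = 1
    k_min: int = 2
    k_max: int = 8
    n_init: int = 10
    cluster_adjp_max: float = 0.05

    # permutation
    n_perm: int = 1000
    seed: int = 17

    def validate(self) -> None:
        if not 0 < self.pvalue_threshold <= 1:
            raise ValueError("pvalue_threshold must be in (0, 1]")
        for name in ("reduction_cutoff", "contrast_cutoff", "deg_adjp_max",
                     "ora_adjp_max", "cluster_adjp_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_dosage not in (1, 2):
            raise ValueError("min_dosage (carrier rule) must be 1 or 2")
        if self.enrichment_side not in ("disease", "healthy", "either"):
            raise ValueError("enrichment_side must be disease, healthy or either")
        if self.n_perm < 1 or self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("invalid n_perm or k range")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def resolve(self, base: str | Path) -> "RunConfig":
        """Resolve every relative input path against ``base``."""
        base = Path(base)
        data = asdict(self)
        path_keys = ["windows_fasta", "motifs_jaspar", "genotypes",
                     "pool_variants", "patients", "ontology_obo", "tf_go",
                     "gene_go", "curated_terms", "outdir"]
        for key in path_keys:
            data[key] = str(base / data[key]) if not Path(data[key]).is_absolute() \
                else data[key]
        data["deg_tables"] = {
            t: str(base / p) if not Path(p).is_absolute() else p
            for t, p in self.deg_tables.items()
        }
        return RunConfig(**data)

    def content_hash(self) -> str:
        """Hash of everything the outputs depend on (outdir excluded: the
        same analysis written elsewhere is the same analysis)."""
        data = asdict(self)
        data.pop("outdir")
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
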