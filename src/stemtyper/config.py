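"""Run configuration for the per-sample analysis pipeline.

A :class:`RunConfig` holds every tunable the pipeline consumes: QC
thresholds, the log-normalization scale factor, variable-gene and PCA
dimensions, the clustering resolution, the RNG seed and paths to the
auxiliary gene-set / network / catalog files.  It round-trips losslessly
through JSON so a run can be reproduced from its serialized config alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Configuration of one sample's processing run.

    Defaults follow the permissive ends of the per-sample QC ranges used
    for the cell-line atlas: minimum 1,600 detected features, maximum
    65,000 total counts, and an adaptive mitochondrial cutoff (fallback
    cap 25%).  Normalization uses a scale factor of 10,000; 2,000
    variable genes, 20 principal components and k=20 neighbours feed the
    SNN graph, clustered at the given resolution.
    """

    sample_id: str = "sample"
    min_features: int = 1600
    max_counts: int = 65000
    max_pct_mito: float = 25.0
    adaptive_mito: bool = True
    scale_factor: float = 10000.0
    n_variable_genes: int = 2000
    n_pcs: int = 20
    knn_k: int = 20
    resolution: float = 0.8
    rng_seed: int = 0
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    ppi_path: str | None = None
    surfaceome_path: str | None = None
    fda_catalog_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_features", "max_counts", "n_variable_genes", "n_pcs", "knn_k"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not (0 < self.max_pct_mito <= 100):
            raise ValueError(f"max_pct_mito must lie in (0, 100], got {self.max_pct_mito}")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
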