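"""Run configuration: one structured file covering every pipeline stage.

Defaults follow the published analysis conventions where they are stated
(1000-bp median bins, 50-kb minimum segment length and merge gap limit,
+/-1 SD copy-number classification, recombination-fraction grouping cut-off
0.2, marker-run minimum 3, LOD threshold 5); everything else is this
package's documented choice.  CLI flags override config-file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import SimConfig
from .genome import GenomeConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    # coverage segmentation
    bin_size: int = 1000
    cbs_alpha: float = 0.01
    n_permutations: int = 1000
    min_width_bins: int = 3
    min_segment_length: int = 50_000
    gap_limit: int = 50_000
    mean_tol: float = 0.10
    k_sd: float = 1.0
    # marker classification
    seg_alpha: float = 0.01
    min_lines: int = 20
    # linkage mapping
    rf_cutoff: float = 0.2
    min_informative: int = 20
    # HE calling
    min_run: int = 3
    min_jaccard: float = 0.25
    # QTL
    lod_threshold: float = 5.0
    qtl_step_cm: float = 1.0
    max_cofactors: int = 5
    cofactor_p_entry: float = 1e-3
    window_cm: float = 10.0
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    The YAML mirrors the dataclass layout; the ``sim`` section accepts the
    SimConfig fields, with ``genome`` nested inside it.
    """
    data: dict = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    sim_data = data.pop("sim", {})
    genome_data = sim_data.pop("genome", {}) if isinstance(sim_data, dict) else {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if genome_data:
        sim_data["genome"] = GenomeConfig(**genome_data)
    if sim_data:
        cfg.sim = SimConfig(**sim_data)
    return cfg
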