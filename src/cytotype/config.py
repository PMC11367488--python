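"""YAML run configuration shared by all CLI subcommands.

One file drives a whole run: paths, harmonization, clustering, CAM, stats
and gating parameters plus a single global seed.  Unknown keys are
rejected so typos fail loudly; every run writes the resolved config next
to its outputs for provenance.  The global seed fans out to independent
per-stage streams so a stage rerun in isolation reproduces its output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_seed"]

_STAGES = ("simulate", "preprocess", "cluster", "explore", "annotate", "stats", "gate")


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys under {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    input_folder: str | None = None
    output_dir: str = "cytotype_out"
    reference_csv: str | None = None
    seed: int = 0
    harmonize: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    cam: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    gate: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {f.name for f in fields(cls)}, "top level")
        _check_keys(
            d.get("harmonize", {}),
            {"peaks_per_channel", "density_floor", "merge_gap", "align", "retro",
             "biexp"},
            "harmonize",
        )
        _check_keys(
            d.get("cluster", {}),
            {"k", "pcs", "resolution", "seed", "backend", "n_clusters"},
            "cluster",
        )
        _check_keys(d.get("cam", {}), {"min_corr", "double_gap"}, "cam")
        _check_keys(
            d.get("stats", {}),
            {"group_var", "groups", "n_perm", "n_boot", "label_col", "markers"},
            "stats",
        )
        _check_keys(d.get("gate", {}), {"targets", "beta", "quantile_grid", "label_col"}, "gate")
        _check_keys(
            d.get("simulate", {}),
            {"n_types", "n_markers", "n_samples", "n_cells", "noise_sd", "batch_shift"},
            "simulate",
        )
        return cls(**d)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.yaml").write_text(self.resolved_yaml())


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return RunConfig.from_dict(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([global_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))
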