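"""Run configuration: a single YAML file drives the whole pipeline.

Unknown keys are rejected by name at every level, so typos fail loudly before
any stage runs. Exactly one of a ``simulate`` block (synthetic data) or an
``inputs`` block (paths to real files) must be present.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig, config_from_dict

STAGES = ("simulate", "profile", "metrics", "classify", "seqanalysis")

_INPUT_KEYS = {
    "genome", "annotation", "gro_basal", "gro_treated", "rna_basal", "rna_treated",
    "cage", "chip_histone", "chip_polii", "peaks", "expression", "genome_length",
    "fragment_length",
}


@dataclass
class AnalysisParams:
    """Analysis-window and threshold defaults used across stages."""

    normalization_target: float = 1e7
    promoter_window: int = 1000            # +/- bp around the TSS, inclusive
    profile_span: int = 2000
    profile_bin: int = 25
    enrichment_alpha: float = 0.001
    binding_radius: int = 500
    fold_threshold: float = 3.0
    rpkm_min: float = 0.25
    fdr_max: float = 0.10
    gc_window: tuple[int, int] = (-500, 100)
    tata_window: tuple[int, int] = (-35, -20)
    cage_flank: int = 1000
    cage_cluster_width: int = 100
    motif_file: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("nascentmetrics_out")
    stages: tuple[str, ...] = STAGES
    simulate: SimConfig | None = None
    inputs: dict | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown {context} key(s): {sorted(unknown)}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys(raw, {"seed", "outdir", "stages", "simulate", "inputs", "params"},
                "top-level")

    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_inputs = "inputs" in raw and raw["inputs"] is not None
    if has_sim == has_inputs:
        raise ValueError("exactly one of 'simulate' or 'inputs' must be provided")

    stages = tuple(raw.get("stages", STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}; expected {STAGES}")

    sim = None
    inputs = None
    if has_sim:
        sim_raw = dict(raw["simulate"])
        # the run seed propagates into the generator unless overridden there
        sim_raw.setdefault("seed", int(raw.get("seed", 0)))
        sim = config_from_dict(sim_raw)
    else:
        inputs = dict(raw["inputs"])
        _check_keys(inputs, _INPUT_KEYS, "inputs")
        for key, val in inputs.items():
            if key in ("genome_length", "fragment_length"):
                continue
            if not Path(val).exists():
                raise FileNotFoundError(f"inputs.{key}: {val} does not exist")

    params_raw = dict(raw.get("params") or {})
    _check_keys(params_raw, {f.name for f in dataclasses.fields(AnalysisParams)},
                "params")
    for key in ("gc_window", "tata_window"):
        if key in params_raw:
            params_raw[key] = tuple(params_raw[key])
    params = AnalysisParams(**params_raw)

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "nascentmetrics_out")),
        stages=stages,
        simulate=sim,
        inputs=inputs,
        params=params,
    )
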