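"""Structured run configuration for the end-to-end pipeline.

A single YAML file drives a whole run; one top-level seed deterministically
derives per-stage seeds so a run is reproducible end to end from one
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .brr import BRRModelSpec
from .simulate import SimConfig

STAGES = (
    "simulate",
    "qc",
    "pcoa",
    "adjust",
    "heritability",
    "cross_generation",
    "cross_family",
    "cv",
)


@dataclass
class RunConfig:
    output_dir: str = "tetragp_run"
    seed: int = 0
    # inputs; empty means "simulate them"
    genotypes: str = ""
    phenotypes: str = ""
    sample_meta: str = ""
    sim: SimConfig = field(default_factory=SimConfig)
    max_missing: float = 0.10
    min_maf: float = 0.05
    pcoa_axes: int = 2
    brr: BRRModelSpec = field(default_factory=BRRModelSpec)
    trait: str = "TW"
    cv_folds: int = 5
    cv_reps: int = 100
    cross_family_pair: tuple[str, str] = ("T1-C", "T1-D")
    train_generations: tuple[str, ...] = ("T2", "T3-7")
    test_generations: tuple[str, ...] = ("T1-A", "T1-B", "T1-C", "T1-D", "T1-E")
    include_parents: bool = True

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the top-level seed (< 2**31)."""
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    bad = sorted(set(data) - known)
    if bad:
        raise ValueError(f"unknown key(s) in {context}: {bad}")
    return cls(**data)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    sim_raw = raw.pop("sim", {})
    for key in ("family_sizes", "generation_sizes", "founder_freq_range"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    sim = _build(SimConfig, sim_raw, "sim")
    brr = _build(BRRModelSpec, raw.pop("brr", {}), "brr")
    cfg = _build(RunConfig, raw, "run config")
    cfg.sim = sim
    cfg.brr = brr
    if isinstance(cfg.cross_family_pair, list):
        cfg.cross_family_pair = tuple(cfg.cross_family_pair)
    if isinstance(cfg.train_generations, list):
        cfg.train_generations = tuple(cfg.train_generations)
    if isinstance(cfg.test_generations, list):
        cfg.test_generations = tuple(cfg.test_generations)
    return cfg
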