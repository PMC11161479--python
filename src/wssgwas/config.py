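"""Declarative run configuration.

A single YAML file drives the whole pipeline; every analysis parameter
defaults to the conventional single-step settings (blend alpha/beta
0.95/0.05, CT 1.125 with exponent cap 5, 3 weighting iterations, 1-Mb
windows, top 10 windows, QC at 0.95/0.95/0.05/1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genotypes import QCThresholds
from .mixed_model import DEFAULT_FIXED_EFFECTS


@dataclass
class RemlSettings:
    init: tuple[float, float, float, float] | None = None  # None: fractions of var(y)
    max_iter: int = 200
    tol: float = 1e-4
    method: str = "ai"  # "ai" (fast, EM fallback inside) or "em" (monotone baseline)


@dataclass
class RunConfig:
    # input paths; all None means "simulate" (see simulate section)
    pedigree: str | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    outdir: str = "wssgwas_out"

    qc: QCThresholds = field(default_factory=QCThresholds)
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS
    trait: str = "trait"
    ww_adjust: bool = False  # derive trait from ww_raw/bw/age_days columns

    alpha: float = 0.95
    beta: float = 0.05
    ct: float = 1.125
    cap: float = 5.0
    n_iter: int = 3
    window_bp: int = 1_000_000
    top_k: int = 10
    seed: int = 0
    inbreeding_in_a_inverse: bool = True  # Meuwissen-Luo diagonal (always used)

    reml: RemlSettings = field(default_factory=RemlSettings)
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-10:
            raise ValueError("alpha + beta must equal 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        paths = raw.pop("paths", {})
        kwargs: dict = {}
        for key in ("pedigree", "phenotypes", "genotypes", "outdir"):
            if key in paths:
                kwargs[key] = paths[key]
        if "qc" in raw:
            kwargs["qc"] = QCThresholds(**raw.pop("qc"))
        if "reml" in raw:
            r = raw.pop("reml")
            if r.get("init") is not None:
                r["init"] = tuple(r["init"])
            kwargs["reml"] = RemlSettings(**r)
        model = raw.pop("model", {})
        if "fixed_effects" in model:
            kwargs["fixed_effects"] = tuple(model["fixed_effects"])
        for key in ("trait", "ww_adjust"):
            if key in model:
                kwargs[key] = model[key]
        blend = raw.pop("blend", {})
        for key in ("alpha", "beta"):
            if key in blend:
                kwargs[key] = blend[key]
        gwas = raw.pop("gwas", {})
        for key in ("ct", "cap", "n_iter", "window_bp", "top_k"):
            if key in gwas:
                kwargs[key] = gwas[key]
        for key in ("seed", "simulate", "inbreeding_in_a_inverse"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        return cls(**kwargs)
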