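"""Run configuration for the simulator and the analysis pipeline.

`SimConfig` holds the study-design constants of the semi-natural enclosure
experiment the simulator emulates: nine replicate enclosures of 10 females,
5 sham males and 5 lesioned males, radiotracked twice a day for 18 days on a
33 m x 18 m flag grid. `AnalysisConfig` holds the downstream thresholds
(core inclusion percentage, overlap threshold, parentage delta, minimum typed
loci, genotyping error rate).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimConfig", "AnalysisConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic enclosure study.

    Defaults reproduce the field design: ``n_enclosures`` replicates each
    holding ``females_per_enclosure`` females plus ``lesion_males`` +
    ``sham_males`` males, tracked ``fixes_per_day`` times per day for
    ``days`` days inside a ``grid_width_m`` x ``grid_height_m`` arena.

    Movement is an isotropic bivariate-normal mixture: residents (and
    females) scatter around a single nest centre with standard deviation
    ``resident_sigma_m``; wanderers draw each fix around one of
    ``n_wanderer_centers`` centres with ``wanderer_sigma_m``. For lesioned
    wanderers the dispersion and centre count are shrunk by
    ``lesion_wanderer_shrink`` — the simulator's single dial for the
    space-use contraction observed in lesioned non-paired males
    (1.0 = no effect).
    """

    n_enclosures: int = 9
    females_per_enclosure: int = 10
    lesion_males: int = 5
    sham_males: int = 5
    grid_width_m: float = 33.0
    grid_height_m: float = 18.0
    days: int = 18
    fixes_per_day: int = 2
    p_resident: float = 0.72
    resident_sigma_m: float = 3.0
    wanderer_sigma_m: float = 9.0
    n_wanderer_centers: int = 3
    lesion_wanderer_shrink: float = 0.4
    fix_loss_rate: float = 0.03
    n_loci: int = 41
    alleles_per_locus: int = 6
    dirichlet_concentration: float = 1.0
    litter_size_mean: float = 4.0
    epf_rate: float = 0.36
    genotype_dropout: float = 0.0
    min_nest_separation_m: float = 4.0
    snap_to_metre: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_resident", "lesion_wanderer_shrink", "fix_loss_rate",
                     "epf_rate", "genotype_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("grid_width_m", "grid_height_m", "resident_sigma_m",
                     "wanderer_sigma_m", "min_nest_separation_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_enclosures", "females_per_enclosure", "days",
                     "fixes_per_day", "n_loci", "alleles_per_locus",
                     "n_wanderer_centers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lesion_males < 0 or self.sham_males < 0:
            raise ValueError("male counts must be >= 0")

    @property
    def males_per_enclosure(self) -> int:
        return self.lesion_males + self.sham_males

    @property
    def fixes_per_animal(self) -> int:
        return self.days * self.fixes_per_day

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the downstream analysis stages.

    ``core_percent`` is the fix-inclusion percentage of the peeled-MCP core
    (None = select automatically from the inclusion curve);
    ``overlap_threshold`` is the minimum directed overlap percentage for two
    cores to count as "overlapping"; ``delta_threshold`` is the natural-log
    likelihood gap required to accept a paternity (ln 2 ~ 0.69, i.e. the best
    candidate at least twice as likely as the runner-up); ``min_typed_loci``
    the per-individual typing requirement; ``error_rate`` the assumed
    per-allele genotyping error.
    """

    core_percent: int | None = 75
    min_fixes: int = 28
    overlap_threshold: float = 0.0
    delta_threshold: float = 0.69
    min_typed_loci: int = 20
    error_rate: float = 1e-5

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path) -> tuple[SimConfig, AnalysisConfig]:
    """Read a YAML config holding any mix of SimConfig / AnalysisConfig keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _SIM_FIELDS - _ANALYSIS_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = SimConfig(**{k: v for k, v in raw.items() if k in _SIM_FIELDS})
    ana = AnalysisConfig(**{k: v for k, v in raw.items() if k in _ANALYSIS_FIELDS})
    return sim, ana


def dump_config(sim: SimConfig, ana: AnalysisConfig | None = None) -> str:
    out: dict[str, Any] = sim.to_dict()
    if ana is not None:
        out.update(ana.to_dict())
    return yaml.safe_dump(out, sort_keys=True)
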