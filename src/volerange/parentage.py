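"""Microsatellite paternity assignment and pair-fidelity tabulation.

Mothers are known (embryos are extracted from them); the task is choosing a
sire among the enclosure's candidate males. For each embryo we score every
candidate with a trio log-likelihood ratio (LOD) summed over loci typed in
the whole trio:

    LOD = sum_l  log P(embryo_l | mother_l, candidate_l)
               - log P(embryo_l | mother_l, random male)

Transmission follows Mendel with a simple error model: with probability
(1 - e) a parent transmits one of its two alleles uniformly; with
probability e the transmitted allele is drawn from the population allele
frequencies (e is the assumed genotyping error rate). The random-male null
draws the paternal allele from the population frequencies directly.

The best candidate is accepted only when delta — the LOD gap between the
best and second-best candidate — is at least ln 2 ~ 0.69, i.e. the best
candidate is at least twice as likely as the runner-up; with a single
candidate the LOD itself (the gap to the random-male null) must clear the
same bar. Individuals must be typed at a minimum number of loci (default
20 of 41) to participate.

Accepted paternities are then crossed with the socio-spatial pair bonds:
each reproductively successful resident pair is classified by whether the
male sired only with his partner (male IPF) or also elsewhere (male EPF,
a 'roving resident'), and whether the female's embryos were all sired by
her partner (female IPF) or not (female EPF — her partner is a 'cuckold').
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sociospatial import TacticAssignment

__all__ = [
    "Genotype",
    "LocusFreqs",
    "ParentageAssignment",
    "FidelityTable",
    "genotypes_from_table",
    "estimate_allele_freqs",
    "trio_lod",
    "assign_sires",
    "classify_pair_fidelity",
    "fidelity_from_counts",
    "parentage_table",
    "DELTA_THRESHOLD",
    "MIN_TYPED_LOCI",
]

DELTA_THRESHOLD = round(math.log(2.0), 2)   # 0.69: best at least twice as likely
MIN_TYPED_LOCI = 20

FIDELITY_CATEGORIES = (
    "male_ipf_female_ipf",      # 'true residents'
    "male_ipf_female_epf",      # male cuckolds
    "male_epf_female_ipf",      # 'roving residents'
    "male_epf_female_epf",
)


@dataclass(frozen=True)
class Genotype:
    """Diploid multilocus genotype; ``calls[l]`` is an allele pair or None."""

    animal_id: str
    calls: tuple[tuple[int, int] | None, ...]

    @property
    def n_typed(self) -> int:
        return sum(c is not None for c in self.calls)


def genotypes_from_table(df: pd.DataFrame,
                         id_column: str = "animal_id") -> dict[str, Genotype]:
    """Parse a wide genotype table (locusNN_a / locusNN_b columns).

    A locus with either allele missing is treated as untyped.
    """
    loci = sorted({c[:-2] for c in df.columns if c.startswith("locus")})
    out: dict[str, Genotype] = {}
    for _, row in df.iterrows():
        calls: list[tuple[int, int] | None] = []
        for loc in loci:
            a, b = row[f"{loc}_a"], row[f"{loc}_b"]
            if pd.isna(a) or pd.isna(b):
                calls.append(None)
            else:
                calls.append((int(a), int(b)))
        out[str(row[id_column])] = Genotype(str(row[id_column]), tuple(calls))
    return out


class LocusFreqs:
    """Per-locus allele frequencies with add-one smoothing.

    Frequencies are observed adult allele proportions smoothed by one
    pseudo-count per observed allele; alleles never seen at a locus get the
    single-pseudo-count floor so an embryo carrying one cannot zero out a
    likelihood. Loci typed in no adult are flagged and skipped.
    """

    def __init__(self, freqs: list[dict[int, float] | None],
                 floors: list[float]):
        self.freqs = freqs
        self.floors = floors

    @property
    def n_loci(self) -> int:
        return len(self.freqs)

    def get(self, locus: int, allele: int) -> float:
        f = self.freqs[locus]
        if f is None:
            raise ValueError(f"locus {locus} has no frequency estimate")
        return f.get(allele, self.floors[locus])

    def usable(self, locus: int) -> bool:
        return self.freqs[locus] is not None


def estimate_allele_freqs(adults: dict[str, Genotype]) -> LocusFreqs:
    """Observed allele proportions per locus, add-one smoothed."""
    if not adults:
        raise ValueError("no adult genotypes")
    n_loci = len(next(iter(adults.values())).calls)
    freqs: list[dict[int, float] | None] = []
    floors: list[float] = []
    for l in range(n_loci):
        counts: dict[int, int] = {}
        for g in adults.values():
            call = g.calls[l]
            if call is not None:
                for a in call:
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            freqs.append(None)
            floors.append(0.0)
            continue
        total = sum(counts.values()) + len(counts)
        freqs.append({a: (c + 1) / total for a, c in counts.items()})
        floors.append(1.0 / total)
    return LocusFreqs(freqs, floors)


def _transmission_prob(allele: int, parent: tuple[int, int],
                       freq_of_allele: float, e: float) -> float:
    """P(parent transmits `allele`) under the mixed Mendel/error model."""
    mendel = (0.5 * (parent[0] == allele) + 0.5 * (parent[1] == allele))
    return (1.0 - e) * mendel + e * freq_of_allele


def _pair_prob(embryo: tuple[int, int], p_maternal, p_paternal) -> float:
    """P(unordered embryo pair) given per-allele transmission functions."""
    a, b = embryo
    if a == b:
        return p_maternal(a) * p_paternal(a)
    return p_maternal(a) * p_paternal(b) + p_maternal(b) * p_paternal(a)


def trio_lod(embryo: Genotype, mother: Genotype, candidate: Genotype,
             freqs: LocusFreqs, error_rate: float = 1e-5) -> float:
    """Trio LOD of a candidate sire versus a random male from the population.

    Loci with a missing call anywhere in the trio (or with no frequency
    estimate) are skipped. A Mendelian-incompatible candidate at e = 0
    yields -inf. Raises if no locus is usable.
    """
    e = error_rate
    lod = 0.0
    used = 0
    for l in range(freqs.n_loci):
        ge, gm, gc = embryo.calls[l], mother.calls[l], candidate.calls[l]
        if ge is None or gm is None or gc is None or not freqs.usable(l):
            continue
        used += 1

        def f(a: int, _l=l) -> float:
            return freqs.get(_l, a)

        num = _pair_prob(ge,
                         lambda a: _transmission_prob(a, gm, f(a), e),
                         lambda a: _transmission_prob(a, gc, f(a), e))
        den = _pair_prob(ge,
                         lambda a: _transmission_prob(a, gm, f(a), e),
                         f)
        if num == 0.0:
            return -math.inf
        lod += math.log(num) - math.log(den)
    if used == 0:
        raise ValueError("no usable loci for trio")
    return lod


@dataclass(frozen=True)
class ParentageAssignment:
    """Outcome of sire assignment for one embryo."""

    embryo_id: str
    mother_id: str
    best_sire_id: str | None
    lod_best: float
    delta: float
    assigned: bool
    n_candidates: int


def assign_sires(embryos: dict[str, Genotype],
                 embryo_mothers: dict[str, str],
                 mothers: dict[str, Genotype],
                 candidates: dict[str, Genotype],
                 freqs: LocusFreqs,
                 error_rate: float = 1e-5,
                 delta_threshold: float = DELTA_THRESHOLD,
                 min_typed_loci: int = MIN_TYPED_LOCI
                 ) -> list[ParentageAssignment]:
    """Assign a sire to each embryo by best LOD and the delta criterion.

    ``candidates`` must already be restricted to the embryo's enclosure
    (at most the 10 resident males). Embryos or candidates typed at fewer
    than ``min_typed_loci`` loci are ineligible. With several candidates,
    delta = LOD(best) - LOD(second best); with exactly one eligible
    candidate, delta = LOD(best) (the gap to the random-male null). The
    best candidate is accepted iff delta >= ``delta_threshold`` and its
    LOD is finite.
    """
    out = []
    for eid in sorted(embryos):
        emb = embryos[eid]
        mid = embryo_mothers[eid]
        mother = mothers[mid]
        lods: list[tuple[float, str]] = []
        if emb.n_typed >= min_typed_loci:
            for cid in sorted(candidates):
                cand = candidates[cid]
                if cand.n_typed < min_typed_loci:
                    continue
                try:
                    lod = trio_lod(emb, mother, cand, freqs, error_rate)
                except ValueError:
                    continue
                lods.append((lod, cid))
        if not lods:
            out.append(ParentageAssignment(eid, mid, None, math.nan,
                                           math.nan, False, 0))
            continue
        lods.sort(key=lambda t: (-t[0], t[1]))
        best_lod, best_id = lods[0]
        if len(lods) == 1:
            delta = best_lod
        else:
            second = lods[1][0]
            delta = (math.inf if second == -math.inf and
                     best_lod > -math.inf else best_lod - second)
        assigned = (best_lod > -math.inf and delta >= delta_threshold)
        out.append(ParentageAssignment(
            eid, mid, best_id,
            best_lod, max(delta, 0.0) if math.isfinite(delta) else delta,
            assigned, len(lods)))
    return out


@dataclass(frozen=True)
class FidelityTable:
    """Resident-pair sexual-monogamy counts by category and male surgery."""

    counts: dict[str, dict[str, int]]   # category -> surgery -> count

    @property
    def n_pairs(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def category_total(self, category: str) -> int:
        return sum(self.counts[category].values())

    def proportions(self) -> dict[str, float]:
        """Category proportions over all reproductively successful pairs,
        plus the proportion of pairs with at least one EPF member."""
        n = self.n_pairs
        if n == 0:
            return {c: 0.0 for c in FIDELITY_CATEGORIES} | {"any_epf": 0.0}
        props = {c: self.category_total(c) / n for c in FIDELITY_CATEGORIES}
        props["any_epf"] = 1.0 - props["male_ipf_female_ipf"]
        return props

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions()
        rows = []
        for c in FIDELITY_CATEGORIES:
            rows.append({
                "category": c,
                "sham": self.counts[c].get("sham", 0),
                "lesion": self.counts[c].get("lesion", 0),
                "total": self.category_total(c),
                "proportion": props[c],
            })
        rows.append({"category": "any_epf", "sham": None, "lesion": None,
                     "total": self.n_pairs
                     - self.category_total("male_ipf_female_ipf"),
                     "proportion": props["any_epf"]})
        return pd.DataFrame(rows)


def fidelity_from_counts(counts: dict[str, dict[str, int]]) -> FidelityTable:
    """Build a FidelityTable directly from category x surgery counts."""
    full = {c: dict(counts.get(c, {})) for c in FIDELITY_CATEGORIES}
    return FidelityTable(full)


def classify_pair_fidelity(assignments: list[TacticAssignment],
                           parentage: list[ParentageAssignment],
                           male_surgery: dict[str, str]) -> FidelityTable:
    """Cross accepted paternities with resident pairs.

    Only resident pairs with at least one assigned embryo involving either
    member count. Male IPF iff every embryo assigned to him was mothered by
    his partner; female IPF iff every assigned embryo she mothered was
    sired by her partner.
    """
    sired: dict[str, set[str]] = {}        # male -> mothers of his embryos
    mothered: dict[str, set[str]] = {}     # female -> sires of her embryos
    for p in parentage:
        if not p.assigned:
            continue
        sired.setdefault(p.best_sire_id, set()).add(p.mother_id)
        mothered.setdefault(p.mother_id, set()).add(p.best_sire_id)

    counts: dict[str, dict[str, int]] = {c: {} for c in FIDELITY_CATEGORIES}
    for a in assignments:
        if a.tactic != "resident" or a.partner_id is None:
            continue
        m, f = a.male_id, a.partner_id
        if m not in sired and f not in mothered:
            continue                      # no reproductive success recorded
        male_ipf = sired.get(m, set()) <= {f}
        female_ipf = mothered.get(f, set()) <= {m}
        cat = (f"male_{'ipf' if male_ipf else 'epf'}"
               f"_female_{'ipf' if female_ipf else 'epf'}")
        surgery = male_surgery.get(m, "sham")
        counts[cat][surgery] = counts[cat].get(surgery, 0) + 1
    return FidelityTable(counts)


def parentage_table(parentage: list[ParentageAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "embryo_id": p.embryo_id,
        "mother_id": p.mother_id,
        "best_sire_id": p.best_sire_id,
        "lod_best": p.lod_best,
        "delta": p.delta,
        "assigned": p.assigned,
        "n_candidates": p.n_candidates,
    } for p in parentage])
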