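"""Encounter rates and mating-tactic classification from core home ranges.

The socio-spatial layer turns per-animal core MCPs into pairwise quantities:

- directed overlap: the percentage of a subject's core covered by another
  animal's core;
- PER (pairwise encounter rate) between male i and female j:
  ``%overlap(i|j) * %overlap(j|i) / 100``, a symmetric 0-100 score that is
  large only when each animal's core occupies much of the other's;
- RER (relative encounter rate): a subject's PER with one opposite-sex
  animal divided by the sum of its PERs over all opposite-sex animals in the
  enclosure — the areal probability that an encounter involves that animal.

A male and female are classified as a bonded *resident* pair when each has
RER >= 0.5 for the other; males without such a mutual partner are
*wanderers*. RER_PRIMARY / RER_SECONDARY (largest and second-largest RER)
serve as continuous fidelity measures, and core-overlap counts (partners
excluded on the male-female side) summarise each male's social exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homerange import HomeRange

__all__ = [
    "RERProfile",
    "TacticAssignment",
    "overlap_percent",
    "overlap_matrix",
    "pairwise_encounter_rate",
    "per_matrix",
    "relative_encounter_rate",
    "rer_profiles",
    "classify_tactics",
    "count_home_range_overlaps",
    "analyze_enclosure",
    "tactics_table",
    "rer_long_table",
]

PAIRING_THRESHOLD = 0.5


def overlap_percent(subject: HomeRange, other: HomeRange) -> float:
    """Percentage of the subject's core area covered by the other's core.

    Directed: overlap(A|B) generally differs from overlap(B|A). A
    degenerate subject (area 0) contributes 0.
    """
    if subject.area_m2 <= 0.0 or other.area_m2 <= 0.0:
        return 0.0
    inter = subject.polygon.to_shapely().intersection(
        other.polygon.to_shapely()).area
    return min(100.0 * inter / subject.area_m2, 100.0)


def overlap_matrix(ranges: dict[str, HomeRange]
                   ) -> dict[tuple[str, str], float]:
    """Directed overlap percentages for every ordered pair of animals."""
    ids = sorted(ranges)
    out: dict[tuple[str, str], float] = {}
    for a in ids:
        for b in ids:
            if a != b:
                out[(a, b)] = overlap_percent(ranges[a], ranges[b])
    return out


def pairwise_encounter_rate(overlap_m_to_f: float,
                            overlap_f_to_m: float) -> float:
    """PER: product of the two directed overlap percentages, over 100."""
    if not (0.0 <= overlap_m_to_f <= 100.0 and 0.0 <= overlap_f_to_m <= 100.0):
        raise ValueError("directed overlaps must be percentages in [0, 100]")
    return overlap_m_to_f * overlap_f_to_m / 100.0


def per_matrix(ranges: dict[str, HomeRange], sexes: dict[str, str]
               ) -> dict[tuple[str, str], float]:
    """PER for every male-female pair, keyed (male_id, female_id)."""
    males = sorted(a for a in ranges if sexes[a] == "M")
    females = sorted(a for a in ranges if sexes[a] == "F")
    out = {}
    for m in males:
        for f in females:
            out[(m, f)] = pairwise_encounter_rate(
                overlap_percent(ranges[m], ranges[f]),
                overlap_percent(ranges[f], ranges[m]))
    return out


@dataclass(frozen=True)
class RERProfile:
    """One animal's normalised encounter-rate vector over the opposite sex."""

    subject_id: str
    rer: dict[str, float]
    per: dict[str, float]
    rer_primary: float
    primary_id: str | None
    rer_secondary: float
    secondary_id: str | None


def relative_encounter_rate(subject_id: str,
                            per_row: dict[str, float]) -> RERProfile:
    """Normalise a subject's PER row to RERs and extract primary/secondary.

    If every PER is zero the profile is all-zero with no primary. Primary
    and secondary are the two largest RERs; ties break by larger raw PER,
    then by smaller id.
    """
    if any(v < 0 for v in per_row.values()):
        raise ValueError("PER scores must be non-negative")
    total = sum(per_row.values())
    if total <= 0.0:
        rer = {k: 0.0 for k in per_row}
        return RERProfile(subject_id, rer, dict(per_row), 0.0, None, 0.0, None)
    rer = {k: v / total for k, v in per_row.items()}
    ranked = sorted(rer, key=lambda k: (-rer[k], -per_row[k], k))
    primary = ranked[0]
    secondary = ranked[1] if len(ranked) > 1 else None
    return RERProfile(
        subject_id=subject_id,
        rer=rer,
        per=dict(per_row),
        rer_primary=rer[primary],
        primary_id=primary,
        rer_secondary=rer[secondary] if secondary is not None else 0.0,
        secondary_id=secondary,
    )


def rer_profiles(per: dict[tuple[str, str], float]
                 ) -> tuple[dict[str, RERProfile], dict[str, RERProfile]]:
    """Male and female RER profiles from a (male, female) -> PER mapping."""
    male_rows: dict[str, dict[str, float]] = {}
    female_rows: dict[str, dict[str, float]] = {}
    for (m, f), v in per.items():
        male_rows.setdefault(m, {})[f] = v
        female_rows.setdefault(f, {})[m] = v
    males = {m: relative_encounter_rate(m, row)
             for m, row in sorted(male_rows.items())}
    females = {f: relative_encounter_rate(f, row)
               for f, row in sorted(female_rows.items())}
    return males, females


@dataclass(frozen=True)
class TacticAssignment:
    """Resident-with-partner or wanderer label for one male."""

    male_id: str
    tactic: str                       # 'resident' or 'wanderer'
    partner_id: str | None
    rer_primary: float
    rer_secondary: float
    n_male_overlaps: int = 0
    n_female_overlaps_excl_partner: int = 0
    n_total_overlaps: int = 0


def classify_tactics(male_profiles: dict[str, RERProfile],
                     female_profiles: dict[str, RERProfile],
                     threshold: float = PAIRING_THRESHOLD
                     ) -> list[TacticAssignment]:
    """Label each male resident (with partner) or wanderer.

    Male m and female f are paired iff rer_m(f) >= threshold AND
    rer_f(m) >= threshold (boundary inclusive). Because RERs sum to one, a
    male can meet the criterion with two females only on an exact 0.5 tie;
    such ties resolve by larger raw PER, then smaller female id. The
    resulting pairing is a partial matching: no animal is partnered twice.
    """
    assignments = []
    claimed: set[str] = set()
    for m in sorted(male_profiles):
        prof = male_profiles[m]
        candidates = [
            f for f, r in prof.rer.items()
            if r >= threshold and f in female_profiles
            and female_profiles[f].rer.get(m, 0.0) >= threshold
            and f not in claimed
        ]
        partner = None
        if candidates:
            partner = min(candidates,
                          key=lambda f: (-prof.rer[f], -prof.per[f], f))
            claimed.add(partner)
        assignments.append(TacticAssignment(
            male_id=m,
            tactic="resident" if partner is not None else "wanderer",
            partner_id=partner,
            rer_primary=prof.rer_primary,
            rer_secondary=prof.rer_secondary,
        ))
    return assignments


def count_home_range_overlaps(assignments: list[TacticAssignment],
                              overlaps: dict[tuple[str, str], float],
                              sexes: dict[str, str],
                              threshold: float = 0.0
                              ) -> list[TacticAssignment]:
    """Attach core-overlap counts to each male's assignment.

    An individual counts as overlapping a male when the directed overlap
    exceeds ``threshold`` percent in either direction. Partners of resident
    males are excluded from the male-female count (and from the total), as
    a bonded pair's near-total overlap is not 'extra' social exposure.
    """
    out = []
    for a in assignments:
        m = a.male_id
        others = {x for pair in overlaps for x in pair if m in pair} - {m}
        def _overlapping(x: str) -> bool:
            return (overlaps.get((m, x), 0.0) > threshold
                    or overlaps.get((x, m), 0.0) > threshold)
        n_mm = sum(1 for x in others if sexes[x] == "M" and _overlapping(x))
        n_mf = sum(1 for x in others
                   if sexes[x] == "F" and x != a.partner_id
                   and _overlapping(x))
        out.append(TacticAssignment(
            male_id=a.male_id, tactic=a.tactic, partner_id=a.partner_id,
            rer_primary=a.rer_primary, rer_secondary=a.rer_secondary,
            n_male_overlaps=n_mm,
            n_female_overlaps_excl_partner=n_mf,
            n_total_overlaps=n_mm + n_mf,
        ))
    return out


def analyze_enclosure(ranges: dict[str, HomeRange], sexes: dict[str, str],
                      overlap_threshold: float = 0.0
                      ) -> tuple[list[TacticAssignment],
                                 dict[str, RERProfile],
                                 dict[str, RERProfile],
                                 dict[tuple[str, str], float]]:
    """Full socio-spatial analysis of one enclosure's core home ranges."""
    per = per_matrix(ranges, sexes)
    male_profiles, female_profiles = rer_profiles(per)
    assignments = classify_tactics(male_profiles, female_profiles)
    overlaps = overlap_matrix(ranges)
    assignments = count_home_range_overlaps(
        assignments, overlaps, sexes, threshold=overlap_threshold)
    return assignments, male_profiles, female_profiles, per


def tactics_table(assignments: list[TacticAssignment],
                  ranges: dict[str, HomeRange] | None = None,
                  meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy per-male table (the contract for any external model fitting)."""
    rows = []
    for a in assignments:
        row = {
            "male_id": a.male_id,
            "tactic": a.tactic,
            "partner_id": a.partner_id,
            "rer_primary": a.rer_primary,
            "rer_secondary": a.rer_secondary,
            "n_male_overlaps": a.n_male_overlaps,
            "n_female_overlaps_excl_partner": a.n_female_overlaps_excl_partner,
            "n_total_overlaps": a.n_total_overlaps,
        }
        if ranges is not None and a.male_id in ranges:
            row["area_m2"] = ranges[a.male_id].area_m2
        rows.append(row)
    df = pd.DataFrame(rows)
    if meta is not None:
        df = df.merge(meta, left_on="male_id", right_on="animal_id",
                      how="left").drop(columns=["animal_id"])
    return df.sort_values("male_id", ignore_index=True)


def rer_long_table(male_profiles: dict[str, RERProfile],
                   female_profiles: dict[str, RERProfile]) -> pd.DataFrame:
    """Long-form PER/RER table over both sexes' profiles."""
    rows = []
    for profs in (male_profiles, female_profiles):
        for sid in sorted(profs):
            p = profs[sid]
            for other in sorted(p.rer):
                rows.append({"subject_id": sid, "other_id": other,
                             "per": p.per[other], "rer": p.rer[other]})
    return pd.DataFrame(rows)
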