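"""End-to-end pipeline: fixes + genotypes -> tactics, parentage, report.

Chains the stages per enclosure — core home ranges at the configured (or
automatically selected) inclusion percentage, encounter-rate tactic
classification, paternity assignment, fidelity tabulation — then pools the
per-male tables, attaches reproductive-success features (number of mating
partners = distinct mothers of embryos assigned to a male; number of
offspring sired = embryos assigned to him) and runs the exact tests and the
PCA screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import homerange as hr
from . import parentage as par
from . import sociospatial as soc
from . import stats_report as sr
from .config import AnalysisConfig

__all__ = ["PipelineResult", "run_pipeline", "male_feature_table"]


@dataclass
class PipelineResult:
    """All pooled outputs of one pipeline run."""

    core_percent: int
    homeranges: pd.DataFrame
    tactics: pd.DataFrame
    rer: pd.DataFrame
    parentage: pd.DataFrame
    fidelity: par.FidelityTable
    tests: list[sr.TestResult] = field(default_factory=list)
    pca: sr.PCAResult | None = None
    report: str = ""
    ranges_by_enclosure: dict[str, dict[str, hr.HomeRange]] = field(
        default_factory=dict)

    def write(self, out: str | Path) -> None:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        self.homeranges.to_csv(outdir / "homeranges.csv", index=False)
        self.tactics.to_csv(outdir / "tactics.csv", index=False)
        self.rer.to_csv(outdir / "rer_matrix.csv", index=False)
        self.parentage.to_csv(outdir / "parentage.csv", index=False)
        self.fidelity.to_frame().to_csv(outdir / "fidelity_table.csv",
                                        index=False)
        if self.tests:
            pd.DataFrame([{
                "test": t.test_name, "statistic": t.statistic,
                "p_value": t.p_value, "inputs": str(t.inputs)}
                for t in self.tests]).to_csv(outdir / "tests.csv", index=False)
        if self.pca is not None:
            self.pca.loadings_frame().to_csv(outdir / "pca_loadings.csv")
            pd.DataFrame(self.pca.scores, columns=[
                f"PC{j + 1}" for j in range(self.pca.scores.shape[1])
            ]).to_csv(outdir / "pca_scores.csv", index=False)
        (outdir / "report.md").write_text(self.report)
        wkt_lines = []
        for enc in sorted(self.ranges_by_enclosure):
            for aid, h in sorted(self.ranges_by_enclosure[enc].items()):
                wkt_lines.append(f"{aid}\t{h.polygon.to_wkt()}")
        (outdir / "homeranges.wkt").write_text("\n".join(wkt_lines) + "\n")


def male_feature_table(tactics: pd.DataFrame,
                       parentage: pd.DataFrame) -> pd.DataFrame:
    """Per-male feature table for the PCA screen.

    Features: core area, same-sex and (non-partner) opposite-sex overlap
    counts, number of mating partners, number of offspring sired,
    RER_PRIMARY and RER_SECONDARY.
    """
    assigned = parentage[parentage["assigned"] == True]  # noqa: E712
    n_off = assigned.groupby("best_sire_id").size()
    n_partners = assigned.groupby("best_sire_id")["mother_id"].nunique()
    feats = tactics.set_index("male_id")
    out = pd.DataFrame({
        "area_m2": feats["area_m2"],
        "n_male_overlaps": feats["n_male_overlaps"],
        "n_female_overlaps": feats["n_female_overlaps_excl_partner"],
        "n_mating_partners": n_partners.reindex(feats.index).fillna(0),
        "n_offspring_sired": n_off.reindex(feats.index).fillna(0),
        "rer_primary": feats["rer_primary"],
        "rer_secondary": feats["rer_secondary"],
    })
    return out.reset_index()


def run_pipeline(fixes: pd.DataFrame, adults: pd.DataFrame,
                 embryos: pd.DataFrame,
                 analysis: AnalysisConfig | None = None,
                 config_echo: dict | None = None) -> PipelineResult:
    """Run the complete analysis on a dataset (simulated or field-format)."""
    ana = analysis or AnalysisConfig()

    # --- core inclusion percentage ---------------------------------------
    if ana.core_percent is None:
        curve = hr.core_inclusion_curve(fixes, min_fixes=ana.min_fixes)
        core_percent = hr.select_core_percentage(curve)
    else:
        core_percent = int(ana.core_percent)

    meta = (fixes[["animal_id", "enclosure_id", "sex", "surgery"]]
            .drop_duplicates("animal_id"))
    sex_of = dict(zip(meta["animal_id"], meta["sex"]))
    surgery_of = dict(zip(meta["animal_id"], meta["surgery"]))

    # --- per-enclosure socio-spatial analysis ----------------------------
    tactics_parts, rer_parts, hr_parts = [], [], []
    ranges_by_enc: dict[str, dict[str, hr.HomeRange]] = {}
    assignments_all: list[soc.TacticAssignment] = []
    for enc, fx in fixes.groupby("enclosure_id", sort=True):
        ranges = hr.home_ranges_for_table(fx, core_percent,
                                          min_fixes=ana.min_fixes)
        ranges_by_enc[str(enc)] = ranges
        assignments, male_prof, female_prof, _ = soc.analyze_enclosure(
            ranges, {a: sex_of[a] for a in ranges},
            overlap_threshold=ana.overlap_threshold)
        assignments_all.extend(assignments)
        tab = soc.tactics_table(assignments, ranges)
        tab.insert(0, "enclosure_id", str(enc))
        tactics_parts.append(tab)
        rer = soc.rer_long_table(male_prof, female_prof)
        rer.insert(0, "enclosure_id", str(enc))
        rer_parts.append(rer)
        htab = hr.home_range_table(ranges)
        htab.insert(0, "enclosure_id", str(enc))
        hr_parts.append(htab)
    tactics = pd.concat(tactics_parts, ignore_index=True)
    tactics["surgery"] = tactics["male_id"].map(surgery_of)
    rer_long = pd.concat(rer_parts, ignore_index=True)
    homeranges = pd.concat(hr_parts, ignore_index=True)

    # --- parentage per enclosure -----------------------------------------
    adult_geno = par.genotypes_from_table(adults)
    embryo_geno = par.genotypes_from_table(embryos, id_column="embryo_id")
    freqs = par.estimate_allele_freqs(adult_geno)
    embryo_mothers = dict(zip(embryos["embryo_id"], embryos["mother_id"]))
    adult_enc = dict(zip(adults["animal_id"], adults["enclosure_id"]))
    adult_sex = dict(zip(adults["animal_id"], adults["sex"]))
    parent_parts: list[par.ParentageAssignment] = []
    for enc, emb_rows in embryos.groupby("enclosure_id", sort=True):
        emb_ids = list(emb_rows["embryo_id"])
        cands = {aid: g for aid, g in adult_geno.items()
                 if adult_enc.get(aid) == enc and adult_sex.get(aid) == "M"}
        mothers = {aid: g for aid, g in adult_geno.items()
                   if adult_enc.get(aid) == enc and adult_sex.get(aid) == "F"}
        parent_parts.extend(par.assign_sires(
            {e: embryo_geno[e] for e in emb_ids},
            {e: embryo_mothers[e] for e in emb_ids},
            mothers, cands, freqs,
            error_rate=ana.error_rate,
            delta_threshold=ana.delta_threshold,
            min_typed_loci=ana.min_typed_loci))
    parentage = par.parentage_table(parent_parts)

    fidelity = par.classify_pair_fidelity(assignments_all, parent_parts,
                                          surgery_of)

    # --- exact tests and PCA ---------------------------------------------
    n_res = int((tactics["tactic"] == "resident").sum())
    n_wan = len(tactics) - n_res
    tests = [sr.sign_test_two_tailed(n_res, n_wan)]
    ct = tactics.groupby("surgery")["tactic"].value_counts().unstack(
        fill_value=0)
    if {"sham", "lesion"} <= set(ct.index) and \
            {"resident", "wanderer"} <= set(ct.columns):
        tests.append(sr.fisher_exact_2x2(
            int(ct.loc["sham", "resident"]), int(ct.loc["sham", "wanderer"]),
            int(ct.loc["lesion", "resident"]),
            int(ct.loc["lesion", "wanderer"])))

    pca = None
    feats = male_feature_table(tactics, parentage)
    try:
        pca = sr.pca_stage(feats.drop(columns=["male_id"]))
    except ValueError:
        pass

    report = sr.build_report(tactics, fidelity.to_frame(), tests, pca,
                             config=(config_echo or {})
                             | {"core_percent": core_percent})
    return PipelineResult(
        core_percent=core_percent,
        homeranges=homeranges,
        tactics=tactics,
        rer=rer_long,
        parentage=parentage,
        fidelity=fidelity,
        tests=tests,
        pca=pca,
        report=report,
        ranges_by_enclosure=ranges_by_enc,
    )
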