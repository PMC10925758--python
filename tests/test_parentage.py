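"""Tests of trio-likelihood paternity and pair-fidelity tabulation."""

import math

import numpy as np
import pytest
from scipy import stats

from volerange import SimConfig, simdata
from volerange import parentage as par
from volerange.sociospatial import TacticAssignment


def geno(aid, calls):
    return par.Genotype(aid, tuple(calls))


def uniform_freqs(n_loci, alleles):
    f = 1.0 / len(alleles)
    return par.LocusFreqs([{a: f for a in alleles}] * n_loci,
                          [f / 10] * n_loci)


# ----------------------------------------------------------------- oracle --

def trio_lod_oracle(embryo, mother, candidate, freqs, e):
    """Exhaustive enumeration over all transmission events at each locus.

    Each parent transmits either one of its two alleles (Mendelian route,
    probability (1-e)/2 each) or a population allele a (error route,
    probability e*f(a)). The locus likelihood sums the probability of every
    event combination producing the embryo's unordered pair; the null
    replaces the paternal side by a population draw.
    """
    lod = 0.0
    for l in range(freqs.n_loci):
        ge, gm, gc = embryo.calls[l], mother.calls[l], candidate.calls[l]
        if ge is None or gm is None or gc is None:
            continue
        alleles = list(freqs.freqs[l])

        def routes(parent):
            out = []
            for a in parent:
                out.append((a, (1 - e) / 2))
            for a in alleles:
                out.append((a, e * freqs.get(l, a)))
            return out

        def pair_prob(maternal_routes, paternal_routes):
            total = 0.0
            target = frozenset(ge)
            for (am, pm_) in maternal_routes:
                for (ap, pp_) in paternal_routes:
                    if frozenset((am, ap)) == target:
                        total += pm_ * pp_
            return total

        null_paternal = [(a, freqs.get(l, a)) for a in alleles]
        num = pair_prob(routes(gm), routes(gc))
        den = pair_prob(routes(gm), null_paternal)
        if num == 0.0:
            return -math.inf
        lod += math.log(num / den)
    return lod


# ------------------------------------------------------------------ tests --

class TestAlleleFreqs:
    def test_monomorphic_locus_near_one(self):
        adults = {f"a{i}": geno(f"a{i}", [(1, 1)]) for i in range(10)}
        freqs = par.estimate_allele_freqs(adults)
        assert freqs.get(0, 1) == pytest.approx(1.0, abs=0.05)

    def test_balanced_locus_half_half(self):
        adults = {"a": geno("a", [(1, 1)]), "b": geno("b", [(2, 2)])}
        freqs = par.estimate_allele_freqs(adults)
        assert freqs.get(0, 1) == pytest.approx(0.5)
        assert freqs.get(0, 2) == pytest.approx(0.5)

    def test_untyped_locus_flagged(self):
        adults = {"a": geno("a", [(1, 2), None])}
        freqs = par.estimate_allele_freqs(adults)
        assert freqs.usable(0) and not freqs.usable(1)

    def test_matches_simulator_truth(self):
        """Estimated frequencies are consistent with the Dirichlet draw the
        simulator used (chi-square goodness of fit at alpha 0.01)."""
        cfg = SimConfig(n_enclosures=3, seed=23)
        agents = simdata.generate_population(cfg)
        adults_df, _ = simdata.simulate_matings_and_genotypes(agents, cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(3)[2])
        true_freqs = rng.dirichlet(
            np.full(cfg.alleles_per_locus, 1.0), size=cfg.n_loci)
        loci = [c[:-2] for c in adults_df.columns
                if c.startswith("locus") and c.endswith("_a")]
        n_adults = len(adults_df)
        rejected = 0
        for l, loc in enumerate(loci):
            obs = np.zeros(cfg.alleles_per_locus)
            for suffix in ("_a", "_b"):
                for v in adults_df[f"{loc}{suffix}"]:
                    obs[int(v) - 1] += 1
            expected = true_freqs[l] * 2 * n_adults
            keep = expected > 1.0
            chi2 = ((obs[keep] - expected[keep]) ** 2
                    / expected[keep]).sum()
            p = stats.chi2.sf(chi2, keep.sum() - 1)
            rejected += p < 0.01
        # at alpha = 0.01 over 41 loci, a couple of rejections may occur
        assert rejected <= 3


class TestTrioLod:
    def test_incompatible_candidate_minus_infinity(self):
        freqs = uniform_freqs(5, [1, 2, 3, 4])
        mother = geno("m", [(1, 1)] * 5)
        embryo = geno("e", [(1, 2)] * 5)
        candidate = geno("c", [(3, 4)] * 5)   # cannot transmit allele 2
        assert par.trio_lod(embryo, mother, candidate, freqs,
                            error_rate=0.0) == -math.inf

    def test_population_average_candidate_scores_zero(self):
        # candidate heterozygous 1/2 at a locus with f(1)=f(2)=0.5 transmits
        # exactly like a random male, so every locus contributes LOD 0
        freqs = uniform_freqs(4, [1, 2])
        mother = geno("m", [(1, 2)] * 4)
        embryo = geno("e", [(1, 2)] * 4)
        candidate = geno("c", [(1, 2)] * 4)
        assert par.trio_lod(embryo, mother, candidate, freqs,
                            error_rate=0.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("e", [0.0, 1e-5, 0.01])
    def test_matches_enumeration_oracle(self, e, rng):
        alleles = [1, 2, 3, 4]
        freqs = par.LocusFreqs(
            [dict(zip(alleles, rng.dirichlet(np.ones(4))))
             for _ in range(5)],
            [1e-3] * 5)
        for _ in range(10):
            def draw():
                return tuple(
                    tuple(rng.choice(alleles, 2)) for _ in range(5))
            mother, candidate = geno("m", draw()), geno("c", draw())
            embryo_calls = []
            for l in range(5):
                embryo_calls.append((mother.calls[l][rng.integers(2)],
                                     candidate.calls[l][rng.integers(2)]))
            embryo = geno("e", tuple(embryo_calls))
            got = par.trio_lod(embryo, mother, candidate, freqs, e)
            want = trio_lod_oracle(embryo, mother, candidate, freqs, e)
            assert got == pytest.approx(want, rel=1e-9)

    def test_skips_loci_with_missing_calls(self):
        freqs = uniform_freqs(2, [1, 2])
        mother = geno("m", [(1, 1), None])
        embryo = geno("e", [(1, 1), (1, 2)])
        candidate = geno("c", [(1, 1), (2, 2)])
        lod = par.trio_lod(embryo, mother, candidate, freqs, 0.0)
        assert math.isfinite(lod)

    def test_no_usable_loci_raises(self):
        freqs = uniform_freqs(1, [1, 2])
        with pytest.raises(ValueError):
            par.trio_lod(geno("e", [None]), geno("m", [(1, 1)]),
                         geno("c", [(1, 1)]), freqs, 0.0)


class TestAssignSires:
    def make_freqs(self):
        return uniform_freqs(25, [1, 2, 3, 4])

    def test_single_compatible_candidate_assigned(self):
        freqs = self.make_freqs()
        mother = geno("m", [(1, 1)] * 25)
        embryo = geno("e", [(1, 2)] * 25)
        good = geno("good", [(2, 2)] * 25)
        bad = geno("bad", [(3, 4)] * 25)
        out = par.assign_sires({"e": embryo}, {"e": "m"}, {"m": mother},
                               {"good": good, "bad": bad}, freqs,
                               error_rate=0.0)
        assert out[0].assigned and out[0].best_sire_id == "good"
        assert out[0].delta == math.inf

    def test_identical_candidates_never_assigned(self):
        freqs = self.make_freqs()
        mother = geno("m", [(1, 1)] * 25)
        embryo = geno("e", [(1, 2)] * 25)
        twin1 = geno("t1", [(2, 3)] * 25)
        twin2 = geno("t2", [(2, 3)] * 25)
        out = par.assign_sires({"e": embryo}, {"e": "m"}, {"m": mother},
                               {"t1": twin1, "t2": twin2}, freqs,
                               error_rate=1e-5)
        assert out[0].delta == pytest.approx(0.0, abs=1e-12)
        assert not out[0].assigned

    def test_min_typed_loci_enforced(self):
        freqs = self.make_freqs()
        mother = geno("m", [(1, 1)] * 25)
        embryo = geno("e", [(1, 2)] * 10 + [None] * 15)   # 10 < 20 typed
        cand = geno("c", [(2, 2)] * 25)
        out = par.assign_sires({"e": embryo}, {"e": "m"}, {"m": mother},
                               {"c": cand}, freqs, error_rate=0.0)
        assert not out[0].assigned and out[0].n_candidates == 0

    def test_mendelian_incompatible_never_assigned_at_zero_error(self):
        cfg = SimConfig(n_enclosures=1, seed=31)
        agents = simdata.generate_population(cfg)
        adults_df, embryos_df = simdata.simulate_matings_and_genotypes(
            agents, cfg)
        adults = par.genotypes_from_table(adults_df)
        embryos = par.genotypes_from_table(embryos_df,
                                           id_column="embryo_id")
        freqs = par.estimate_allele_freqs(adults)
        sex = dict(zip(adults_df.animal_id, adults_df.sex))
        males = {a: g for a, g in adults.items() if sex[a] == "M"}
        mothers = {a: g for a, g in adults.items() if sex[a] == "F"}
        emb_mothers = dict(zip(embryos_df.embryo_id, embryos_df.mother_id))
        out = par.assign_sires(embryos, emb_mothers, mothers, males, freqs,
                               error_rate=0.0)
        truth = dict(zip(embryos_df.embryo_id, embryos_df.true_sire_id))
        for p in out:
            if p.assigned:
                # with e = 0 an accepted sire must be Mendelian-compatible
                # at every typed locus; the planted sire always is
                assert p.best_sire_id == truth[p.embryo_id]


class TestFidelity:
    def test_reference_count_table(self):
        ft = par.fidelity_from_counts({
            "male_ipf_female_ipf": {"sham": 12, "lesion": 9},
            "male_ipf_female_epf": {"sham": 6, "lesion": 3},
            "male_epf_female_ipf": {"sham": 2, "lesion": 1},
        })
        assert ft.n_pairs == 33
        props = ft.proportions()
        assert props["male_ipf_female_ipf"] == pytest.approx(21 / 33)
        assert props["male_ipf_female_epf"] == pytest.approx(9 / 33)
        assert props["male_epf_female_ipf"] == pytest.approx(3 / 33)
        assert props["any_epf"] == pytest.approx(12 / 33)

    def test_empty_table(self):
        ft = par.fidelity_from_counts({})
        assert ft.n_pairs == 0
        assert all(v == 0.0 for v in ft.proportions().values())

    def test_classification_rules(self):
        assignments = [
            TacticAssignment("m1", "resident", "f1", 0.9, 0.05),
            TacticAssignment("m2", "resident", "f2", 0.8, 0.1),
            TacticAssignment("m3", "wanderer", None, 0.4, 0.3),
        ]
        parentage = [
            par.ParentageAssignment("e1", "f1", "m1", 10.0, 5.0, True, 2),
            par.ParentageAssignment("e2", "f2", "m2", 10.0, 5.0, True, 2),
            par.ParentageAssignment("e3", "f2", "m3", 10.0, 5.0, True, 2),
            par.ParentageAssignment("e4", "f3", "m2", 10.0, 5.0, True, 2),
        ]
        ft = par.classify_pair_fidelity(
            assignments, parentage, {"m1": "sham", "m2": "lesion"})
        # m1/f1: all embryos within pair
        assert ft.counts["male_ipf_female_ipf"] == {"sham": 1}
        # m2 sired with f3 (roving) and f2 mothered by m3 (cuckolded)
        assert ft.counts["male_epf_female_epf"] == {"lesion": 1}
        assert ft.n_pairs == 2

    def test_epf_rate_zero_gives_all_true_residents(self):
        # judged against the planted pairs (simulator truth), an enclosure
        # without extra-pair matings has only pure intra-pair pairs
        cfg = SimConfig(n_enclosures=1, seed=37, epf_rate=0.0)
        agents, fixes, adults, embryos = simdata.simulate_dataset(cfg)
        adult_geno = par.genotypes_from_table(adults)
        embryo_geno = par.genotypes_from_table(embryos,
                                               id_column="embryo_id")
        freqs = par.estimate_allele_freqs(adult_geno)
        sex = dict(zip(adults.animal_id, adults.sex))
        males = {a: g for a, g in adult_geno.items() if sex[a] == "M"}
        mothers = {a: g for a, g in adult_geno.items() if sex[a] == "F"}
        out = par.assign_sires(
            embryo_geno, dict(zip(embryos.embryo_id, embryos.mother_id)),
            mothers, males, freqs, error_rate=1e-5)
        planted = [
            TacticAssignment(a.animal_id, "resident", a.partner_id, 1.0, 0.0)
            for a in agents if a.sex == "M" and a.true_tactic == "resident"]
        ft = par.classify_pair_fidelity(
            planted, out, {a.animal_id: a.surgery for a in agents})
        assert ft.n_pairs > 0
        assert ft.proportions()["male_ipf_female_ipf"] == 1.0

    def test_counts_sum_to_pairs_with_assignments(self,
                                                  one_enclosure_dataset):
        from volerange.pipeline import run_pipeline
        agents, fixes, adults, embryos = one_enclosure_dataset
        res = run_pipeline(fixes, adults, embryos)
        total = sum(sum(d.values()) for d in res.fidelity.counts.values())
        assert total == res.fidelity.n_pairs


class TestDeltaThreshold:
    def test_threshold_is_ln_two_to_two_decimals(self):
        assert par.DELTA_THRESHOLD == round(math.log(2), 2) == 0.69
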