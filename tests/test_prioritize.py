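"""Discovery cascade: filters, candidate patterns, exclusion, segregation.

Per-individual candidate operations are checked against exhaustive
brute-force oracles on small random matrices, including enumeration of
parental-origin assignments for compound heterozygosity.
"""

from itertools import combinations

import numpy as np
import pytest

from recgene import prioritize, simulate
from recgene.model import CohortGenotypes, Individual, Pedigree, Variant


def _mk_variants(genes_per_variant):
    return [
        Variant("1", 100 + i, "A", "G", gene=g, func_class="missense")
        for i, g in enumerate(genes_per_variant)
    ]


def _mk_genotypes(variants, individuals, matrix):
    return CohortGenotypes.from_records(
        [v.key_str for v in variants], individuals, matrix)


class TestFilters:
    def test_functional_filter_membership_and_order(self):
        variants = [
            Variant("1", 1, "A", "G", func_class="missense"),
            Variant("1", 2, "A", "G", func_class="synonymous"),
            Variant("1", 3, "A", "G", func_class="splice_site"),
            Variant("1", 4, "A", "G", func_class="other"),
            Variant("1", 5, "A", "G", func_class="nonsense"),
        ]
        kept = prioritize.filter_functional(variants)
        assert [v.pos for v in kept] == [1, 3, 5]
        assert prioritize.filter_functional([]) == []

    def test_known_filter_requires_full_key_match(self):
        # a different alternate allele at a catalogued position is retained
        at_known_pos = Variant("3", 133674014, "G", "T", func_class="nonsense")
        exact = Variant("3", 133667736, "G", "A", func_class="splice_site")
        known = {("3", 133674014, "G", "A"): "rs148547180",
                 ("3", 133667736, "G", "A"): "rs0"}
        kept = prioritize.filter_known([at_known_pos, exact], known)
        assert kept == [at_known_pos]

    def test_filter_counts_match_generator_truth(self, cohort):
        functional = prioritize.filter_functional(cohort.variants)
        assert len(functional) == cohort.truth["counts"]["functional"]
        survivors = prioritize.filter_known(functional, cohort.known)
        assert len(survivors) == cohort.truth["counts"]["functional_not_known"]


class TestHomozygousCandidates:
    def test_hom_variant_nominates_gene(self):
        variants = _mk_variants(["SLCO2A1", "OTHER"])
        gt = _mk_genotypes(variants, ["A_V_2"], [[2], [1]])
        out = prioritize.homozygous_candidate_genes(gt, "A_V_2", variants)
        assert out == {("SLCO2A1", variants[0].key_str)}

    def test_all_het_individual_has_no_candidates(self):
        variants = _mk_variants(["G1", "G2"])
        gt = _mk_genotypes(variants, ["X"], [[1], [1]])
        assert prioritize.homozygous_candidate_genes(gt, "X", variants) == set()

    def test_unknown_individual_raises(self):
        variants = _mk_variants(["G1"])
        gt = _mk_genotypes(variants, ["X"], [[2]])
        with pytest.raises(KeyError):
            prioritize.homozygous_candidate_genes(gt, "nobody", variants)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(101)
        for _ in range(30):
            n_var, n_ind = int(rng.integers(1, 20)), int(rng.integers(1, 8))
            genes = [f"G{int(g)}" for g in rng.integers(0, 5, size=n_var)]
            variants = _mk_variants(genes)
            mat = rng.choice([0, 1, 2, None], size=(n_var, n_ind),
                             p=[0.4, 0.3, 0.2, 0.1])
            inds = [f"I{k}" for k in range(n_ind)]
            gt = _mk_genotypes(variants, inds, mat.tolist())
            ind = inds[int(rng.integers(0, n_ind))]
            got = prioritize.homozygous_candidate_genes(gt, ind, variants)
            expected = {
                (v.gene, v.key_str)
                for i, v in enumerate(variants)
                if mat[i][inds.index(ind)] == 2
            }
            assert got == expected


def _trio_pedigree(child="kid", father="dad", mother="mum"):
    return Pedigree([
        Individual(father, "F1", None, None, "male", "no"),
        Individual(mother, "F1", None, None, "female", "no"),
        Individual(child, "F1", father, mother, "female", "yes"),
    ])


def _compound_het_oracle(variants, gt, individual, father, mother):
    """Enumerate parental-origin assignments for every het pair."""
    by_gene = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)
    result = set()
    for gene, vs in by_gene.items():
        hets = [v for v in sorted(vs, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
                if gt.alt_count(v.key_str, individual) == 1]
        for v1, v2 in combinations(hets, 2):
            def origins(v):
                out = set()
                for parent in (father, mother):
                    if parent is None:
                        return {"dad", "mum"}  # unconstrained
                    ac = gt.alt_count(v.key_str, parent) if parent in gt.individuals else None
                    if ac is None or ac > 0:
                        out.add(parent)
                return out
            if father is None or mother is None:
                result.add((gene, (v1.key_str, v2.key_str)))
                continue
            o1, o2 = origins(v1), origins(v2)
            if any(a != b for a in o1 for b in o2):
                result.add((gene, (v1.key_str, v2.key_str)))
    return result


class TestCompoundHetCandidates:
    def test_sib_pair_gene_qualifies_without_parental_data(self):
        variants = _mk_variants(["SLCO2A1", "SLCO2A1"])
        gt = _mk_genotypes(variants, ["D_II_4"], [[1], [1]])
        out = prioritize.compound_het_candidate_genes(gt, "D_II_4", variants)
        assert out == {("SLCO2A1", (variants[0].key_str, variants[1].key_str))}

    def test_cis_forced_pair_disqualified(self):
        # both hets carried by the same single parent, absent in the other
        variants = _mk_variants(["G", "G"])
        ped = _trio_pedigree()
        gt = _mk_genotypes(variants, ["kid", "dad", "mum"],
                           [[1, 1, 0], [1, 1, 0]])
        out = prioritize.compound_het_candidate_genes(gt, "kid", variants, ped)
        assert out == set()

    def test_trans_possible_pair_qualifies(self):
        variants = _mk_variants(["G", "G"])
        ped = _trio_pedigree()
        gt = _mk_genotypes(variants, ["kid", "dad", "mum"],
                           [[1, 1, 0], [1, 0, 1]])
        out = prioritize.compound_het_candidate_genes(gt, "kid", variants, ped)
        assert len(out) == 1

    def test_missing_parent_call_keeps_origin_open(self):
        variants = _mk_variants(["G", "G"])
        ped = _trio_pedigree()
        gt = _mk_genotypes(variants, ["kid", "dad", "mum"],
                           [[1, 1, 0], [1, 0, None]])
        out = prioritize.compound_het_candidate_genes(gt, "kid", variants, ped)
        assert len(out) == 1  # the second variant could come from the mother

    def test_matches_phase_enumeration_oracle(self):
        rng = np.random.default_rng(202)
        ped = _trio_pedigree()
        for _ in range(40):
            n_var = int(rng.integers(2, 15))
            genes = [f"G{int(g)}" for g in rng.integers(0, 4, size=n_var)]
            variants = _mk_variants(genes)
            mat = rng.choice([0, 1, 2, None], size=(n_var, 3),
                             p=[0.35, 0.35, 0.15, 0.15]).tolist()
            gt = _mk_genotypes(variants, ["kid", "dad", "mum"], mat)
            got = prioritize.compound_het_candidate_genes(gt, "kid", variants, ped)
            expected = _compound_het_oracle(variants, gt, "kid", "dad", "mum")
            assert got == expected


class TestSharedAndExclusion:
    def test_intersection_identities(self):
        s1 = {("A", "k1"), ("B", "k2")}
        s2 = {("B", "k3"), ("C", "k4")}
        assert prioritize.shared_candidate_genes([s1, s2]) == {"B"}
        assert prioritize.shared_candidate_genes([s1]) == {"A", "B"}
        assert prioritize.shared_candidate_genes([s1, {("D", "k")}]) == set()

    def test_unaffected_homozygote_removes_gene(self):
        variants = _mk_variants(["CAND"])
        ped = Pedigree([
            Individual("aff", "F", None, None, "female", "yes"),
            Individual("unaff", "F", None, None, "female", "no"),
        ])
        gt = _mk_genotypes(variants, ["aff", "unaff"], [[2, 2]])
        out = prioritize.exclude_by_unaffected_and_extend({"CAND"}, gt, ped, variants)
        assert out == set()

    def test_het_carrier_does_not_exclude(self):
        variants = _mk_variants(["CAND"])
        ped = Pedigree([
            Individual("aff", "F", None, None, "female", "yes"),
            Individual("carrier", "F", None, None, "female", "no"),
        ])
        gt = _mk_genotypes(variants, ["aff", "carrier"], [[2, 1]])
        out = prioritize.exclude_by_unaffected_and_extend({"CAND"}, gt, ped, variants)
        assert out == {"CAND"}

    def test_no_unaffecteds_or_additional_is_identity(self):
        variants = _mk_variants(["CAND"])
        ped = Pedigree([Individual("aff", "F", None, None, "female", "yes")])
        gt = _mk_genotypes(variants, ["aff"], [[2]])
        out = prioritize.exclude_by_unaffected_and_extend({"CAND"}, gt, ped, variants)
        assert out == {"CAND"}

    def test_additional_affected_must_show_ar_pattern(self):
        variants = _mk_variants(["CAND", "CAND"])
        ped = Pedigree([
            Individual("aff1", "F", None, None, "female", "yes"),
            Individual("sib", "F", None, None, "female", "yes"),
        ])
        # sib has only one het in the gene: no AR pattern
        gt = _mk_genotypes(variants, ["aff1", "sib"], [[2, 1], [0, 0]])
        out = prioritize.exclude_by_unaffected_and_extend(
            {"CAND"}, gt, ped, variants, additional_affecteds=["sib"])
        assert out == set()


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_planted_gene(self, seed):
        c = simulate.generate_cohort(simulate.SimConfig(seed=seed))
        rep = prioritize.discover(
            c.variants, c.genotypes, c.pedigree, c.known,
            required_hom_individuals=simulate.CONSANGUINEOUS_PROBANDS,
            additional_affecteds=simulate.SIB_PAIR)
        assert rep.final_genes == [c.truth["causal_gene"]]
        assert len(rep.shared_genes) == 1 + len(c.truth["distractor_genes"])

    def test_cascade_monotonic_and_order_invariant(self, cohort):
        rng = np.random.default_rng(7)
        base = None
        for _ in range(3):
            order = rng.permutation(len(cohort.variants))
            variants = [cohort.variants[i] for i in order]
            rep = prioritize.discover(
                variants, cohort.genotypes, cohort.pedigree, cohort.known,
                required_hom_individuals=simulate.CONSANGUINEOUS_PROBANDS,
                additional_affecteds=simulate.SIB_PAIR)
            a = rep.audit
            assert (a["input_variants"] >= a["functional"] >= a["after_known_filter"])
            assert a["shared_candidate_genes"] >= a["final_genes"]
            if base is None:
                base = (rep.final_genes, rep.shared_genes)
            assert (rep.final_genes, rep.shared_genes) == base


class TestSegregation:
    def _family_a(self, cohort):
        key = cohort.truth["causal_variants"]["family_A_hom"]
        return key, cohort.segregation_genotypes

    def test_study_family_is_consistent(self, cohort):
        key, gt = self._family_a(cohort)
        res = prioritize.check_segregation(cohort.pedigree, gt, [key], family_id="A")
        assert res.consistent and res.violations == []
        assert res.observed["A_V_2"] == "biallelic"
        assert res.observed["A_IV_1"] == "carrier"

    def test_unaffected_homozygote_is_violation(self, cohort):
        key, gt = self._family_a(cohort)
        tampered = CohortGenotypes(gt.table.copy())
        tampered.table.at[key, "A_V_3"] = 2
        res = prioritize.check_segregation(cohort.pedigree, tampered, [key], family_id="A")
        assert not res.consistent
        assert any("A_V_3" in v for v in res.violations)

    def test_missing_genotype_is_untestable_not_violation(self, cohort):
        key, gt = self._family_a(cohort)
        tampered = CohortGenotypes(gt.table.copy())
        tampered.table.at[key, "A_V_1"] = None
        res = prioritize.check_segregation(cohort.pedigree, tampered, [key], family_id="A")
        assert res.consistent
        assert "A_V_1" in res.untestable

    def test_perturbation_flags_exactly_the_tampered_individuals(self, cohort):
        key, gt = self._family_a(cohort)
        rng = np.random.default_rng(55)
        fam_a = [i for i in cohort.pedigree.individuals if i.family_id == "A"]
        for _ in range(20):
            tampered = CohortGenotypes(gt.table.copy())
            expected_bad = set()
            for ind in fam_a:
                if rng.random() < 0.3:
                    if ind.affected == "yes":
                        tampered.table.at[key, ind.id] = 1  # demote the proband
                        expected_bad.add(ind.id)
                    elif ind.affected == "no" and rng.random() < 0.5:
                        tampered.table.at[key, ind.id] = 2  # unaffected biallelic
                        expected_bad.add(ind.id)
            res = prioritize.check_segregation(cohort.pedigree, tampered, [key],
                                               family_id="A")
            flagged = {v.split()[1] for v in res.violations
                       if v.startswith(("affected", "unaffected"))}
            assert flagged == expected_bad

    def test_parent_without_causal_allele_is_violation(self, cohort):
        key, gt = self._family_a(cohort)
        tampered = CohortGenotypes(gt.table.copy())
        tampered.table.at[key, "A_IV_1"] = 0
        res = prioritize.check_segregation(cohort.pedigree, tampered, [key], family_id="A")
        assert any("A_IV_1" in v and "carries no causal allele" in v
                   for v in res.violations)
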