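"""Autosomal-recessive candidate-gene discovery from filtered exome calls.

The cascade mirrors how a recessive disease gene is mapped in a small,
partly consanguineous cohort:

1. keep functional variants (missense, nonsense, splice-site);
2. drop variants present in the known-polymorphism list (full-key match on
   chrom, pos, ref AND alt — a different alternate allele at a known
   position is retained);
3. per consanguineous affected, collect genes with a homozygous candidate
   variant (compound heterozygotes optionally admitted too);
4. intersect candidate gene sets across the required affecteds (gene-level:
   different families may carry different variants of the same gene);
5. remove genes in which any unaffected individual carries a qualifying
   biallelic genotype (homozygous or trans-configurable compound het — mere
   heterozygous carriage never excludes a recessive gene), then retain only
   genes that also show an AR pattern in every additional affected;
6. verify segregation of the nominated variants through the full pedigree.

Missing genotypes are conservative in both directions: they never qualify an
individual for a candidate pattern and never disqualify a gene during
unaffected exclusion (strict mode makes unaffected missingness
disqualifying).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .model import CohortGenotypes, Pedigree, Variant, sort_key


def filter_functional(variants: Sequence[Variant]) -> list[Variant]:
    """Retain missense, nonsense and splice-site variants, preserving order."""
    return [v for v in variants if v.is_functional]


def filter_known(
    variants: Sequence[Variant],
    known: Iterable[tuple[str, int, str, str]],
) -> list[Variant]:
    """Drop variants whose full (chrom, pos, ref, alt) key is in the known list."""
    known_keys = set(known)
    return [v for v in variants if v.key not in known_keys]


def _gene_index(variants: Sequence[Variant]) -> dict[str, list[Variant]]:
    by_gene: dict[str, list[Variant]] = {}
    for v in variants:
        if v.gene is None:
            continue
        by_gene.setdefault(v.gene, []).append(v)
    return by_gene


def homozygous_candidate_genes(
    genotypes: CohortGenotypes,
    individual: str,
    variants: Sequence[Variant],
) -> set[tuple[str, str]]:
    """Genes with at least one homozygous-alternate candidate variant in
    ``individual``; returns (gene, variant key) pairs.  Missing is not 2."""
    col = genotypes.column(individual)  # raises on unknown individual
    out = set()
    for v in variants:
        if v.gene is None:
            continue
        ac = col.get(v.key_str)
        if ac is not None and not _isna(ac) and int(ac) == 2:
            out.add((v.gene, v.key_str))
    return out


def _isna(x) -> bool:
    import pandas as pd

    return x is None or pd.isna(x)


def _het_origins(
    genotypes: CohortGenotypes,
    variant_key: str,
    father: Optional[str],
    mother: Optional[str],
) -> Optional[set[str]]:
    """Possible parental origins of a child's het allele.

    Returns None when either parent is ungenotyped (origin unconstrained).
    A parent with a missing call at this site stays a possible origin
    (missingness never disqualifies)."""
    if father is None or mother is None:
        return None
    origins = set()
    for label, parent in (("father", father), ("mother", mother)):
        ac = _safe_alt(genotypes, variant_key, parent)
        if ac is None or ac > 0:
            origins.add(label)
    return origins


def _safe_alt(genotypes: CohortGenotypes, key: str, individual: str) -> Optional[int]:
    if individual not in genotypes.table.columns or key not in genotypes.table.index:
        return None
    return genotypes.alt_count(key, individual)


def compound_het_candidate_genes(
    genotypes: CohortGenotypes,
    individual: str,
    variants: Sequence[Variant],
    pedigree: Optional[Pedigree] = None,
) -> set[tuple[str, tuple[str, str]]]:
    """Genes with a possible trans pair of heterozygous candidate variants.

    With both parents genotyped a pair qualifies only if the two variants can
    be assigned to different parental origins; without parental data the
    trans configuration is assumed.  Returns (gene, (key1, key2)) with the
    pair in deterministic (chrom, pos, ref, alt) order.
    """
    genotypes.column(individual)  # raises on unknown individual
    father_id = mother_id = None
    if pedigree is not None and individual in pedigree:
        father, mother = pedigree.parents(individual)
        father_id = father.id if father is not None and father.id in genotypes.table.columns else None
        mother_id = mother.id if mother is not None and mother.id in genotypes.table.columns else None

    out: set[tuple[str, tuple[str, str]]] = set()
    for gene, gene_vars in _gene_index(variants).items():
        hets = [v for v in sorted(gene_vars, key=sort_key)
                if _safe_alt(genotypes, v.key_str, individual) == 1]
        for v1, v2 in combinations(hets, 2):
            o1 = _het_origins(genotypes, v1.key_str, father_id, mother_id)
            o2 = _het_origins(genotypes, v2.key_str, father_id, mother_id)
            if o1 is None or o2 is None:
                trans_possible = True  # no parental data: assume trans
            else:
                trans_possible = any(
                    a != b for a in o1 for b in o2
                )
            if trans_possible:
                out.add((gene, (v1.key_str, v2.key_str)))
    return out


def shared_candidate_genes(candidate_sets: Sequence[set]) -> set[str]:
    """Gene-level intersection of per-individual candidate sets."""
    if not candidate_sets:
        raise ValueError("need at least one candidate set")
    gene_sets = [{entry[0] for entry in s} for s in candidate_sets]
    shared = set(gene_sets[0])
    for gs in gene_sets[1:]:
        shared &= gs
    return shared


def _ar_pattern_genes(
    genotypes: CohortGenotypes,
    individual: str,
    variants: Sequence[Variant],
    pedigree: Optional[Pedigree],
    hom_only: bool = False,
) -> set[str]:
    genes = {g for g, _ in homozygous_candidate_genes(genotypes, individual, variants)}
    if not hom_only:
        genes |= {g for g, _ in compound_het_candidate_genes(genotypes, individual, variants, pedigree)}
    return genes


def exclude_by_unaffected_and_extend(
    shared_genes: set[str],
    genotypes: CohortGenotypes,
    pedigree: Pedigree,
    variants: Sequence[Variant],
    additional_affecteds: Sequence[str] = (),
    strict_missing: bool = False,
) -> set[str]:
    """Drop genes with a qualifying biallelic genotype in any unaffected
    genotyped individual, then keep only genes showing an AR pattern in every
    additional affected.

    ``strict_missing`` treats a missing unaffected genotype at a candidate
    variant as disqualifying for its gene.
    """
    genotyped = set(genotypes.individuals)
    surviving = set(shared_genes)
    for ind in pedigree.unaffecteds():
        if ind.id not in genotyped:
            continue
        biallelic = _ar_pattern_genes(genotypes, ind.id, variants, pedigree)
        surviving -= biallelic
        if strict_missing:
            for v in variants:
                if v.gene in surviving and _safe_alt(genotypes, v.key_str, ind.id) is None:
                    surviving.discard(v.gene)
    for aff in additional_affecteds:
        patterns = _ar_pattern_genes(genotypes, aff, variants, pedigree)
        surviving &= patterns
    return surviving


@dataclass
class CandidateReport:
    """Output of the staged discovery cascade with an audit trail."""

    per_individual: dict[str, set] = field(default_factory=dict)
    per_family_genes: dict[str, set] = field(default_factory=dict)
    shared_genes: set = field(default_factory=set)
    final_genes: list = field(default_factory=list)
    supporting: dict[str, dict[str, list]] = field(default_factory=dict)
    audit: dict[str, int] = field(default_factory=dict)


def discover(
    variants: Sequence[Variant],
    genotypes: CohortGenotypes,
    pedigree: Pedigree,
    known: Iterable[tuple[str, int, str, str]],
    required_hom_individuals: Sequence[str],
    additional_affecteds: Sequence[str] = (),
    hom_only_for_consanguineous: bool = True,
    strict_missing: bool = False,
) -> CandidateReport:
    """Run the full cascade and return the candidate report.

    ``required_hom_individuals`` are the (consanguineous) affecteds whose
    shared candidate genes seed the intersection; ``additional_affecteds``
    must each independently show an AR pattern for a gene to survive.
    """
    report = CandidateReport()
    report.audit["input_variants"] = len(variants)
    functional = filter_functional(variants)
    report.audit["functional"] = len(functional)
    candidates = filter_known(functional, known)
    report.audit["after_known_filter"] = len(candidates)

    cand_sets = []
    for ind_id in required_hom_individuals:
        s = homozygous_candidate_genes(genotypes, ind_id, candidates)
        if not hom_only_for_consanguineous:
            s = s | {
                (g, pair) for g, pair in
                compound_het_candidate_genes(genotypes, ind_id, candidates, pedigree)
            }
        report.per_individual[ind_id] = s
        fam = pedigree.get(ind_id).family_id if ind_id in pedigree else ind_id
        report.per_family_genes.setdefault(fam, set()).update(g for g, _ in s)
        cand_sets.append(s)

    report.shared_genes = shared_candidate_genes(cand_sets)
    report.audit["shared_candidate_genes"] = len(report.shared_genes)

    final = exclude_by_unaffected_and_extend(
        report.shared_genes, genotypes, pedigree, candidates,
        additional_affecteds=additional_affecteds, strict_missing=strict_missing,
    )
    report.final_genes = sorted(final)
    report.audit["final_genes"] = len(final)

    by_gene = _gene_index(candidates)
    for gene in report.final_genes:
        support: dict[str, list] = {}
        for ind_id in list(required_hom_individuals) + list(additional_affecteds):
            keys = [v.key_str for v in sorted(by_gene.get(gene, []), key=sort_key)
                    if (_safe_alt(genotypes, v.key_str, ind_id) or 0) > 0]
            support[ind_id] = keys
        report.supporting[gene] = support
    return report


@dataclass
class SegregationResult:
    variant_keys: list[str]
    expected: dict[str, str]
    observed: dict[str, str]
    violations: list[str]
    untestable: list[str]

    @property
    def consistent(self) -> bool:
        return not self.violations


def check_segregation(
    pedigree: Pedigree,
    genotypes: CohortGenotypes,
    causal_variant_keys: Sequence[str],
    family_id: Optional[str] = None,
) -> SegregationResult:
    """Check that the nominated variant(s) track disease through the pedigree
    under an autosomal-recessive model.

    Consistent iff every affected is biallelic (homozygous for one causal
    variant or carrying two distinct ones), no unaffected is biallelic, and
    every genotyped parent of an affected carries at least one causal allele.
    Individuals without genotype data are reported untestable, not violated.
    """
    keys = list(causal_variant_keys)
    members = [i for i in pedigree.individuals
               if family_id is None or i.family_id == family_id]
    genotyped = set(genotypes.individuals)
    expected: dict[str, str] = {}
    observed: dict[str, str] = {}
    violations: list[str] = []
    untestable: list[str] = []

    def state(ind_id: str) -> Optional[str]:
        counts = [_safe_alt(genotypes, k, ind_id) for k in keys]
        if all(c is None for c in counts):
            return None
        known_counts = [c for c in counts if c is not None]
        if any(c == 2 for c in known_counts) or sum(1 for c in known_counts if c >= 1) >= 2:
            return "biallelic"
        if any(c == 1 for c in known_counts):
            return "carrier"
        return "noncarrier"

    for ind in members:
        expected[ind.id] = {"yes": "biallelic", "no": "not biallelic", "unknown": "any"}[ind.affected]
        if ind.id not in genotyped:
            untestable.append(ind.id)
            observed[ind.id] = "ungenotyped"
            continue
        st = state(ind.id)
        if st is None:
            untestable.append(ind.id)
            observed[ind.id] = "missing"
            continue
        observed[ind.id] = st
        if ind.affected == "yes" and st != "biallelic":
            violations.append(f"affected {ind.id} is {st}, expected biallelic")
        if ind.affected == "no" and st == "biallelic":
            violations.append(f"unaffected {ind.id} is biallelic")

    for ind in members:
        if ind.affected != "yes":
            continue
        for parent in pedigree.parents(ind.id):
            if parent is None or parent.id not in genotyped:
                continue
            st = state(parent.id)
            if st == "noncarrier":
                violations.append(
                    f"parent {parent.id} of affected {ind.id} carries no causal allele"
                )
    return SegregationResult(
        variant_keys=keys, expected=expected, observed=observed,
        violations=violations, untestable=sorted(set(untestable)),
    )
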