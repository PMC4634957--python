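"""Synthetic exome cohorts with planted recessive disease genes.

The default configuration emulates the discovery design of the study this
package supports: three affected probands from consanguineous matings, two of
whom share the same homozygous splice-site variant while the third carries a
private one; an affected sibling pair compound-heterozygous for a missense
and a nonsense variant in the same gene; and one unaffected relative (the
first proband's sister) who carries a single causal allele.  A configurable
number of distractor genes is engineered to pass the shared-homozygosity
filter and fail the unaffected/sibling stages, and background polymorphisms
are drawn per individual with homozygote probability q^2 + F*q*(1-q) for
consanguineous individuals (inbreeding coefficient F) and q^2 otherwise.

Everything is driven by one seeded generator: identical configs give
byte-identical output files.  A truth record (JSON) accompanies each cohort
so downstream stages can be checked against the planted answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CdnaPosition,
    CohortGenotypes,
    ConfigError,
    Individual,
    Pedigree,
    ProteinConsequence,
    SpliceOutcome,
    TranscriptModel,
    Variant,
)
from . import formats

_BASES = np.array(list("ACGT"))

# functional-class mix for background variants (exome-like; functional ~38%)
_FUNC_CLASSES = ["synonymous", "missense", "other", "splice_site", "nonsense"]
_FUNC_PROBS = [0.50, 0.33, 0.12, 0.03, 0.02]


@dataclass(frozen=True)
class BiomarkerConfig:
    """Two-group biomarker (urinary PGE-M scale): mean, SEM and n per group."""

    mean_case: float = 116.1
    sem_case: float = 15.6
    n_case: int = 15
    mean_control: float = 35.9
    sem_control: float = 4.6
    n_control: int = 13

    def __post_init__(self):
        if self.sem_case < 0 or self.sem_control < 0:
            raise ConfigError("SEMs must be non-negative")
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("group sizes must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Cohort design.  The defaults are the study design; scale parameters
    (gene count, variants per gene, background allele frequency) are the
    package's fixed choice of a small but structurally faithful exome."""

    seed: int = 0
    n_genes: int = 60
    mean_variants_per_gene: float = 3.0
    background_alt_freq: float = 0.005
    known_fraction: float = 0.9
    n_distractor_shared_hom: int = 9
    inbreeding_f: float = 1.0 / 16.0
    causal_gene: str = "SLCO2A1"
    include_relatives_in_vcf: bool = False
    biomarker: BiomarkerConfig = field(default_factory=BiomarkerConfig)

    def __post_init__(self):
        if not 0.0 <= self.background_alt_freq <= 1.0:
            raise ConfigError("background_alt_freq must be in [0, 1]")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ConfigError("known_fraction must be in [0, 1]")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ConfigError("inbreeding_f must be in [0, 1]")
        if self.n_distractor_shared_hom >= self.n_genes - 1:
            raise ConfigError("n_distractor_shared_hom must leave room for non-candidate genes")
        if self.n_genes < 2:
            raise ConfigError("need at least two genes")
        if self.mean_variants_per_gene < 0:
            raise ConfigError("mean_variants_per_gene must be >= 0")


# -- pedigree layout (fixed study design) ------------------------------------

EXOME_SAMPLES = ["A_V_2", "B_IV_3", "C_IV_3", "D_II_4", "D_II_5", "A_V_3"]
CONSANGUINEOUS_PROBANDS = ["A_V_2", "B_IV_3", "C_IV_3"]
SIB_PAIR = ["D_II_4", "D_II_5"]
UNAFFECTED_EXOME = "A_V_3"
CONSANGUINITY_DEGREES = {"A": 5, "B": 3, "C": 3}


def study_pedigree() -> Pedigree:
    """The fixed four-family pedigree: three consanguineous trios (family A
    extended with unaffected sibs, spouse and children) plus the affected
    sibling pair and their parents."""
    rows = [
        # id, family, father, mother, sex, affected
        ("A_IV_1", "A", None, None, "male", "no"),
        ("A_IV_2", "A", None, None, "female", "no"),
        ("A_V_2", "A", "A_IV_1", "A_IV_2", "female", "yes"),
        ("A_V_3", "A", "A_IV_1", "A_IV_2", "female", "no"),
        ("A_V_1", "A", "A_IV_1", "A_IV_2", "male", "no"),
        ("A_V_4", "A", None, None, "male", "no"),
        ("A_VI_1", "A", "A_V_4", "A_V_2", "female", "no"),
        ("A_VI_2", "A", "A_V_4", "A_V_2", "male", "no"),
        ("B_III_1", "B", None, None, "male", "no"),
        ("B_III_2", "B", None, None, "female", "no"),
        ("B_IV_3", "B", "B_III_1", "B_III_2", "female", "yes"),
        ("C_III_1", "C", None, None, "male", "no"),
        ("C_III_2", "C", None, None, "female", "no"),
        ("C_IV_3", "C", "C_III_1", "C_III_2", "female", "yes"),
        ("D_I_1", "D", None, None, "male", "no"),
        ("D_I_2", "D", None, None, "female", "no"),
        ("D_II_4", "D", "D_I_1", "D_I_2", "female", "yes"),
        ("D_II_5", "D", "D_I_1", "D_I_2", "female", "yes"),
    ]
    individuals = [Individual(i, f, fa, mo, s, a) for i, f, fa, mo, s, a in rows]
    return Pedigree(individuals, consanguinity=dict(CONSANGUINITY_DEGREES))


# -- cohort generation --------------------------------------------------------


def _gene_window(i: int) -> tuple[str, int, int]:
    chrom = str(i % 22 + 1)
    start = 100_000 * i + 1
    return chrom, start, start + 89_999


def _random_snv(rng, chrom, lo, hi, used: set) -> tuple[int, str, str]:
    while True:
        pos = int(rng.integers(lo, hi + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    ref, alt = rng.choice(4, size=2, replace=False)
    return pos, str(_BASES[ref]), str(_BASES[alt])


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its truth record."""

    config: SimConfig
    variants: list[Variant]
    genotypes: CohortGenotypes
    pedigree: Pedigree
    known: dict[tuple[str, int, str, str], str]
    truth: dict
    segregation_variants: list[Variant]
    segregation_genotypes: CohortGenotypes
    biomarker: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "pedigree.ped",
            "known": outdir / "known_variants.tsv",
            "truth": outdir / "truth.json",
            "segregation_vcf": outdir / "segregation.vcf",
            "biomarker": outdir / "biomarker.tsv",
        }
        formats.write_vcf(paths["vcf"], self.variants, self.genotypes)
        formats.write_ped(paths["ped"], self.pedigree)
        formats.write_known_list(paths["known"], self.known)
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        formats.write_vcf(paths["segregation_vcf"], self.segregation_variants,
                          self.segregation_genotypes)
        self.biomarker.to_csv(paths["biomarker"], sep="\t", index=False)
        return paths


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the cohort, its pedigree, the known-variant list, the Sanger-style
    family genotyping table for segregation, the biomarker table, and the truth
    record.  Background variants are emitted only when at least one genotyped
    sample carries the alternate allele (as a variant caller would)."""
    rng = np.random.default_rng(config.seed)
    ped = study_pedigree()

    gene_names = [f"GENE{i:04d}" for i in range(config.n_genes)]
    causal_idx = config.n_genes // 2
    gene_names[causal_idx] = config.causal_gene
    non_causal = [i for i in range(config.n_genes) if i != causal_idx]
    distractor_idx = sorted(
        rng.choice(non_causal, size=config.n_distractor_shared_hom, replace=False).tolist()
    )
    distractor_genes = [gene_names[i] for i in distractor_idx]

    samples = list(EXOME_SAMPLES)
    if config.include_relatives_in_vcf:
        samples += [i.id for i in ped.individuals if i.id not in EXOME_SAMPLES]
    consang = set(CONSANGUINEOUS_PROBANDS)

    used_pos: set = set()
    variants: list[Variant] = []
    rows: list[list[Optional[int]]] = []
    known: dict[tuple[str, int, str, str], str] = {}
    planted: dict[str, dict[str, int]] = {}
    n_known_id = 0

    def plant(var: Variant, genos: dict[str, int]) -> None:
        variants.append(var)
        rows.append([genos.get(s, 0) for s in samples])
        planted[var.key_str] = dict(genos)

    # --- causal variants (never in the known list) ---------------------------
    chrom, lo, hi = _gene_window(causal_idx)
    pos_a, ref_a, alt_a = _random_snv(rng, chrom, lo, hi, used_pos)
    v_a = Variant(chrom, pos_a, ref_a, alt_a, gene=config.causal_gene,
                  func_class="splice_site", cdna_pos=CdnaPosition(1461, 1))
    pos_bc, ref_bc, alt_bc = _random_snv(rng, chrom, lo, hi, used_pos)
    v_bc = Variant(chrom, pos_bc, ref_bc, alt_bc, gene=config.causal_gene,
                   func_class="splice_site", cdna_pos=CdnaPosition(940, 1))
    pos_d1, ref_d1, alt_d1 = _random_snv(rng, chrom, lo, hi, used_pos)
    v_d1 = Variant(chrom, pos_d1, ref_d1, alt_d1, gene=config.causal_gene,
                   func_class="missense", cdna_pos=CdnaPosition(664),
                   deleterious_flags=("damaging",))
    pos_d2, ref_d2, alt_d2 = _random_snv(rng, chrom, lo, hi, used_pos)
    v_d2 = Variant(chrom, pos_d2, ref_d2, alt_d2, gene=config.causal_gene,
                   func_class="nonsense", cdna_pos=CdnaPosition(1807))

    family_a_het = ["A_IV_1", "A_IV_2", "A_V_3", "A_V_1", "A_VI_1", "A_VI_2"]
    plant(v_a, {"A_V_2": 2, **{i: 1 for i in family_a_het}})
    plant(v_bc, {"B_IV_3": 2, "C_IV_3": 2,
                 "B_III_1": 1, "B_III_2": 1, "C_III_1": 1, "C_III_2": 1})
    plant(v_d1, {"D_II_4": 1, "D_II_5": 1, "D_I_1": 1})
    plant(v_d2, {"D_II_4": 1, "D_II_5": 1, "D_I_2": 1})

    # --- distractor genes: shared hom in the consanguineous probands ---------
    distractor_keys = []
    for j, gi in enumerate(distractor_idx):
        chrom, lo, hi = _gene_window(gi)
        pos, ref, alt = _random_snv(rng, chrom, lo, hi, used_pos)
        dv = Variant(chrom, pos, ref, alt, gene=gene_names[gi], func_class="missense")
        genos = {p: 2 for p in CONSANGUINEOUS_PROBANDS}
        if j % 3 == 0:
            genos[UNAFFECTED_EXOME] = 2  # fails at the unaffected-exclusion stage
        genos["D_II_4"] = 1  # a lone het: never an AR pattern in the sib pair
        plant(dv, genos)
        distractor_keys.append(dv.key_str)

    # --- background polymorphisms --------------------------------------------
    q = config.background_alt_freq
    f_coef = config.inbreeding_f
    n_bg = rng.poisson(config.mean_variants_per_gene, size=config.n_genes)
    n_background_emitted = 0
    for gi in range(config.n_genes):
        chrom, lo, hi = _gene_window(gi)
        for _ in range(int(n_bg[gi])):
            pos, ref, alt = _random_snv(rng, chrom, lo, hi, used_pos)
            func = _FUNC_CLASSES[rng.choice(len(_FUNC_CLASSES), p=_FUNC_PROBS)]
            is_known = bool(rng.random() < config.known_fraction)
            var = Variant(chrom, pos, ref, alt, gene=gene_names[gi], func_class=func,
                          known_id=f"rs{900000 + n_known_id}" if is_known else None)
            genos = []
            for s in samples:
                f_ind = f_coef if s in consang else 0.0
                p_hom = q * q + f_ind * q * (1 - q)
                p_het = 2 * q * (1 - q) * (1 - f_ind)
                u = rng.random()
                genos.append(2 if u < p_hom else (1 if u < p_hom + p_het else 0))
            if is_known:
                known[var.key] = var.known_id
                n_known_id += 1
            if any(g > 0 for g in genos):
                variants.append(var)
                rows.append(list(genos))
                n_background_emitted += 1

    genotypes = CohortGenotypes.from_records([v.key_str for v in variants], samples, rows)

    # --- Sanger-style segregation table (all pedigree members, causal sites) --
    seg_variants = [v_a, v_bc, v_d1, v_d2]
    seg_samples = [i.id for i in ped.individuals]
    seg_rows = [[planted[v.key_str].get(s, 0) for s in seg_samples] for v in seg_variants]
    seg_genotypes = CohortGenotypes.from_records(
        [v.key_str for v in seg_variants], seg_samples, seg_rows)

    biomarker = generate_biomarker(config, rng)

    n_functional = sum(1 for v in variants if v.is_functional)
    n_after_known = sum(1 for v in variants if v.is_functional and v.key not in known)
    truth = {
        "seed": config.seed,
        "causal_gene": config.causal_gene,
        "causal_variants": {
            "family_A_hom": v_a.key_str,
            "family_BC_shared_hom": v_bc.key_str,
            "sib_pair_het_1": v_d1.key_str,
            "sib_pair_het_2": v_d2.key_str,
        },
        "distractor_genes": distractor_genes,
        "distractor_variants": distractor_keys,
        "planted_genotypes": planted,
        "consanguinity_degrees": CONSANGUINITY_DEGREES,
        "inbreeding_f": f_coef,
        "counts": {
            "variants_emitted": len(variants),
            "functional": n_functional,
            "functional_not_known": n_after_known,
            "background_emitted": n_background_emitted,
        },
        "biomarker_groups": {
            row.individual: row.group for row in biomarker.itertuples()
        },
    }
    cohort = Cohort(
        config=config, variants=variants, genotypes=genotypes, pedigree=ped,
        known=known, truth=truth, segregation_variants=seg_variants,
        segregation_genotypes=seg_genotypes, biomarker=biomarker,
    )
    verify_truth(cohort)
    return cohort


def generate_biomarker(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-individual biomarker values: normal draws on the measurement scale,
    group SD recovered from the configured SEM (sd = sem * sqrt(n))."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 10_007)
    b = config.biomarker
    recs = []
    for group, mean, sem, n in (
        ("case", b.mean_case, b.sem_case, b.n_case),
        ("control", b.mean_control, b.sem_control, b.n_control),
    ):
        sd = sem * np.sqrt(n)
        vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        for i, v in enumerate(vals, start=1):
            recs.append((f"{group}_{i:02d}", group, round(float(v), 4)))
    return pd.DataFrame(recs, columns=["individual", "group", "value"])


def verify_truth(cohort: Cohort) -> None:
    """Post-generation consistency check: planted genotypes appear verbatim in
    the emitted matrix, causal variants are absent from the known list, and
    the truth counts match the emitted variant table."""
    gt = cohort.genotypes
    samples = set(gt.individuals)
    for key, genos in cohort.truth["planted_genotypes"].items():
        for ind, expect in genos.items():
            if ind in samples:
                got = gt.alt_count(key, ind)
                if got != expect:
                    raise AssertionError(f"planted genotype mismatch at {key} for {ind}: {got} != {expect}")
    for key in cohort.truth["causal_variants"].values():
        chrom, pos, ref, alt = key.split(":")
        if (chrom, int(pos), ref, alt) in cohort.known:
            raise AssertionError(f"causal variant {key} leaked into the known list")
    counts = cohort.truth["counts"]
    if counts["variants_emitted"] != len(cohort.variants):
        raise AssertionError("truth variant count inconsistent")
    if counts["functional"] != sum(1 for v in cohort.variants if v.is_functional):
        raise AssertionError("truth functional count inconsistent")


# -- transcript cases ----------------------------------------------------------

_CODON_TABLE = {}  # independent codon table for the embedded truth oracle
for _aas, _codons in {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "*": ["TAA", "TAG", "TGA"],
}.items():
    for _c in _codons:
        _CODON_TABLE[_c] = _aas
_SENSE_CODONS = sorted(c for c, a in _CODON_TABLE.items() if a != "*")


def _oracle_translate(seq: str) -> tuple[str, bool]:
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(prot), True
        prot.append(aa)
    return "".join(prot), False


def _oracle_consequence(ref_cds: str, mut_cds: str, ref_downstream: str = "") -> ProteinConsequence:
    """Codon-by-codon truth: translate both sequences with the embedded codon
    table and classify by direct protein comparison (in-frame calls demand a
    verbatim nucleotide realignment, extended past the stop by the 3'UTR)."""
    ref_p, _ = _oracle_translate(ref_cds)
    mut_p, mut_term = _oracle_translate(mut_cds)
    if mut_p == ref_p:
        return ProteinConsequence(category="no_change", hgvs_p="p.=")
    i = 0
    while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
        i += 1
    if i == len(ref_p):
        raise AssertionError("oracle: generated case lost the stop codon")
    if i == len(mut_p):
        if not mut_term:
            return ProteinConsequence(category="no_stop_found", position=i + 1,
                                      ref_aa=ref_p[i], hgvs_p=f"p.{ref_p[i]}{i + 1}fs*?")
        return ProteinConsequence(category="nonsense", position=i + 1, ref_aa=ref_p[i],
                                  new_aa="*", hgvs_p=f"p.{ref_p[i]}{i + 1}X")
    delta = len(ref_p) - len(mut_p)

    ref_full = ref_cds[: 3 * (len(ref_p) + 1)] + ref_downstream

    def nt_ok(p_ref, p_mut, min_len=6):
        # true in-frame events keep the downstream nucleotides verbatim
        a = ref_full[3 * p_ref :]
        b = mut_cds[3 * p_mut :]
        n = min(len(a), len(b))
        return n >= min_len and a[:n] == b[:n]

    if (delta == 0 and mut_term and ref_p[i + 1 :] == mut_p[i + 1 :]
            and nt_ok(i + 1, i + 1, min_len=3)):
        return ProteinConsequence(category="missense", position=i + 1, ref_aa=ref_p[i],
                                  new_aa=mut_p[i], hgvs_p=f"p.{ref_p[i]}{i + 1}{mut_p[i]}")
    if delta != 0 and mut_term:
        aligned = (
            (delta > 0 and ref_p[i + delta :] == mut_p[i:] and nt_ok(i + delta, i))
            or (delta < 0 and mut_p[i - delta :] == ref_p[i:] and nt_ok(i, i - delta))
            or (ref_p[i + 1 + max(delta, 0) :] == mut_p[i + 1 + max(-delta, 0) :]
                and nt_ok(i + 1 + max(delta, 0), i + 1 + max(-delta, 0)))
        )
        if aligned:
            return ProteinConsequence(category="inframe_deletion", position=i + 1,
                                      ref_aa=ref_p[i], hgvs_p=f"p.{ref_p[i]}{i + 1}del?")
    if not mut_term:
        return ProteinConsequence(category="no_stop_found", position=i + 1, ref_aa=ref_p[i],
                                  new_aa=mut_p[i], hgvs_p=f"p.{ref_p[i]}{i + 1}{mut_p[i]}fs*?")
    off = len(mut_p) - i + 1
    return ProteinConsequence(category="frameshift", position=i + 1, ref_aa=ref_p[i],
                              new_aa=mut_p[i], stop_offset=off,
                              hgvs_p=f"p.{ref_p[i]}{i + 1}{mut_p[i]}fs*{off}")


def generate_transcript_case(
    seed: int,
    exon_count: int = 6,
    skip_exon: Optional[int] = None,
    insert_len: Optional[int] = None,
) -> tuple[TranscriptModel, SpliceOutcome, ProteinConsequence]:
    """Build a random multi-exon transcript and a splice outcome (exon skip or
    intronic insertion at a CDS-internal junction), with the truth consequence
    computed by the embedded codon-by-codon oracle.

    Exactly one of ``skip_exon`` (an internal exon index, in transcript order)
    or ``insert_len`` must be given.
    """
    if (skip_exon is None) == (insert_len is None):
        raise ConfigError("give exactly one of skip_exon or insert_len")
    if exon_count < 3:
        raise ConfigError("need at least 3 exons for an internal event")
    if skip_exon is not None and not 2 <= skip_exon <= exon_count - 1:
        raise ConfigError(f"skip_exon must be internal (2..{exon_count - 1})")
    if insert_len is not None and insert_len < 1:
        raise ConfigError("insert_len must be >= 1")

    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        try:
            return _build_transcript_case(rng, exon_count, skip_exon, insert_len, seed)
        except _StopLossDraw:
            # a draw that would disrupt or faithfully recreate the stop codon
            # (extension events are outside the supported consequence space);
            # redraw deterministically from the same stream
            continue
    raise RuntimeError("could not draw a supported transcript case")


class _StopLossDraw(Exception):
    pass


def _build_transcript_case(
    rng: np.random.Generator,
    exon_count: int,
    skip_exon: Optional[int],
    insert_len: Optional[int],
    seed: int,
) -> tuple[TranscriptModel, SpliceOutcome, ProteinConsequence]:
    n_res = int(rng.integers(50, 150))
    cds = "ATG" + "".join(
        _SENSE_CODONS[k] for k in rng.choice(len(_SENSE_CODONS), size=n_res)
    ) + ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    utr5 = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(5, 30)))])
    utr3 = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(10, 40)))])
    tx = utr5 + cds + utr3
    cds_start = len(utr5) + 1
    cds_end = len(utr5) + len(cds)

    # cut points strictly inside the CDS interior: start codon stays in exon 1,
    # the stop codon in the last exon, internal exons wholly coding
    interior = np.arange(cds_start + 3, cds_end - 3)
    cuts = np.sort(rng.choice(interior, size=exon_count - 1, replace=False))
    bounds = [0] + cuts.tolist() + [len(tx)]
    tx_exon_seqs = [tx[bounds[k] : bounds[k + 1]] for k in range(exon_count)]

    strand = "+" if rng.random() < 0.5 else "-"
    # genomic layout with random intron gaps
    g_exon_seqs = list(tx_exon_seqs)
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        g_exon_seqs = [s.translate(comp)[::-1] for s in reversed(tx_exon_seqs)]
    exons = []
    pos = int(rng.integers(10_000, 50_000))
    for s in g_exon_seqs:
        exons.append((pos, pos + len(s) - 1))
        pos += len(s) + int(rng.integers(60, 600))
    model = TranscriptModel(gene=f"TX{seed % 10_000:04d}", strand=strand, exons=exons,
                            exon_seqs=g_exon_seqs, cds_start=cds_start, cds_end=cds_end)

    if skip_exon is not None:
        outcome = SpliceOutcome(kind="exon_skip", exon_index=skip_exon)
        start, end = bounds[skip_exon - 1], bounds[skip_exon]
        mut_tx = tx[:start] + tx[end:]
        mut_cds = mut_tx[cds_start - 1 :]
    else:
        junction = int(bounds[int(rng.integers(1, exon_count))])
        ins = "".join(_BASES[rng.integers(0, 4, size=insert_len)])
        outcome = SpliceOutcome(kind="insertion", insert_after=junction, inserted_seq=ins)
        mut_tx = tx[:junction] + ins + tx[junction:]
        mut_cds = mut_tx[cds_start - 1 :]

    try:
        truth = _oracle_consequence(tx[cds_start - 1 : cds_end], mut_cds,
                                    ref_downstream=tx[cds_end:])
    except AssertionError:
        raise _StopLossDraw()
    return model, outcome, truth


def config_to_json(config: SimConfig) -> dict:
    doc = dataclasses.asdict(config)
    return doc
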