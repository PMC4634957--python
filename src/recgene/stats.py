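"""Cohort-level aggregates and statistics.

Works over a per-patient table (one row per genetically confirmed patient:
sex, consanguinity, the two mutation labels of the diplotype, affected gut
segments, clinical covariates).  A transcription of the 18-patient CEAS
cohort ships with the package (``load_ceas_cohort``) together with the
seven-site mutation catalogue (``load_ceas_mutations``); mutation labels may
be given in cDNA (``c.664G>A``), three-letter (``Gly222Arg``) or one-letter
(``G222R``) form and are canonicalised to the cDNA name.

Statistics: per-patient biallelic classification, per-variant allele counts
over an explicit patient subset (the discovery+Sanger patients 1-16 form the
CNSU denominator of 32 chromosomes; the two patients found by screening a
Crohn's-disease cohort are counted separately), Fisher's exact test for 2x2
tables, and a Welch t test recomputable from printed mean/SEM/n summaries.
"""

from __future__ import annotations

import functools
import importlib.resources
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Optional, Sequence

import pandas as pd
from scipy import stats as sps

DISEASE_SITES = ("S", "D", "J", "I")  # stomach, duodenum, jejunum, ileum


@dataclass(frozen=True)
class PatientRecord:
    id: str
    sex: str
    genotype: tuple[str, str]
    sites: frozenset[str]
    consanguinity_degree: Optional[int] = None
    screening_group: str = ""
    covariates: tuple = ()

    def __post_init__(self):
        if not self.sites <= set(DISEASE_SITES):
            raise ValueError(f"unknown disease site in {sorted(self.sites)}")


def _data_path(name: str):
    return importlib.resources.files("recgene.data").joinpath(name)


def load_ceas_mutations() -> pd.DataFrame:
    """The seven-site mutation catalogue (hg19 chr3 positions, cDNA and
    protein names, cohort allele counts as published)."""
    with importlib.resources.as_file(_data_path("ceas_mutations.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str}, keep_default_na=False)


@functools.lru_cache(maxsize=1)
def _label_map() -> dict[str, str]:
    mut = load_ceas_mutations()
    mapping: dict[str, str] = {}
    for row in mut.itertuples():
        for alias in (row.cdna, row.protein3, row.protein1):
            if alias:
                mapping[alias] = row.cdna
    return mapping


def canonical_label(label: str) -> str:
    """Canonicalise a mutation label to its cDNA name; 'WT' passes through."""
    label = label.strip()
    if label.upper() in {"WT", "-", ""}:
        return "WT"
    mapping = _label_map()
    if label in mapping:
        return mapping[label]
    return label  # labels outside the catalogue are kept verbatim


def load_ceas_cohort() -> list[PatientRecord]:
    """The packaged 18-patient cohort table, one PatientRecord per row."""
    with importlib.resources.as_file(_data_path("ceas_cohort.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples():
        slots = parse_genotype(row.genotype)
        degree = row.consanguinity_degree
        records.append(PatientRecord(
            id=str(row.patient),
            sex=row.sex,
            genotype=slots,
            sites=frozenset(s for s in row.disease_sites.split(",") if s),
            consanguinity_degree=int(degree) if degree.isdigit() else None,
            screening_group=row.screening_group,
        ))
    return records


def parse_genotype(text: str) -> tuple[str, str]:
    """Parse a 'label/label' diplotype string into two canonical labels."""
    parts = [p.strip() for p in text.split("/")]
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"genotype must have exactly two slots: {text!r}")
    return (canonical_label(parts[0]), canonical_label(parts[1]))


def classify_genotype(patient: PatientRecord) -> str:
    """homozygous | compound_het | single_het | none."""
    a, b = patient.genotype
    if a == "WT" and b == "WT":
        return "none"
    if a == "WT" or b == "WT":
        return "single_het"
    return "homozygous" if a == b else "compound_het"


@dataclass(frozen=True)
class AlleleCountRow:
    label: str
    case_alt: int
    case_total: int
    control_alt: Optional[int] = None
    control_total: Optional[int] = None

    @property
    def frequency(self) -> float:
        return self.case_alt / self.case_total if self.case_total else float("nan")


def allele_counts(patients: Sequence[PatientRecord], label: str) -> AlleleCountRow:
    """Mutant allele count of ``label`` over an explicit patient subset:
    2 per homozygote, 1 per heterozygous carrier; total = 2 x patients."""
    canon = canonical_label(label)
    alt = sum(sum(1 for slot in p.genotype if slot == canon) for p in patients)
    return AlleleCountRow(label=canon, case_alt=alt, case_total=2 * len(patients))


def feature_proportions(
    patients: Sequence[PatientRecord], predicate: Callable[[PatientRecord], bool]
) -> tuple[int, float]:
    """(count, percent) of patients matching the predicate; percent half-up to
    one decimal (5/18 -> 27.8)."""
    if not patients:
        raise ValueError("empty patient list")
    k = sum(1 for p in patients if predicate(p))
    # exact decimal arithmetic, then round half-up to 1 decimal (5/18 -> 27.8)
    pct = Decimal(100 * k) / Decimal(len(patients))
    return k, float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    haldane: bool  # odds ratio used the +0.5 zero-cell correction


def fisher_exact_2x2(a: int, b: int, c: int, d: int, method: str = "prob") -> FisherResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    ``method='prob'`` (default) sums hypergeometric probabilities no larger
    than the observed table's; ``method='doubling'`` doubles the smaller
    tail.  The odds ratio is ad/bc with the Haldane +0.5 correction when a
    cell is zero (flagged in the result).
    """
    cells = (a, b, c, d)
    if any((not isinstance(x, (int,)) and not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a zero margin makes the test undefined")
    if method == "prob":
        p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    elif method == "doubling":
        n, r1, c1 = a + b + c + d, a + b, a + c
        hg = sps.hypergeom(n, r1, c1)
        p = min(1.0, 2.0 * min(float(hg.cdf(a)), float(hg.sf(a - 1))))
    else:
        raise ValueError(f"unknown method {method!r}")
    if 0 in cells:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return FisherResult(odds_ratio=odds, p_value=p, haldane=True)
    return FisherResult(odds_ratio=(a * d) / (b * c), p_value=p, haldane=False)


@dataclass(frozen=True)
class GroupSummary:
    """A group reported as mean +/- SEM with its size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sem <= 0:
            raise ValueError("sem must be positive")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        import numpy as np

        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()),
                   sem=float(arr.std(ddof=1) / math.sqrt(len(arr))), n=len(arr))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary, pooled: bool = False) -> TTestResult:
    """Two-sided two-sample t test recomputed from printed summaries.

    Default is Welch's unequal-variance form: t = (m1-m2)/sqrt(sem1^2+sem2^2)
    with Welch-Satterthwaite degrees of freedom on the squared SEMs.
    ``pooled=True`` gives the classical equal-variance Student form (group
    SDs recovered as sem*sqrt(n)).
    """
    if pooled:
        s1sq = g1.sem**2 * g1.n
        s2sq = g2.sem**2 * g2.n
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * s1sq + (g2.n - 1) * s2sq) / df
        t = (g1.mean - g2.mean) / math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    else:
        v1, v2 = g1.sem**2, g2.sem**2
        t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p_value=p)


def classification_counts(patients: Sequence[PatientRecord]) -> dict[str, int]:
    """Partition of a patient list by biallelic classification."""
    counts = {"homozygous": 0, "compound_het": 0, "single_het": 0, "none": 0}
    for p in patients:
        counts[classify_genotype(p)] += 1
    return counts
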