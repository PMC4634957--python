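"""Core domain types for the recessive-gene discovery pipeline.

Coordinates are 1-based inclusive genomic positions.  HGVS cDNA (``c.``)
positions count from the A of the initiator ATG; intronic positions carry an
offset (``c.940+1`` is the first intronic base after the exon ending at
coding position 940).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

FUNC_CLASSES = frozenset({"missense", "nonsense", "splice_site", "synonymous", "other"})
#: classes retained by the functional filter (non-synonymous or splice-site)
FUNCTIONAL_CLASSES = frozenset({"missense", "nonsense", "splice_site"})

MISSING = None  # sentinel for an uncalled genotype


class FormatError(ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: Optional[int] = None, path: Optional[str] = None):
        loc = ""
        if path is not None:
            loc += f"{path}: "
        if line is not None:
            loc += f"line {line}: "
        super().__init__(loc + message)
        self.line = line
        self.path = path


class ConfigError(ValueError):
    """An invalid or infeasible configuration."""


class PipelineError(RuntimeError):
    """A stage failed at run time; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class CdnaPosition:
    """HGVS c. position: coding base ``base`` plus optional intron ``offset``.

    ``c.940+1`` -> ``CdnaPosition(940, 1)``; ``c.665-2`` -> ``CdnaPosition(665, -2)``.
    """

    base: int
    offset: int = 0

    def __post_init__(self):
        if self.base < 1:
            raise ValueError(f"cDNA base must be >= 1, got {self.base}")

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    @classmethod
    def parse(cls, text: str) -> "CdnaPosition":
        text = text.strip()
        for sep in ("+", "-"):
            if sep in text[1:]:
                i = text.index(sep, 1)
                return cls(int(text[:i]), int(text[i:]))
        return cls(int(text))


@dataclass(frozen=True)
class Variant:
    """A single alternate allele at a genomic site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    func_class: Optional[str] = None
    known_id: Optional[str] = None
    deleterious_flags: tuple[str, ...] = ()
    cdna_pos: Optional[CdnaPosition] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("Variant holds a single alternate allele; split multi-allelic records")
        if self.func_class is not None and self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_functional(self) -> bool:
        return self.func_class in FUNCTIONAL_CLASSES


def sort_key(v: Variant) -> tuple:
    """Deterministic variant ordering: (chrom, pos, ref, alt) with natural chrom order."""
    c = v.chrom
    return (0, int(c)) if c.isdigit() else (1, c), v.pos, v.ref, v.alt


class CohortGenotypes:
    """Variants x individuals matrix of diploid alternate-allele counts.

    Backed by a pandas DataFrame with string variant keys ("chrom:pos:ref:alt")
    as the index, sample ids as columns, and nullable integers (pd.NA encodes a
    missing/uncalled genotype).
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype("Int64")

    @classmethod
    def from_records(
        cls,
        variant_keys: Sequence[str],
        individuals: Sequence[str],
        counts: Iterable[Sequence[Optional[int]]],
    ) -> "CohortGenotypes":
        df = pd.DataFrame(list(counts), index=list(variant_keys), columns=list(individuals))
        return cls(df)

    @property
    def individuals(self) -> list[str]:
        return list(self.table.columns)

    @property
    def variant_keys(self) -> list[str]:
        return list(self.table.index)

    def alt_count(self, variant_key: str, individual: str) -> Optional[int]:
        val = self.table.at[variant_key, individual]
        return None if pd.isna(val) else int(val)

    def column(self, individual: str) -> pd.Series:
        if individual not in self.table.columns:
            raise KeyError(f"unknown individual id {individual!r}")
        return self.table[individual]

    def restrict(self, variant_keys: Sequence[str]) -> "CohortGenotypes":
        return CohortGenotypes(self.table.loc[list(variant_keys)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortGenotypes) and self.table.equals(other.table)


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affected: str  # "yes" | "no" | "unknown"


@dataclass
class Pedigree:
    """A set of families: individuals with parental links and affection status."""

    individuals: list[Individual]
    consanguinity: dict[str, int] = field(default_factory=dict)  # family_id -> degree

    def __post_init__(self):
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise FormatError("duplicate individual id in pedigree")
        self._validate_links()

    def _validate_links(self):
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise FormatError(f"individual {ind.id}: parent {pid} absent from pedigree")
                if parent.family_id != ind.family_id:
                    raise FormatError(
                        f"individual {ind.id}: parent {pid} belongs to family "
                        f"{parent.family_id}, not {ind.family_id}"
                    )
        # no individual may be its own ancestor
        for ind in self.individuals:
            seen = set()
            stack = [ind.id]
            while stack:
                cur = self._by_id[stack.pop()]
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid == ind.id:
                        raise FormatError(f"pedigree cycle: {ind.id} is its own ancestor")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def get(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def parents(self, individual_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        ind = self.get(individual_id)
        father = self._by_id.get(ind.father_id) if ind.father_id else None
        mother = self._by_id.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def affecteds(self) -> list[Individual]:
        return [i for i in self.individuals if i.affected == "yes"]

    def unaffecteds(self) -> list[Individual]:
        return [i for i in self.individuals if i.affected == "no"]


@dataclass
class TranscriptModel:
    """Exon structure plus sequence for a single transcript.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order; ``exon_seqs`` give the plus-strand genomic sequence of each exon.
    ``cds_start``/``cds_end`` are 1-based transcript-relative coordinates of
    the CDS (inclusive; cds_end is the last base of the stop codon).
    """

    gene: str
    strand: str
    exons: list[tuple[int, int]]
    exon_seqs: list[str]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) != len(self.exon_seqs):
            raise FormatError("exon coordinate and sequence counts differ")
        prev_end = 0
        for (s, e), seq in zip(self.exons, self.exon_seqs):
            if s > e:
                raise FormatError(f"exon interval {s}-{e} is inverted")
            if s <= prev_end:
                raise FormatError(f"exons overlap or are unsorted near {s}-{e}")
            if e - s + 1 != len(seq):
                raise FormatError(f"exon {s}-{e} length does not match its sequence")
            prev_end = e
        tx = self.spliced()
        if not 1 <= self.cds_start < self.cds_end <= len(tx):
            raise FormatError("CDS bounds outside transcript")
        if self.cds_end - self.cds_start + 1 < 3:
            raise FormatError("CDS shorter than one codon")
        if tx[self.cds_start - 1 : self.cds_start + 2] != "ATG":
            raise FormatError("CDS does not begin with a start codon (ATG)")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            import warnings

            warnings.warn(f"CDS length of {self.gene} is not a multiple of 3", stacklevel=2)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths_tx_order(self) -> list[int]:
        lens = [e - s + 1 for s, e in self.exons]
        return lens if self.strand == "+" else lens[::-1]

    def spliced(self) -> str:
        """Spliced transcript sequence in transcript (5'->3') orientation."""
        from Bio.Seq import Seq

        if self.strand == "+":
            return "".join(self.exon_seqs)
        return str(Seq("".join(self.exon_seqs)).reverse_complement())

    def cds(self) -> str:
        return self.spliced()[self.cds_start - 1 : self.cds_end]


@dataclass(frozen=True)
class SpliceOutcome:
    """Observed effect of a splice-site mutation on the mature transcript.

    ``exon_skip``: exon ``exon_index`` (1-based in transcript order) is absent
    from the mature mRNA.  ``insertion``: ``inserted_seq`` is retained after
    transcript position ``insert_after`` (intron retention is modeled by
    giving the retained bases explicitly).
    """

    kind: str  # "exon_skip" | "insertion"
    exon_index: Optional[int] = None
    insert_after: Optional[int] = None
    inserted_seq: Optional[str] = None

    def __post_init__(self):
        if self.kind == "exon_skip":
            if self.exon_index is None or self.exon_index < 1:
                raise ValueError("exon_skip requires a 1-based exon_index")
        elif self.kind == "insertion":
            if not self.inserted_seq:
                raise ValueError("insertion requires a non-empty inserted sequence")
            if self.insert_after is None or self.insert_after < 1:
                raise ValueError("insertion requires a transcript position")
        else:
            raise ValueError(f"unknown splice outcome kind {self.kind!r}")


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect with HGVS p. name.

    ``stop_offset`` (frameshift only) is the Ter position in the shifted
    frame, counting the first altered residue as 1 — a stop appearing after
    six novel residues is ``fs*7``.
    """

    category: str  # missense | nonsense | frameshift | inframe_deletion | no_change | no_stop_found
    position: Optional[int] = None
    ref_aa: Optional[str] = None
    new_aa: Optional[str] = None
    stop_offset: Optional[int] = None
    hgvs_p: str = "p.="

    def __post_init__(self):
        if self.category == "frameshift" and (self.stop_offset is None or self.stop_offset < 2):
            raise ValueError("frameshift requires stop_offset >= 2")
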