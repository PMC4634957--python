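"""Protein-level consequences of coding and splice-site mutations.

Splice-site mutations at donor +1 positions typically either skip the
upstream exon or retain intronic sequence in the mature mRNA.  Given a
transcript model and an observed splice outcome this module rebuilds the
mutant coding sequence, translates it, and names the protein change in HGVS
style: a skipped exon whose length is not a multiple of 3 shifts the reading
frame and usually introduces a premature stop (``p.R288Gfs*7`` means the
frame shifts at residue 288, arginine becomes glycine, and a stop appears at
position 7 of the new frame); an in-frame skip deletes a block of residues.

Only the standard nuclear genetic code is supported; selenocysteine
recoding and non-ATG initiation are not.
"""

from __future__ import annotations

import re
from typing import Optional

from Bio.Seq import Seq

from .model import CdnaPosition, ProteinConsequence, SpliceOutcome, TranscriptModel

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Ter",
}


class UnsupportedConsequenceError(ValueError):
    """A case outside the supported event space (e.g. loss of the start codon)."""


def cdna_codon_index(cdna_pos: int | CdnaPosition) -> int:
    """Residue index of the codon containing coding position ``cdna_pos``.

    Position 1 is the A of the initiator ATG, so the mapping is
    ceil(pos / 3): c.664 -> 222, c.1807 -> 603.  Intron-offset positions have
    no codon and are rejected.
    """
    if isinstance(cdna_pos, CdnaPosition):
        if cdna_pos.is_intronic:
            raise ValueError(f"c.{cdna_pos} is intronic; no codon index")
        pos = cdna_pos.base
    else:
        pos = int(cdna_pos)
    if pos < 1:
        raise ValueError(f"cDNA position must be >= 1, got {pos}")
    return (pos + 2) // 3


def translate_to_stop(cds: str) -> tuple[str, bool]:
    """Translate codons until the first stop; returns (protein, stop_found).

    Trailing bases short of a full codon are ignored.
    """
    usable = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:usable]).translate())
    stop = prot.find("*")
    if stop >= 0:
        return prot[:stop], True
    return prot, False


def apply_splice_outcome(model: TranscriptModel, outcome: SpliceOutcome) -> str:
    """Rebuild the mutant coding sequence implied by a splice outcome.

    The CDS is re-extracted from the original start codon and runs to the end
    of the mutant transcript (a shifted frame moves the stop, so the original
    CDS end is meaningless).  Skipping the exon that contains the start codon
    is not supported.
    """
    tx = model.spliced()
    cds_start = model.cds_start
    if outcome.kind == "exon_skip":
        lens = model.exon_lengths_tx_order()
        idx = outcome.exon_index
        if not 1 <= idx <= len(lens):
            raise ValueError(f"exon index {idx} outside 1..{len(lens)}")
        start = sum(lens[: idx - 1])  # 0-based transcript offset of the exon
        end = start + lens[idx - 1]
        # start codon occupies 0-based offsets [cds_start-1, cds_start+2)
        if start < cds_start + 2 and end > cds_start - 1:
            raise UnsupportedConsequenceError("skipped exon overlaps the start codon")
        mutant = tx[:start] + tx[end:]
        new_cds_start = cds_start - (end - start) if end <= cds_start - 1 else cds_start
        return mutant[new_cds_start - 1 :]
    elif outcome.kind == "insertion":
        p = outcome.insert_after
        if p > len(tx):
            raise ValueError(f"insertion point {p} beyond transcript length {len(tx)}")
        mutant = tx[:p] + outcome.inserted_seq.upper() + tx[p:]
        new_cds_start = cds_start + len(outcome.inserted_seq) if p < cds_start else cds_start
        return mutant[new_cds_start - 1 :]
    raise ValueError(f"unknown outcome kind {outcome.kind!r}")


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def name_consequence(
    ref_cds: str,
    mut_cds: str,
    three_letter: bool = False,
    ref_downstream: str = "",
) -> ProteinConsequence:
    """Compare reference and mutant coding sequences and name the change.

    The reference CDS must translate without an internal stop (its terminal
    stop codon may be present or implied).  Classification is at the protein
    level: identical products are ``no_change``; a truncation whose stop
    replaces the first altered residue is ``nonsense``; a single substitution
    is ``missense``; an in-frame net length change whose downstream product
    realigns is ``inframe_deletion``; anything else that still reaches a stop
    is a ``frameshift``; a mutant that runs off the sequence end without a
    stop is reported as ``no_stop_found`` rather than an error.

    In-frame calls additionally require the realigned nucleotides to match
    verbatim through the stop codon — a shifted frame can recreate a short
    protein suffix by chance, but (given context) not the nucleotide tail.
    Pass the reference 3'UTR as ``ref_downstream`` when available: it extends
    that comparison beyond the stop codon and resolves events close to the
    transcript end.
    """
    ref_cds = ref_cds.upper()
    mut_cds = mut_cds.upper()
    ref_downstream = ref_downstream.upper()
    usable = len(ref_cds) - len(ref_cds) % 3
    full = str(Seq(ref_cds[:usable]).translate())
    first_stop = full.find("*")
    if 0 <= first_stop < len(full) - 1:
        raise ValueError("reference CDS contains an internal stop codon")
    ref_p, ref_term = translate_to_stop(ref_cds)
    mut_p, mut_term = translate_to_stop(mut_cds)

    if mut_p == ref_p:
        return ProteinConsequence(category="no_change", hgvs_p="p.=")

    i = _common_prefix_len(ref_p, mut_p)  # 0-based first divergent residue

    def fmt(aa: str) -> str:
        return AA3[aa] if three_letter else ("X" if aa == "*" else aa)

    if i == len(ref_p):
        # the whole reference product is a prefix of the mutant: stop lost
        raise UnsupportedConsequenceError("stop-codon loss / extension is outside the event space")

    if i == len(mut_p):
        if not mut_term:
            return ProteinConsequence(
                category="no_stop_found", position=i + 1, ref_aa=ref_p[i],
                hgvs_p=f"p.{fmt(ref_p[i])}{i + 1}fs*?",
            )
        # truncated product: stop codon at the first altered residue
        return ProteinConsequence(
            category="nonsense", position=i + 1, ref_aa=ref_p[i], new_aa="*",
            hgvs_p=f"p.{fmt(ref_p[i])}{i + 1}{'Ter' if three_letter else 'X'}",
        )

    delta = len(ref_p) - len(mut_p)  # >0 net deletion, <0 net insertion

    ref_full = ref_cds[: 3 * (len(ref_p) + 1)] + ref_downstream

    def nt_realigned(p_ref: int, p_mut: int, min_len: int = 6) -> bool:
        a = ref_full[3 * p_ref :]
        b = mut_cds[3 * p_mut :]
        n = min(len(a), len(b))
        return n >= min_len and a[:n] == b[:n]

    if (delta == 0 and mut_term and ref_p[i + 1 :] == mut_p[i + 1 :]
            and nt_realigned(i + 1, i + 1, min_len=3)):
        return ProteinConsequence(
            category="missense", position=i + 1, ref_aa=ref_p[i], new_aa=mut_p[i],
            hgvs_p=f"p.{fmt(ref_p[i])}{i + 1}{fmt(mut_p[i])}",
        )

    if delta != 0 and mut_term:
        # pure block deletion/insertion: suffixes realign exactly at i
        if delta > 0 and ref_p[i + delta :] == mut_p[i:] and nt_realigned(i + delta, i):
            last = i + delta  # 1-based index of last deleted residue
            if delta == 1:
                hgvs = f"p.{fmt(ref_p[i])}{i + 1}del"
            else:
                hgvs = f"p.{fmt(ref_p[i])}{i + 1}_{fmt(ref_p[last - 1])}{last}del"
            return ProteinConsequence(
                category="inframe_deletion", position=i + 1, ref_aa=ref_p[i], hgvs_p=hgvs,
            )
        if delta < 0 and mut_p[i - delta :] == ref_p[i:] and nt_realigned(i, i - delta):
            ins = mut_p[i : i - delta]
            hgvs = f"p.{fmt(ref_p[max(i - 1, 0)])}{i}_{fmt(ref_p[i])}{i + 1}ins{''.join(fmt(a) for a in ins)}"
            return ProteinConsequence(
                category="inframe_deletion", position=i + 1, ref_aa=ref_p[i], hgvs_p=hgvs,
            )
        # delins at the junction residue: suffixes realign one residue later
        # (the protein suffix may be empty when the deleted block reaches the
        # end of the protein; the nucleotide check carries the evidence then)
        if (ref_p[i + 1 + max(delta, 0) :] == mut_p[i + 1 + max(-delta, 0) :]
                and nt_realigned(i + 1 + max(delta, 0), i + 1 + max(-delta, 0))):
            new_block = mut_p[i : i + 1 + max(-delta, 0)]
            hgvs = f"p.{fmt(ref_p[i])}{i + 1}delins{''.join(fmt(a) for a in new_block)}"
            return ProteinConsequence(
                category="inframe_deletion", position=i + 1, ref_aa=ref_p[i],
                new_aa=mut_p[i], hgvs_p=hgvs,
            )

    if not mut_term:
        return ProteinConsequence(
            category="no_stop_found", position=i + 1, ref_aa=ref_p[i], new_aa=mut_p[i],
            hgvs_p=f"p.{fmt(ref_p[i])}{i + 1}{fmt(mut_p[i])}fs*?",
        )

    stop_offset = len(mut_p) - i + 1  # Ter position with the first altered residue as 1
    return ProteinConsequence(
        category="frameshift", position=i + 1, ref_aa=ref_p[i], new_aa=mut_p[i],
        stop_offset=stop_offset,
        hgvs_p=f"p.{fmt(ref_p[i])}{i + 1}{fmt(mut_p[i])}fs*{stop_offset}",
    )


def apply_cdna_substitution(cds: str, cdna_pos: int | CdnaPosition, ref: str, alt: str) -> str:
    """Apply an exonic single-base substitution (c.NX>Y) to a CDS string."""
    if isinstance(cdna_pos, CdnaPosition):
        if cdna_pos.is_intronic:
            raise ValueError("intronic substitutions have no direct CDS edit")
        pos = cdna_pos.base
    else:
        pos = int(cdna_pos)
    if not 1 <= pos <= len(cds):
        raise ValueError(f"c.{pos} outside CDS of length {len(cds)}")
    if cds[pos - 1] != ref.upper():
        raise ValueError(f"reference base at c.{pos} is {cds[pos - 1]}, not {ref}")
    return cds[: pos - 1] + alt.upper() + cds[pos:]


_HGVS_RE = re.compile(
    r"^p\.(?:(?P<eq>=)|"
    r"(?P<ref>[A-Z\*])(?P<pos>\d+)"
    r"(?:(?P<stop>X)$|"
    r"(?P<fs_new>[A-Z])?fs\*(?P<fs_off>\d+|\?)|"
    r"_(?P<ref2>[A-Z])(?P<pos2>\d+)(?:del$|ins(?P<ins>[A-Z]+))|"
    r"del$|delins(?P<delins>[A-Z\*]+)|"
    r"(?P<new>[A-Z])$))",
)


def parse_hgvs_p(hgvs: str) -> tuple[str, Optional[int], Optional[int]]:
    """Parse a single-letter HGVS p. string emitted by this module back to
    (category, position, stop_offset)."""
    m = _HGVS_RE.match(hgvs)
    if not m:
        raise ValueError(f"unparseable HGVS p. string {hgvs!r}")
    if m.group("eq"):
        return ("no_change", None, None)
    pos = int(m.group("pos"))
    if m.group("fs_off") is not None:
        if m.group("fs_off") == "?":
            return ("no_stop_found", pos, None)
        return ("frameshift", pos, int(m.group("fs_off")))
    if m.group("stop"):
        return ("nonsense", pos, None)
    if m.group("ref2") or hgvs.endswith("del") or m.group("delins") or m.group("ins"):
        # insertions report the position after the anchor residue
        if m.group("ins"):
            return ("inframe_deletion", pos + 1, None)
        return ("inframe_deletion", pos, None)
    if m.group("new"):
        if m.group("new") == "X":
            return ("nonsense", pos, None)
        return ("missense", pos, None)
    raise ValueError(f"unparseable HGVS p. string {hgvs!r}")
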