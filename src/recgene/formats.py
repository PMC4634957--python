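"""Readers and writers for the pipeline's external formats.

Formats (all plain text):

* VCF v4.2 subset — columns CHROM POS ID REF ALT QUAL FILTER INFO FORMAT
  plus one column per sample.  Recognised INFO keys: ``GENE`` (gene symbol),
  ``FUNC`` (functional class), ``KNOWN`` (known-variant id), ``DEL``
  (comma-joined opaque deleteriousness flags), ``CDNA`` (HGVS c. position,
  e.g. ``940+1``).  FORMAT must contain ``GT``.  Multi-allelic records are
  split into one variant per alternate allele with genotype allele indices
  remapped; ``./.`` maps to a missing call; a phase separator ``|`` is
  accepted and discarded at this layer.
* PED — 6 whitespace-separated columns: family, individual, father, mother,
  sex (1=male 2=female 0=unknown), phenotype (1=unaffected 2=affected
  0=unknown).  ``0`` in a parent column means "not in pedigree".
* Known-variant list — header ``chrom pos ref alt id``, tab-separated.
* Transcript model — a JSON document with keys ``gene``, ``strand``,
  ``exons`` (list of [start, end]), ``exon_seqs``, ``cds_start``,
  ``cds_end``.

The VCF writer emits a canonical form: round-tripping a canonical file is
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from .model import (
    CdnaPosition,
    CohortGenotypes,
    FormatError,
    FUNC_CLASSES,
    Individual,
    Pedigree,
    TranscriptModel,
    Variant,
)

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">',
    '##INFO=<ID=KNOWN,Number=1,Type=String,Description="Known-variant identifier">',
    '##INFO=<ID=DEL,Number=.,Type=String,Description="Deleteriousness annotations">',
    '##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS cDNA position">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _parse_info(info: str, n_alts: int, line_no: int, path: str) -> list[dict]:
    """Split an INFO string into one dict per alternate allele."""
    per_alt: list[dict] = [dict() for _ in range(n_alts)]
    if info in {".", ""}:
        return per_alt
    for item in info.split(";"):
        if not item:
            continue
        if "=" not in item:
            continue  # flag keys are not part of the subset; ignored
        key, _, value = item.partition("=")
        values = value.split(",")
        if key in {"GENE", "FUNC", "KNOWN", "CDNA"} and len(values) not in {1, n_alts}:
            raise FormatError(
                f"INFO {key} has {len(values)} values for {n_alts} alternate alleles",
                line=line_no,
                path=path,
            )
        for i in range(n_alts):
            if key == "DEL":
                per_alt[i][key] = tuple(values)
            else:
                per_alt[i][key] = values[i] if len(values) == n_alts else values[0]
    return per_alt


def _parse_gt(gt: str, alt_index: int, line_no: int, path: str) -> Optional[int]:
    gt = gt.split(":", 1)[0]
    sep = "|" if "|" in gt else "/"
    fields = gt.split(sep)
    if len(fields) != 2:
        raise FormatError(f"malformed GT {gt!r} (diploid calls required)", line=line_no, path=path)
    if fields[0] == "." or fields[1] == ".":
        if fields != [".", "."]:
            raise FormatError(f"malformed GT {gt!r} (half-missing calls unsupported)", line=line_no, path=path)
        return None
    try:
        alleles = [int(f) for f in fields]
    except ValueError:
        raise FormatError(f"malformed GT {gt!r}", line=line_no, path=path) from None
    if any(a < 0 for a in alleles):
        raise FormatError(f"malformed GT {gt!r}", line=line_no, path=path)
    return sum(1 for a in alleles if a == alt_index)


def read_vcf(path, strict_func: bool = False) -> tuple[list[Variant], CohortGenotypes]:
    """Read the VCF subset; returns variants (input order, multi-allelics split)
    and the cohort genotype matrix.

    With ``strict_func=True`` records lacking a FUNC annotation are rejected
    rather than carried with an unknown class.
    """
    path = str(path)
    samples: list[str] = []
    variants: list[Variant] = []
    rows: list[list[Optional[int]]] = []
    seen_keys: set = set()
    with open(path) as fh:
        header_seen = False
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise FormatError("malformed #CHROM header", line=line_no, path=path)
                samples = cols[9:]
                if len(set(samples)) != len(samples):
                    raise FormatError("duplicate sample id in header", line=line_no, path=path)
                header_seen = True
                continue
            if not header_seen:
                raise FormatError("data line before #CHROM header", line=line_no, path=path)
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise FormatError(
                    f"expected {9 + len(samples)} columns, found {len(cols)}",
                    line=line_no, path=path,
                )
            chrom, pos_s, vid, ref, alt_s, _qual, _filt, info_s, fmt = cols[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"non-integer POS {pos_s!r}", line=line_no, path=path) from None
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise FormatError("FORMAT lacks GT", line=line_no, path=path)
            if fmt_keys[0] != "GT":
                raise FormatError("GT must be the first FORMAT key", line=line_no, path=path)
            alts = alt_s.split(",")
            infos = _parse_info(info_s, len(alts), line_no, path)
            for ai, (alt, inf) in enumerate(zip(alts, infos), start=1):
                func = inf.get("FUNC")
                if func is not None and func not in FUNC_CLASSES:
                    raise FormatError(f"unknown FUNC value {func!r}", line=line_no, path=path)
                if strict_func and func is None:
                    raise FormatError("record lacks FUNC annotation (strict mode)", line=line_no, path=path)
                known = inf.get("KNOWN")
                if known is None and vid not in {".", ""}:
                    known = vid.split(";")[0]
                try:
                    var = Variant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gene=inf.get("GENE"),
                        func_class=func,
                        known_id=known,
                        deleterious_flags=inf.get("DEL", ()),
                        cdna_pos=CdnaPosition.parse(inf["CDNA"]) if "CDNA" in inf else None,
                    )
                except ValueError as exc:
                    raise FormatError(str(exc), line=line_no, path=path) from None
                if var.key in seen_keys:
                    raise FormatError(f"duplicate variant {var.key_str}", line=line_no, path=path)
                seen_keys.add(var.key)
                variants.append(var)
                rows.append([_parse_gt(g, ai, line_no, path) for g in cols[9:]])
    genotypes = CohortGenotypes.from_records([v.key_str for v in variants], samples, rows)
    return variants, genotypes


def write_vcf(path, variants: Sequence[Variant], genotypes: CohortGenotypes) -> None:
    """Write the canonical single-allele-per-record form of the VCF subset."""
    with open(path, "w") as fh:
        for hline in _VCF_HEADER_LINES:
            fh.write(hline + "\n")
        fh.write("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                            "INFO", "FORMAT"] + genotypes.individuals) + "\n")
        for v in variants:
            info_items = []
            if v.gene is not None:
                info_items.append(f"GENE={v.gene}")
            if v.func_class is not None:
                info_items.append(f"FUNC={v.func_class}")
            if v.known_id is not None:
                info_items.append(f"KNOWN={v.known_id}")
            if v.deleterious_flags:
                info_items.append("DEL=" + ",".join(v.deleterious_flags))
            if v.cdna_pos is not None:
                info_items.append(f"CDNA={v.cdna_pos}")
            info = ";".join(info_items) if info_items else "."
            gts = []
            for ind in genotypes.individuals:
                ac = genotypes.alt_count(v.key_str, ind)
                gts.append({None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}[ac])
            fh.write("\t".join([v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".",
                                info, "GT"] + gts) + "\n")


_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PHENO = {"1": "no", "2": "yes", "0": "unknown"}


def read_ped(path, consanguinity: Optional[dict[str, int]] = None) -> Pedigree:
    """Read a 6-column PED file into a validated Pedigree.

    ``consanguinity`` optionally maps family id -> degree of the consanguineous
    mating (PED has no column for it).
    """
    path = str(path)
    individuals: list[Individual] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise FormatError(f"expected 6 columns, found {len(cols)}", line=line_no, path=path)
            fam, iid, father, mother, sex, pheno = cols
            if sex not in _SEX:
                raise FormatError(f"sex must be 0/1/2, got {sex!r}", line=line_no, path=path)
            if pheno not in _PHENO:
                raise FormatError(f"phenotype must be 0/1/2, got {pheno!r}", line=line_no, path=path)
            individuals.append(Individual(
                id=iid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX[sex],
                affected=_PHENO[pheno],
            ))
    return Pedigree(individuals, consanguinity=dict(consanguinity or {}))


def write_ped(path, pedigree: Pedigree) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"no": "1", "yes": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            fh.write("\t".join([
                ind.family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
                sex_code[ind.sex], pheno_code[ind.affected],
            ]) + "\n")


def read_known_list(path) -> dict[tuple[str, int, str, str], str]:
    """Read the known-variant list; keys are full (chrom, pos, ref, alt) tuples."""
    path = str(path)
    known: dict[tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if line_no == 1 and cols[:4] == ["chrom", "pos", "ref", "alt"]:
                continue
            if len(cols) != 5:
                raise FormatError(f"expected 5 columns, found {len(cols)}", line=line_no, path=path)
            chrom, pos_s, ref, alt, vid = cols
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"non-integer pos {pos_s!r}", line=line_no, path=path) from None
            known[(chrom, pos, ref, alt)] = vid
    return known


def write_known_list(path, known: dict[tuple[str, int, str, str], str]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tid\n")
        for (chrom, pos, ref, alt), vid in known.items():
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{vid}\n")


def read_transcript(path) -> TranscriptModel:
    """Read and validate a transcript model from its JSON document."""
    path = str(path)
    with open(path) as fh:
        doc = json.load(fh)
    missing = {"gene", "strand", "exons", "exon_seqs", "cds_start", "cds_end"} - set(doc)
    if missing:
        raise FormatError(f"transcript model lacks keys: {sorted(missing)}", path=path)
    return TranscriptModel(
        gene=doc["gene"],
        strand=doc["strand"],
        exons=[tuple(e) for e in doc["exons"]],
        exon_seqs=[s.upper() for s in doc["exon_seqs"]],
        cds_start=int(doc["cds_start"]),
        cds_end=int(doc["cds_end"]),
    )


def write_transcript(path, model: TranscriptModel) -> None:
    doc = {
        "gene": model.gene,
        "strand": model.strand,
        "exons": [list(e) for e in model.exons],
        "exon_seqs": model.exon_seqs,
        "cds_start": model.cds_start,
        "cds_end": model.cds_end,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_tsv(path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    """Write a report TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if x is None else str(x) for x in row) + "\n")
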