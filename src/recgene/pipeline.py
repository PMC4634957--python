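"""End-to-end orchestration: simulate -> prioritize -> segregate ->
consequence -> stats, with TSV/JSON outputs and a reproducibility manifest.

Each stage writes only into its own subdirectory of the output directory;
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__, consequence, formats, prioritize, simulate, stats
from .model import ConfigError, PipelineError, SpliceOutcome

_KNOWN_KEYS = {"seed", "out", "sim", "prioritize", "stats"}
_KNOWN_PRI_KEYS = {
    "required_hom_individuals", "additional_affecteds",
    "hom_only_for_consanguineous", "strict_missing",
}
_KNOWN_STATS_KEYS = {"ttest", "fisher"}


@dataclass
class RunConfig:
    seed: int = 0
    out: str = "recgene_out"
    sim: dict = field(default_factory=dict)
    required_hom_individuals: list[str] = field(
        default_factory=lambda: list(simulate.CONSANGUINEOUS_PROBANDS))
    additional_affecteds: list[str] = field(default_factory=lambda: list(simulate.SIB_PAIR))
    hom_only_for_consanguineous: bool = True
    strict_missing: bool = False
    ttest: str = "welch"
    fisher: str = "prob"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        pri = doc.get("prioritize", {})
        if set(pri) - _KNOWN_PRI_KEYS:
            raise ConfigError(f"unknown prioritize keys: {sorted(set(pri) - _KNOWN_PRI_KEYS)}")
        st = doc.get("stats", {})
        if set(st) - _KNOWN_STATS_KEYS:
            raise ConfigError(f"unknown stats keys: {sorted(set(st) - _KNOWN_STATS_KEYS)}")
        cfg = cls(seed=int(doc.get("seed", 0)), out=str(doc.get("out", "recgene_out")),
                  sim=dict(doc.get("sim", {})))
        for k in _KNOWN_PRI_KEYS:
            if k in pri:
                setattr(cfg, k, pri[k])
        if "ttest" in st:
            cfg.ttest = st["ttest"]
        if "fisher" in st:
            cfg.fisher = st["fisher"]
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    try:
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
    except TypeError as exc:
        raise ConfigError(f"bad sim config: {exc}") from exc
    cohort = simulate.generate_cohort(sim_cfg)
    paths = cohort.write(outdir / "sim")
    return {"paths": {k: str(v) for k, v in paths.items()},
            "counts": cohort.truth["counts"]}


def stage_prioritize(
    config: RunConfig, outdir: Path,
    vcf: Path, ped: Path, known_path: Path,
) -> dict:
    for p, name in ((vcf, "vcf"), (ped, "ped"), (known_path, "known list")):
        if not Path(p).exists():
            raise FileNotFoundError(f"stage 'prioritize': missing {name} file {p}")
    variants, genotypes = formats.read_vcf(vcf)
    pedigree = formats.read_ped(ped)
    known = formats.read_known_list(known_path)
    for ind in config.required_hom_individuals + config.additional_affecteds:
        if ind not in genotypes.individuals:
            raise PipelineError("prioritize", f"required individual {ind} not genotyped")
    report = prioritize.discover(
        variants, genotypes, pedigree, known,
        required_hom_individuals=config.required_hom_individuals,
        additional_affecteds=config.additional_affecteds,
        hom_only_for_consanguineous=config.hom_only_for_consanguineous,
        strict_missing=config.strict_missing,
    )
    stage_dir = outdir / "prioritize"
    stage_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gene in report.final_genes:
        for ind, keys in sorted(report.supporting[gene].items()):
            rows.append((gene, ind, ";".join(keys)))
    formats.write_tsv(stage_dir / "candidate_genes.tsv",
                      ["gene", "individual", "supporting_variants"], rows)
    shared_rows = [(g, "yes" if g in report.final_genes else "no")
                   for g in sorted(report.shared_genes)]
    formats.write_tsv(stage_dir / "shared_genes.tsv", ["gene", "survives_exclusion"], shared_rows)
    (stage_dir / "audit.json").write_text(json.dumps(report.audit, indent=1, sort_keys=True) + "\n")
    return {"audit": report.audit, "final_genes": report.final_genes}


def stage_segregate(
    config: RunConfig, outdir: Path,
    vcf: Path, ped: Path, variant_keys: list[str], family_id: Optional[str] = None,
) -> dict:
    if not Path(vcf).exists() or not Path(ped).exists():
        raise FileNotFoundError("stage 'segregate': missing genotype or pedigree file")
    variants, genotypes = formats.read_vcf(vcf)
    pedigree = formats.read_ped(ped)
    result = prioritize.check_segregation(pedigree, genotypes, variant_keys, family_id=family_id)
    stage_dir = outdir / "segregate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    rows = [(ind, result.expected[ind], result.observed[ind]) for ind in sorted(result.expected)]
    formats.write_tsv(stage_dir / "segregation.tsv", ["individual", "expected", "observed"], rows)
    doc = {"variants": result.variant_keys, "consistent": result.consistent,
           "violations": result.violations, "untestable": result.untestable}
    (stage_dir / "segregation.json").write_text(json.dumps(doc, indent=1) + "\n")
    return doc


def stage_consequence(config: RunConfig, outdir: Path,
                      model, outcomes: list[SpliceOutcome]) -> dict:
    stage_dir = outdir / "consequence"
    stage_dir.mkdir(parents=True, exist_ok=True)
    ref_cds = model.cds()
    downstream = model.spliced()[model.cds_end :]
    rows = []
    for oc in outcomes:
        mut = consequence.apply_splice_outcome(model, oc)
        pc = consequence.name_consequence(ref_cds, mut, ref_downstream=downstream)
        desc = (f"skip_exon_{oc.exon_index}" if oc.kind == "exon_skip"
                else f"ins{len(oc.inserted_seq)}bp@{oc.insert_after}")
        rows.append((model.gene, desc, pc.category, pc.position, pc.stop_offset, pc.hgvs_p))
    formats.write_tsv(stage_dir / "consequences.tsv",
                      ["gene", "event", "category", "position", "stop_offset", "hgvs_p"], rows)
    return {"events": [dict(zip(["gene", "event", "category", "position",
                                 "stop_offset", "hgvs_p"], r)) for r in rows]}


def stage_stats(config: RunConfig, outdir: Path) -> dict:
    stage_dir = outdir / "stats"
    stage_dir.mkdir(parents=True, exist_ok=True)
    cohort = stats.load_ceas_cohort()
    cnsu = [p for p in cohort if p.screening_group in {"wes", "sanger"}]
    catalogue = stats.load_ceas_mutations()
    rows = []
    for rec in catalogue.itertuples():
        ac = stats.allele_counts(cnsu, rec.cdna)
        rows.append((rec.number, rec.cdna, rec.effect, f"{ac.case_alt}/{ac.case_total}"))
    formats.write_tsv(stage_dir / "allele_counts.tsv",
                      ["number", "cdna", "effect", "cnsu_allele_frequency"], rows)
    cls = stats.classification_counts(cohort)
    n_f, pct_f = stats.feature_proportions(cohort, lambda p: p.sex == "F")
    site_rows = []
    for site in stats.DISEASE_SITES:
        k, pct = stats.feature_proportions(cohort, lambda p, s=site: s in p.sites)
        site_rows.append((site, k, len(cohort), pct))
    formats.write_tsv(stage_dir / "proportions.tsv",
                      ["feature", "count", "n", "percent"],
                      [("female", n_f, len(cohort), pct_f)] + site_rows)
    b = simulate.BiomarkerConfig()
    tt = stats.welch_t_from_summary(
        stats.GroupSummary(b.mean_case, b.sem_case, b.n_case),
        stats.GroupSummary(b.mean_control, b.sem_control, b.n_control),
        pooled=(config.ttest == "pooled"),
    )
    doc = {
        "classification": cls,
        "female": {"count": n_f, "n": len(cohort), "percent": pct_f},
        "sites": {s: {"count": k, "n": n, "percent": pct} for s, k, n, pct in site_rows},
        "biomarker_ttest": {"t": tt.t, "df": tt.df, "p": tt.p_value, "flavor": config.ttest},
    }
    (stage_dir / "summary.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in study order and write the manifest; returns it."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": {"name": "recgene", "version": __version__},
        "config": {
            "seed": config.seed, "sim": config.sim,
            "prioritize": {
                "required_hom_individuals": config.required_hom_individuals,
                "additional_affecteds": config.additional_affecteds,
                "hom_only_for_consanguineous": config.hom_only_for_consanguineous,
                "strict_missing": config.strict_missing,
            },
            "stats": {"ttest": config.ttest, "fisher": config.fisher},
        },
        "stages": {},
    }
    sim_info = stage_simulate(config, outdir)
    manifest["stages"]["simulate"] = sim_info
    sim_paths = {k: Path(v) for k, v in sim_info["paths"].items()}
    manifest["inputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                          for k, p in sorted(sim_paths.items())}

    pri = stage_prioritize(config, outdir, sim_paths["vcf"], sim_paths["ped"], sim_paths["known"])
    manifest["stages"]["prioritize"] = pri

    truth = json.loads(sim_paths["truth"].read_text())
    seg = stage_segregate(
        config, outdir, sim_paths["segregation_vcf"], sim_paths["ped"],
        [truth["causal_variants"]["family_A_hom"]], family_id="A",
    )
    manifest["stages"]["segregate"] = seg

    model, outcome, _truth_pc = simulate.generate_transcript_case(
        seed=config.seed + 101, exon_count=7, skip_exon=4)
    model_i, outcome_i, _ = simulate.generate_transcript_case(
        seed=config.seed + 202, exon_count=7, insert_len=23)
    cons = stage_consequence(config, outdir, model, [outcome])
    cons_i = stage_consequence(config, outdir / "insertion_case", model_i, [outcome_i])
    manifest["stages"]["consequence"] = {"exon_skip": cons, "insertion": cons_i}

    manifest["stages"]["stats"] = stage_stats(config, outdir)

    audit = pri["audit"]
    order = ["input_variants", "functional", "after_known_filter",
             "shared_candidate_genes", "final_genes"]
    counts = [audit[k] for k in order]
    if any(x < y for x, y in zip(counts[:3], counts[1:3])) or counts[3] < counts[4]:
        raise PipelineError("manifest", "filter cascade counts increased")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
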