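# Methods

## The inference model

The pipeline assumes a fully penetrant autosomal-recessive disease in a
small cohort of exome-sequenced individuals. Under consanguinity the causal
genotype is homozygous by descent, so candidate genes in a consanguineous
affected are those with at least one homozygous functional variant absent
from the known-polymorphism list. In outbred affected sib pairs the causal
genotype may instead be compound-heterozygous: two distinct heterozygous
candidate variants in one gene, in trans. When both parents are genotyped, a
pair qualifies only if the two variants can be assigned to different
parental origins (a variant's possible origins are the parents that carry
it; a parent with a missing call at that site remains a possible origin);
without parental data the trans configuration is assumed, which is
deliberately permissive — phase cannot be observed from unrelated short
reads.

Candidate sets are intersected across families at the **gene** level, not
the variant level, because different families can carry different alleles
of the same gene (here, one family carries a private splice-site allele
while two others share a second one). Exclusion by unaffected individuals
applies the same biallelic pattern test as candidacy — homozygous or
trans-possible compound het — and never mere carriage, since unaffected
carriers are expected under a recessive model. Genes must additionally show
an AR pattern in every supplementary affected.

Missing genotypes are conservative in both directions: they never qualify
an individual for a candidate pattern and never disqualify a gene during
unaffected exclusion. A strict mode (`strict_missing`) treats missingness
in unaffecteds as disqualifying for users who prefer to fail safe in the
other direction. `hom_only_for_consanguineous` (default true) restricts the
consanguineous branch to homozygous patterns, matching the discovery design
this package reproduces; setting it false also admits compound hets there.

Segregation checking declares a pedigree consistent iff every affected is
biallelic for the nominated variants, no unaffected is, and every genotyped
parent of an affected carries at least one causal allele. Ungenotyped or
uncalled individuals are reported untestable rather than violated.

## Consequence naming

Splice outcomes are applied to a validated transcript model (ordered,
non-overlapping exons; spliced sequence; CDS beginning with ATG). An exon
skip removes the exon's bases from the mature transcript; intron retention
is modelled as an explicit inserted sequence at a transcript position —
cryptic-splice-site prediction is out of scope, so the retained bases are
an input, not a prediction. The mutant CDS is re-extracted from the
original start codon and runs to the transcript end, since a shifted frame
moves the stop.

Classification compares the translated products (standard nuclear code
only): identical → `no_change`; truncation with a stop at the first altered
residue → `nonsense` (this also covers the rare frameshift whose first
shifted codon is a stop, which HGVS likewise names as a substitution to
Ter); single substitution → `missense`; in-frame net length change with a
realigned downstream product → `inframe_deletion`; otherwise `frameshift`,
with `fs*N` counting the new-frame stop from the first altered residue as 1
(a stop "after six residues" is `fs*7`). A mutant that reaches the sequence
end without a stop is reported as `no_stop_found`, not an error.

In-frame calls additionally require the realigned **nucleotides** to match
verbatim (at least two codons' worth, through the stop codon, extended into
the 3'UTR when the caller provides it). This matters: a shifted frame can
recreate a short protein suffix — or even the terminal residue plus stop
codon — by chance, in which case the frameshift and delins descriptions are
genuinely indistinguishable at the sequence level. With 3'UTR context the
ambiguity is resolved essentially always; without it, events very close to
the stop codon may be named as the other form. Stop-codon loss (the whole
reference product is a prefix of the mutant) is outside the supported event
space and raises a dedicated error.

Both single-letter (`p.R603X`, canonical in reports) and three-letter
(`p.Arg603X`) forms are emitted, and every emitted name parses back to
(category, position, stop offset).

## Synthetic cohorts

The generator emulates the study design exactly: probands A, B, C from
consanguineous matings (degrees 5, 3, 3), with A homozygous for a private
splice-site variant and B and C sharing a second one; an affected sib pair
compound-heterozygous for a missense and a nonsense variant with one
carrier parent each; A's unaffected sister heterozygous for A's variant.
Nine distractor genes (configurable) carry a variant homozygous in all
three probands; about a third are additionally homozygous in the unaffected
relative (failing at exclusion) and the rest fail at the sib-pair stage.
Causal and distractor variants are never in the known list.

Background polymorphisms are drawn per gene (Poisson, mean 3 variants/gene
over 60 genes), with per-individual genotypes at allele frequency q:
homozygote probability q² + F·q·(1−q) for consanguineous individuals and q²
otherwise, heterozygote 2q(1−q)(1−F). Consanguinity is a single inbreeding
coefficient F (default 1/16, second-cousin scale; the recorded degrees map
to F = (1/2)^(degree+1) if preferred) rather than simulated IBD segments —
sufficient to exercise the filter logic, but it reproduces neither linkage
disequilibrium nor runs of homozygosity. Defaults q = 0.005 and known
fraction 0.9 describe rare, mostly catalogued exome polymorphism; genome
scale is configurable because the real study's genome-wide counts derive
from unreleased data and cannot be calibrated. A background site is emitted
only when a genotyped sample carries the alternate allele, as a variant
caller would; analytic checks against q² + F·q·(1−q) therefore rescale by
the emission probability.

The exome VCF genotypes only the six sequenced individuals, as in the
study; a separate Sanger-style `segregation.vcf` genotypes every pedigree
member at the four causal sites for the confirmation stage. Family members'
background genotypes are drawn independently (no Mendelian transmission of
background alleles) — adequate here because only planted variants cross the
filters, but a reason passing tests say nothing about transmission
artefacts in real trios.

The biomarker table draws normal values per group from the published-scale
summaries (case 116.1 ± 15.6 SEM, n = 15; control 35.9 ± 4.6 SEM, n = 13;
group SD recovered as sem·√n). Note the group separation gives the Welch
test a power of 0.79 at α = 0.001 (noncentral-t, confirmed by Monte Carlo)
— large but not overwhelming, because the case group's recovered SD is
itself large.

Everything flows from one seeded generator in a fixed order, so a config
(including its seed) determines every output byte. Transcript cases embed
an independent codon-by-codon translation oracle (hand-coded codon table)
that computes the truth consequence; draws that would disrupt or silently
recreate the stop codon (extensions) are redrawn deterministically.

## Statistics

* **Fisher's exact test** (2x2, two-sided) sums hypergeometric
  probabilities no larger than the observed table's — the common "sum of
  less-probable tables" convention; a double-the-smaller-tail variant is
  available by flag. The odds ratio is ad/bc with the Haldane +0.5
  correction when a cell is zero (flagged). Zero margins are an error.
* **Welch's t from summaries**: t = (m₁−m₂)/√(sem₁²+sem₂²) with
  Welch–Satterthwaite degrees of freedom on the squared SEMs; a pooled
  option reproduces the classical Student form. Recomputation is
  summary-based by necessity — the underlying per-patient values are not
  published. From the printed summaries the Welch p is 1.40e-4 and the
  pooled p 9.0e-5, bracketing the published 1.3e-4 (computed from raw
  data); Welch is the default as the closer and assumption-lighter form.
* **Proportions** round half-up to one decimal (5/18 → 27.8).
* The 16-patient CNSU allele-count denominator (32 chromosomes) excludes
  the two patients found by screening a Crohn's-disease cohort, which are
  tabulated separately; blank cells in the published frequency columns are
  represented as absent, not zero.

## Numerical and design notes

* Coordinates are 1-based inclusive; HGVS c. positions count from the A of
  ATG, with intronic offsets parsed as (base, offset).
* Multi-allelic VCF records are split with allele indices remapped; phase
  separators are accepted and discarded at the I/O layer (phase is inferred
  from the pedigree in the prioritiser). Genotype matrices use pandas
  nullable integers with NA for missing calls.
* Deterministic ordering throughout: genes lexicographic, variants by
  (chrom, pos, ref, alt); the VCF writer emits a canonical form that
  round-trips byte-identically.
* Gene assignment and functional class come from input annotation (GENE /
  FUNC), not from transcript overlap — annotation is upstream's job. A
  strict mode rejects records without FUNC instead of guessing.
* Indels and SNVs are treated identically by the filters (func_class is
  what matters); the source analysis did not state a distinction.

## Limitations

* No dominant or X-linked models, no runs-of-homozygosity mapping, no
  population-frequency databases beyond the supplied known list.
* The trans test is an any-consistent-assignment check, not a likelihood
  phasing; with both parents carrying both variants it cannot reject cis.
* Reproducing the published protein-level names of the two real splice
  products (p.R288Gfs*7, p.I488Lfs*11) requires the real transcript
  sequence (NM_005630) and, for the intron retention, the retained genomic
  bases, neither of which ships with the package; the machinery is instead
  verified on generated transcripts against an independent oracle.
* The biomarker generator assumes normality on the measurement scale; the
  source reports only mean ± SEM, and urinary metabolite levels are
  plausibly right-skewed in reality.
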