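# Methods

## Scope and data model

The package analyses a trio of inbred genomes — a backcross-derived
line (offspring), its donor parent and its recurrent parent — called
against a single external reference, plus a gene-level count matrix
from a genotype × treatment × replicate inoculation experiment. All
variant handling is VCF-style 1-based inclusive; conversion to 0-based
half-open coordinates happens only inside the interval index and the
simulator's segment arithmetic.

## Parental-origin classification

Genotypes are collapsed to REF/ALT/MISSING under an inbred
(homozygous) assumption. For a biallelic site:

- offspring = donor ≠ recurrent → **DONOR**
- offspring = recurrent ≠ donor → **RECURRENT**
- all three equal → **NON_POLYMORPHIC**
- parents equal, offspring differs → **NOVEL**
- any missing genotype → **AMBIGUOUS**

Heterozygous calls (residual heterozygosity) map to AMBIGUOUS by
default; the `major-allele` policy collapses them to the non-reference
allele instead (a 0/1 dosage tie has no majority, so the policy is a
coin with a declared side). Multi-allelic records are split into
biallelic sites against the same REF; a sample carrying neither allele
at a split site is MISSING for that site. Indels are kept when their
REF/ALT length difference is 1–99 bp (inclusive); input is assumed
left-aligned and is not re-normalized.

## Gene-structure assignment and coding effects

Each gene contributes a *footprint*: its span plus a putative promoter
window, by default the 1000 bp 5′ of the ORF (CDS) start, strand-aware
and clipped at contig ends. Anchoring the window at the ORF start
rather than the transcript start matches the usual promoter-proximal
reading; its length is configurable. Within a gene, a position takes
the most specific label available: coding exon > UTR > intron >
upstream window. A variant overlapping several gene footprints is
reported once per gene (no evidence is discarded); deletions are
assigned by their leftmost deleted base, SNVs and insertions by their
anchor base.

Coding SNVs mutate the affected codon (standard genetic code,
strand-aware) and compare translations; coding indels are in-frame iff
their length is divisible by 3. Genes whose summed CDS length is not
divisible by 3 are flagged malformed and excluded from coding-effect
calls. Mobile-element and unknown-protein genes (GFF3 attributes) are
removed before inheritance bookkeeping.

## Gene-level verdicts and the donor fraction

A gene with ≥1 donor-origin variant and none recurrent is DONOR
(symmetrically RECURRENT); both kinds → MIXED; neither →
NON_POLYMORPHIC. One concordant variant suffices by default
(`min_evidence` raises the bar). The donor-inherited fraction is
100·N_D/(N_D+N_R), reported to one decimal; MIXED genes appear in the
verdict counts but in neither term, keeping the two disjoint sets the
formula assumes. Per-chromosome donor-gene counts are reported with
whole-percent shares. A gene counted once even when it has both SNV and
indel evidence — the per-class counts are reported alongside.

`expected_backcross_fraction(b)` returns 100·(½)^b, the
halving-per-backcross model in which five backcrosses give ≈3%. The
standard pedigree expectation for a BC_b line counts the F1 as the
first halving and is 100·(½)^(b+1) (1.56% for b=5); the simulator's
Monte-Carlo mean matches this closed form, and both conventions are
noted wherever the expectation is surfaced.

## Backcross simulator

Meiosis follows Haldane's model: per chromosome the crossover count is
Poisson(length in Morgans), positions are uniform in bp, no
interference — the simplest defensible recombination model. The
pedigree is donor × recurrent, then b backcrosses to the recurrent
parent, then s selfings (defaults b=5, s=4), one random offspring per
generation and no selection. The diploid mosaic is collapsed to a
homozygous genotype mosaic (agreeing intervals keep their label; rare
residual-heterozygous intervals are resolved by a seeded fair coin,
idealizing continued inbreeding), so all emitted genotypes are
homozygous; an optional `het_fraction` error mode flips offspring
genotypes to 0/1 for robustness tests.

The full study generator conditions on the derived line retaining at
least one fully donor-origin, promoter-accessible coding gene,
re-drawing the pedigree when necessary (a substantial fraction of
unconditioned BC5F4 draws carries no donor gene at all). This mirrors the provenance
of real material: a line bred for a donor-derived trait necessarily
kept the donor locus. The conditioning biases single-study donor
fractions above the unconditioned mean — as selection does in a real
programme — and the unconditioned pedigree operation remains available
and is what the Monte-Carlo expectation checks use.

**Genome defaults.** 7 chromosomes × 1 Mb / 100 cM, 196 genes with
strand, 1–3 exons, UTRs and CDS (valid start/stop, length divisible by
3, sense codons), 10% flagged mobile-element and 10% unknown-protein
(disjoint). Desk-scale, but preserving per-chromosome reporting and
every structural gene part the region logic distinguishes.

**Variants.** Sites are placed relative to the external reference with
the ALT carried by the donor (0.45), the recurrent parent (0.35) or
both (0.20) — both-carrier sites are non-polymorphic within the trio,
as in real cultivar comparisons. Default densities are 1 SNV / 500 bp
and 1 indel / 5 kb, realistic for distinct pea cultivars and dense
enough that nearly every gene footprint carries informative markers;
indel lengths are uniform on 1–120 bp so the 99-bp analysis filter is
exercised. The offspring genotype at each site is the parental
genotype of the mosaic segment covering it, and a truth sidecar stores
the expected origin label computed directly from carrier × segment —
independently of the classifier under test. In dense-marker mode a
parent-distinguishing SNV is additionally guaranteed at both ends of
every gene footprint, which makes gene-level recovery exact: any
crossover strictly inside a footprint is flanked by discordant markers,
so MIXED verdicts coincide exactly with truly mixed footprints.

**The planted cis marker.** One donor-origin gene (eligible when its
upstream window covers a point 100 bp 5′ of the gene span) receives a
donor-only promoter insertion, 9 bp by default, and its coding
intervals are kept free of all other variants — its protein-coding
sequence is identical across the trio, the canonical cis-regulatory
signature.

**Counts.** NB(mean, dispersion) with log-normal baselines (median
150), common dispersion 0.1, log-normal library-size factors
(sd 0.1 on the log scale), in a 3 genotypes × {control, inoculated} ×
3 replicates design. Six genes (~3% — the same order as DEG rates
observed in inoculation experiments) respond to inoculation in every
genotype with |log2FC| in 1.5–4 (70% up); responsive baselines are
floored at 30 so the planted signal is detectable, as published DEGs
by construction are. The cis gene (baseline floored at 50) is induced
(log2FC 5) only in the genotypes carrying the donor promoter allele:
the offspring and the donor parent.

What the generator does **not** emulate: sequencing error, genotype
likelihoods, alignment artefacts, structural variants beyond simple
indels, linked selection, transcript isoforms, count over-dispersion
heterogeneity across genes, or 3′-bias. Passing tests therefore show
the pipeline's logic and calibration are correct on clean inputs, not
that it is robust to upstream noise in real data.

## Differential expression

Per genotype, inoculated vs control (3 vs 3): size factors by
median-of-ratios; normalized per-gene dispersions by method of moments
within groups, floored at 1e-8; each gene's working dispersion is the
**maximum** of its own estimate and the across-gene median. This
conservative sharing is the key small-sample choice: with 4 residual
degrees of freedom the raw moment estimator underestimates often
enough to make a plain normal-reference Wald test anti-conservative,
while a heavy-tailed t reference collapses FDR-adjusted power for
strong effects; the max-sharing rule restores both. The acceptance
suite measures the result directly — type-I error within 0.05 ± 0.02
and power ≥ 0.8 for planted log2FC=2 genes at mean ≥ 100 — on a
2000-gene null-plus-planted simulation. The per-gene NB GLM (log link, size-factor
offset) is fit with statsmodels; Wald p-values are two-sided normal,
Benjamini–Hochberg adjusted within each genotype contrast (mirroring
per-genotype DEG reporting); UP/DOWN require adjusted p < α (default
0.05) with the matching fold-change sign. All-zero genes are NS with
undefined p; unstable fits fall back to a pseudo-counted moment
fold-change with undefined p. Exact numeric parity with any external
DE tool is a non-goal; the contract is calibration on synthetic truth.

TPM uses exonic gene lengths; the low-expression filter removes genes
below 10 TPM in **every** sample (a gene expressed in even one sample
survives — the stricter any-sample reading would discard exactly the
induced genes of interest). The heatmap matrix is log2(TPM+1),
replicate-averaged per (genotype, treatment), per-gene z-scored;
zero-variance rows are set to 0 and flagged. The qPCR helper returns
2^(−ΔΔCt).

## ASE candidates

A candidate must be donor-like in expression (UP in offspring and
donor, NS in recurrent — NS only, the permissive reading; a nominal
up-trend in the recurrent parent is not required) and DONOR by gene
origin, or MIXED with a donor regulatory variant. `cis_flag` requires
≥1 donor variant in the upstream window or a UTR and **no**
donor-origin coding-altering variant (non-synonymous, in-frame indel
or frameshift); synonymous donor variants do not clear the flag, an
explicitly permissive operationalization of "identical protein-coding
sequence". Candidates are ranked by offspring adjusted p; variant
reports give strand-aware distances to the ORF start (negative =
upstream). Genotype-vs-genotype contrasts within one treatment (for
control-condition ASE genes) are available through
`expression.nb_genotype_contrast`, which relabels the design and
reuses the same NB Wald engine.

## Numerical and degenerate-input choices

- Coincident crossover positions are deduplicated (measure-zero under
  the continuous model); zero-length chromosomes are configuration
  errors.
- Variant positions are deduplicated per chromosome with the planted
  cis insertion taking priority, then guaranteed markers, then
  background.
- donor fraction with N_D = N_R = 0 raises rather than returning a
  silent 0.
- Summary JSON floats are written to 6 significant digits; identical
  seed and config give byte-identical outputs.
- BH is applied only to genes with defined p-values; undefined-p genes
  are NS.

## Problem sizes

Default test and acceptance runs use the desk-scale genome above
(≈15k variant sites, 196 genes, 18 samples); calibration suites use
2000-gene count matrices and 10–20 seeded studies. These sizes were
chosen so the full suite exercises every stage end-to-end in a couple
of minutes on one core while keeping Monte-Carlo standard errors well
inside the tolerances being checked.

## Known limitations

- One transcript per gene; splice-site, start/stop-loss and isoform
  effects are out of scope.
- The classifier assumes a trio; cohorts and genotype likelihoods are
  not modelled.
- The DE engine is a two-group Wald test: no shrinkage of fold
  changes, no GLM covariates beyond treatment, no outlier handling.
- The absolute variant counts of a real study depend on its reference
  and read data and are not reproduced at desk scale; the package's
  claims are about the inheritance arithmetic itself and about
  calibration on synthetic truth.
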