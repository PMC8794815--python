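# Methods

## Model and scope

`startseq` analyzes paired Ribo-seq/RNA-seq experiments in which a
translation-initiation inhibitor arrests bacterial ribosomes at start
codons in a sequence-context-dependent way. The analysis layer is
agnostic to where the alignments come from (any ungapped single-end SAM
or BED6 over a replicon FASTA + CDS GFF3 + operon table works); the
simulation layer generates data under an explicit mechanistic model so
the full chain can be validated without external data.

The mechanistic model, encoded in `SimConfig`:

- Initiation events arrive on gene *i* as a Poisson process with rate
  proportional to a per-gene lognormal mRNA abundance (default
  lognormal(0, 1); transcript abundance is identical between
  conditions — drug-induced transcriptome remodeling is out of scope).
- Untreated cells: every event traverses the ORF. A traversing ribosome
  is captured as footprints at `footprints_per_codon` (default 0.2) per
  sense codon, placed uniformly over sense codons with a mild 1.5×
  weight on the start codon (basal initiation pausing).
- Drug-treated cells: an event escapes arrest with probability
  `escape_prob[b]` where *b* is the base immediately 5′ of the start
  codon (defaults G 0.05, C 0.3, T 0.6, A 0.6 — the severity ordering
  G ≫ C > U ≈ A). For downstream operonic genes whose start codon
  overlaps the upstream stop codon, arrest probability is multiplied by
  `coupling_attenuation` (default 0.5), modeling partial protection by
  reinitiation. Arrested ribosomes leave a single footprint with its
  A-site on the start codon with probability
  `stall_footprint_fraction_retained` (default 0.8), else they
  dissociate and leave nothing. How long an arrested ribosome persists
  before dissociating is not quantified by available data, so the
  retention fraction is an explicit free parameter rather than an
  asserted value.
- Footprint geometry: the 3′ end is placed 12 nt downstream (in
  transcript direction) of the A-site codon's first base; lengths are
  uniform in 25–40 nt (Ribo-seq) and 25–45 nt (RNA-seq, matching a gel
  excision window). RNA fragments are uniform along the transcript
  (5′ UTR + CDS).

### Snapshot sampling, not per-event reads

Per-gene footprint counts are Poisson draws of the two thinned event
streams (arrested × retention at the start codon; traversing ×
`footprints_per_codon` × sense codons over the body). An earlier
formulation that emitted a fixed batch of reads per discrete event
compounds the event-level Poisson noise by the per-event read count,
which at realistic depths produces spurious zero-count genes and a
noise-dominated inhibition tail. The thinned-Poisson form is the
steady-state snapshot a sequencing library actually takes and keeps
the marginal expectations of the event model exactly.

Consequences worth knowing: a strongly arrested gene retains CDS reads
(the start-codon pileup counts toward its TE), so the maximum
observable TE loss is bounded by
`escape + (1−escape)·retained/(footprints_per_codon·n_codons)`; and
because RPKM normalizes by the (smaller) drug library, escaping genes
show positive log2 TE changes — only relative comparisons between
context groups are meaningful, which is all the analysis uses.

## Genome construction

Operons are laid out on a single synthetic replicon (60-nt pads at the
ends, 40–100 nt spacers between operons) with 1–5 genes per operon,
CDS lengths 100–300 codons (stop included), 5′ UTRs 15–40 nt. Every
gene's −1 base is drawn from `minus1_base_weights` (default uniform)
and written into the sequence, so annotation and FASTA always agree.
Downstream genes overlap the upstream stop codon with probability 0.4
using the ATGA-type junction: the start codon's first base sits three
bases before the stop codon's last base, which forces the upstream stop
to TGA and places the downstream gene's −1 base inside the upstream
gene's final sense codon (that codon's first base is restricted to
A/C/G so no in-frame stop can form). Reverse-strand operons are off by
default and enabled with `include_reverse_strand` to exercise strand
handling; all analysis code is strand-aware regardless.

Default scale — 100 operons ≈ 300 genes, 2×10⁵ reads per library —
runs the whole analysis in about a second while leaving ~70+ genes per
−1-base group and ~80 overlapping genes, enough for stable medians,
rank correlations and exact/asymptotic rank tests.

## Read processing

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the reader. Only primary, mapped, ungapped alignments
within the length window are used (Ribo-seq default 20–45 nt, RNA-seq
25–45 nt). Multi-mappers are removed by the NH tag when present, else
by duplicate query names, which requires buffering the file; the
streaming bounded-memory path is the NH route. Gapped CIGARs are
skipped with a warning, or abort under strict mode.

A-site assignment: plus strand `(left + length − 1) − 12`, minus strand
`left + 12`; a shifted position off the replicon drops the read (it is
not counted in `total_mass`, preserving the mass-conservation
invariant). RNA-seq fragments add 1/N per covered base via a
difference-array prefix sum, so each accepted read carries exactly unit
mass.

## Gene quantification and TE change

RPKM uses the track's total accepted mass as library size. TE is
undefined below `min_rna_rpkm` (default 1). The "expressed" floor —
control `rna_rpkm ≥ 1` and control `ribo_count ≥ 32` — is a documented
stand-in for a filter whose exact published form is not available;
both knobs are exposed. ΔTE applies a pseudocount (default 0.1) to
RPKM rather than raw counts, keeping log ratios finite at zero
coverage; hard filtering of zero-count genes is reachable by setting
the pseudocount to 0 and relying on the expression floor.

Top-fraction selection rounds half away from zero (5% of 2,057 genes
is 103) with lexicographic gene-id tie-breaking so reruns are
deterministic. Group tests use the exact Mann–Whitney distribution
when both groups have ≤ 8 members and the tie-corrected normal
approximation otherwise; the t test is Welch's (unequal variances).
Bonferroni multiplies by the number of tested pairs and caps at 1.

## Occupancy statistics

Metagene profiles cover −30..+60 nt around the start codon's first
base. Genes qualify with CDS ≥ window end + 9 nt and mean CDS density
≥ 0.1 reads/nt (configurable); each gene's window is normalized by its
own mean CDS density so the start peak does not deflate itself, and
the profile is the across-gene median, which is robust to the heavy
right tail of pileup heights. A-site density lives only on codon first
bases, so profiles show a 3-nt comb; the median at offset 0 is the
head-peak readout.

Head enrichment uses head = CDS nt 0–14 (codons 1–5) and body = nt 15
to CDS_len − 9 (stop region excluded), with pseudocount 0.1 in both
numerator and denominator. The exact spans published for this metric
are not available, so the defaults were chosen to bracket the observed
head peak and are recorded in output metadata and fully configurable.
HE is scale-invariant at pseudocount 0 and equals 1 for uniform
density. The HE/TE comparison uses Spearman rank correlation with
average-rank ties; it raises on constant input (e.g. a
control-vs-control null) rather than returning an undefined value.

## Context enrichment

Context strings cover −15..+17 around the start codon's first base
(33 nt; genomic sequence, reverse-complemented for minus-strand genes,
so short UTRs simply read into upstream genomic sequence). The
background is the analyzed-gene universe, not the whole genome, and
background frequencies are per position because start-proximal
composition is position-structured (Shine–Dalgarno). Scores are signed
binomial tails computed through `scipy.stats.binom.logsf/logcdf` for
numerical stability; the unit-test oracle enumerates the same tails
exactly with `fractions.Fraction`. A zero background frequency with
nonzero foreground count is capped at 300 with a warning. The
significance line is Bonferroni over all 4 × 33 cells:
`−log10(α/132) ≈ 3.42` at α = 0.05.

## Coupling categories

Rank-1 genes and singletons are `other`; a downstream gene is
`overlapping_operonic` iff, in transcript coordinates, its start
codon's first base lies at or before the last base of the upstream
stop codon (≥ 1 nt overlap or start fully upstream), else
`nonoverlapping_operonic`. Exactly adjacent codons (0-nt gap) are
nonoverlapping — the literal reading of the definition. Operon
membership is an input table, never inferred; the simulator emits the
true one.

## What the simulator does and does not establish

Passing recovery tests shows the analysis chain correctly extracts the
encoded signals at realistic depth and cohort size: the −1-base
severity ordering, the G(−1) motif in the inhibition tail, the
negative ΔHE/ΔTE correlation, coupling protection, and the start-codon
metagene peak. The generator deliberately omits features of real data
— elongation pauses, the secondary "neck-region" peak a few codons
into the ORF, drug dissociation during early elongation, leaderless
transcripts, fragment/GC bias, PCR duplicates, multi-mapping reads,
and transcriptome remodeling — so passing these tests does not
calibrate absolute effect sizes on real libraries, only the
correctness and direction of the estimators. Real-data magnitudes
(e.g. the published ρ values for the HE/TE correlation) require the
original sequencing data and are not claimed here.

## Numerical and degenerate-input policy

Seeds: every library draws from `numpy` Generator seeded by
`(config.seed, stream, condition)`, so outputs are bit-identical per
seed and conditions are independent. Empty libraries abort
(quantification is meaningless at zero mass); a zero-depth request
yields a valid empty SAM. Genes too short for disjoint head/body or
for the metagene window are skipped with warnings, never silently
zeroed. All tables are TSV; the pipeline writes a JSON summary and a
run log with resolved parameters and versions.
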