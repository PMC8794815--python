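# startseq

Start-codon-resolved analysis of context-specific translation-initiation
inhibition from bacterial ribosome profiling, with a mechanistic footprint
simulator.

## The problem

Some ribosome-targeting antibiotics do not shut translation down uniformly:
an initiation inhibitor that binds in the small subunit's mRNA channel can
arrest ribosomes at start codons with a severity that depends on the mRNA
sequence around the ribosome binding site. Genome-wide, this shows up as
four coupled signatures in paired Ribo-seq/RNA-seq data from treated versus
untreated cells:

1. per-gene translation efficiency (TE) drops by amounts that depend on the
   nucleotide immediately 5′ of the start codon (the −1 base), with G(−1)
   by far the most inhibitory context;
2. the most-inhibited genes are enriched for G at −1 in a position-specific
   sequence-context test;
3. ribosome density piles up on start codons ("head enrichment"), and the
   genes that pile up most are the ones whose TE collapses — a negative
   rank correlation;
4. downstream operonic genes whose start codon overlaps the upstream stop
   codon (translationally coupled, reinitiation-driven) are partially
   protected.

`startseq` implements the full analysis chain for these signatures and a
generative simulator of the underlying arrest model, so every stage is
testable end-to-end without any external data.

## The statistics

With per-base A-site footprint density (each footprint placed at its 3′ end
minus 12 nt) and fractional RNA-seq coverage (an *N*-nt fragment adds 1/*N*
per covered base):

- **TE** per gene: `TE = ribo_RPKM / rna_RPKM` over the CDS, with
  `RPKM = count / (CDS_kb · library_millions)`;
- **TE change**: `ΔTE = log2((ribo_t+p)/(rna_t+p)) − log2((ribo_c+p)/(rna_c+p))`
  on RPKM with pseudocount *p*;
- **head enrichment**: `HE = (mean head density + p) / (mean body density + p)`,
  head = first five codons, body = rest of the CDS minus the stop region;
  its drug-induced change is `log2(HE_t/HE_c)`, compared with ΔTE by
  Spearman rank correlation;
- **context enrichment**: for each position in −15..+17 around the start
  codon and each base, a signed binomial tail score
  `−log10 Pr[Bin(n, q) ≥ k]` (overrepresented) or `+log10 Pr[Bin(n, q) ≤ k]`
  (underrepresented) of the foreground count *k* of *n* genes against the
  per-position background frequency *q*, with a Bonferroni significance
  line `−log10(α / (4·33))`;
- **group tests**: pairwise two-sided Mann–Whitney U (exact for small
  groups) or Welch t, Bonferroni-adjusted.

The simulator encodes the arrest model: initiation events arrive per gene
at a rate proportional to a lognormal abundance; under drug an event
escapes arrest with a probability set by its −1 base
(defaults G 0.05, C 0.3, T 0.6, A 0.6), arrest probability halved for
start/stop-overlapping genes; arrested ribosomes leave one start-codon
footprint with probability 0.8, traversing ribosomes leave footprints in
proportion to ORF length.

## Worked example

```
$ python examples/02_te_change_by_start_context.py
analyzed genes (expressed in control): 298

median log2 TE change by -1 base:
minus1_base
A    0.42
C   -0.53
G   -2.42
T    0.45

pairwise Mann-Whitney (Bonferroni-adjusted):
group_a group_b  median_a  median_b  p_adjusted
      A       G     0.424    -2.082       0.000
      ...
```

The G(−1) group loses ~5.6× more translation than the A(−1) group
(median −2.42 vs +0.42 log2 units; positive values arise because library
normalization redistributes density onto escaping genes), and the
separation survives exclusion of the top-5% most-inhibited genes.
Continuing with `examples/03_motif_enrichment.py` and
`examples/04_metagene_and_head_enrichment.py`:

```
score at (-1, G): 9.82          # Bonferroni line: 3.42
drug: metagene peak at offset 0 (median normalized density 13.6, 230 genes)
Spearman rho(dHE, dTE) = -0.54 over 298 genes
```

i.e. the most-inhibited genes are G(−1)-marked, drug-treated ribosomes
accumulate exactly on the first base of the start codon, and start-codon
pileup predicts translational loss.

A shell workflow is available too:

```
startseq sim --outdir sim --seed 1
startseq quant --ribo sim/ribo_control.sam --rna sim/rna_control.sam \
    --fasta sim/genome.fa --gff sim/genes.gff3 --operons sim/operons.tsv \
    --out quant_control.tsv
startseq run-demo --outdir demo_out --seed 1
```

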