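"""One-call demo: simulate a data set to disk (FASTA + GFF3 + operon
TSV + four SAM libraries) and run the complete file-based pipeline on
it, exactly as a real-data run would.

Outputs land in demo_out/analysis/ as TSV tables plus summary.json.
"""

from startseq import run_demo

results = run_demo("demo_out", seed=1)
delta = results["delta"]
print(f"analyzed genes: {len(delta)}")
print(f"median log2 TE change: {delta['log2_te_change'].median():.2f}")
print(f"Spearman rho(dHE, dTE): {results['spearman_rho']:.2f}")
print(f"motif threshold: {results['motif_threshold']:.2f}; "
      f"score at (-1, G): {results['motif'].score(-1, 'G'):.2f}")
print("tables written to demo_out/analysis/")
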