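"""Generator contracts: genome geometry, determinism, truth table,
limit-case behavior of the arrest model."""

import dataclasses

import numpy as np
import pytest

from startseq import (
    SimConfig,
    assign_ribo_density,
    assign_rna_density,
    build_genome,
    quantify_genes,
    simulate_riboseq,
    simulate_rnaseq,
)
from startseq.annotation import revcomp
from startseq.simulate import STOP_CODONS, SimulationError


def test_gene_count_within_operon_bounds():
    cfg = SimConfig(n_operons=10, genes_per_operon_range=(1, 3), seed=0)
    genome = build_genome(cfg)
    assert 10 <= len(genome.genes) <= 30


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(n_operons=5, ribo_depth=2000, rna_depth=2000, seed=42)
    for d in ("a", "b"):
        genome = build_genome(cfg)
        paths = genome.write(tmp_path / d)
        simulate_riboseq(genome, "drug").write_sam(
            tmp_path / d / "ribo.sam", genome.sequence
        )
    for name in ("genome.fa", "genes.gff3", "operons.tsv", "truth.tsv", "ribo.sam"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name


def test_degenerate_minus1_weights_force_single_base():
    cfg = SimConfig(
        n_operons=6,
        minus1_base_weights={"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0},
        seed=1,
    )
    genome = build_genome(cfg)
    assert all(g.minus1_base == "G" for g in genome.genes)


def test_genome_sequence_consistent_with_annotation(tiny_genome):
    seq = tiny_genome.sequence
    for g in tiny_genome.genes:
        cds = seq[g.cds_start : g.cds_end]
        m1 = seq[g.cds_start - 1] if g.strand == "+" else revcomp(seq[g.cds_end])
        if g.strand == "-":
            cds = revcomp(cds)
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        assert g.cds_len % 3 == 0
        assert m1 == g.minus1_base


def test_overlap_geometry_matches_category(tiny_genome):
    by_id = {g.gene_id: g for g in tiny_genome.genes}
    ops = {}
    for g in tiny_genome.genes:
        ops.setdefault(g.operon_id, []).append(g)
    n_overlap = 0
    for members in ops.values():
        members.sort(key=lambda g: g.operon_rank)
        for up, down in zip(members, members[1:]):
            if down.category == "overlapping_operonic":
                n_overlap += 1
                # start codon shares >= 1 nt with the upstream stop codon
                if down.strand == "+":
                    assert down.cds_start <= up.cds_end - 1
                else:
                    assert down.cds_end - 1 >= up.cds_start
                assert down.operon_id == up.operon_id
    assert n_overlap > 0  # the default overlap probability produces some


def test_truth_escape_is_pure_function_of_base_and_coupling(tiny_genome, tiny_config):
    cfg = tiny_config
    for _, row in tiny_genome.truth.iterrows():
        expected = cfg.effective_escape(
            row["minus1_base"], row["category"] == "overlapping_operonic"
        )
        assert row["escape_true"] == pytest.approx(expected)


def test_escape_one_makes_drug_behave_as_control():
    """With all escape probabilities 1 the drug changes nothing: the
    per-gene log2 drug/control CDS density ratio is centered at 0."""
    cfg = SimConfig(
        n_operons=20,
        escape_prob={"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
        ribo_depth=100_000,
        rna_depth=50_000,
        seed=11,
    )
    genome = build_genome(cfg)
    tracks = {
        c: assign_ribo_density(simulate_riboseq(genome, c), genome.replicon_lengths)
        for c in ("control", "drug")
    }
    ratios = []
    for g in genome.genes:
        c = tracks["control"].cds_density(g).sum()
        d = tracks["drug"].cds_density(g).sum()
        if c > 50:
            ratios.append(np.log2((d + 1) / (c + 1)))
    assert abs(np.median(ratios)) < 0.1


def test_full_arrest_with_full_retention_puts_all_reads_at_start():
    cfg = SimConfig(
        n_operons=10,
        escape_prob={"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.5},
        stall_footprint_fraction_retained=1.0,
        ribo_depth=50_000,
        seed=13,
    )
    genome = build_genome(cfg)
    track = assign_ribo_density(
        simulate_riboseq(genome, "drug"), genome.replicon_lengths
    )
    g_genes = [
        g
        for g in genome.genes
        if g.minus1_base == "G" and g.category != "overlapping_operonic"
    ]
    assert g_genes
    for g in g_genes:
        cds = track.cds_density(g)
        assert cds.sum() == cds[0]  # every A-site at the start codon


def test_body_density_ratio_recovers_escape_probability():
    """For uncoupled G(-1) genes the post-head drug/control body density
    ratio estimates escape_prob[G]; at 2e5 depth the pooled log2 ratio
    lands within sampling error of log2(0.05)."""
    cfg = SimConfig(seed=17)  # defaults: escape G = 0.05, depth 2e5
    genome = build_genome(cfg)
    tracks = {
        c: assign_ribo_density(simulate_riboseq(genome, c), genome.replicon_lengths)
        for c in ("control", "drug")
    }
    num = den = 0.0
    for g, esc in zip(genome.genes, genome.truth["escape_true"]):
        if g.minus1_base != "G" or g.category == "overlapping_operonic":
            continue
        num += tracks["drug"].cds_density(g)[15:].sum()
        den += tracks["control"].cds_density(g)[15:].sum()
    observed = np.log2(num / den)
    assert observed == pytest.approx(np.log2(0.05), abs=0.15)


def test_rna_depth_zero_gives_empty_read_set(tiny_genome):
    cfg = dataclasses.replace(tiny_genome.config, rna_depth=0)
    rs = simulate_rnaseq(tiny_genome, cfg)
    assert len(rs) == 0


def test_rna_single_expressed_gene_confines_reads(tiny_genome):
    genome = dataclasses.replace(tiny_genome)
    truth = genome.truth.copy()
    truth["abundance"] = 0.0
    target = genome.genes[3]
    truth.loc[truth["gene_id"] == target.gene_id, "abundance"] = 1.0
    genome = dataclasses.replace(genome, truth=truth)
    rs = simulate_rnaseq(genome, dataclasses.replace(genome.config, rna_depth=2000))
    assert len(rs) > 0
    lo = target.cds_start - (target.utr5_len if target.strand == "+" else 0)
    hi = target.cds_end + (target.utr5_len if target.strand == "-" else 0)
    assert (rs.lefts >= lo).all() and (rs.lefts + rs.lengths <= hi).all()


def test_rna_abundance_ratio_recovered(tiny_genome):
    """Two genes at 4:1 abundance yield a ~4:1 read-count ratio."""
    genome = dataclasses.replace(tiny_genome)
    truth = genome.truth.copy()
    truth["abundance"] = 0.0
    a, b = genome.genes[0], genome.genes[5]
    truth.loc[truth["gene_id"] == a.gene_id, "abundance"] = 4.0
    truth.loc[truth["gene_id"] == b.gene_id, "abundance"] = 1.0
    genome = dataclasses.replace(genome, truth=truth)
    rs = simulate_rnaseq(genome, dataclasses.replace(genome.config, rna_depth=20_000))
    in_a = ((rs.lefts >= a.cds_start - 50) & (rs.lefts < a.cds_end)).sum()
    in_b = ((rs.lefts >= b.cds_start - 50) & (rs.lefts < b.cds_end)).sum()
    assert in_a / in_b == pytest.approx(4.0, rel=0.15)


def test_unknown_condition_rejected(tiny_genome):
    with pytest.raises(ValueError, match="unknown condition"):
        simulate_riboseq(tiny_genome, "mock")


def test_infeasible_packing_raises():
    cfg = SimConfig(n_operons=50, max_replicon_length=1000, seed=0)
    with pytest.raises(SimulationError, match="infeasible packing"):
        build_genome(cfg)


def test_invalid_config_rejected():
    with pytest.raises(SimulationError):
        SimConfig(escape_prob={"A": 1.2, "C": 0.5, "G": 0.5, "T": 0.5}).validate()
    with pytest.raises(SimulationError):
        SimConfig(minus1_base_weights={"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5}).validate()
    with pytest.raises(SimulationError):
        SimConfig(genes_per_operon_range=(3, 1)).validate()


def test_reverse_strand_genes_produced_and_consistent():
    cfg = SimConfig(n_operons=20, include_reverse_strand=True, seed=19)
    genome = build_genome(cfg)
    strands = {g.strand for g in genome.genes}
    assert strands == {"+", "-"}  # both strands exercised
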