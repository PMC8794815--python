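"""Density assignment rules and gene quantification.

The A-site rule is forced by the 3'-end -12 nt shift; RNA coverage is
fractional (1/N per covered base); both conserve one unit of mass per
accepted read. RPKM and TE follow their closed forms and are invariant
under library rescaling.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from startseq import (
    DensityTrack,
    assign_ribo_density,
    assign_rna_density,
    quantify_genes,
    relative_occupancy,
)
from startseq.annotation import GeneModel
from startseq.density import EmptyLibraryError
from startseq.reads import AlignedRead, ReadSet

LENGTHS = {"chr1": 2000}


def read(left, length, strand="+", name="r"):
    return AlignedRead(name, "chr1", strand, left, length)


class TestAsiteRule:
    def test_plus_strand_example(self):
        track = assign_ribo_density([read(982, 30)], LENGTHS)
        assert track.vector("chr1", "+")[999] == 1.0
        assert track.total_mass == 1.0

    def test_minus_strand_example(self):
        track = assign_ribo_density([read(500, 28, "-")], LENGTHS)
        assert track.vector("chr1", "-")[512] == 1.0

    def test_off_replicon_shift_dropped(self):
        track = assign_ribo_density([read(0, 10)], LENGTHS)  # 3' end 9, shift -12
        assert track.total_mass == 0.0

    def test_mass_conservation_bulk(self):
        rng = np.random.default_rng(0)
        reads = [
            read(int(l), int(n), s, f"r{i}")
            for i, (l, n, s) in enumerate(
                zip(
                    rng.integers(50, 1900, 1000),
                    rng.integers(25, 41, 1000),
                    rng.choice(["+", "-"], 1000),
                )
            )
        ]
        track = assign_ribo_density(reads, LENGTHS)
        assert track.total_mass == 1000.0
        total = sum(track.vector("chr1", s).sum() for s in "+-")
        assert total == pytest.approx(1000.0)


class TestRnaFractional:
    def test_single_read_mass_one(self):
        track = assign_rna_density([read(100, 30)], LENGTHS)
        vec = track.vector("chr1", "+")
        assert np.allclose(vec[100:130], 1 / 30)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_reads_stack(self):
        track = assign_rna_density([read(100, 30, name="a"), read(100, 30, name="b")], LENGTHS)
        assert np.allclose(track.vector("chr1", "+")[100:130], 2 / 30)

    def test_mixed_lengths_conserve_mass(self):
        track = assign_rna_density([read(100, 25), read(500, 45)], LENGTHS)
        assert track.total_mass == 2.0
        assert track.vector("chr1", "+").sum() == pytest.approx(2.0, abs=1e-9)


def test_fast_and_slow_paths_agree(tiny_genome):
    """Vectorized ReadSet assignment matches the per-read loop."""
    from startseq import simulate_riboseq, simulate_rnaseq

    rs = simulate_riboseq(tiny_genome, "drug")
    lengths = tiny_genome.replicon_lengths
    fast = assign_ribo_density(rs, lengths)
    slow = assign_ribo_density(list(rs), lengths)
    for s in "+-":
        assert np.array_equal(
            fast.vector(tiny_genome.replicon, s), slow.vector(tiny_genome.replicon, s)
        )
    rn = simulate_rnaseq(tiny_genome)
    fast = assign_rna_density(rn, lengths)
    slow = assign_rna_density(list(rn), lengths)
    for s in "+-":
        assert np.allclose(
            fast.vector(tiny_genome.replicon, s),
            slow.vector(tiny_genome.replicon, s),
            atol=1e-9,
        )


def _uniform_tracks(ribo_val=1.0, rna_val=1.0, mass=1e6):
    ribo = DensityTrack.zeros("ribo_Asite", LENGTHS)
    rna = DensityTrack.zeros("rna_fractional", LENGTHS)
    ribo.data["chr1"]["+"][:] = ribo_val
    rna.data["chr1"]["+"][:] = rna_val
    ribo.total_mass = mass
    rna.total_mass = mass
    return ribo, rna


GENE = GeneModel("g1", "chr1", "+", 600, 1101, utr5_len=30)


class TestQuantify:
    def test_rpkm_closed_form(self):
        ribo = DensityTrack.zeros("ribo_Asite", LENGTHS)
        rna = DensityTrack.zeros("rna_fractional", LENGTHS)
        gene = GeneModel("g1", "chr1", "+", 600, 1200)
        ribo.data["chr1"]["+"][600:1200] = 12 / 600  # ribo_count 12 over 600 nt
        rna.data["chr1"]["+"][600:1200] = 12 / 600
        ribo.total_mass = 1e6
        rna.total_mass = 2e6
        q = quantify_genes(ribo, rna, [gene], min_rna_rpkm=0.0, min_ribo_count=0.0)
        assert q.loc["g1", "ribo_rpkm"] == pytest.approx(20.0)
        assert q.loc["g1", "rna_rpkm"] == pytest.approx(10.0)
        assert q.loc["g1", "te"] == pytest.approx(2.0)

    def test_te_undefined_below_floor(self):
        ribo, rna = _uniform_tracks(rna_val=0.0)
        q = quantify_genes(ribo, rna, [GENE], min_rna_rpkm=1.0)
        assert np.isnan(q.loc["g1", "te"])
        assert not q.loc["g1", "expressed"]

    def test_empty_library_aborts(self):
        ribo, rna = _uniform_tracks()
        rna.total_mass = 0.0
        with pytest.raises(EmptyLibraryError, match="empty library"):
            quantify_genes(ribo, rna, [GENE])

    def test_gene_outside_replicon_aborts(self):
        ribo, rna = _uniform_tracks()
        bad = GeneModel("g2", "chr1", "+", 1990, 2500)
        with pytest.raises(ValueError, match="outside replicon"):
            quantify_genes(ribo, rna, [bad])

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_rpkm_invariant_under_library_rescaling(self, scale):
        """Multiplying all counts and total_mass by one constant leaves
        RPKM (hence TE) unchanged."""
        ribo, rna = _uniform_tracks()
        q1 = quantify_genes(ribo, rna, [GENE], min_rna_rpkm=0, min_ribo_count=0)
        ribo2, rna2 = _uniform_tracks()
        for t in (ribo2, rna2):
            t.data["chr1"]["+"] *= scale
            t.total_mass *= scale
        q2 = quantify_genes(ribo2, rna2, [GENE], min_rna_rpkm=0, min_ribo_count=0)
        assert q2.loc["g1", "ribo_rpkm"] == pytest.approx(q1.loc["g1", "ribo_rpkm"])
        assert q2.loc["g1", "te"] == pytest.approx(q1.loc["g1", "te"])

    @settings(max_examples=25, deadline=None)
    @given(
        ribo_scale=st.floats(min_value=0.1, max_value=50.0),
        rna_scale=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_te_invariant_under_independent_library_sizes(self, ribo_scale, rna_scale):
        ribo, rna = _uniform_tracks()
        q1 = quantify_genes(ribo, rna, [GENE], min_rna_rpkm=0, min_ribo_count=0)
        ribo2, rna2 = _uniform_tracks()
        ribo2.data["chr1"]["+"] *= ribo_scale
        ribo2.total_mass *= ribo_scale
        rna2.data["chr1"]["+"] *= rna_scale
        rna2.total_mass *= rna_scale
        q2 = quantify_genes(ribo2, rna2, [GENE], min_rna_rpkm=0, min_ribo_count=0)
        assert q2.loc["g1", "te"] == pytest.approx(q1.loc["g1", "te"])


def test_strand_roundtrip_quantification(tiny_genome):
    """Mirroring a read set to the opposite strand at mirrored
    coordinates yields the identical gene quantification."""
    from startseq import simulate_riboseq, simulate_rnaseq
    import dataclasses

    g = tiny_genome
    n = len(g.sequence)
    ribo = simulate_riboseq(g, "control")
    rna = simulate_rnaseq(g)
    mirror = lambda rs: ReadSet(
        replicon=rs.replicon,
        replicon_length=rs.replicon_length,
        lefts=n - (rs.lefts + rs.lengths),
        lengths=rs.lengths,
        is_reverse=~rs.is_reverse,
    )
    genes_m = [
        dataclasses.replace(
            gm,
            cds_start=n - gm.cds_end,
            cds_end=n - gm.cds_start,
            strand="-" if gm.strand == "+" else "+",
        )
        for gm in g.genes
    ]
    q1 = quantify_genes(
        assign_ribo_density(ribo, g.replicon_lengths),
        assign_rna_density(rna, g.replicon_lengths),
        g.genes,
    )
    q2 = quantify_genes(
        assign_ribo_density(mirror(ribo), g.replicon_lengths),
        assign_rna_density(mirror(rna), g.replicon_lengths),
        genes_m,
    )
    assert np.allclose(q1["ribo_count"], q2["ribo_count"])
    assert np.allclose(q1["rna_count"], q2["rna_count"], atol=1e-9)
    assert np.allclose(q1["te"], q2["te"], equal_nan=True)


class TestRelativeOccupancy:
    def test_identity_scaling_and_linearity(self):
        ribo, _ = _uniform_tracks(ribo_val=3.0)
        v1 = relative_occupancy(ribo, GENE, rna_rpkm=2.0, global_factor=1.0)
        assert np.allclose(v1, 1.5)
        v2 = relative_occupancy(ribo, GENE, rna_rpkm=2.0, global_factor=0.5)
        assert np.allclose(v2, v1 * 0.5)
        assert len(v1) == GENE.utr5_len + GENE.cds_len

    def test_zero_rna_rpkm_errors(self):
        ribo, _ = _uniform_tracks()
        with pytest.raises(ValueError, match="rna_rpkm"):
            relative_occupancy(ribo, GENE, rna_rpkm=0.0)
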