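"""Synthetic genome, Ribo-seq and RNA-seq read generator.

The generator encodes a mechanistic model of start-codon-specific
inhibition of translation initiation: in drug-treated cells an
initiation event either escapes arrest (with a probability set by the
identity of the base immediately 5' of the start codon, G being by far
the most arrest-prone, then C, then U/A) and produces footprints across
the coding sequence as in untreated cells, or the ribosome is arrested
at the start codon, where it leaves a start-codon footprint with a
configurable retention probability (arrested ribosomes may instead
dissociate and leave nothing). Translational coupling is modeled by
attenuating the arrest probability for downstream operonic genes whose
start codon overlaps the upstream stop codon.

The genome is a single synthetic replicon of operons with leadered
genes; downstream operonic genes overlap the upstream stop codon with
configurable probability using the classic ATGA-type junction. mRNA
abundance per gene is lognormal and identical between conditions.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from .annotation import GeneModel
from .coupling import categorize_genes
from .reads import ReadSet

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)
CONTROL_START_WEIGHT = 1.5  # mild basal initiation pausing in untreated cells


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the generative model.

    ``escape_prob`` maps the -1 base to the fraction of initiation
    events that escape drug arrest; ``coupling_attenuation`` multiplies
    the arrest probability (1 - escape) for start/stop-overlapping
    downstream genes. ``ribo_depth`` is the expected footprint count of
    the control library (the drug library is smaller in proportion to
    how much translation is lost); ``rna_depth`` the expected RNA-seq
    fragment count. ``footprints_per_codon`` is the expected number of
    footprints captured per codon traversed by a ribosome — a
    traversing ribosome therefore leaves reads in proportion to ORF
    length, while an arrested one leaves at most a single start-codon
    footprint. CDS lengths are in codons including the stop codon.
    """

    n_operons: int = 100
    genes_per_operon_range: tuple[int, int] = (1, 5)
    cds_length_range_codons: tuple[int, int] = (100, 300)
    utr5_length_range_nt: tuple[int, int] = (15, 40)
    overlap_probability: float = 0.4
    minus1_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    escape_prob: dict[str, float] = field(
        default_factory=lambda: {"G": 0.05, "C": 0.3, "T": 0.6, "A": 0.6}
    )
    coupling_attenuation: float = 0.5
    stall_footprint_fraction_retained: float = 0.8
    footprints_per_codon: float = 0.2
    ribo_depth: int = 200_000
    rna_depth: int = 200_000
    ribo_len_range: tuple[int, int] = (25, 40)
    rna_len_range: tuple[int, int] = (25, 45)
    abundance_lognormal_params: tuple[float, float] = (0.0, 1.0)
    include_reverse_strand: bool = False
    max_replicon_length: int | None = None
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "overlap_probability": self.overlap_probability,
            "coupling_attenuation": self.coupling_attenuation,
            "stall_footprint_fraction_retained": self.stall_footprint_fraction_retained,
            **{f"escape_prob[{b}]": p for b, p in self.escape_prob.items()},
            **{f"minus1_base_weights[{b}]": w for b, w in self.minus1_base_weights.items()},
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise SimulationError(f"{name} = {p} outside [0, 1]")
        if set(self.minus1_base_weights) != set(BASES) or set(self.escape_prob) != set(BASES):
            raise SimulationError("base maps must cover exactly {A,C,G,T}")
        if abs(sum(self.minus1_base_weights.values()) - 1.0) > 1e-9:
            raise SimulationError("minus1_base_weights must sum to 1")
        for name, (lo, hi) in {
            "genes_per_operon_range": self.genes_per_operon_range,
            "cds_length_range_codons": self.cds_length_range_codons,
            "utr5_length_range_nt": self.utr5_length_range_nt,
            "ribo_len_range": self.ribo_len_range,
            "rna_len_range": self.rna_len_range,
        }.items():
            if lo < 1 or hi < lo:
                raise SimulationError(f"{name} = ({lo}, {hi}) is not a valid range")
        if self.cds_length_range_codons[0] < 4:
            raise SimulationError("CDS must be at least 4 codons")
        if self.n_operons < 1 or self.ribo_depth < 0 or self.rna_depth < 0:
            raise SimulationError("n_operons must be >= 1 and depths >= 0")
        if self.footprints_per_codon <= 0:
            raise SimulationError("footprints_per_codon must be > 0")

    def effective_escape(self, minus1_base: str, overlapping: bool) -> float:
        """True escape probability: a pure function of -1 base and coupling."""
        e = self.escape_prob[minus1_base]
        if overlapping:
            return 1.0 - self.coupling_attenuation * (1.0 - e)
        return e


@dataclass
class SimGenome:
    """A synthetic replicon with its annotation and ground truth."""

    replicon: str
    sequence: str
    genes: list[GeneModel]
    truth: pd.DataFrame  # gene_id, minus1_base, category, escape_true, abundance
    config: SimConfig

    @property
    def replicon_lengths(self) -> dict[str, int]:
        return {self.replicon: len(self.sequence)}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff": outdir / "genes.gff3",
            "operons": outdir / "operons.tsv",
            "truth": outdir / "truth.tsv",
        }
        ann.write_fasta(paths["fasta"], {self.replicon: self.sequence})
        ann.write_gff3(paths["gff"], self.genes)
        ann.write_operon_tsv(paths["operons"], self.genes)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# genome construction

def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, n)]


def _rand_codons(rng: np.random.Generator, n: int, pool=SENSE_CODONS) -> list[str]:
    return [pool[i] for i in rng.integers(0, len(pool), n)]


def build_genome(config: SimConfig, replicon_name: str = "synchr1") -> SimGenome:
    """Deterministically build the synthetic replicon and annotation.

    Every gene's -1 base is drawn from ``minus1_base_weights`` and
    written into the sequence (the base 5' of the start codon in
    transcript orientation), so annotation and sequence always agree.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = np.array([config.minus1_base_weights[b] for b in BASES])
    g_lo, g_hi = config.genes_per_operon_range
    c_lo, c_hi = config.cds_length_range_codons
    u_lo, u_hi = config.utr5_length_range_nt

    parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    emit("".join(_rand_seq(rng, 60)))  # leading pad for read overhangs

    for op_idx in range(config.n_operons):
        oid = f"op{op_idx:04d}"
        n_genes = int(rng.integers(g_lo, g_hi + 1))
        overlaps = [False] + [
            bool(rng.random() < config.overlap_probability) for _ in range(n_genes - 1)
        ]
        minus1 = [BASES[i] for i in rng.choice(4, size=n_genes, p=weights)]
        n_codons = rng.integers(c_lo, c_hi + 1, size=n_genes)
        block_start = pos
        block_parts: list[str] = []
        bpos = 0
        brec = []  # (gene_idx_in_operon, b_cds_start, b_cds_end, utr5)

        def bemit(seq: str) -> None:
            nonlocal bpos
            block_parts.append(seq)
            bpos += len(seq)

        for i in range(n_genes):
            nc = int(n_codons[i])
            next_ovl = i + 1 < n_genes and overlaps[i + 1]
            if not overlaps[i]:
                utr_len = int(rng.integers(u_lo, u_hi + 1))
                utr = _rand_seq(rng, utr_len)
                utr[-1] = minus1[i]
                bemit("".join(utr))
                cds_start = bpos
                codons = ["ATG"]
                if next_ovl:
                    codons += _rand_codons(rng, nc - 3)
                    # final sense codon is X m A (m = next gene's -1 base);
                    # X must not be T or a stop codon could form
                    x = "ACG"[rng.integers(0, 3)]
                    codons.append(x + minus1[i + 1] + "A")
                    codons.append("TGA")
                else:
                    codons += _rand_codons(rng, nc - 2)
                    codons.append(STOP_CODONS[rng.integers(0, 3)])
                bemit("".join(codons))
                brec.append((i, cds_start, bpos, utr_len))
            else:
                # ATGA-type junction: start codon first base = upstream stop
                # last base - 3. Upstream wrote ... X m A | T G A; the
                # downstream CDS reuses the trailing "ATGA" (codon 1 = ATG,
                # codon 2 starts with the stop codon's A).
                cds_start = bpos - 4
                codons = ["A" + "".join(_rand_seq(rng, 2))]  # codon 2, A** never stop
                if next_ovl:
                    codons += _rand_codons(rng, nc - 4)
                    x = "ACG"[rng.integers(0, 3)]
                    codons.append(x + minus1[i + 1] + "A")
                    codons.append("TGA")
                else:
                    codons += _rand_codons(rng, nc - 3)
                    codons.append(STOP_CODONS[rng.integers(0, 3)])
                bemit("".join(codons)[1:])  # first base of codon 2 already emitted
                brec.append((i, cds_start, cds_start + 3 * nc, 0))

        block = "".join(block_parts)
        strand = "+"
        if config.include_reverse_strand and rng.random() < 0.5:
            strand = "-"
            block = ann.revcomp(block)
            brec = [(i, len(block) - e, len(block) - s, u) for i, s, e, u in brec]
        emit(block)
        for i, s, e, utr_len in brec:
            genes.append(
                GeneModel(
                    gene_id=f"g{op_idx:04d}_{i + 1:02d}",
                    replicon=replicon_name,
                    strand=strand,
                    cds_start=block_start + s,
                    cds_end=block_start + e,
                    utr5_len=utr_len,
                    operon_id=oid,
                    operon_rank=i + 1,
                    minus1_base=minus1[i],
                )
            )
        emit("".join(_rand_seq(rng, int(rng.integers(40, 101)))))  # spacer

    emit("".join(_rand_seq(rng, 60)))  # trailing pad
    sequence = "".join(parts)
    if config.max_replicon_length is not None and len(sequence) > config.max_replicon_length:
        raise SimulationError(
            f"infeasible packing: genome needs {len(sequence)} nt but the "
            f"replicon length budget is {config.max_replicon_length} nt; "
            "reduce n_operons or gene lengths"
        )

    genes = categorize_genes(genes)
    _check_genes(sequence, genes)

    mu, sd = config.abundance_lognormal_params
    abund = rng.lognormal(mu, sd, size=len(genes))
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "minus1_base": [g.minus1_base for g in genes],
            "category": [g.category for g in genes],
            "escape_true": [
                config.effective_escape(g.minus1_base, g.category == "overlapping_operonic")
                for g in genes
            ],
            "abundance": abund,
        }
    )
    return SimGenome(replicon_name, sequence, genes, truth, config)


def _check_genes(seq: str, genes: list[GeneModel]) -> None:
    for g in genes:
        cds = seq[g.cds_start : g.cds_end]
        if g.strand == "-":
            cds = ann.revcomp(cds)
        assert cds[:3] == "ATG", f"{g.gene_id} does not start with ATG"
        assert cds[-3:] in STOP_CODONS, f"{g.gene_id} does not end with a stop"
        if g.strand == "+":
            m1 = seq[g.cds_start - 1]
        else:
            m1 = ann.revcomp(seq[g.cds_end])
        assert m1 == g.minus1_base, f"{g.gene_id}: -1 base mismatch"
        # no internal stop in frame
        internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal), f"{g.gene_id}: internal stop"


# ---------------------------------------------------------------------------
# read simulation

def _event_counts(rng, genome: SimGenome, depth: int) -> np.ndarray:
    a = genome.truth["abundance"].to_numpy()
    return rng.poisson(depth * a / a.sum())


def _footprints_for_codons(
    rng, gene: GeneModel, codon_idx: np.ndarray, len_range
) -> tuple[np.ndarray, np.ndarray]:
    """Genomic left coordinates and lengths for footprints whose A-site
    first base sits at the given sense-codon indices. The 3' end (in
    transcript direction) is placed 12 nt downstream of the A-site
    first base; lengths are uniform in ``len_range``."""
    L = rng.integers(len_range[0], len_range[1] + 1, size=len(codon_idx))
    if gene.strand == "+":
        a = gene.cds_start + 3 * codon_idx
        left = a + 12 - (L - 1)
    else:
        a = gene.cds_end - 1 - 3 * codon_idx
        left = a - 12
    return left, L


def simulate_riboseq(
    genome: SimGenome, condition: str, config: SimConfig | None = None
) -> ReadSet:
    """Simulate one Ribo-seq library for ``condition`` ("control"/"drug").

    Initiation events arrive on gene i at a rate proportional to its
    abundance. A traversing ribosome (every control event; drug events
    that escape arrest) is footprint-sampled at
    ``footprints_per_codon`` per sense codon, placed uniformly over
    sense codons with a mild basal start-codon weight. A drug event is
    arrested at the start codon with probability 1 - escape_i and
    leaves a single start-codon footprint with probability
    ``stall_footprint_fraction_retained`` (else it dissociates and
    leaves nothing). The library is a snapshot of this steady state:
    per-gene footprint counts are Poisson draws of the two thinned
    event streams (arrested and traversing), with event rates scaled
    so the control library has ``ribo_depth`` expected footprints.
    """
    if condition not in ("control", "drug"):
        raise ValueError(f"unknown condition {condition!r}")
    config = config or genome.config
    if not genome.genes:
        raise SimulationError("empty genome")
    salt = {"control": 1, "drug": 2}[condition]
    rng = np.random.default_rng([config.seed, 101, salt])
    a = genome.truth["abundance"].to_numpy()
    n_sense_arr = np.array([g.cds_len // 3 - 1 for g in genome.genes])
    fpc = config.footprints_per_codon
    rate = config.ribo_depth * a / (fpc * float(a @ n_sense_arr))
    escape = genome.truth["escape_true"].to_numpy()
    if condition == "drug":
        esc_eff = escape
        stall_fp = rng.poisson(
            rate * (1.0 - escape) * config.stall_footprint_fraction_retained
        )
    else:
        esc_eff = np.ones_like(escape)
        stall_fp = np.zeros(len(escape), dtype=np.int64)
    body_fp = rng.poisson(rate * esc_eff * fpc * n_sense_arr)

    lefts, lengths, revs = [], [], []
    for g, n_stall, n_body, n_sense in zip(
        genome.genes, stall_fp, body_fp, n_sense_arr
    ):
        if n_stall + n_body == 0:
            continue
        codons = [np.zeros(n_stall, dtype=np.int64)]
        if n_body:
            w = np.ones(n_sense)
            w[0] = CONTROL_START_WEIGHT
            w /= w.sum()
            codons.append(rng.choice(n_sense, size=n_body, p=w))
        codon_idx = np.concatenate(codons)
        left, L = _footprints_for_codons(rng, g, codon_idx, config.ribo_len_range)
        lefts.append(left)
        lengths.append(L)
        revs.append(np.full(len(L), g.strand == "-"))

    return _pack_reads(genome, lefts, lengths, revs, prefix=f"rfp_{condition}_")


def simulate_rnaseq(
    genome: SimGenome, config: SimConfig | None = None, condition: str = "control"
) -> ReadSet:
    """Simulate one RNA-seq library: fragments uniform along each
    transcript (5' UTR + CDS), counts proportional to abundance,
    lengths uniform in ``rna_len_range``. Abundances do not change
    between conditions; the condition label only decouples the
    sampling noise of the two libraries."""
    config = config or genome.config
    if not genome.genes:
        raise SimulationError("empty genome")
    rng = np.random.default_rng(
        [config.seed, 202, zlib.crc32(condition.encode()) % (2**31)]
    )
    counts = _event_counts(rng, genome, config.rna_depth)

    lefts, lengths, revs = [], [], []
    for g, n_frags in zip(genome.genes, counts):
        if n_frags == 0:
            continue
        if g.strand == "+":
            ts, te = g.cds_start - g.utr5_len, g.cds_end
        else:
            ts, te = g.cds_start, g.cds_end + g.utr5_len
        span = te - ts
        L = rng.integers(config.rna_len_range[0], config.rna_len_range[1] + 1, n_frags)
        L = np.minimum(L, span)
        left = ts + (rng.random(n_frags) * (span - L + 1)).astype(np.int64)
        lefts.append(left)
        lengths.append(L)
        revs.append(np.full(n_frags, g.strand == "-"))

    return _pack_reads(genome, lefts, lengths, revs, prefix=f"rna_{condition}_")


def _pack_reads(genome, lefts, lengths, revs, prefix) -> ReadSet:
    if lefts:
        left = np.concatenate(lefts)
        L = np.concatenate(lengths)
        rev = np.concatenate(revs)
    else:
        left = np.zeros(0, dtype=np.int64)
        L = np.zeros(0, dtype=np.int64)
        rev = np.zeros(0, dtype=bool)
    n = len(genome.sequence)
    ok = (left >= 0) & (left + L <= n)
    if not ok.all():
        log.warning("dropping %d simulated reads off-replicon", int((~ok).sum()))
    return ReadSet(
        replicon=genome.replicon,
        replicon_length=n,
        lefts=left[ok],
        lengths=L[ok],
        is_reverse=rev[ok],
        name_prefix=prefix,
    )
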