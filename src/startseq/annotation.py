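"""Gene models and annotation input/output.

A :class:`GeneModel` describes one protein-coding gene on a replicon:
its CDS interval (0-based, half-open, stop codon included), strand,
5' UTR length, operon membership, the identity of the nucleotide
immediately preceding the start codon (the "-1 base"), and its
translational-coupling category.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the reader/writer boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

log = logging.getLogger(__name__)

CATEGORIES = ("overlapping_operonic", "nonoverlapping_operonic", "other")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene.

    ``cds_start``/``cds_end`` delimit the CDS including the stop codon,
    0-based half-open on the replicon. ``minus1_base`` is the base 5' of
    the start codon in transcript orientation. ``operon_rank`` is 1-based
    position within the operon in transcription order.
    """

    gene_id: str
    replicon: str
    strand: str
    cds_start: int
    cds_end: int
    utr5_len: int = 0
    operon_id: str = ""
    operon_rank: int = 1
    minus1_base: str = "N"
    category: str = "other"
    leaderless: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        n = self.cds_end - self.cds_start
        if n < 6 or n % 3:
            raise ValueError(
                f"{self.gene_id}: CDS length {n} must be >= 6 and divisible by 3"
            )
        if self.operon_rank < 1:
            raise ValueError(f"{self.gene_id}: operon_rank must be >= 1")

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def start_first_base(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    def transcript_window(self, lo: int, hi: int) -> tuple[int, int]:
        """Genomic half-open interval for transcript offsets [lo, hi)
        relative to the first base of the start codon."""
        if self.strand == "+":
            return self.cds_start + lo, self.cds_start + hi
        return self.cds_end - hi, self.cds_end - lo


# ---------------------------------------------------------------------------
# writers

def write_fasta(path: str | Path, replicons: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in replicons.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, genes: list[GeneModel]) -> None:
    """Write CDS features, 1-based inclusive, with a locus_tag attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID=cds-{g.gene_id};locus_tag={g.gene_id};"
                f"utr5_len={g.utr5_len};minus1={g.minus1_base}"
            )
            fh.write(
                "\t".join(
                    [
                        g.replicon,
                        "startseq",
                        "CDS",
                        str(g.cds_start + 1),
                        str(g.cds_end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_operon_tsv(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "operon_id", "rank"])
        for g in genes:
            w.writerow([g.gene_id, g.operon_id, g.operon_rank])


# ---------------------------------------------------------------------------
# readers

def read_operon_tsv(path: str | Path) -> dict[str, tuple[str, int]]:
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["gene_id"]] = (row["operon_id"], int(row["rank"]))
    return out


def load_annotation(
    gff_path: str | Path,
    operon_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> list[GeneModel]:
    """Load CDS features from GFF3 into :class:`GeneModel` records.

    The -1 base is taken from the genome sequence when a FASTA is given
    (authoritative), otherwise from the optional ``minus1`` GFF attribute.
    Operon membership comes from a gene_id/operon_id/rank TSV.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    operons = read_operon_tsv(operon_path) if operon_path else {}
    seqs = read_fasta(fasta_path) if fasta_path else {}

    genes: list[GeneModel] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        gid = feat.attributes.get("locus_tag", [feat.id])[0]
        cds_start, cds_end = feat.start - 1, feat.end  # to 0-based half-open
        utr5 = int(feat.attributes.get("utr5_len", [0])[0])
        minus1 = feat.attributes.get("minus1", ["N"])[0]
        if seqs:
            seq = seqs[feat.seqid]
            if feat.strand == "+":
                if cds_start >= 1:
                    minus1 = seq[cds_start - 1]
            else:
                if cds_end < len(seq):
                    minus1 = revcomp(seq[cds_end])
        operon_id, rank = operons.get(gid, (gid, 1))
        genes.append(
            GeneModel(
                gene_id=gid,
                replicon=feat.seqid,
                strand=feat.strand,
                cds_start=cds_start,
                cds_end=cds_end,
                utr5_len=utr5,
                operon_id=operon_id,
                operon_rank=rank,
                minus1_base=minus1,
            )
        )
    return genes


def write_annotation_tsv(path: str | Path, genes: list[GeneModel]) -> None:
    """Augmented annotation table (category and -1 base filled)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene_id",
                "replicon",
                "strand",
                "cds_start",
                "cds_end",
                "utr5_len",
                "operon_id",
                "operon_rank",
                "minus1_base",
                "category",
            ]
        )
        for g in genes:
            w.writerow(
                [
                    g.gene_id,
                    g.replicon,
                    g.strand,
                    g.cds_start,
                    g.cds_end,
                    g.utr5_len,
                    g.operon_id,
                    g.operon_rank,
                    g.minus1_base,
                    g.category,
                ]
            )
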