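"""Per-base density tracks and gene-level quantification.

Two track kinds are produced from accepted alignments:

* ``ribo_Asite`` — each footprint contributes unit mass at the first
  base of its A-site codon, obtained by taking the footprint's 3' end
  and shifting 12 nt against the direction of transcription:
  plus strand ``(left + length - 1) - 12``, minus strand ``left + 12``.
* ``rna_fractional`` — an N-nt RNA-seq fragment contributes 1/N to each
  of the N bases it covers, so every accepted read carries total mass 1.

In both cases ``total_mass`` equals the number of accepted reads (reads
whose shifted position falls off the replicon are dropped and do not
count). Gene quantities are RPKM over the CDS and translation
efficiency TE = ribo_RPKM / rna_RPKM, left undefined below an
expression floor on mRNA coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .reads import AlignedRead, ReadSet

log = logging.getLogger(__name__)

A_SITE_SHIFT = 12


class EmptyLibraryError(ValueError):
    pass


@dataclass
class DensityTrack:
    """Per-replicon, per-strand nonnegative coverage vectors."""

    kind: str
    data: dict[str, dict[str, np.ndarray]]
    total_mass: float = 0.0

    @classmethod
    def zeros(cls, kind: str, replicon_lengths: dict[str, int]) -> "DensityTrack":
        data = {
            name: {"+": np.zeros(n), "-": np.zeros(n)}
            for name, n in replicon_lengths.items()
        }
        return cls(kind=kind, data=data)

    def vector(self, replicon: str, strand: str) -> np.ndarray:
        return self.data[replicon][strand]

    def gene_window(self, gene: GeneModel, lo: int, hi: int) -> np.ndarray:
        """Density over transcript offsets [lo, hi) relative to the first
        base of the start codon, oriented 5'->3'. Out-of-replicon
        positions are returned as 0."""
        vec = self.vector(gene.replicon, gene.strand)
        gs, ge = gene.transcript_window(lo, hi)
        out = np.zeros(hi - lo)
        s, e = max(gs, 0), min(ge, len(vec))
        if s < e:
            out[s - gs : e - gs] = vec[s:e]
        if gene.strand == "-":
            out = out[::-1]
        return out

    def cds_density(self, gene: GeneModel) -> np.ndarray:
        return self.gene_window(gene, 0, gene.cds_len)


def _as_arrays(reads) -> tuple[str, np.ndarray, np.ndarray, np.ndarray] | None:
    if isinstance(reads, ReadSet):
        return reads.replicon, reads.lefts, reads.lengths, reads.is_reverse
    return None


def assign_ribo_density(
    reads: Iterable[AlignedRead] | ReadSet,
    replicon_lengths: dict[str, int],
) -> DensityTrack:
    """A-site assignment: 3' end of each footprint shifted -12 nt."""
    track = DensityTrack.zeros("ribo_Asite", replicon_lengths)
    fast = _as_arrays(reads)
    n_dropped = 0
    if fast is not None:
        rep, lefts, lengths, is_rev = fast
        n = replicon_lengths[rep]
        pos = np.where(is_rev, lefts + A_SITE_SHIFT, lefts + lengths - 1 - A_SITE_SHIFT)
        ok = (pos >= 0) & (pos < n)
        n_dropped = int((~ok).sum())
        for strand, rev in (("+", False), ("-", True)):
            sel = ok & (is_rev == rev)
            np.add.at(track.data[rep][strand], pos[sel], 1.0)
        track.total_mass = float(ok.sum())
    else:
        for r in reads:
            pos = (
                r.left + A_SITE_SHIFT
                if r.strand == "-"
                else r.left + r.length - 1 - A_SITE_SHIFT
            )
            vec = track.data[r.replicon][r.strand]
            if 0 <= pos < len(vec):
                vec[pos] += 1.0
                track.total_mass += 1.0
            else:
                n_dropped += 1
    if n_dropped:
        log.warning("A-site assignment: dropped %d reads off-replicon", n_dropped)
    return track


def assign_rna_density(
    reads: Iterable[AlignedRead] | ReadSet,
    replicon_lengths: dict[str, int],
) -> DensityTrack:
    """Fractional base assignment: an N-nt read adds 1/N at each covered base."""
    track = DensityTrack.zeros("rna_fractional", replicon_lengths)
    fast = _as_arrays(reads)
    n_dropped = 0
    if fast is not None:
        rep, lefts, lengths, is_rev = fast
        n = replicon_lengths[rep]
        ok = (lefts >= 0) & (lefts + lengths <= n)
        n_dropped = int((~ok).sum())
        for strand, rev in (("+", False), ("-", True)):
            sel = ok & (is_rev == rev)
            # interval addition via a difference array, then prefix sum
            diff = np.zeros(n + 1)
            w = 1.0 / lengths[sel]
            np.add.at(diff, lefts[sel], w)
            np.add.at(diff, lefts[sel] + lengths[sel], -w)
            track.data[rep][strand] += np.cumsum(diff[:-1])
        track.total_mass = float(ok.sum())
    else:
        for r in reads:
            vec = track.data[r.replicon][r.strand]
            if r.left < 0 or r.left + r.length > len(vec):
                n_dropped += 1
                continue
            vec[r.left : r.left + r.length] += 1.0 / r.length
            track.total_mass += 1.0
    if n_dropped:
        log.warning("RNA assignment: dropped %d reads off-replicon", n_dropped)
    return track


# ---------------------------------------------------------------------------
# gene quantification

def quantify_genes(
    ribo: DensityTrack,
    rna: DensityTrack,
    genes: list[GeneModel],
    min_rna_rpkm: float = 1.0,
    min_ribo_count: float = 32.0,
) -> pd.DataFrame:
    """Per-gene counts, RPKM and TE for one condition.

    RPKM_x = count_x / ((CDS_len/1e3) * (total_mass_x/1e6)). TE is NaN
    when rna_rpkm falls below ``min_rna_rpkm``; the ``expressed`` flag
    additionally requires ``ribo_count >= min_ribo_count``.
    """
    if ribo.total_mass <= 0 or rna.total_mass <= 0:
        raise EmptyLibraryError("empty library: a track has zero total mass")
    rows = []
    for g in genes:
        vec_len = len(ribo.vector(g.replicon, g.strand))
        if g.cds_start < 0 or g.cds_end > vec_len:
            raise ValueError(f"{g.gene_id} outside replicon bounds")
        ribo_count = float(ribo.cds_density(g).sum())
        rna_count = float(rna.cds_density(g).sum())
        kb = g.cds_len / 1e3
        ribo_rpkm = ribo_count / (kb * (ribo.total_mass / 1e6))
        rna_rpkm = rna_count / (kb * (rna.total_mass / 1e6))
        te = ribo_rpkm / rna_rpkm if rna_rpkm >= min_rna_rpkm else np.nan
        rows.append(
            {
                "gene_id": g.gene_id,
                "ribo_count": ribo_count,
                "rna_count": rna_count,
                "ribo_rpkm": ribo_rpkm,
                "rna_rpkm": rna_rpkm,
                "te": te,
                "expressed": rna_rpkm >= min_rna_rpkm and ribo_count >= min_ribo_count,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def relative_occupancy(
    ribo: DensityTrack,
    gene: GeneModel,
    rna_rpkm: float,
    global_factor: float = 1.0,
) -> np.ndarray:
    """Relative ribosome occupancy over the gene window (5' UTR + CDS).

    The A-site density is normalized by the gene's mRNA abundance
    (RNA-seq RPKM) and scaled by the residual global translation level
    measured independently (e.g. by metabolic labeling); 1.0 for
    untreated cells.
    """
    if rna_rpkm <= 0:
        raise ValueError(f"{gene.gene_id}: rna_rpkm must be > 0")
    if not 0 < global_factor <= 1:
        raise ValueError("global_factor must be in (0, 1]")
    window = ribo.gene_window(gene, -gene.utr5_len, gene.cds_len)
    return window / rna_rpkm * global_factor
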