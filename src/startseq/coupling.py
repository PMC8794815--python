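"""Translational-coupling categories for operonic genes.

Genes are partitioned into three classes by their position in the operon
and the geometry of their start codon relative to the upstream cistron:

* ``overlapping_operonic`` — a downstream (rank > 1) gene whose start
  codon overlaps the upstream gene's stop codon, or begins upstream of
  it (the classic ATGA-type junction and deeper overlaps). These are
  the genes where translational coupling by ribosome reinitiation is
  expected to be strongest.
* ``nonoverlapping_operonic`` — any other downstream operonic gene.
* ``other`` — singletons and the first gene of each operon, which
  initiate de novo.

The boundary rule: a gene is overlapping iff, in transcript
coordinates, the first base of its start codon lies at or before the
last base of the upstream gene's stop codon. Exactly adjacent codons
(0-nt gap) are nonoverlapping.
"""

from __future__ import annotations

from dataclasses import replace

from .annotation import GeneModel


class OperonError(ValueError):
    pass


def categorize_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Return a new gene list with ``category`` assigned for every gene."""
    by_operon: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_operon.setdefault(g.operon_id, []).append(g)

    upstream: dict[str, GeneModel] = {}
    for oid, members in by_operon.items():
        members.sort(key=lambda g: g.operon_rank)
        ranks = [g.operon_rank for g in members]
        if ranks != list(range(1, len(members) + 1)):
            raise OperonError(f"operon {oid}: ranks {ranks} not contiguous from 1")
        if len({g.strand for g in members}) > 1:
            raise OperonError(f"operon {oid}: genes on mixed strands")
        for prev, cur in zip(members, members[1:]):
            upstream[cur.gene_id] = prev

    out = []
    for g in genes:
        if g.operon_rank == 1:
            cat = "other"
        else:
            up = upstream.get(g.gene_id)
            if up is None:
                raise OperonError(
                    f"operon {g.operon_id}: rank {g.operon_rank} gene "
                    f"{g.gene_id} has no upstream gene"
                )
            cat = (
                "overlapping_operonic"
                if _start_overlaps_upstream_stop(g, up)
                else "nonoverlapping_operonic"
            )
        out.append(replace(g, category=cat))
    return out


def _start_overlaps_upstream_stop(gene: GeneModel, up: GeneModel) -> bool:
    if gene.strand == "+":
        # stop codon last base of upstream = up.cds_end - 1
        return gene.cds_start <= up.cds_end - 1
    # minus strand: transcript runs right-to-left; start first base is
    # cds_end - 1, upstream stop last base is up.cds_start
    return gene.cds_end - 1 >= up.cds_start
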