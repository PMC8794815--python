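"""Aligned-read containers and SAM/BED input.

Only uniquely mapped, ungapped, single-end alignments are analyzed;
multi-mappers (NH tag > 1, or a query name seen more than once when no
NH tags are present), unmapped/secondary/supplementary records, gapped
CIGARs and reads outside the length window are dropped, with per-reason
counts reported.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

log = logging.getLogger(__name__)

_CIGAR_UNGAPPED = re.compile(r"^(\d+)M$")


class SamFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """One ungapped single-end alignment (0-based inclusive ``left``)."""

    query_id: str
    replicon: str
    strand: str
    left: int
    length: int
    is_unique: bool = True

    def __post_init__(self):
        if self.length < 1 or self.left < 0:
            raise ValueError(f"bad alignment geometry for {self.query_id}")


@dataclass
class ReadSet:
    """Column-oriented batch of ungapped alignments on one replicon.

    Iterating yields :class:`AlignedRead`; the arrays are used directly
    by the vectorized density-assignment fast path.
    """

    replicon: str
    replicon_length: int
    lefts: np.ndarray
    lengths: np.ndarray
    is_reverse: np.ndarray
    name_prefix: str = "r"

    def __post_init__(self):
        self.lefts = np.asarray(self.lefts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.is_reverse = np.asarray(self.is_reverse, dtype=bool)
        n = len(self.lefts)
        if not (len(self.lengths) == n == len(self.is_reverse)):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.lefts)

    def __iter__(self) -> Iterator[AlignedRead]:
        for i in range(len(self)):
            yield AlignedRead(
                query_id=f"{self.name_prefix}{i:07d}",
                replicon=self.replicon,
                strand="-" if self.is_reverse[i] else "+",
                left=int(self.lefts[i]),
                length=int(self.lengths[i]),
            )

    def write_sam(self, path: str | Path, sequence: str | None = None) -> None:
        """Write a valid single-end ungapped SAM (CIGAR ``<len>M``, NH:i:1)."""
        import pysam

        from .annotation import revcomp

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.replicon, "LN": int(self.replicon_length)}],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(len(self)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{self.name_prefix}{i:07d}"
                a.flag = 16 if self.is_reverse[i] else 0
                a.reference_id = 0
                a.reference_start = int(self.lefts[i])
                a.mapping_quality = 42
                L = int(self.lengths[i])
                a.cigarstring = f"{L}M"
                if sequence is not None:
                    s = sequence[self.lefts[i] : self.lefts[i] + L]
                    a.query_sequence = revcomp(s) if self.is_reverse[i] else s
                else:
                    a.query_sequence = "N" * L
                a.set_tag("NH", 1)
                out.write(a)


# ---------------------------------------------------------------------------
# input

def read_alignments(
    path: str | Path,
    length_filter: tuple[int, int] = (20, 45),
    fmt: str | None = None,
    strict: bool = False,
    stats: dict | None = None,
) -> list[AlignedRead]:
    """Read and filter alignments from SAM or BED6.

    ``length_filter`` is an inclusive (min, max) read-length window.
    Under ``strict`` a gapped CIGAR aborts; otherwise it is skipped with
    a warning. ``stats``, if given, is filled with per-reason drop counts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() in {".bed", ".tsv"} else "sam"
    if fmt == "sam":
        reads, dropped = _read_sam(path, length_filter, strict)
    elif fmt == "bed":
        reads, dropped = _read_bed(path, length_filter)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    for reason, n in sorted(dropped.items()):
        if n:
            log.info("%s: dropped %d reads (%s)", path.name, n, reason)
    if stats is not None:
        stats.update(dropped)
        stats["accepted"] = len(reads)
    return reads


def _read_sam(path: Path, length_filter, strict) -> tuple[list[AlignedRead], Counter]:
    import pysam

    lo, hi = length_filter
    dropped: Counter = Counter()
    rows = []  # (name, replicon, strand, left, length, nh)
    any_missing_nh = False
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise SamFormatError(f"{path}: malformed SAM header: {exc}") from exc
    with sam:
        for rec in sam:
            if rec.is_unmapped:
                dropped["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                dropped["secondary_or_supplementary"] += 1
                continue
            cig = rec.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:
                if strict:
                    raise SamFormatError(
                        f"{path}: gapped/clipped CIGAR {rec.cigarstring!r} "
                        f"for {rec.query_name} (strict mode)"
                    )
                dropped["gapped_cigar"] += 1
                log.warning("skipping gapped alignment %s", rec.query_name)
                continue
            length = cig[0][1]
            if not lo <= length <= hi:
                dropped["length_filter"] += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            if nh is None:
                any_missing_nh = True
            rows.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    rec.reference_start,
                    length,
                    nh,
                )
            )

    multi_names: set[str] = set()
    if any_missing_nh:
        counts = Counter(name for name, *_ in rows)
        multi_names = {n for n, c in counts.items() if c > 1}

    reads = []
    for name, ref, strand, left, length, nh in rows:
        if (nh is not None and nh > 1) or name in multi_names:
            dropped["multimapper"] += 1
            continue
        reads.append(AlignedRead(name, ref, strand, left, length))
    return reads, dropped


def _read_bed(path: Path, length_filter) -> tuple[list[AlignedRead], Counter]:
    lo, hi = length_filter
    dropped: Counter = Counter()
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: BED6 line with {len(f)} fields")
            chrom, start, end, name, _score, strand = f[:6]
            length = int(end) - int(start)
            if not lo <= length <= hi:
                dropped["length_filter"] += 1
                continue
            reads.append(AlignedRead(name, chrom, strand, int(start), length))
    return reads, dropped
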