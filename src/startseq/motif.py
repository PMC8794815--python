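"""Position-specific binomial enrichment of start-codon context.

For a foreground gene set (e.g. the most drug-inhibited genes) against
a background universe (all analyzed genes), each (position, base) cell
is scored by the binomial tail probability of observing the foreground
count k out of n given the background frequency q at that position:

    score = -log10 Pr[Binomial(n, q) >= k]   if k/n >= q  (overrepresented)
    score = +log10 Pr[Binomial(n, q) <= k]   otherwise    (<= 0, under-)

so positive scores mark overrepresented bases and negative scores
underrepresented ones, on a -log10 p scale. The significance line is
Bonferroni-corrected over all base-by-position tests:
threshold = -log10(alpha / (4 * window_width)).

The context window spans offsets -15..+17 relative to the first base
of the start codon (33 nt; offsets 0..2 are the start codon itself).
Background frequencies are computed per position, since start-proximal
composition is position-structured (Shine-Dalgarno).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, revcomp

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
DEFAULT_WINDOW = (-15, 18)
SCORE_CAP = 300.0
LN10 = math.log(10.0)


class MotifError(ValueError):
    pass


@dataclass
class MotifResult:
    """Signed position-by-base enrichment scores with a significance line."""

    scores: pd.DataFrame  # index: offset, columns: A,C,G,T
    threshold: float
    fg_n: int
    bg_freqs: pd.DataFrame

    def score(self, offset: int, base: str) -> float:
        return float(self.scores.loc[offset, base])

    def significant(self) -> pd.DataFrame:
        """(offset, base, score) rows whose |score| exceeds the threshold."""
        rows = [
            {"offset": off, "base": b, "score": float(v)}
            for off, row in self.scores.iterrows()
            for b, v in row.items()
            if abs(v) > self.threshold
        ]
        return pd.DataFrame(rows, columns=["offset", "base", "score"])


def extract_context(
    genes: list[GeneModel],
    sequence: str | dict[str, str],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.Series:
    """Fixed-width genomic context string around each start codon.

    Minus-strand genes are reverse-complemented so the string always
    reads 5'->3' on the transcript. The window is genomic: if the
    annotated 5' UTR is shorter than the upstream extent, upstream
    replicon sequence is used. Genes whose window exits the replicon
    are dropped with a warning.
    """
    lo, hi = window
    seqs = sequence if isinstance(sequence, dict) else None
    out = {}
    dropped = 0
    for g in genes:
        seq = seqs[g.replicon] if seqs else sequence
        gs, ge = g.transcript_window(lo, hi)
        if gs < 0 or ge > len(seq):
            dropped += 1
            continue
        ctx = seq[gs:ge]
        if g.strand == "-":
            ctx = revcomp(ctx)
        out[g.gene_id] = ctx.upper()
    if dropped:
        log.warning("extract_context: dropped %d genes with windows off-replicon", dropped)
    return pd.Series(out, name="context")


def _tail_scores(k: int, n: int, q: float) -> float:
    """Signed -log10 binomial tail for one (position, base) cell."""
    if q <= 0.0:
        if k > 0:
            log.warning("background frequency 0 with foreground count %d; capped", k)
            return SCORE_CAP
        return 0.0
    if q >= 1.0:
        return 0.0  # Pr[X >= k] = 1 for any k <= n
    if k / n >= q:
        logp = stats.binom.logsf(k - 1, n, q)  # Pr[X >= k]
        return min(SCORE_CAP, -logp / LN10)
    logp = stats.binom.logcdf(k, n, q)  # Pr[X <= k]
    return max(-SCORE_CAP, logp / LN10)


def plogo_scores(
    foreground: pd.Series,
    background: pd.Series,
    alpha: float = 0.05,
    min_fg: int = 5,
    window_start: int = DEFAULT_WINDOW[0],
) -> MotifResult:
    """Score the foreground context matrix against the background.

    Both inputs are fixed-width context strings (from
    :func:`extract_context`); the foreground gene ids must be a subset
    of the background universe.
    """
    if len(foreground) < min_fg:
        raise MotifError(f"foreground has {len(foreground)} genes; need >= {min_fg}")
    if not set(foreground.index).issubset(set(background.index)):
        raise MotifError("foreground genes must be a subset of the background universe")
    widths = {len(s) for s in background} | {len(s) for s in foreground}
    if len(widths) != 1:
        raise MotifError(f"inconsistent context widths: {sorted(widths)}")
    width = widths.pop()
    offsets = np.arange(window_start, window_start + width)

    fg = np.array([list(s) for s in foreground])
    bg = np.array([list(s) for s in background])
    n = len(fg)
    m = 4 * width
    threshold = -math.log10(alpha / m)

    scores = pd.DataFrame(0.0, index=offsets, columns=list(BASES))
    freqs = pd.DataFrame(0.0, index=offsets, columns=list(BASES))
    for j, off in enumerate(offsets):
        for b in BASES:
            q = float((bg[:, j] == b).mean())
            k = int((fg[:, j] == b).sum())
            freqs.loc[off, b] = q
            scores.loc[off, b] = _tail_scores(k, n, q)
    scores.index.name = "offset"
    freqs.index.name = "offset"
    return MotifResult(scores=scores, threshold=threshold, fg_n=n, bg_freqs=freqs)
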