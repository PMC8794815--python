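"""Start-codon-proximal ribosome occupancy statistics.

* Metagene profile: per gene, A-site density over a window around the
  first base of the start codon is divided by that gene's mean CDS
  density; the profile is the median of these normalized values across
  qualifying genes at each offset. Normalizing by the CDS mean (rather
  than the window mean) keeps a large start peak from deflating itself.
* Head enrichment HE: mean density over the "head" (first five codons
  by default) relative to the mean over the ORF body (the rest of the
  CDS minus the stop-codon region), each stabilized by a pseudocount.
  Its drug-induced log2 change, gene by gene, is compared with the TE
  change by Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .density import DensityTrack

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (-30, 61)
DEFAULT_HEAD = (0, 15)  # CDS nt, half-open: codons 1-5
BODY_STOP_EXCLUSION = 9  # nt excluded at the CDS 3' end (stop codon region)


@dataclass
class CorrelationResult:
    rho: float
    n: int


def metagene_profile(
    track: DensityTrack,
    genes: list[GeneModel],
    window: tuple[int, int] = DEFAULT_WINDOW,
    by_minus1_base: bool = False,
    coverage_floor: float = 0.1,
    pseudocount: float = 1e-9,
    margin: int = 9,
    min_genes: int = 1,
):
    """Median per-gene-normalized density around start codons.

    Genes qualify when the CDS extends at least ``window[1] + margin``
    nt and mean CDS density is at least ``coverage_floor`` (reads/nt).
    Returns a DataFrame with columns offset, value, n_genes; with
    ``by_minus1_base`` a dict base -> DataFrame.
    """
    lo, hi = window
    rows_by_key: dict[str, list[np.ndarray]] = {}
    for g in genes:
        if g.cds_len < hi + margin:
            continue
        cds = track.cds_density(g)
        mean_cds = float(cds.mean())
        if mean_cds < coverage_floor:
            continue
        win = track.gene_window(g, lo, hi)
        norm = win / (mean_cds + pseudocount)
        key = g.minus1_base if by_minus1_base else "all"
        rows_by_key.setdefault(key, []).append(norm)

    def to_profile(rows):
        arr = np.vstack(rows)
        return pd.DataFrame(
            {
                "offset": np.arange(lo, hi),
                "value": np.median(arr, axis=0),
                "n_genes": len(rows),
            }
        )

    if not rows_by_key or all(len(v) < min_genes for v in rows_by_key.values()):
        raise ValueError(
            f"no genes qualify for the metagene profile "
            f"(CDS length >= {hi + margin} nt, mean CDS density >= {coverage_floor})"
        )
    if by_minus1_base:
        return {k: to_profile(v) for k, v in rows_by_key.items() if len(v) >= min_genes}
    return to_profile(rows_by_key["all"])


def head_enrichment(
    track: DensityTrack,
    gene: GeneModel,
    head_window: tuple[int, int] = DEFAULT_HEAD,
    body_stop_exclusion: int = BODY_STOP_EXCLUSION,
    pseudocount: float = 0.1,
) -> float | None:
    """HE = (mean head density + p) / (mean body density + p).

    Head and body are disjoint CDS windows (defaults: nt 0..14 and
    nt 15 .. CDS_len - 9). Returns None for genes too short to hold
    both, which callers should skip.
    """
    h_lo, h_hi = head_window
    body_end = gene.cds_len - body_stop_exclusion
    if body_end <= h_hi:
        log.warning("%s: CDS too short for disjoint head/body, skipped", gene.gene_id)
        return None
    cds = track.cds_density(gene)
    head = float(cds[h_lo:h_hi].mean())
    body = float(cds[h_hi:body_end].mean())
    return (head + pseudocount) / (body + pseudocount)


def head_enrichment_table(
    track: DensityTrack, genes: list[GeneModel], **kwargs
) -> pd.Series:
    vals = {}
    for g in genes:
        he = head_enrichment(track, g, **kwargs)
        if he is not None:
            vals[g.gene_id] = he
    return pd.Series(vals, name="he")


def delta_head_enrichment(
    treated: pd.Series, control: pd.Series
) -> pd.DataFrame:
    """Per-gene log2(HE_treated / HE_control) for genes present in both."""
    common = treated.index.intersection(control.index)
    missing = len(treated) + len(control) - 2 * len(common)
    if missing:
        log.info("delta HE: %d gene entries present in only one condition", missing)
    out = pd.DataFrame(
        {
            "he_control": control.loc[common],
            "he_treated": treated.loc[common],
        }
    )
    out["log2_he_change"] = np.log2(out["he_treated"] / out["he_control"])
    return out


def spearman_he_te(delta: pd.DataFrame) -> CorrelationResult:
    """Spearman rank correlation between log2 HE change and log2 TE
    change (average-rank tie handling), over genes where both are finite."""
    df = delta[["log2_he_change", "log2_te_change"]].dropna()
    df = df[np.isfinite(df).all(axis=1)]
    if len(df) < 3:
        raise ValueError(f"need >= 3 genes with both quantities finite, got {len(df)}")
    if df["log2_he_change"].nunique() == 1 or df["log2_te_change"].nunique() == 1:
        raise ValueError("rank correlation undefined: an input is constant")
    rho, _ = stats.spearmanr(df["log2_he_change"], df["log2_te_change"])
    return CorrelationResult(rho=float(rho), n=len(df))
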