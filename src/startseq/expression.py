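"""Drug-induced translation-efficiency changes and group comparisons.

The central quantity is the per-gene log2 change in translation
efficiency between a treated and a control library,

    dTE = log2((ribo_rpkm_t + p) / (rna_rpkm_t + p))
        - log2((ribo_rpkm_c + p) / (rna_rpkm_c + p)),

with a small RPKM pseudocount p keeping the ratio defined at zero
coverage. Genes failing the expression floor in the control sample are
excluded. The most-inhibited gene set is the top fraction of the
ranked dTE list (round half away from zero, deterministic gene_id
tie-break), and groups of genes (by -1 base or by coupling category)
are compared with pairwise two-sided Mann-Whitney U or Welch t tests
under Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

log = logging.getLogger(__name__)


def delta_te(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    pseudocount: float = 0.1,
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Per-gene log2 TE change, treated vs control.

    Both inputs are gene-quantification tables (from
    :func:`startseq.density.quantify_genes`) over the same annotation.
    Only genes flagged expressed in the control sample are kept.
    When ``genes`` is given, -1 base and coupling category columns are
    attached for downstream grouping.
    """
    if set(treated.index) != set(control.index):
        diff = set(treated.index) ^ set(control.index)
        raise ValueError(f"gene sets differ between conditions: {sorted(diff)[:10]}")
    control = control.loc[treated.index]
    p = pseudocount
    lt = np.log2((treated["ribo_rpkm"] + p) / (treated["rna_rpkm"] + p))
    lc = np.log2((control["ribo_rpkm"] + p) / (control["rna_rpkm"] + p))
    out = pd.DataFrame(
        {
            "log2_te_change": lt - lc,
            "expressed": control["expressed"],
        },
        index=treated.index,
    )
    out = out[out["expressed"]].drop(columns="expressed")
    if genes is not None:
        meta = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "minus1_base": [g.minus1_base for g in genes],
                "category": [g.category for g in genes],
            }
        ).set_index("gene_id")
        out = out.join(meta, how="left")
    return out.sort_index()


def top_fraction_size(n: int, fraction: float) -> int:
    """Number of genes in the top ``fraction`` of ``n``: round half away
    from zero, never below 1 (0.05 of 2,057 genes -> 103)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return max(1, int(math.floor(fraction * n + 0.5)))


def select_top_inhibited(delta: pd.DataFrame, fraction: float = 0.05) -> list[str]:
    """The k most-inhibited (most negative dTE) gene ids, deterministic."""
    if delta.empty:
        raise ValueError("empty delta table")
    finite = delta[np.isfinite(delta["log2_te_change"])]
    k = top_fraction_size(len(finite), fraction)
    order = sorted(zip(finite["log2_te_change"], finite.index))
    return [gid for _, gid in order[:k]]


def compare_groups(
    delta: pd.DataFrame,
    by: str = "minus1_base",
    test: str = "mann_whitney",
    exclude_top_fraction: float | None = None,
) -> pd.DataFrame:
    """All pairwise two-sided group tests with Bonferroni adjustment.

    ``by`` names a column of the delta table (``minus1_base`` or
    ``category``). ``exclude_top_fraction`` first removes the
    most-inhibited genes, as done when asking whether the context trend
    holds across the remaining bulk of the translatome. Pairs where a
    group has fewer than 2 members are skipped with a warning.
    """
    df = delta[np.isfinite(delta["log2_te_change"])]
    if exclude_top_fraction:
        top = set(select_top_inhibited(df, exclude_top_fraction))
        df = df[~df.index.isin(top)]
    groups = {k: v["log2_te_change"].to_numpy() for k, v in df.groupby(by)}
    groups = {k: v for k, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups by {by!r}, got {len(groups)}")
    pairs = list(itertools.combinations(sorted(groups), 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            log.warning("skipping pair (%s, %s): group with < 2 members", a, b)
            continue
        if test == "mann_whitney":
            method = "exact" if max(len(xa), len(xb)) <= 8 else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            stat = float(res.statistic)
        elif test == "t_test":
            res = stats.ttest_ind(xa, xb, equal_var=False)
            stat = float(res.statistic)
        else:
            raise ValueError(f"unknown test {test!r}")
        raw = float(res.pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "statistic": stat,
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)
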