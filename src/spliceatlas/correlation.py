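"""Transcript-to-host-gene expression correlation classes.

Each transcript-gene pair gets a Pearson r over samples and a two-sided
p-value from the t transform with n - 2 degrees of freedom; the pair is
``positive`` when p < 0.05 and r > 0.3, ``negative`` when p < 0.05 and
r < -0.3, else ``uncorrelated``.  Zero-variance vectors leave r undefined
and yield ``uncorrelated`` with a flag instead of an error, so a full
catalog run never crashes on a constant row.  No multiple-testing
correction is applied by default (Benjamini-Hochberg is available as an
option on the batch runner).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationRecord",
    "correlate_transcript_gene",
    "correlate_catalog",
    "gene_expression_from_transcripts",
    "relation_by_isoform_count",
]


@dataclass(frozen=True)
class CorrelationRecord:
    transcript_id: str
    gene_id: str
    r: float  # NaN when undefined (zero variance)
    p: float
    relation: str
    n_samples: int
    degenerate: bool = False


def correlate_transcript_gene(
    tx_expr: pd.Series,
    gene_expr: pd.Series,
    transcript_id: str = "",
    gene_id: str = "",
    r_threshold: float = 0.3,
    alpha: float = 0.05,
) -> CorrelationRecord:
    """Correlate one transcript with its host gene across samples.

    Both vectors must be indexed by the same sample set (order-insensitive).
    """
    if set(tx_expr.index) != set(gene_expr.index):
        raise ValueError("transcript and gene vectors cover different samples")
    gene_expr = gene_expr.reindex(tx_expr.index)
    n = len(tx_expr)
    if n < 3:
        raise ValueError("need >= 3 samples for a correlation")
    x = tx_expr.to_numpy(dtype=float)
    y = gene_expr.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(
            transcript_id, gene_id, float("nan"), float("nan"),
            "uncorrelated", n, degenerate=True,
        )
    r, p = stats.pearsonr(x, y)
    if p < alpha and r > r_threshold:
        relation = "positive"
    elif p < alpha and r < -r_threshold:
        relation = "negative"
    else:
        relation = "uncorrelated"
    return CorrelationRecord(transcript_id, gene_id, float(r), float(p), relation, n)


def gene_expression_from_transcripts(
    tpm: pd.DataFrame, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Gene-level expression as the sum of each gene's transcript TPM.

    A fallback when no independently quantified gene matrix is supplied;
    results based on it are flagged by the caller.
    """
    genes = pd.Series({t: g for t, g in tx2gene.items() if t in tpm.index})
    return tpm.loc[genes.index].groupby(genes).sum()


def correlate_catalog(
    tpm: pd.DataFrame,
    tx2gene: Mapping[str, str],
    gene_expr: Optional[pd.DataFrame] = None,
    r_threshold: float = 0.3,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Correlate every mapped transcript with its host gene.

    When *gene_expr* is absent, gene expression is computed as the sum of
    transcript TPM and the output carries ``gene_expr_source='tx_sum'``.
    With ``bh_correct=True`` the p < alpha gate is applied to BH-adjusted
    p-values instead.
    """
    source = "provided"
    if gene_expr is None:
        gene_expr = gene_expression_from_transcripts(tpm, tx2gene)
        source = "tx_sum"
    rows = []
    for tid, gid in sorted(tx2gene.items()):
        if tid not in tpm.index or gid not in gene_expr.index:
            continue
        rec = correlate_transcript_gene(
            tpm.loc[tid], gene_expr.loc[gid], tid, gid, r_threshold, alpha
        )
        rows.append(rec.__dict__)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        ok = out["p"].notna()
        q = pd.Series(np.nan, index=out.index)
        q[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q"] = q
        relation = np.where(
            (out["q"] < alpha) & (out["r"] > r_threshold), "positive",
            np.where((out["q"] < alpha) & (out["r"] < -r_threshold),
                     "negative", "uncorrelated"),
        )
        out["relation"] = relation
    out["gene_expr_source"] = source
    return out.set_index("transcript_id")


def relation_by_isoform_count(
    records: pd.DataFrame, isoforms_per_gene: Mapping[str, int]
) -> pd.DataFrame:
    """Relation proportions binned by the host gene's isoform count.

    Bins are 1..10 plus an overflow bin ``10+`` for genes producing more
    than 10 transcripts.  Returns per-bin counts of each relation and the
    corresponding proportions; empty input yields an empty table.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["bin", "relation", "count", "proportion"]
        )
    missing = [g for g in records["gene_id"].unique() if g not in isoforms_per_gene]
    if missing:
        raise KeyError(f"genes without isoform counts: {missing[:5]}")
    counts = records["gene_id"].map(isoforms_per_gene)
    bins = counts.where(counts <= 10).astype("Int64").astype(str).str.replace(
        r"\.0$", "", regex=True
    )
    bins = bins.mask(counts > 10, "10+")
    tab = (
        records.assign(bin=bins.to_numpy())
        .groupby(["bin", "relation"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = tab.groupby("bin")["count"].transform("sum")
    tab["proportion"] = tab["count"] / totals
    order = [str(i) for i in range(1, 11)] + ["10+"]
    tab["bin"] = pd.Categorical(tab["bin"], categories=order, ordered=True)
    return tab.sort_values(["bin", "relation"]).reset_index(drop=True)
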