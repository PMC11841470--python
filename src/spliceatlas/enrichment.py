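"""Hypergeometric overrepresentation analysis for arbitrary term maps.

A generic one-sided gene-set test: for a foreground of n genes drawn from a
background universe of N genes, a term annotating K background genes and
overlapping the foreground in k genes, the enrichment p-value is the upper
hypergeometric tail P(X >= k).  Benjamini-Hochberg correction is applied
across the tested terms; terms with no background overlap are skipped.
Works with any user-supplied mapping (GO, KEGG, PFAM, custom), read from
GMT or two-column TSV files.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "read_term_tsv",
    "overrepresentation",
]


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file (term, description, genes...) into a term map."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            genes = {g for g in parts[2:] if g}
            if genes:
                terms[parts[0]] = genes
    return terms


def read_term_tsv(path: str) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV into a term map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term"):
        out[str(term)] = set(grp["gene"].astype(str))
    return out


def overrepresentation(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, Set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each term in the foreground.

    Returns a table sorted by p with columns: term, k (overlap), K (term
    size in background), n (foreground size), N (background size), p and
    BH q, plus a ``significant`` flag at q < alpha.  The foreground must
    be a subset of the background.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    for t, genes in terms.items():
        if not genes:
            raise ValueError(f"term {t!r} has an empty gene set")
    n, N = len(fg), len(bg)
    rows = []
    for term in sorted(terms):
        term_bg = terms[term] & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & fg)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out.sort_values(["p", "term"]).reset_index(drop=True)
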