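"""Classify assembled transcripts against a reference annotation.

Assembled transcripts are partitioned into five classes by genomic-span
overlap with annotated genes: ``fusion`` (>= 2 same-strand genes),
``intergenic`` (no gene), ``antisense`` (opposite-strand genes only),
``reference_match`` (one same-strand gene, intron chain identical to a
reference isoform of that gene; single-exon transcripts require an exact
span match) and ``novel_in_gene`` (everything else in one gene).  Antisense
and intergenic transcripts are treated as potential non-coding RNAs and,
like fusions, are excluded from downstream expression analyses; only
``reference_match`` and ``novel_in_gene`` transcripts flow on.

Overlap means >= 1 bp of genomic-span intersection on the same chromosome.
An opposite-strand second gene never creates a fusion: the antisense
exclusion is applied before fusion logic is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import ExpressionMatrix, TranscriptModel

__all__ = [
    "TranscriptClass",
    "GeneIndex",
    "classify_transcript",
    "classify_catalog",
    "structural_summaries",
    "expressed_per_chromosome",
    "DOWNSTREAM_LABELS",
]

#: classes retained for expression-level analyses
DOWNSTREAM_LABELS = frozenset({"reference_match", "novel_in_gene"})

_LABELS = ("reference_match", "novel_in_gene", "intergenic", "antisense", "fusion")


@dataclass(frozen=True)
class TranscriptClass:
    label: str
    host_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "fusion" and len(self.host_gene_ids) < 2:
            raise ValueError("fusion requires >= 2 host genes")
        if self.label == "intergenic" and self.host_gene_ids:
            raise ValueError("intergenic must have no host genes")


class GeneIndex:
    """Interval index over reference gene spans with per-gene intron chains."""

    def __init__(self, reference: Sequence[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.gene_strand: dict[str, str] = {}
        self.gene_chrom: dict[str, str] = {}
        # per gene: set of reference intron chains, and exact spans of
        # single-exon isoforms (for the single-exon match rule)
        self.gene_chains: dict[str, set[tuple]] = {}
        self.gene_mono_spans: dict[str, set[tuple[int, int]]] = {}
        spans: dict[str, tuple[int, int]] = {}
        for tx in reference:
            gid = tx.gene_id
            if gid is None:
                raise ValueError(
                    f"reference transcript {tx.transcript_id} lacks a gene_id"
                )
            s, e = tx.span
            if gid in spans:
                ps, pe = spans[gid]
                spans[gid] = (min(ps, s), max(pe, e))
            else:
                spans[gid] = (s, e)
                self.gene_strand[gid] = tx.strand
                self.gene_chrom[gid] = tx.chrom
                self.gene_chains[gid] = set()
                self.gene_mono_spans[gid] = set()
            if tx.n_exons == 1:
                self.gene_mono_spans[gid].add(tx.span)
            else:
                self.gene_chains[gid].add(tx.intron_chain)
        for gid, (s, e) in spans.items():
            tree = self._trees.setdefault(self.gene_chrom[gid], IntervalTree())
            tree.addi(s, e + 1, gid)  # half-open storage for closed intervals

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Genes whose span intersects [start, end] (1-based closed)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))


def classify_transcript(tx: TranscriptModel, gene_index: GeneIndex) -> TranscriptClass:
    """Assign one of the five catalog classes to an assembled transcript."""
    if tx.n_exons == 0:  # TranscriptModel forbids this, but guard the contract
        raise ValueError("transcript with zero exons")
    s, e = tx.span
    hits = gene_index.overlapping(tx.chrom, s, e)
    same = tuple(g for g in hits if gene_index.gene_strand[g] == tx.strand)
    opposite = tuple(g for g in hits if gene_index.gene_strand[g] != tx.strand)
    if len(same) >= 2:
        return TranscriptClass("fusion", same)
    if len(same) == 1:
        gid = same[0]
        if tx.n_exons == 1:
            matched = tx.span in gene_index.gene_mono_spans[gid]
        else:
            matched = tx.intron_chain in gene_index.gene_chains[gid]
        return TranscriptClass("reference_match" if matched else "novel_in_gene", (gid,))
    if opposite:
        return TranscriptClass("antisense", opposite)
    return TranscriptClass("intergenic", ())


def classify_catalog(
    assembled: Sequence[TranscriptModel], reference: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Classify a whole assembled catalog; one row per transcript."""
    index = GeneIndex(reference)
    rows = []
    for tx in assembled:
        cls = classify_transcript(tx, index)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "label": cls.label,
                "host_gene_ids": ",".join(cls.host_gene_ids),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def structural_summaries(
    catalog: Sequence[TranscriptModel], length_bin_width: int = 250
) -> dict[str, pd.DataFrame]:
    """Exon-count histogram, genomic-span length histogram and
    per-chromosome gene/transcript counts.

    Length is the genomic span (introns included).  Length bins are
    half-open ``[k*w, (k+1)*w)`` and reported with explicit bounds.
    """
    if not catalog:
        raise ValueError("empty catalog")
    exon_counts = pd.Series([tx.n_exons for tx in catalog])
    exon_hist = (
        exon_counts.value_counts().sort_index().rename("n_transcripts")
        .rename_axis("n_exons").reset_index()
    )

    lengths = np.array([tx.length for tx in catalog])
    nbins = int(lengths.max() // length_bin_width) + 1
    edges = np.arange(nbins + 1) * length_bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    length_hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n_transcripts": counts}
    )

    chroms = sorted({tx.chrom for tx in catalog})
    per_chrom = pd.DataFrame(
        {
            "chrom": chroms,
            "n_transcripts": [
                sum(1 for tx in catalog if tx.chrom == c) for c in chroms
            ],
            "n_genes": [
                len({tx.gene_id for tx in catalog if tx.chrom == c and tx.gene_id})
                for c in chroms
            ],
        }
    )
    return {
        "exon_count_hist": exon_hist,
        "length_hist": length_hist,
        "per_chromosome": per_chrom,
    }


def expressed_per_chromosome(
    expr: ExpressionMatrix,
    catalog: Sequence[TranscriptModel],
    threshold: float = 1.0,
    chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-chromosome counts of expressed transcripts.

    A transcript counts as expressed in a sample iff TPM >= *threshold*
    (default 1 TPM).  Chromosomes with no expressed transcript appear as
    zero rows, not absent keys.
    """
    chrom_of = {tx.transcript_id: tx.chrom for tx in catalog}
    unknown = [t for t in expr.transcripts if t not in chrom_of]
    if unknown:
        raise KeyError(f"expression rows not in catalog: {unknown[:5]}")
    chroms = sorted(set(chromosomes) if chromosomes is not None
                    else {tx.chrom for tx in catalog})
    expressed = expr.values >= threshold
    groups = pd.Series([chrom_of[t] for t in expr.transcripts],
                       index=expr.transcripts)
    out = expressed.groupby(groups).sum().reindex(chroms, fill_value=0)
    out.index.name = "chrom"
    return out.astype(int)
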