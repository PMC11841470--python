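"""Core data containers shared across the pipeline.

A :class:`TranscriptModel` is the unit of cataloging, tissue-specificity
scoring, host-gene correlation and splicing-event generation: a stranded,
exon-structured transcript, optionally linked to a host gene.  An
:class:`ExpressionMatrix` pairs a transcripts x samples TPM table with the
sample-to-tissue map every tissue-level computation needs.

Annotation files (GFF3 or GTF) are parsed with :mod:`gffutils`; both
``gene_id``/``transcript_id`` attribute dialects (GTF) and ``ID``/``Parent``
hierarchies (GFF3) are accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd

__all__ = [
    "TranscriptModel",
    "ExpressionMatrix",
    "read_annotation",
    "write_gff3",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded transcript as an ordered exon chain.

    Exons are 1-based closed intervals, sorted ascending, non-overlapping.
    ``source`` distinguishes reference-annotation transcripts from assembled
    (e.g. StringTie-merged) ones.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: Optional[str] = None
    source: str = "reference"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) == 0:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        prev_end = 0
        for start, end in exons:
            if start > end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span: first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Genomic span length (introns included)."""
        s, e = self.span
        return e - s + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based closed), in genomic order."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Junction chain as (donor-side exon end, acceptor-side exon start)
        pairs in genomic order; empty for single-exon transcripts."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (reversed genomic order on '-')."""
        return self.exons if self.strand == "+" else self.exons[::-1]


class ExpressionMatrix:
    """Transcripts x samples TPM with a sample-to-tissue map.

    Values must be non-negative with no missing cells, and every sample
    column must carry a tissue label.
    """

    def __init__(self, values: pd.DataFrame, sample_tissue: Mapping[str, str]):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative TPM")
        missing = [s for s in values.columns if s not in sample_tissue]
        if missing:
            raise KeyError(f"samples without tissue label: {missing[:5]}")
        self.values = values
        self.sample_tissue = dict(sample_tissue)

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def tissues(self) -> list[str]:
        return sorted({self.sample_tissue[s] for s in self.values.columns})

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]

    def to_tsv(self, expr_path: str, map_path: str) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="transcript_id")
        pd.Series(self.sample_tissue, name="tissue").rename_axis("sample_id").to_csv(
            map_path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, expr_path: str, map_path: str) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        smap = pd.read_csv(map_path, sep="\t", index_col=0)["tissue"].to_dict()
        return cls(values, smap)


def read_annotation(path: str, source: Optional[str] = None) -> list[TranscriptModel]:
    """Parse a GFF3/GTF file into transcript models.

    Accepts files where transcripts are ``mRNA``/``transcript`` features with
    ``exon`` children, in either GFF3 (ID/Parent) or GTF
    (gene_id/transcript_id) attribute style.  ``source`` overrides the
    provenance tag on the returned models (defaults to ``reference``).
    """
    dialect = "gtf" if path.endswith((".gtf", ".GTF")) else "gff3"
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(dialect == "gtf"),
        disable_infer_transcripts=(dialect == "gtf"),
    )
    out: list[TranscriptModel] = []
    for feat in db.all_features():
        if feat.featuretype not in ("mRNA", "transcript"):
            continue
        tid = feat.attributes.get("transcript_id", [feat.id])[0] or feat.id
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            parents = feat.attributes.get("Parent", [])
            gid = parents[0] if parents else None
        exons = sorted(
            (child.start, child.end)
            for child in db.children(feat, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"transcript {tid} has zero exons in {path}")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=tuple(exons),
                gene_id=gid,
                source=source or "reference",
            )
        )
    return out


def write_gff3(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write transcripts as a minimal, deterministic GFF3 (1-based closed).

    Emits one gene feature per distinct gene_id (span = union of its
    transcripts), then mRNA and exon features.  Transcripts without a
    gene_id get a synthetic gene record of their own span.
    """
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    order: list[str] = []
    for tx in transcripts:
        gid = tx.gene_id or f"gene_of_{tx.transcript_id}"
        if gid not in by_gene:
            by_gene[gid] = []
            order.append(gid)
        by_gene[gid].append(tx)
    for gid in order:
        txs = by_gene[gid]
        gstart = min(t.span[0] for t in txs)
        gend = max(t.span[1] for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        lines.append(
            f"{chrom}\tspliceatlas\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        for tx in txs:
            s, e = tx.span
            lines.append(
                f"{chrom}\tspliceatlas\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={tx.transcript_id};Parent={gid};gene_id={gid};"
                f"transcript_id={tx.transcript_id}"
            )
            for i, (xs, xe) in enumerate(tx.exons, 1):
                lines.append(
                    f"{chrom}\tspliceatlas\texon\t{xs}\t{xe}\t.\t{strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id};"
                    f"gene_id={gid};transcript_id={tx.transcript_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
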