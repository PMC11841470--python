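"""Local alternative-splicing event enumeration and PSI quantification.

Events are enumerated from transcript exon structures per gene, in the
style of event-centric AS tools: every pairwise structural contrast between
two isoforms is classified into one of seven local event types and then
deduplicated across the gene, with inclusion/total transcript sets collecting
*all* isoforms compatible with each form, not just the defining pair.

Types (A3/A5/AF/AL are strand-relative):

* ``SE``  exon skipping: an internal exon present in one isoform, absent in
  another that joins the two flanking splice sites directly.
* ``RI``  intron retention: one isoform's exon spans another's intron with
  both flanking exon boundaries matched.
* ``A3``/``A5``  alternative 3' acceptor / 5' donor: two introns sharing
  their donor (resp. acceptor) with different, overlapping alternative
  exons on the other side.
* ``AF``/``AL``  alternative first / last exon: non-overlapping terminal
  exons splicing into a shared site.
* ``MX``  mutually exclusive exons: two non-overlapping internal exons with
  both outer flanking splice sites shared.

PSI of an event in a sample is the summed TPM of its inclusion-form
transcripts over the summed TPM of all event transcripts, undefined
(missing) when the denominator is zero.  Inclusion polarity is a fixed
convention — SE: exon included; RI: intron retained; A3/A5: shorter
intron; AF/AL: alternative exon more distal from the shared site;
MX: genomically upstream exon — chosen so complementarity
(PSI_inclusion + PSI_exclusion = 1) always holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import TranscriptModel

__all__ = [
    "ASEvent",
    "generate_events",
    "generate_events_catalog",
    "compute_psi",
    "psi_matrix",
    "filter_events",
    "event_type_summaries",
]

EVENT_TYPES = ("SE", "RI", "A3", "A5", "AF", "AL", "MX")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts or not self.total_transcripts:
            raise ValueError("inclusion and total sets must be nonempty")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValueError("inclusion must be a proper subset of total")

    @property
    def exclusion_transcripts(self) -> frozenset[str]:
        return self.total_transcripts - self.inclusion_transcripts


# ---------------------------------------------------------------------------
# event generation


def _junctions(tx: TranscriptModel) -> list[tuple[int, int]]:
    """(left exon end, right exon start) pairs in genomic order."""
    return list(tx.intron_chain)


def generate_events(transcripts: Sequence[TranscriptModel]) -> list[ASEvent]:
    """Enumerate deduplicated local AS events among one gene's isoforms.

    All transcripts must share gene_id, chrom and strand; fewer than two
    isoforms yield an empty list.
    """
    if not transcripts:
        return []
    gene = transcripts[0].gene_id
    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    for tx in transcripts:
        if (tx.gene_id, tx.chrom, tx.strand) != (gene, chrom, strand):
            raise ValueError(
                "all transcripts of one event-generation call must share "
                "gene, chromosome and strand"
            )
    if len(transcripts) < 2:
        return []
    txs = sorted(transcripts, key=lambda t: t.transcript_id)
    junc_sets = {t.transcript_id: set(_junctions(t)) for t in txs}
    exon_sets = {t.transcript_id: set(t.exons) for t in txs}

    found: dict[str, ASEvent] = {}

    def _add(event_type: str, coords: tuple, incl_pred, excl_pred) -> None:
        key = f"{gene};{event_type}:{chrom}:" + ":".join(
            "-".join(str(c) for c in part) for part in coords
        ) + f":{strand}"
        if key in found:
            return
        incl = frozenset(t.transcript_id for t in txs if incl_pred(t))
        excl = frozenset(t.transcript_id for t in txs if excl_pred(t))
        if not incl or not excl:
            return
        found[key] = ASEvent(
            event_id=key, event_type=event_type, gene_id=gene or "",
            chrom=chrom, strand=strand, coords=coords,
            inclusion_transcripts=incl,
            total_transcripts=incl | excl,
        )

    for a in txs:
        ja = junc_sets[a.transcript_id]
        # SE and MX pivot on internal exons of one isoform
        for i in range(1, a.n_exons - 1):
            e2s, e2e = a.exons[i]
            d = a.exons[i - 1][1]
            ac = a.exons[i + 1][0]
            # SE: some isoform joins the flanks directly
            if any((d, ac) in junc_sets[b.transcript_id] for b in txs if b is not a):
                _add(
                    "SE",
                    ((d, e2s), (e2e, ac)),
                    lambda t, d=d, e2s=e2s, e2e=e2e, ac=ac: (d, e2s) in junc_sets[t.transcript_id]
                    and (e2e, ac) in junc_sets[t.transcript_id],
                    lambda t, d=d, ac=ac: (d, ac) in junc_sets[t.transcript_id],
                )
            # MX: another isoform holds a non-overlapping internal exon
            # behind the same outer flanks
            for b in txs:
                if b is a:
                    continue
                for j in range(1, b.n_exons - 1):
                    f2s, f2e = b.exons[j]
                    if b.exons[j - 1][1] != d or b.exons[j + 1][0] != ac:
                        continue
                    if f2s <= e2e and e2s <= f2e:  # overlapping: not MX
                        continue
                    up, dn = sorted(((e2s, e2e), (f2s, f2e)))
                    _add(
                        "MX",
                        ((d, up[0]), (up[1], ac), (d, dn[0]), (dn[1], ac)),
                        lambda t, d=d, up=up, ac=ac: (d, up[0]) in junc_sets[t.transcript_id]
                        and (up[1], ac) in junc_sets[t.transcript_id],
                        lambda t, d=d, dn=dn, ac=ac: (d, dn[0]) in junc_sets[t.transcript_id]
                        and (dn[1], ac) in junc_sets[t.transcript_id],
                    )
        # RI: some isoform's single exon spans one of a's introns with
        # matched outer boundaries
        for i in range(a.n_exons - 1):
            s1, e1 = a.exons[i]
            s2, e2 = a.exons[i + 1]
            if any((s1, e2) in exon_sets[b.transcript_id] for b in txs if b is not a):
                _add(
                    "RI",
                    ((s1,), (e1, s2), (e2,)),
                    lambda t, s1=s1, e2=e2: (s1, e2) in exon_sets[t.transcript_id],
                    lambda t, s1=s1, e1=e1, s2=s2, e2=e2: (e1, s2) in junc_sets[t.transcript_id]
                    and (s1, e1) in exon_sets[t.transcript_id]
                    and (s2, e2) in exon_sets[t.transcript_id],
                )
        # junction-pair contrasts: A3/A5 (overlapping alternative exons)
        # and AF/AL (non-overlapping terminal exons)
        for b in txs:
            if b.transcript_id <= a.transcript_id:
                continue
            for (d1, a1) in ja:
                for (d2, a2) in junc_sets[b.transcript_id]:
                    if d1 == d2 and a1 != a2:
                        _right_variable(
                            a, b, d1, a1, a2, strand, exon_sets, junc_sets, _add
                        )
                    elif a1 == a2 and d1 != d2:
                        _left_variable(
                            a, b, a1, d1, d2, strand, exon_sets, junc_sets, _add
                        )

    return sorted(found.values(), key=lambda e: e.event_id)


def _exon_right_of(tx: TranscriptModel, start: int) -> Optional[tuple[int, int]]:
    for e in tx.exons:
        if e[0] == start:
            return e
    return None


def _exon_left_of(tx: TranscriptModel, end: int) -> Optional[tuple[int, int]]:
    for e in tx.exons:
        if e[1] == end:
            return e
    return None


def _right_variable(a, b, d, a1, a2, strand, exon_sets, junc_sets, _add) -> None:
    """Shared genomic-left splice site, different right exon starts."""
    ea = _exon_right_of(a, a1)
    eb = _exon_right_of(b, a2)
    if ea is None or eb is None:
        return
    overlap = ea[0] <= eb[1] and eb[0] <= ea[1]
    lo, hi = min(a1, a2), max(a1, a2)
    if overlap:
        # genomic-right variability: acceptor side on '+', donor side on '-'
        etype = "A3" if strand == "+" else "A5"
        _add(
            etype,
            ((d, lo), (d, hi)),
            # shorter intron = inclusion
            lambda t, d=d, lo=lo: (d, lo) in junc_sets[t.transcript_id],
            lambda t, d=d, hi=hi: (d, hi) in junc_sets[t.transcript_id],
        )
    else:
        # terminal on the right: last exon on '+', first (tx-order) on '-'
        if a.exons[-1] != ea or b.exons[-1] != eb:
            return
        etype = "AL" if strand == "+" else "AF"
        x_lo, x_hi = sorted((ea, eb))
        _add(
            etype,
            ((d, x_lo[0]), (x_lo[1],), (d, x_hi[0]), (x_hi[1],)),
            # more distal from the shared site = inclusion
            lambda t, d=d, x_hi=x_hi: (d, x_hi[0]) in junc_sets[t.transcript_id]
            and t.exons[-1] == x_hi,
            lambda t, d=d, x_lo=x_lo: (d, x_lo[0]) in junc_sets[t.transcript_id]
            and t.exons[-1] == x_lo,
        )


def _left_variable(a, b, ac, d1, d2, strand, exon_sets, junc_sets, _add) -> None:
    """Shared genomic-right splice site, different left exon ends."""
    ea = _exon_left_of(a, d1)
    eb = _exon_left_of(b, d2)
    if ea is None or eb is None:
        return
    overlap = ea[0] <= eb[1] and eb[0] <= ea[1]
    lo, hi = min(d1, d2), max(d1, d2)
    if overlap:
        etype = "A5" if strand == "+" else "A3"
        _add(
            etype,
            ((lo, ac), (hi, ac)),
            # shorter intron (larger donor-side coordinate) = inclusion
            lambda t, hi=hi, ac=ac: (hi, ac) in junc_sets[t.transcript_id],
            lambda t, lo=lo, ac=ac: (lo, ac) in junc_sets[t.transcript_id],
        )
    else:
        if a.exons[0] != ea or b.exons[0] != eb:
            return
        etype = "AF" if strand == "+" else "AL"
        x_lo, x_hi = sorted((ea, eb))
        _add(
            etype,
            ((x_lo[0],), (x_lo[1], ac), (x_hi[0],), (x_hi[1], ac)),
            # more distal = farther from the shared site = genomic-left exon
            lambda t, x_lo=x_lo, ac=ac: (x_lo[1], ac) in junc_sets[t.transcript_id]
            and t.exons[0] == x_lo,
            lambda t, x_hi=x_hi, ac=ac: (x_hi[1], ac) in junc_sets[t.transcript_id]
            and t.exons[0] == x_hi,
        )


def generate_events_catalog(
    transcripts: Sequence[TranscriptModel],
) -> list[ASEvent]:
    """Generate events for every gene in a mixed catalog.

    Transcripts without a gene_id are ignored; genes are processed on each
    (gene, chrom, strand) group independently.
    """
    groups: dict[tuple, list[TranscriptModel]] = {}
    for tx in transcripts:
        if tx.gene_id is None:
            continue
        groups.setdefault((tx.gene_id, tx.chrom, tx.strand), []).append(tx)
    events: list[ASEvent] = []
    for key in sorted(groups):
        events.extend(generate_events(groups[key]))
    return events


# ---------------------------------------------------------------------------
# PSI


def compute_psi(event: ASEvent, tpm: Mapping[str, float] | pd.Series) -> float:
    """PSI of one event in one sample; NaN when total abundance is zero."""
    incl = 0.0
    total = 0.0
    for tid in event.total_transcripts:
        v = float(tpm[tid])
        if v < 0:
            raise ValueError(f"negative TPM for {tid}")
        total += v
        if tid in event.inclusion_transcripts:
            incl += v
    if total == 0:
        return float("nan")
    return incl / total


def psi_matrix(events: Sequence[ASEvent], tpm: pd.DataFrame) -> pd.DataFrame:
    """Events x samples PSI from a transcripts x samples TPM matrix."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative TPM in expression matrix")
    rows = {}
    for ev in events:
        missing = [t for t in ev.total_transcripts if t not in tpm.index]
        if missing:
            raise KeyError(f"event {ev.event_id} transcripts absent: {missing}")
        total = tpm.loc[sorted(ev.total_transcripts)].sum(axis=0)
        incl = tpm.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[ev.event_id] = (incl / total).where(total > 0)
    out = pd.DataFrame(rows).T
    out.index.name = "event_id"
    out.columns = tpm.columns
    return out


def filter_events(
    psi: pd.DataFrame, min_psi: float = 0.1, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Retain events with PSI > min_psi in at least ceil(min_fraction * N)
    samples; missing PSI counts as failing."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    need = math.ceil(min_fraction * psi.shape[1])
    passing = (psi > min_psi).sum(axis=1) >= need
    return psi.loc[passing]


def event_type_summaries(
    psi: pd.DataFrame,
    events: Sequence[ASEvent],
    catalog_labels: Optional[Mapping[str, str]] = None,
    top_k: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Per-type event counts, PSI moments and the top-K most variable events.

    When *catalog_labels* (transcript -> catalog class) is given, each event
    is tagged ``novel`` if any of its transcripts is ``novel_in_gene``,
    else ``reference``.  Variance is computed over non-missing PSI only;
    the top-K ranking is deterministic, ties broken by event_id.
    """
    ev_by_id = {e.event_id: e for e in events}
    kept = [ev_by_id[i] for i in psi.index if i in ev_by_id]

    def provenance(ev: ASEvent) -> str:
        if catalog_labels is None:
            return "unknown"
        labels = {catalog_labels.get(t, "unknown") for t in ev.total_transcripts}
        return "novel" if "novel_in_gene" in labels else "reference"

    meta = pd.DataFrame(
        {
            "event_id": [e.event_id for e in kept],
            "event_type": [e.event_type for e in kept],
            "provenance": [provenance(e) for e in kept],
        }
    ).set_index("event_id")
    stats = pd.DataFrame(
        {
            "psi_mean": psi.mean(axis=1, skipna=True),
            "psi_var": psi.var(axis=1, ddof=1, skipna=True).fillna(0.0),
        }
    )
    meta = meta.join(stats)

    type_counts = (
        meta.groupby(["event_type", "provenance"], observed=True)
        .size()
        .rename("n_events")
        .reset_index()
    )
    type_psi = (
        meta.groupby("event_type", observed=True)[["psi_mean", "psi_var"]]
        .mean()
        .reset_index()
    )
    if top_k > len(meta):
        warnings.warn(
            f"top_k={top_k} exceeds event count {len(meta)}; truncating",
            stacklevel=2,
        )
        top_k = len(meta)
    top = (
        meta.sort_values(["psi_var", "event_id"], ascending=[False, True])
        .head(top_k)
        .reset_index()
    )
    return {"type_counts": type_counts, "type_psi": type_psi, "top_variable": top}
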