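import itertools
import random

import numpy as np
import pandas as pd
import pytest

from spliceatlas import (
    TranscriptModel,
    compute_psi,
    event_type_summaries,
    filter_events,
    generate_events,
    generate_events_catalog,
    psi_matrix,
)

# ---------------------------------------------------------------------------
# brute-force oracle: classify every transcript pair independently


def _junc(tx):
    return {(tx.exons[i][1], tx.exons[i + 1][0]) for i in range(tx.n_exons - 1)}


def _pair_events(a, b, strand):
    """All (type, coords) contrasts between two isoforms, enumerated naively."""
    out = set()
    ja, jb = _junc(a), _junc(b)
    ea_set, eb_set = set(a.exons), set(b.exons)
    for x, y, jy, ey in ((a, b, jb, eb_set), (b, a, ja, ea_set)):
        # SE
        for i in range(1, x.n_exons - 1):
            d, ac = x.exons[i - 1][1], x.exons[i + 1][0]
            if (d, ac) in jy:
                out.add(("SE", ((d, x.exons[i][0]), (x.exons[i][1], ac))))
        # RI
        for i in range(x.n_exons - 1):
            s1, e1 = x.exons[i]
            s2, e2 = x.exons[i + 1]
            if (s1, e2) in ey:
                out.add(("RI", ((s1,), (e1, s2), (e2,))))
    # MX
    for i in range(1, a.n_exons - 1):
        for j in range(1, b.n_exons - 1):
            if (
                a.exons[i - 1][1] == b.exons[j - 1][1]
                and a.exons[i + 1][0] == b.exons[j + 1][0]
            ):
                ea, eb = a.exons[i], b.exons[j]
                if ea[0] <= eb[1] and eb[0] <= ea[1]:
                    continue
                up, dn = sorted((ea, eb))
                d, ac = a.exons[i - 1][1], a.exons[i + 1][0]
                out.add(("MX", ((d, up[0]), (up[1], ac), (d, dn[0]), (dn[1], ac))))
    # junction-vs-junction contrasts
    for (d1, a1), (d2, a2) in itertools.product(ja, jb):
        if d1 == d2 and a1 != a2:
            xa = next(e for e in a.exons if e[0] == a1)
            xb = next(e for e in b.exons if e[0] == a2)
            if xa[0] <= xb[1] and xb[0] <= xa[1]:
                t = "A3" if strand == "+" else "A5"
                lo, hi = sorted((a1, a2))
                out.add((t, ((d1, lo), (d1, hi))))
            elif a.exons[-1] == xa and b.exons[-1] == xb:
                t = "AL" if strand == "+" else "AF"
                lo, hi = sorted((xa, xb))
                out.add((t, ((d1, lo[0]), (lo[1],), (d1, hi[0]), (hi[1],))))
        elif a1 == a2 and d1 != d2:
            xa = next(e for e in a.exons if e[1] == d1)
            xb = next(e for e in b.exons if e[1] == d2)
            if xa[0] <= xb[1] and xb[0] <= xa[1]:
                t = "A5" if strand == "+" else "A3"
                lo, hi = sorted((d1, d2))
                out.add((t, ((lo, a1), (hi, a1))))
            elif a.exons[0] == xa and b.exons[0] == xb:
                t = "AF" if strand == "+" else "AL"
                lo, hi = sorted((xa, xb))
                out.add((t, ((lo[0],), (lo[1], a1), (hi[0],), (hi[1], a1))))
    return out


def brute_force_events(transcripts):
    out = set()
    for a, b in itertools.combinations(transcripts, 2):
        out |= _pair_events(a, b, transcripts[0].strand)
    return out


# ---------------------------------------------------------------------------


def test_planted_genes_yield_exactly_their_event_type(bundle, truth):
    by_gene = {}
    for tx in bundle["reference"]:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gid, etype in truth.event_inventory.items():
        events = generate_events(by_gene[gid])
        assert [e.event_type for e in events] == [etype], gid


def test_matches_brute_force_on_all_synthetic_genes(bundle):
    by_gene = {}
    for tx in bundle["reference"] + [
        t for t in bundle["assembled"] if t.gene_id is not None
    ]:
        by_gene.setdefault((tx.gene_id, tx.source), []).append(tx)
    checked = 0
    for txs in by_gene.values():
        if len(txs) > 5:
            continue
        got = {(e.event_type, e.coords) for e in generate_events(txs)}
        assert got == brute_force_events(txs), txs[0].gene_id
        checked += 1
    assert checked >= 7


def test_single_transcript_and_strand_mixing():
    t1 = TranscriptModel("t1", "chr1", "+", ((1, 100), (201, 300)), "g")
    assert generate_events([t1]) == []
    t2 = TranscriptModel("t2", "chr1", "-", ((1, 100), (201, 300)), "g")
    with pytest.raises(ValueError, match="strand"):
        generate_events([t1, t2])


def test_event_generation_order_invariant(bundle):
    txs = [t for t in bundle["reference"] if t.gene_id == "G0006"]  # MX design
    ids = {e.event_id for e in generate_events(txs)}
    for seed in range(3):
        shuffled = txs[:]
        random.Random(seed).shuffle(shuffled)
        assert {e.event_id for e in generate_events(shuffled)} == ids


def test_inclusion_sets_collect_all_compatible_transcripts():
    """A third isoform sharing the inclusion structure joins the event's
    inclusion set even though it did not define the event."""
    base = [
        TranscriptModel("i1", "chr1", "+", ((1, 100), (201, 300), (401, 500)), "g"),
        TranscriptModel("i2", "chr1", "+", ((1, 100), (401, 500)), "g"),
        # same skipped-exon structure as i1, different last exon end
        TranscriptModel("i3", "chr1", "+", ((1, 100), (201, 300), (401, 520)), "g"),
    ]
    events = [e for e in generate_events(base) if e.event_type == "SE"]
    assert len(events) == 1
    assert events[0].inclusion_transcripts == frozenset({"i1", "i3"})
    assert events[0].total_transcripts == frozenset({"i1", "i2", "i3"})


def test_psi_arithmetic_and_degenerate_cases():
    txs = [
        TranscriptModel("i1", "chr1", "+", ((1, 100), (201, 300), (401, 500)), "g"),
        TranscriptModel("i2", "chr1", "+", ((1, 100), (401, 500)), "g"),
    ]
    (event,) = generate_events(txs)
    assert compute_psi(event, {"i1": 3.0, "i2": 1.0}) == pytest.approx(0.75)
    assert np.isnan(compute_psi(event, {"i1": 0.0, "i2": 0.0}))
    assert compute_psi(event, {"i1": 5.0, "i2": 0.0}) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="negative"):
        compute_psi(event, {"i1": -1.0, "i2": 1.0})


def test_psi_complementarity_and_scale_invariance(bundle):
    gene_linked = [t for t in bundle["assembled"] if t.gene_id is not None]
    events = generate_events_catalog(gene_linked)
    ref_tpm = bundle["expression"].values.loc[
        [t.transcript_id for t in gene_linked]
    ]
    psi = psi_matrix(events, ref_tpm)
    # complement each event by swapping inclusion and exclusion sets
    import dataclasses

    for ev in events:
        flipped = dataclasses.replace(
            ev,
            inclusion_transcripts=ev.exclusion_transcripts,
        )
        p1 = psi_matrix([ev], ref_tpm).iloc[0]
        p2 = psi_matrix([flipped], ref_tpm).iloc[0]
        both = p1.notna() & p2.notna()
        assert np.allclose((p1 + p2)[both], 1.0, atol=1e-9)
    scaled = ref_tpm * pd.Series(
        np.linspace(0.5, 7.0, ref_tpm.shape[1]), index=ref_tpm.columns
    )
    psi_scaled = psi_matrix(events, scaled)
    pd.testing.assert_frame_equal(psi, psi_scaled, check_exact=False, atol=1e-12)


def test_filter_retention_threshold_semantics():
    n = 100
    need = 5  # ceil(0.05 * 100)
    rows = {
        "kept": [0.2] * need + [0.0] * (n - need),
        "dropped_below_count": [0.2] * (need - 1) + [0.0] * (n - need + 1),
        "dropped_low_psi": [0.1] * n,  # strict >: 0.1 never passes
    }
    psi = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    out = filter_events(psi, min_psi=0.1, min_fraction=0.05)
    assert list(out.index) == ["kept"]
    with pytest.raises(ValueError):
        filter_events(psi, min_fraction=0.0)


def test_missing_psi_counts_as_failing_the_filter():
    psi = pd.DataFrame(
        {f"s{i}": [np.nan] for i in range(20)}, index=["all_missing"]
    )
    assert filter_events(psi).empty


def test_event_type_summaries_ranking_and_conservation(bundle, truth):
    gene_linked = [t for t in bundle["assembled"] if t.gene_id is not None]
    events = generate_events_catalog(gene_linked)
    ref_tpm = bundle["expression"].values.loc[
        [t.transcript_id for t in gene_linked]
    ]
    psi = psi_matrix(events, ref_tpm)
    labels = {t.transcript_id: "reference_match" for t in gene_linked}
    with pytest.warns(UserWarning, match="truncating"):
        s = event_type_summaries(psi, events, labels, top_k=10_000)
    assert s["type_counts"]["n_events"].sum() == len(psi)
    top = s["top_variable"]
    assert (top["psi_var"].to_numpy()[:-1] >= top["psi_var"].to_numpy()[1:]).all()
    # constant PSI rows rank last
    const_ids = psi.index[psi.nunique(axis=1, dropna=True) <= 1]
    if len(const_ids):
        assert set(top.tail(len(const_ids))["event_id"]) >= set(const_ids) or (
            top["psi_var"].tail(len(const_ids)) <= top["psi_var"].min() + 1e-12
        ).all()
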