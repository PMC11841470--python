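import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceatlas import (
    SimulationConfig,
    VariantRecord,
    apply_fdr_and_summarize,
    build_covariates,
    cluster_introns,
    filter_variants,
    intron_ratios_and_filter,
    map_sqtl,
    normalize_phenotypes,
    read_vcf,
    scan_cis,
    simulate_genotypes_and_introns,
)
from spliceatlas.sqtl import snp_intron_distance

# ---------------------------------------------------------------------------
# toy VCF: 6 clean sites + 4 that each violate one filter (20 samples)

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _vcf_line(pos, snp_id, alt, fs, qd, gts):
    return (
        f"chr1\t{pos}\t{snp_id}\tA\t{alt}\t.\tPASS\tFS={fs};QD={qd}\tGT\t"
        + "\t".join(gts)
    )


@pytest.fixture()
def toy_vcf(tmp_path):
    clean = ["0/0"] * 12 + ["0/1"] * 6 + ["1/1"] * 2  # MAF 0.25
    lines = [_vcf_line(1000 * (i + 1), f"clean{i}", "G", 5.0, 20.0, clean)
             for i in range(6)]
    lines.append(_vcf_line(7000, "triallelic", "G,T", 5.0, 20.0, clean))
    low_maf = ["0/0"] * 19 + ["0/1"]  # MAF 0.025 < 0.05
    lines.append(_vcf_line(8000, "low_maf", "G", 5.0, 20.0, low_maf))
    missing = ["./."] * 3 + clean[3:]  # 15% missing
    lines.append(_vcf_line(9000, "too_missing", "G", 5.0, 20.0, missing))
    lines.append(_vcf_line(10000, "bad_fs", "G", 35.0, 20.0, clean))
    path = tmp_path / "toy.vcf"
    samples = "\t".join(f"s{i}" for i in range(20))
    path.write_text(
        _VCF_HEADER
        + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
        + "\n".join(lines)
        + "\n"
    )
    return str(path)


def test_variant_filter_contract_and_idempotence(toy_vcf):
    records, samples = read_vcf(toy_vcf)
    assert len(records) == 10 and len(samples) == 20
    kept = filter_variants(records)
    assert sorted(r.snp_id for r in kept) == [f"clean{i}" for i in range(6)]
    assert filter_variants(kept) == kept  # idempotent


def test_qd_and_info_handling():
    clean = tuple([0] * 10 + [1] * 6 + [2] * 4)
    rec_low_qd = VariantRecord("chr1", 1, "x", "A", "G", 5.0, 1.5, clean)
    assert filter_variants([rec_low_qd]) == []
    rec_no_info = VariantRecord("chr1", 1, "y", "A", "G", float("nan"),
                                float("nan"), clean)
    assert filter_variants([rec_no_info]) == []
    with pytest.warns(UserWarning, match="missing FS/QD"):
        assert filter_variants([rec_no_info], drop_missing_info=False) == [rec_no_info]


# ---------------------------------------------------------------------------
# clustering


def _union_find_oracle(intron_ids):
    """Brute-force union-find over shared splice-site coordinates."""
    parent = {i: i for i in intron_ids}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def union(a, b):
        parent[find(a)] = find(b)

    coords = {}
    for iid in intron_ids:
        chrom, s, e = iid.split(":")[0], int(iid.split(":")[1]), int(iid.split(":")[2])
        coords[iid] = {(chrom, s), (chrom, e)}
    for a in intron_ids:
        for b in intron_ids:
            if a < b and coords[a] & coords[b]:
                union(a, b)
    groups = {}
    for i in intron_ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


def test_clustering_examples_and_oracle():
    # shared donor -> one cluster of 2
    out = cluster_introns(["chr1:100:200:x", "chr1:100:300:x"])
    assert len(out) == 1 and len(out[0].introns) == 2
    # disjoint singletons both dropped
    assert cluster_introns(["chr1:100:200:x", "chr1:500:600:x"]) == []
    # chain a-b, b-c -> one 3-member cluster
    out = cluster_introns(["chr1:100:200:x", "chr1:150:200:x", "chr1:150:400:x"])
    assert len(out) == 1 and len(out[0].introns) == 3
    with pytest.raises(ValueError, match="duplicate"):
        cluster_introns(["chr1:1:2:x", "chr1:1:2:x"])
    # randomized comparison against a union-find oracle
    rng = np.random.default_rng(4)
    sites = rng.choice(np.arange(100, 1000, 50), size=(60, 2))
    ids = sorted({f"chr{1 + i % 2}:{min(a, b)}:{max(a, b) + 1}" for i, (a, b)
                  in enumerate(sites)})
    got = {frozenset(c.introns) for c in cluster_introns(ids)}
    assert got == _union_find_oracle(ids)


def test_ratio_computation_presence_and_variation_filters():
    samples = [f"s{i}" for i in range(10)]
    counts = pd.DataFrame(
        {
            "chr1:100:200:c": [30] * 10,
            "chr1:100:300:c": [10] * 10,
            # present in only 20% of samples
            "chr1:500:600:d": [5, 5, 0, 0, 0, 0, 0, 0, 0, 0],
            "chr1:500:700:d": [5, 5, 10, 10, 10, 10, 10, 10, 10, 10],
        },
        index=samples,
    ).T
    clusters = cluster_introns(list(counts.index))
    ratios = intron_ratios_and_filter(counts, clusters, min_sd=-1.0)
    # constant 30/10 split: ratios exact, kept only when variation allowed
    assert ratios.loc["chr1:100:200:c"].eq(0.75).all()
    assert ratios.loc["chr1:100:300:c"].eq(0.25).all()
    assert "chr1:500:600:d" not in ratios.index  # 20% presence < 40%
    # with the default variation filter the constant rows are dropped too
    strict = intron_ratios_and_filter(counts, clusters)
    assert "chr1:100:200:c" not in strict.index


def test_ratios_sum_to_one_within_cluster(bundle):
    counts = bundle["intron_counts"]
    clusters = cluster_introns(list(counts.index))
    ratios = intron_ratios_and_filter(counts, clusters, min_presence=0.0,
                                      min_sd=-1.0)
    groups = ratios.index.str.rsplit(":", n=1).str[-1]
    sums = ratios.groupby(groups).sum()
    assert np.allclose(sums.to_numpy(), 1.0)


def test_inverse_normal_transform_closed_form_and_rank_preservation():
    row = pd.DataFrame({"s0": [0.3], "s1": [0.1], "s2": [0.9]},
                       index=["chr1:1:100:c"])
    out = normalize_phenotypes(row)
    expected = stats.norm.ppf((np.array([2, 1, 3]) - 0.5) / 3)
    assert np.allclose(out.to_numpy()[0], expected)
    rng = np.random.default_rng(9)
    x = rng.random(50)
    big = normalize_phenotypes(pd.DataFrame([x], index=["i"],
                                            columns=[f"s{i}" for i in range(50)]))
    assert (np.argsort(big.to_numpy()[0]) == np.argsort(x)).all()
    assert abs(big.to_numpy().mean()) < 1e-9
    # all-missing rows dropped; missing entries stay missing
    half = pd.DataFrame([[np.nan, 0.2, 0.8], [np.nan] * 3],
                        index=["a", "b"], columns=["s0", "s1", "s2"])
    out = normalize_phenotypes(half)
    assert list(out.index) == ["a"]
    assert np.isnan(out.loc["a", "s0"])


def test_covariates_orthogonal_deterministic_and_rank_capped():
    rng = np.random.default_rng(2)
    samples = [f"s{i}" for i in range(30)]
    pheno = pd.DataFrame(rng.normal(size=(8, 30)), columns=samples)
    geno = pd.DataFrame(rng.integers(0, 3, size=(40, 30)), columns=samples)
    cov = build_covariates(pheno, geno, k_pheno=3, k_geno=3)
    assert cov.shape == (30, 6)
    for block in ("pheno", "geno"):
        sub = cov.filter(like=block).to_numpy()
        gram = sub.T @ sub
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-10)
    # rank bound: a rank-2 phenotype matrix cannot give 10 components
    low = pd.DataFrame(np.outer([1, 2, 3], rng.normal(size=30))
                       + np.outer([0, 1, 1], rng.normal(size=30)),
                       columns=samples)
    with pytest.warns(UserWarning, match="rank"):
        cov2 = build_covariates(low, geno, k_pheno=10, k_geno=2)
    assert cov2.filter(like="pheno").shape[1] <= 3
    with pytest.raises(ValueError, match="no variance"):
        build_covariates(pheno * 0, geno, k_pheno=2, k_geno=2)


def test_scan_perfect_fit_window_and_refusal():
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(40)]
    g = rng.integers(0, 3, size=40).astype(float)
    genotypes = pd.DataFrame(
        [g, rng.integers(0, 3, size=40)], index=["near", "far"], columns=samples
    )
    positions = {"near": ("chr1", 60_000), "far": ("chr1", 300_000)}
    pheno = pd.Series(g, index=samples)
    recs = scan_cis(genotypes, positions, pheno, "chr1:100000:101000:c")
    assert [r.snp_id for r in recs] == ["near"]  # 150kb-away SNP not tested
    assert recs[0].beta == pytest.approx(1.0)
    assert recs[0].p_nominal < 1e-12
    assert recs[0].distance_bp == 40_000 and recs[0].is_cis
    with pytest.raises(ValueError, match="covariates"):
        cov = pd.DataFrame(np.eye(40)[:, :39], index=samples)
        scan_cis(genotypes, positions, pheno, "chr1:100000:101000:c", cov)


def test_distance_symmetric_upstream_downstream():
    assert snp_intron_distance(50, 100, 200) == 50
    assert snp_intron_distance(250, 100, 200) == 50
    assert snp_intron_distance(150, 100, 200) == 0


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(8)
    p = rng.random(1000) ** 2
    from spliceatlas import SQTLRecord

    recs = [
        SQTLRecord(f"s{i}", "i", 0.0, 1.0, float(pi), float("nan"), 0, True)
        for i, pi in enumerate(p)
    ]
    out = apply_fdr_and_summarize(recs)["records"]
    m = len(p)
    order = np.argsort(p)
    q_oracle = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q_oracle[order[rank]] = running
    assert np.allclose(out["q_fdr"].to_numpy(), q_oracle)
    # single test: q == p
    single = apply_fdr_and_summarize(recs[:1])["records"]
    assert single["q_fdr"].iloc[0] == pytest.approx(recs[0].p_nominal)
    # empty input: empty outputs, no error
    empty = apply_fdr_and_summarize([])
    assert empty["records"].empty and empty["significant"].empty


def test_planted_sqtl_recovered_end_to_end(bundle, truth):
    res = map_sqtl(
        bundle["variant_info"].assign(dummy=1).pipe(
            lambda df: [
                VariantRecord(
                    r.chrom, int(r.pos), sid, r.ref, r.alt, float(r.FS),
                    float(r.QD),
                    tuple(int(x) for x in bundle["genotypes"].loc[sid]),
                )
                for sid, r in df.iterrows()
            ]
        ),
        list(bundle["genotypes"].columns),
        bundle["intron_counts"],
        k_pheno=0,
        k_geno=2,
    )
    sig = set(zip(res["significant"].snp_id, res["significant"].intron_id))
    hits = sum((snp, intron) in sig for snp, intron, _ in truth.causal_pairs)
    assert hits >= len(truth.causal_pairs) - 1
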