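"""Cis splicing-QTL mapping from a filtered VCF and intron split-read counts.

The stages mirror the standard intron-excision-ratio workflow:

1. variant filtering (biallelic, Fisher-strand FS < 30, quality-by-depth
   QD > 2, site missingness, minor allele frequency);
2. intron clustering: connected components of the graph joining introns
   that share a donor or acceptor coordinate (singletons dropped — a lone
   intron carries no ratio information);
3. per-sample intron excision ratios (intron count / cluster total),
   filtered on presence (non-missing and nonzero in >= 40% of samples) and
   on minimal variation (ratio SD > epsilon);
4. rank-based inverse normal transform per intron (ties averaged), giving
   an approximately standard-normal phenotype per row;
5. covariates: top principal components of the phenotype matrix (a
   deterministic stand-in for latent-factor correction) concatenated with
   top genotype principal components for population structure;
6. a cis linear scan: for every SNP within 100 kb of the intron, regress
   the transformed phenotype on dosage plus covariates (missing dosages
   mean-imputed per SNP), with a two-sided t test on the dosage slope;
7. Benjamini-Hochberg FDR over all tested pairs, significance at q < 0.05,
   plus distance and sharing summaries.

The scan residualizes phenotype and dosage against the covariates once and
tests the partial correlation, which is algebraically identical to the full
multiple regression t-test with n - k_covariates - 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariantRecord",
    "IntronCluster",
    "SQTLRecord",
    "read_vcf",
    "filter_variants",
    "parse_intron_id",
    "cluster_introns",
    "intron_ratios_and_filter",
    "normalize_phenotypes",
    "build_covariates",
    "scan_cis",
    "apply_fdr_and_summarize",
    "map_sqtl",
]

CIS_WINDOW = 100_000


@dataclass(frozen=True)
class VariantRecord:
    """One SNP with its quality annotations and per-sample dosages.

    Dosages are alternate-allele counts in {0, 1, 2}; -1 marks a missing
    call.  ``n_alt`` carries the pre-filter alternate-allele count so that
    multi-allelic sites can be rejected."""

    chrom: str
    pos: int
    snp_id: str
    ref: str
    alt: str
    fs: float
    qd: float
    dosages: tuple[int, ...]
    n_alt: int = 1


@dataclass(frozen=True)
class IntronCluster:
    cluster_id: str
    introns: tuple[str, ...]  # intron ids "chrom:start:end[:cluster]"

    def __post_init__(self) -> None:
        if len(self.introns) < 2:
            raise ValueError("clusters must contain >= 2 introns")


@dataclass(frozen=True)
class SQTLRecord:
    snp_id: str
    intron_id: str
    beta: float
    se: float
    p_nominal: float
    q_fdr: float
    distance_bp: int
    is_cis: bool


# ---------------------------------------------------------------------------
# VCF input and variant filtering


def read_vcf(path: str) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF (v4.x, GT format; FS/QD INFO) into variant records.

    Returns ``(records, sample_ids)``.  Absent FS/QD INFO keys are stored
    as NaN and handled by :func:`filter_variants`.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosages = tuple(
            -1 if t == 2 else (0 if t == 0 else (1 if t == 1 else 2))
            for t in v.gt_types
        )
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                snp_id=v.ID or f"{v.CHROM}:{v.POS}",
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                fs=float(v.INFO.get("FS", np.nan)),
                qd=float(v.INFO.get("QD", np.nan)),
                dosages=dosages,
                n_alt=len(v.ALT),
            )
        )
    return records, samples


def filter_variants(
    records: Sequence[VariantRecord],
    fs_max: float = 30.0,
    qd_min: float = 2.0,
    max_missing: float = 0.9,
    maf_min: float = 0.05,
    drop_missing_info: bool = True,
) -> list[VariantRecord]:
    """Apply the biallelic / FS / QD / missingness / MAF site filters.

    A site passes iff it has exactly one alternate allele, FS < ``fs_max``,
    QD > ``qd_min``, a called-genotype fraction >= ``max_missing`` (i.e.
    missing rate <= 10% at the default), and minor allele frequency >=
    ``maf_min`` among non-missing calls.  Sites lacking FS/QD INFO are
    dropped by default; with ``drop_missing_info=False`` they pass those
    two checks with a warning.  The filter is idempotent.
    """
    import warnings

    out = []
    for rec in records:
        if rec.n_alt != 1:
            continue
        fs_ok = rec.fs < fs_max
        qd_ok = rec.qd > qd_min
        if math.isnan(rec.fs) or math.isnan(rec.qd):
            if drop_missing_info:
                continue
            warnings.warn(
                f"{rec.snp_id}: missing FS/QD INFO, passing through",
                stacklevel=2,
            )
            fs_ok = qd_ok = True
        if not (fs_ok and qd_ok):
            continue
        dos = np.asarray(rec.dosages)
        called = dos >= 0
        if called.mean() < max_missing:
            continue
        if called.sum() == 0:
            continue
        af = dos[called].sum() / (2 * called.sum())
        maf = min(af, 1 - af)
        if maf < maf_min:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# intron clustering and excision-ratio phenotypes


def parse_intron_id(intron_id: str) -> tuple[str, int, int, Optional[str]]:
    """Split ``chrom:start:end[:cluster]`` into its parts."""
    parts = intron_id.split(":")
    if len(parts) not in (3, 4):
        raise ValueError(f"malformed intron id {intron_id!r}")
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    cluster = parts[3] if len(parts) == 4 else None
    return chrom, start, end, cluster


def cluster_introns(intron_ids: Sequence[str]) -> list[IntronCluster]:
    """Group introns sharing a donor or acceptor coordinate.

    Clusters are connected components of the share-a-splice-site graph,
    per chromosome; singleton components are dropped.  Cluster ids are
    ``clu_1, clu_2, ...`` in genomic order of the leftmost member.
    """
    if len(set(intron_ids)) != len(intron_ids):
        raise ValueError("duplicate intron ids")
    g = nx.Graph()
    g.add_nodes_from(intron_ids)
    by_site: dict[tuple[str, int], list[str]] = {}
    for iid in intron_ids:
        chrom, start, end, _ = parse_intron_id(iid)
        by_site.setdefault((chrom, start), []).append(iid)
        by_site.setdefault((chrom, end), []).append(iid)
    for members in by_site.values():
        for other in members[1:]:
            g.add_edge(members[0], other)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: parse_intron_id(c[0])[:3])
    return [
        IntronCluster(cluster_id=f"clu_{i + 1}", introns=tuple(c))
        for i, c in enumerate(comps)
    ]


def intron_ratios_and_filter(
    counts: pd.DataFrame,
    clusters: Sequence[IntronCluster],
    min_presence: float = 0.40,
    min_sd: float = 0.005,
) -> pd.DataFrame:
    """Per-intron excision ratios within clusters, presence/variation filtered.

    Ratio = intron count / cluster total per sample, missing where the
    cluster total is zero.  An intron is kept iff its ratio is non-missing
    and nonzero in >= ``min_presence`` of samples and its ratio SD exceeds
    ``min_sd``.  Within a cluster the per-sample ratios of all members sum
    to 1 wherever the total is nonzero.
    """
    rows = {}
    for clu in clusters:
        member = [i for i in clu.introns if i in counts.index]
        if len(member) < 2:
            continue
        sub = counts.loc[member]
        total = sub.sum(axis=0)
        with np.errstate(invalid="ignore"):
            ratios = sub.div(total, axis=1)
        ratios.loc[:, total == 0] = np.nan
        for iid in member:
            rows[iid] = ratios.loc[iid]
    if not rows:
        return pd.DataFrame(columns=counts.columns)
    ratio_df = pd.DataFrame(rows).T
    ratio_df.index.name = "intron_id"
    present = (ratio_df.notna() & (ratio_df > 0)).mean(axis=1)
    sd = ratio_df.std(axis=1, ddof=1)
    keep = (present >= min_presence) & (sd > min_sd)
    return ratio_df.loc[keep]


def normalize_phenotypes(ratios: pd.DataFrame) -> pd.DataFrame:
    """Row-wise rank-based inverse normal transform.

    Ranks (ties averaged) map through Phi^-1((r - 0.5) / n) computed over
    non-missing entries; missing entries stay missing; all-missing rows are
    dropped.  Output rows have mean ~0 and SD ~1.
    """
    out = {}
    for iid, row in ratios.iterrows():
        x = row.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() == 0:
            continue
        ranks = stats.rankdata(x[ok])
        z = stats.norm.ppf((ranks - 0.5) / ok.sum())
        y = np.full_like(x, np.nan)
        y[ok] = z
        out[iid] = y
    res = pd.DataFrame(out, index=ratios.columns).T
    res.index.name = "intron_id"
    return res


# ---------------------------------------------------------------------------
# covariates and the cis scan


def _pca_components(mat: np.ndarray, k: int, label: str) -> np.ndarray:
    """Top-k sample-space principal components (columns), deterministic sign.

    *mat* is features x samples; rows are centered; components whose
    largest-magnitude loading is negative are flipped.
    """
    x = mat - mat.mean(axis=1, keepdims=True)
    if not np.isfinite(x).all():
        raise ValueError(f"{label}: non-finite values in PCA input")
    if np.allclose(x, 0):
        raise ValueError(f"{label}: matrix has no variance")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if k > rank:
        import warnings

        warnings.warn(
            f"{label}: requested {k} components but rank is {rank}; truncating",
            stacklevel=3,
        )
        k = rank
    comps = vt[:k]  # k x samples
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps.T  # samples x k


def build_covariates(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    k_pheno: int = 10,
    k_geno: int = 10,
) -> pd.DataFrame:
    """Samples x covariates matrix: phenotype PCs then genotype PCs.

    Phenotype rows with missing entries are mean-imputed for the
    decomposition only.  Missing dosages (< 0) are likewise mean-imputed
    per SNP.  Requires identical sample sets in both matrices.
    """
    if set(phenotypes.columns) != set(genotypes.columns):
        raise ValueError("phenotype and genotype matrices cover different samples")
    samples = list(phenotypes.columns)
    ph = phenotypes[samples].to_numpy(dtype=float)
    row_mean = np.nanmean(ph, axis=1, keepdims=True)
    ph = np.where(np.isnan(ph), row_mean, ph)
    gt = genotypes[samples].to_numpy(dtype=float)
    gt = np.where(gt < 0, np.nan, gt)
    gt = np.where(np.isnan(gt), np.nanmean(gt, axis=1, keepdims=True), gt)
    n = len(samples)
    pcs_p = _pca_components(ph, k_pheno, "phenotypes") if k_pheno > 0 else np.empty((n, 0))
    pcs_g = _pca_components(gt, k_geno, "genotypes") if k_geno > 0 else np.empty((n, 0))
    cols = [f"pheno_PC{i + 1}" for i in range(pcs_p.shape[1])] + [
        f"geno_PC{i + 1}" for i in range(pcs_g.shape[1])
    ]
    return pd.DataFrame(
        np.hstack([pcs_p, pcs_g]), index=pd.Index(samples, name="sample_id"),
        columns=cols,
    )


def snp_intron_distance(pos: int, start: int, end: int) -> int:
    """Distance from a SNP to an intron interval; 0 when inside."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def _residualize(y: np.ndarray, cov: Optional[np.ndarray]) -> np.ndarray:
    if cov is None or cov.shape[1] == 0:
        return y - y.mean()
    q, _ = np.linalg.qr(np.column_stack([np.ones(len(y)), cov]))
    return y - q @ (q.T @ y)


def scan_cis(
    genotypes: pd.DataFrame,
    snp_positions: Mapping[str, tuple[str, int]],
    phenotype: pd.Series,
    intron_id: str,
    covariates: Optional[pd.DataFrame] = None,
    window: int = CIS_WINDOW,
) -> list[SQTLRecord]:
    """Linear scan of one transformed intron phenotype against cis SNPs.

    Tests every SNP whose position lies within *window* bp of the intron
    interval (on its chromosome).  Missing dosages are mean-imputed per
    SNP; samples with a missing phenotype are excluded.  Slope, SE and the
    two-sided p-value come from the t distribution with
    n - n_covariates - 2 degrees of freedom.  ``q_fdr`` is NaN here and
    filled in by :func:`apply_fdr_and_summarize` over all scanned pairs.
    """
    chrom, start, end, _ = parse_intron_id(intron_id)
    samples = [s for s in genotypes.columns if not np.isnan(phenotype.get(s, np.nan))]
    n = len(samples)
    k_cov = 0 if covariates is None else covariates.shape[1]
    if n < k_cov + 3:
        raise ValueError(
            f"{intron_id}: {n} usable samples cannot support {k_cov} covariates"
        )
    y = phenotype[samples].to_numpy(dtype=float)
    cov = None if covariates is None else covariates.loc[samples].to_numpy(dtype=float)
    y_res = _residualize(y, cov)
    df = n - k_cov - 2

    records = []
    for snp_id in genotypes.index:
        snp_chrom, pos = snp_positions[snp_id]
        if snp_chrom != chrom:
            continue
        dist = snp_intron_distance(pos, start, end)
        if dist > window:
            continue
        g = genotypes.loc[snp_id, samples].to_numpy(dtype=float)
        g = np.where(g < 0, np.nan, g)
        if np.isnan(g).any():
            g = np.where(np.isnan(g), np.nanmean(g), g)
        g_res = _residualize(g, cov)
        gss = float(g_res @ g_res)
        if gss <= 0:
            continue  # monomorphic after imputation/residualization
        beta = float(g_res @ y_res) / gss
        resid = y_res - beta * g_res
        sigma2 = float(resid @ resid) / df
        se = math.sqrt(sigma2 / gss) if sigma2 > 0 else 0.0
        if se == 0.0:
            p = 0.0 if beta != 0 else 1.0
        else:
            t = beta / se
            p = float(2 * stats.t.sf(abs(t), df))
        records.append(
            SQTLRecord(
                snp_id=snp_id,
                intron_id=intron_id,
                beta=beta,
                se=se,
                p_nominal=p,
                q_fdr=float("nan"),
                distance_bp=dist,
                is_cis=dist <= CIS_WINDOW,
            )
        )
    return records


def apply_fdr_and_summarize(
    records: Sequence[SQTLRecord], alpha: float = 0.05,
    distance_bin_bp: int = 10_000,
) -> dict:
    """Benjamini-Hochberg q-values over all tested pairs plus summaries.

    Returns a dict with the full record table (``records``), the
    significant set at q < alpha (``significant``), a SNP-to-event distance
    histogram of significant pairs, and the events-per-SNP / SNPs-per-event
    sharing counts.  Empty input yields empty tables.
    """
    cols = [
        "snp_id", "intron_id", "beta", "se", "p_nominal", "q_fdr",
        "distance_bp", "is_cis",
    ]
    if not records:
        empty = pd.DataFrame(columns=cols)
        return {
            "records": empty,
            "significant": empty,
            "distance_hist": pd.DataFrame(columns=["bin_start", "bin_end", "n"]),
            "events_per_snp": pd.Series(dtype=int),
            "snps_per_event": pd.Series(dtype=int),
        }
    tab = pd.DataFrame([r.__dict__ for r in records])[cols]
    tab["q_fdr"] = multipletests(tab["p_nominal"], method="fdr_bh")[1]
    sig = tab[tab["q_fdr"] < alpha].reset_index(drop=True)

    nbins = int(np.ceil((CIS_WINDOW + 1) / distance_bin_bp))
    edges = np.arange(nbins + 1) * distance_bin_bp
    counts, _ = np.histogram(sig["distance_bp"], bins=edges)
    dist_hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n": counts}
    )
    return {
        "records": tab,
        "significant": sig,
        "distance_hist": dist_hist,
        "events_per_snp": sig.groupby("snp_id")["intron_id"].nunique(),
        "snps_per_event": sig.groupby("intron_id")["snp_id"].nunique(),
    }


def map_sqtl(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    intron_counts: pd.DataFrame,
    k_pheno: int = 10,
    k_geno: int = 10,
    window: int = CIS_WINDOW,
    alpha: float = 0.05,
    min_presence: float = 0.40,
    min_sd: float = 0.005,
) -> dict:
    """End-to-end cis-sQTL scan from filtered variants and intron counts."""
    filtered = filter_variants(variants)
    if not filtered:
        return apply_fdr_and_summarize([], alpha)
    genotypes = pd.DataFrame(
        [v.dosages for v in filtered],
        index=pd.Index([v.snp_id for v in filtered], name="snp_id"),
        columns=list(samples),
    )
    snp_positions = {v.snp_id: (v.chrom, v.pos) for v in filtered}
    clusters = cluster_introns(list(intron_counts.index))
    ratios = intron_ratios_and_filter(
        intron_counts, clusters, min_presence=min_presence, min_sd=min_sd
    )
    pheno = normalize_phenotypes(ratios)
    if pheno.empty:
        return apply_fdr_and_summarize([], alpha)
    covariates = build_covariates(pheno, genotypes, k_pheno, k_geno)
    all_records: list[SQTLRecord] = []
    for iid in pheno.index:
        all_records.extend(
            scan_cis(genotypes, snp_positions, pheno.loc[iid], iid,
                     covariates, window)
        )
    return apply_fdr_and_summarize(all_records, alpha)
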