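"""Synthetic multi-tissue splicing-atlas data with planted ground truth.

Generates the four inputs the pipeline consumes — a reference + assembled
transcript annotation, a transcript TPM matrix with a sample-to-tissue map,
a biallelic SNP VCF, and an intron split-read count matrix — with known
planted structure:

* seven designed genes whose isoform pairs instantiate exactly one local
  splicing event type each (SE, RI, A3, A5, AF, AL, MX), on both strands;
* assembled transcripts planted as reference matches, novel isoforms,
  intergenic, antisense and gene-fusion cases for catalog tests;
* tissue-restricted transcripts expressed at a target level in one tissue
  and essentially silent elsewhere;
* splicing QTLs as additive allelic effects on the latent (logit) intron
  excision ratio inside two-intron clusters, realized as binomial split-read
  counts at fixed cluster depth.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` generator, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, TranscriptModel, write_gff3

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_annotation",
    "simulate_expression",
    "simulate_genotypes_and_introns",
    "simulate_all",
    "write_vcf",
]

#: transcription-order event designs; exon coordinates are offsets into the
#: gene locus (1-based closed).  Each design is (strand, isoform exon lists).
_EVENT_DESIGNS: dict[str, tuple[str, list[list[tuple[int, int]]]]] = {
    "SE": ("+", [[(1, 200), (301, 400), (501, 700)], [(1, 200), (501, 700)]]),
    "RI": ("+", [[(1, 200), (301, 500)], [(1, 500)]]),
    # minus strand: shared donor at 301 (exon start of tx-first exon),
    # alternative acceptors at 200 vs 120
    "A3": ("-", [[(1, 200), (301, 500)], [(1, 120), (301, 500)]]),
    "A5": ("+", [[(1, 200), (401, 600)], [(1, 280), (401, 600)]]),
    "AF": ("+", [[(1, 100), (401, 600)], [(201, 300), (401, 600)]]),
    # minus strand: alternative last (tx-order) exons are genomic-leftmost
    "AL": ("-", [[(301, 400), (501, 700)], [(101, 180), (501, 700)]]),
    "MX": (
        "+",
        [
            [(1, 200), (301, 400), (701, 900)],
            [(1, 200), (501, 600), (701, 900)],
        ],
    ),
}

_EVENT_ORDER = ["SE", "RI", "A3", "A5", "AF", "AL", "MX"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic atlas; defaults define the study conditions.

    ``specificity_fold`` is the expression contrast of planted
    tissue-restricted transcripts between their target tissue and all
    others; the default (1000x, i.e. off-target means below the 0.1 TPM
    detection floor) models transcripts that are genuinely silent outside
    their tissue.  ``beta_sqtl`` is the additive effect per alternate
    allele on the latent logit excision ratio, in units of the residual
    (noise) SD.
    """

    seed: int = 0
    n_genes: int = 30
    n_tissues: int = 8
    samples_per_tissue: int = 10
    n_specific_transcripts: int = 10
    specificity_fold: float = 1000.0
    specific_target_tpm: float = 50.0
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_sqtl: int = 5
    beta_sqtl: float = 1.0
    noise_sd: float = 1.0
    chrom_length: int = 2_000_000
    chrom: str = "chr1"
    # baseline TPM is log-normal: heavy-tailed like real transcript abundance
    meanlog: float = 1.0
    sdlog: float = 1.0
    # within-tissue sample-level biological noise on log TPM
    sample_sdlog: float = 0.25
    n_intron_clusters: int = 12
    cluster_depth: int = 200
    genotype_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.samples_per_tissue * self.n_tissues < 10:
            raise ValueError("need at least 10 samples in total")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.samples_per_tissue <= 0:
            raise ValueError("samples_per_tissue must be positive")
        if self.n_snps < self.n_causal_sqtl:
            raise ValueError("n_snps must be >= n_causal_sqtl")
        if self.specificity_fold <= 0 or self.noise_sd <= 0:
            raise ValueError("specificity_fold and noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.samples_per_tissue

    def sample_ids(self) -> list[str]:
        return [
            f"{t}_s{j}"
            for t in self.tissue_names()
            for j in range(self.samples_per_tissue)
        ]

    def tissue_names(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]


@dataclass
class GroundTruth:
    """Planted structure recoverable from the emitted files."""

    #: planted tissue-restricted transcript -> its target tissue
    specific_transcripts: dict[str, str] = field(default_factory=dict)
    #: planted uniformly-expressed transcripts (negative controls)
    uniform_transcripts: list[str] = field(default_factory=list)
    #: designed event gene -> its single planted event type
    event_inventory: dict[str, str] = field(default_factory=dict)
    #: planted assembled-transcript catalog labels
    catalog_truth: dict[str, str] = field(default_factory=dict)
    #: (snp_id, intron_id, beta) planted splicing QTLs
    causal_pairs: list[tuple[str, str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# annotation


def make_annotation(
    config: SimulationConfig,
    out_dir: Optional[str] = None,
    truth: Optional[GroundTruth] = None,
) -> tuple[list[TranscriptModel], list[TranscriptModel], GroundTruth]:
    """Build reference and assembled transcript catalogs.

    The first seven genes instantiate one splicing event type each (the
    planted event inventory); remaining genes get 1-3 isoforms built by
    skipping internal exons.  The assembled catalog mirrors every reference
    isoform under a new id and adds planted novel, intergenic, antisense
    and fusion transcripts.  Writes ``reference.gff3`` / ``assembled.gff3``
    into *out_dir* when given.
    """
    if config.n_genes < 7:
        raise ValueError("n_genes must be >= 7 to place all event designs")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = truth if truth is not None else GroundTruth()

    spacing = 20_000
    first_offset = 10_000
    needed = first_offset + (config.n_genes + 2) * spacing
    if config.chrom_length < needed:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small to place "
            f"{config.n_genes} genes (need >= {needed})"
        )

    reference: list[TranscriptModel] = []
    gene_strands: dict[str, str] = {}
    for gi in range(config.n_genes):
        gid = f"G{gi:04d}"
        offset = first_offset + gi * spacing
        if gi < 7:
            ev_type = _EVENT_ORDER[gi]
            strand, isoforms = _EVENT_DESIGNS[ev_type]
            truth.event_inventory[gid] = ev_type
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            isoforms = _random_isoforms(rng)
        gene_strands[gid] = strand
        for k, exons in enumerate(isoforms):
            reference.append(
                TranscriptModel(
                    transcript_id=f"{gid}.t{k + 1}",
                    chrom=config.chrom,
                    strand=strand,
                    exons=tuple((offset + s, offset + e) for s, e in exons),
                    gene_id=gid,
                    source="reference",
                )
            )

    assembled = _make_assembled(config, reference, gene_strands, truth, rng)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_gff3(reference, os.path.join(out_dir, "reference.gff3"))
        write_gff3(assembled, os.path.join(out_dir, "assembled.gff3"))
    return reference, assembled, truth


def _random_isoforms(rng: np.random.Generator) -> list[list[tuple[int, int]]]:
    """1-3 isoforms over a random 3-6 exon backbone; extra isoforms skip
    one internal exon (shared flanks), so every pair is a clean SE."""
    n_exons = int(rng.integers(3, 7))
    pos = 1
    backbone: list[tuple[int, int]] = []
    for _ in range(n_exons):
        exon_len = int(rng.integers(80, 300))
        backbone.append((pos, pos + exon_len - 1))
        pos += exon_len + int(rng.integers(100, 500))
    isoforms = [backbone]
    n_iso = int(rng.integers(1, 4))
    internal = list(range(1, n_exons - 1))
    rng.shuffle(internal)
    for skip_idx in internal[: n_iso - 1]:
        isoforms.append([e for j, e in enumerate(backbone) if j != skip_idx])
    return isoforms


def _make_assembled(
    config: SimulationConfig,
    reference: list[TranscriptModel],
    gene_strands: dict[str, str],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[TranscriptModel]:
    assembled: list[TranscriptModel] = []
    # every reference isoform reappears in the assembly under a new id
    for tx in reference:
        atx = dataclasses.replace(
            tx, transcript_id=f"A_{tx.transcript_id}", source="assembled"
        )
        assembled.append(atx)
        truth.catalog_truth[atx.transcript_id] = "reference_match"

    # planted novel isoform: first multi-exon gene transcript, first exon
    # truncated by 30 bp at the inner boundary -> shifted splice site
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in reference:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gid, txs in sorted(by_gene.items()):
        base = txs[0]
        if base.n_exons < 2:
            continue
        exons = list(base.exons)
        s0, e0 = exons[0]
        if e0 - 30 > s0:
            exons[0] = (s0, e0 - 30)
            ntx = TranscriptModel(
                transcript_id=f"A_{gid}.novel",
                chrom=base.chrom,
                strand=base.strand,
                exons=tuple(exons),
                gene_id=gid,
                source="assembled",
            )
            assembled.append(ntx)
            truth.catalog_truth[ntx.transcript_id] = "novel_in_gene"
            break

    gene_ids = sorted(by_gene)
    spacing = 20_000
    first_offset = 10_000

    # intergenic: parked in the gap beyond the last gene locus
    ig_start = first_offset + config.n_genes * spacing + 5_000
    ig = TranscriptModel(
        transcript_id="A_intergenic_1",
        chrom=config.chrom,
        strand="+",
        exons=((ig_start, ig_start + 300), (ig_start + 800, ig_start + 1_000)),
        gene_id=None,
        source="assembled",
    )
    assembled.append(ig)
    truth.catalog_truth[ig.transcript_id] = "intergenic"

    # antisense: inside gene 0's span on the opposite strand
    g0 = by_gene[gene_ids[0]][0]
    anti = TranscriptModel(
        transcript_id="A_antisense_1",
        chrom=config.chrom,
        strand="-" if g0.strand == "+" else "+",
        exons=((g0.span[0] + 10, g0.span[0] + 150),),
        gene_id=None,
        source="assembled",
    )
    assembled.append(anti)
    truth.catalog_truth[anti.transcript_id] = "antisense"

    # fusion: single exon chain spanning two consecutive same-strand genes
    fusion = None
    for a, b in zip(gene_ids, gene_ids[1:]):
        if gene_strands[a] == gene_strands[b]:
            sa = by_gene[a][0].span
            sb = by_gene[b][0].span
            fusion = TranscriptModel(
                transcript_id="A_fusion_1",
                chrom=config.chrom,
                strand=gene_strands[a],
                exons=((sa[0], sa[1]), (sb[0], sb[1])),
                gene_id=None,
                source="assembled",
            )
            break
    if fusion is not None:
        assembled.append(fusion)
        truth.catalog_truth[fusion.transcript_id] = "fusion"
    return assembled


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    transcripts: list[TranscriptModel],
    truth: Optional[GroundTruth] = None,
    out_dir: Optional[str] = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Multi-tissue log-normal TPM with planted tissue-restricted transcripts.

    Each transcript draws a log-normal baseline mean shared across tissues;
    sample values add log-normal biological noise.  Planted transcripts are
    set to ``specific_target_tpm`` in their target tissue and
    ``specific_target_tpm / specificity_fold`` elsewhere.  Per-transcript
    TPM is not renormalized across the matrix.
    """
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tids = [t.transcript_id for t in transcripts]
    if len(set(tids)) != len(tids):
        raise ValueError("duplicate transcript ids in catalog")

    gene_linked = [t.transcript_id for t in transcripts if t.gene_id is not None]
    n_spec = min(config.n_specific_transcripts, len(gene_linked))
    planted = sorted(rng.choice(gene_linked, size=n_spec, replace=False).tolist())
    tissues = config.tissue_names()
    for i, tid in enumerate(planted):
        truth.specific_transcripts[tid] = tissues[i % len(tissues)]
    truth.uniform_transcripts = [t for t in tids if t not in truth.specific_transcripts]

    samples = config.sample_ids()
    sample_tissue = {
        s: t for t in tissues for s in samples if s.startswith(t + "_")
    }
    base = rng.lognormal(config.meanlog, config.sdlog, size=len(tids))
    mean = np.tile(base[:, None], (1, len(samples)))
    tid_index = {t: i for i, t in enumerate(tids)}
    for tid, target in truth.specific_transcripts.items():
        if tid not in tid_index:
            raise ValueError(f"planted transcript {tid} not in catalog")
        row = tid_index[tid]
        off = config.specific_target_tpm / config.specificity_fold
        for j, s in enumerate(samples):
            mean[row, j] = (
                config.specific_target_tpm if sample_tissue[s] == target else off
            )
    noise = rng.lognormal(0.0, config.sample_sdlog, size=mean.shape)
    values = pd.DataFrame(mean * noise, index=pd.Index(tids, name="transcript_id"),
                          columns=samples)
    expr = ExpressionMatrix(values, sample_tissue)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        expr.to_tsv(
            os.path.join(out_dir, "tpm.tsv"), os.path.join(out_dir, "samples.tsv")
        )
    return expr, truth


# ---------------------------------------------------------------------------
# genotypes and intron counts


def simulate_genotypes_and_introns(
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
    out_dir: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Hardy-Weinberg genotypes plus intron split-read counts with planted
    additive splicing effects.

    Returns ``(genotypes, variant_info, intron_counts, truth)``:
    genotypes are SNP x sample dosages (0/1/2, -1 for missing), variant_info
    carries pos/ref/alt/FS/QD, intron_counts is introns x samples with ids
    ``chrom:start:end:cluster``.  Each intron cluster holds two introns
    sharing a donor; the excision ratio of the first follows
    ``logit(p) = logit(p0) + beta * dosage + N(0, noise_sd)`` and is
    realized as a binomial draw at ``cluster_depth`` reads.  Causal SNPs sit
    within 100 kb of their intron.  Writes ``snps.vcf`` and
    ``intron_counts.tsv`` when *out_dir* is given.
    """
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    samples = config.sample_ids()
    n = len(samples)
    if config.n_intron_clusters < config.n_causal_sqtl:
        raise ValueError("n_intron_clusters must be >= n_causal_sqtl")

    # cluster loci spread along the chromosome, two introns sharing a donor
    usable = config.chrom_length - 20_000
    cluster_pos = np.linspace(10_000, usable, config.n_intron_clusters).astype(int)
    intron_ids: list[str] = []
    intron_rows: list[tuple[int, int, str]] = []
    for ci, p in enumerate(cluster_pos):
        clu = f"clu_{ci + 1}"
        for s_, e_ in ((p, p + 400), (p, p + 800)):
            intron_ids.append(f"{config.chrom}:{s_}:{e_}:{clu}")
            intron_rows.append((s_, e_, clu))

    # SNP positions: causal ones near their cluster, the rest uniform
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    pos = np.sort(rng.integers(1, config.chrom_length, size=config.n_snps))
    causal_clusters = rng.choice(
        config.n_intron_clusters, size=config.n_causal_sqtl, replace=False
    )
    snp_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    causal_snp_idx = rng.choice(config.n_snps, size=config.n_causal_sqtl, replace=False)
    pos = pos.astype(np.int64)
    for k, (ci, sj) in enumerate(zip(causal_clusters, causal_snp_idx)):
        lo = max(1, int(cluster_pos[ci]) - 50_000)
        hi = min(config.chrom_length, int(cluster_pos[ci]) + 50_000)
        pos[sj] = int(rng.integers(lo, hi))
        maf[sj] = 0.3  # fixed moderate frequency keeps planted power stable

    # Hardy-Weinberg dosages
    u = rng.random(size=(config.n_snps, n))
    p_alt = maf[:, None]
    geno = np.where(
        u < (1 - p_alt) ** 2, 0, np.where(u < (1 - p_alt) ** 2 + 2 * p_alt * (1 - p_alt), 1, 2)
    ).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random(size=geno.shape) < config.genotype_missing_rate
        geno = np.where(miss, -1, geno)

    # latent excision ratio of the donor-proximal intron in each cluster
    beta_per_cluster = np.zeros(config.n_intron_clusters)
    for ci, sj in zip(causal_clusters, causal_snp_idx):
        beta_per_cluster[ci] = config.beta_sqtl * config.noise_sd
        truth.causal_pairs.append(
            (snp_ids[sj], intron_ids[2 * ci], config.beta_sqtl)
        )
    p0 = rng.uniform(0.3, 0.7, size=config.n_intron_clusters)
    counts = np.zeros((len(intron_ids), n), dtype=np.int64)
    causal_by_cluster = {ci: sj for ci, sj in zip(causal_clusters, causal_snp_idx)}
    for ci in range(config.n_intron_clusters):
        logit0 = np.log(p0[ci] / (1 - p0[ci]))
        eff = np.zeros(n)
        if ci in causal_by_cluster:
            g = geno[causal_by_cluster[ci]].astype(float)
            g[g < 0] = np.nan
            g = np.where(np.isnan(g), np.nanmean(g), g)
            eff = beta_per_cluster[ci] * g
        latent = logit0 + eff + rng.normal(0.0, config.noise_sd, size=n)
        p = 1.0 / (1.0 + np.exp(-latent))
        c1 = rng.binomial(config.cluster_depth, p)
        counts[2 * ci] = c1
        counts[2 * ci + 1] = config.cluster_depth - c1

    genotypes = pd.DataFrame(geno, index=pd.Index(snp_ids, name="snp_id"),
                             columns=samples)
    variant_info = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "FS": np.round(rng.uniform(0.0, 10.0, size=config.n_snps), 3),
            "QD": np.round(rng.uniform(10.0, 30.0, size=config.n_snps), 3),
        },
        index=genotypes.index,
    )
    intron_counts = pd.DataFrame(
        counts, index=pd.Index(intron_ids, name="intron_id"), columns=samples
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_vcf(genotypes, variant_info, os.path.join(out_dir, "snps.vcf"),
                  contig=config.chrom, contig_length=config.chrom_length)
        intron_counts.to_csv(
            os.path.join(out_dir, "intron_counts.tsv"), sep="\t",
            index_label="intron_id",
        )
    return genotypes, variant_info, intron_counts, truth


def write_vcf(
    genotypes: pd.DataFrame,
    variant_info: pd.DataFrame,
    path: str,
    contig: str = "chr1",
    contig_length: int = 2_000_000,
) -> None:
    """Emit a minimal VCF v4.2 (GT format; FS/QD INFO) from dosage rows."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.columns)
            + "\n"
        )
        for snp_id, row in genotypes.iterrows():
            info = variant_info.loc[snp_id]
            gts = "\t".join(gt_code[int(v)] for v in row.to_numpy())
            fh.write(
                f"{info['chrom']}\t{int(info['pos'])}\t{snp_id}\t{info['ref']}\t"
                f"{info['alt']}\t.\tPASS\tFS={info['FS']};QD={info['QD']}\tGT\t{gts}\n"
            )


def simulate_all(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> dict:
    """Run all three generators under one seed; returns a dict bundle."""
    truth = GroundTruth()
    reference, assembled, truth = make_annotation(config, out_dir, truth)
    expr, truth = simulate_expression(config, assembled, truth, out_dir)
    genotypes, variant_info, intron_counts, truth = simulate_genotypes_and_introns(
        config, truth, out_dir
    )
    return {
        "reference": reference,
        "assembled": assembled,
        "expression": expr,
        "genotypes": genotypes,
        "variant_info": variant_info,
        "intron_counts": intron_counts,
        "truth": truth,
    }
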