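"""Synthetic maternal-transcriptome cohort generator.

Emulates the statistical structure of an oocyte-maturation expression
study: a GV (germinal vesicle) transcriptome, a GV->MII degradation wave
that removes ~20% of total RNA while leaving per-gene dosage relatively
stabilized / destabilized / unchanged, and a maternal conditional
knockout (mCKO) of an m6A reader in which motif-bearing target genes
fail to be degraded at MII. Target transcripts carry the reader's
binding motif planted at stop-codon-proximal positions, and m6A peak
intervals are concentrated near target stop codons, so the positional
motif profile and the metagene peak profile downstream have a known
planted signal.

Every draw is taken from a generator seeded from ``cfg.seed`` alone, so
identical configs give byte-identical fixtures.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import MATURATION_CLASSES, SyntheticConfig
from .records import (
    ExpressionStudy,
    GeneModel,
    PeakInterval,
    SimulatedCohort,
    TranscriptRecord,
)

_RNA = np.frombuffer(b"ACGU", dtype="S1")
_STOPS = ("UAA", "UAG", "UGA")
_CONTIG_OFFSET = 1000  # genomic slack left of each single-exon gene

# independent deterministic streams per stage, all derived from cfg.seed
_STREAM_TRUTH, _STREAM_SEQ, _STREAM_EXPR, _STREAM_PEAKS = range(4)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def parse_pattern(pattern: str) -> list[str]:
    """Split an RNA pattern like ``GAC[UA]`` into per-position choice sets."""
    tokens: list[str] = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            tokens.append(pattern[i + 1 : j])
            i = j + 1
        else:
            tokens.append(pattern[i])
            i += 1
    return tokens


def assign_truth(cfg: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth labels: maturation class and knockout-target flag.

    Class counts are fixed by largest remainder so the cohort composition
    matches ``class_fractions`` exactly; targets are drawn from the
    destabilized + unchanged pool (the knockout stabilizes transcripts
    that would otherwise be degraded or turned over normally).
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_TRUTH)
    n = cfg.n_genes
    fracs = [cfg.class_fractions[c] for c in MATURATION_CLASSES]
    counts = [int(math.floor(f * n)) for f in fracs]
    remainders = [f * n - c for f, c in zip(fracs, counts)]
    for i in np.argsort(remainders)[::-1][: n - sum(counts)]:
        counts[int(i)] += 1
    labels = np.repeat(MATURATION_CLASSES, counts)
    labels = labels[rng.permutation(n)]

    gene_ids = [f"G{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {"maturation_class": labels, "is_ko_target": False}, index=gene_ids
    )
    truth.index.name = "gene_id"

    pool = truth.index[truth["maturation_class"] != "stabilized"]
    n_targets = int(round(cfg.ko_target_fraction * len(pool)))
    if n_targets:
        chosen = rng.choice(len(pool), size=n_targets, replace=False)
        truth.loc[pool[np.sort(chosen)], "is_ko_target"] = True
    return truth


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _RNA[rng.integers(0, 4, size=n)]


def _concretize(tokens: list[str], rng: np.random.Generator) -> bytes:
    return "".join(t if len(t) == 1 else t[rng.integers(len(t))] for t in tokens).encode()


def _plant_positions(
    rng: np.random.Generator,
    n_sites: int,
    lo: int,
    hi: int,
    codon_starts: tuple[int, ...],
    plen: int,
    *,
    centered_at: float | None,
    sd: float,
) -> list[int]:
    """Sample non-overlapping plant positions in [lo, hi], avoiding codons."""
    if n_sites <= 0 or hi < lo:
        return []
    if centered_at is None:
        raw = rng.integers(lo, hi + 1, size=n_sites)
    else:
        raw = np.rint(rng.normal(centered_at, sd, size=n_sites)).astype(int)
        raw = np.clip(raw, lo, hi)
    keep: list[int] = []
    for p in sorted(int(x) for x in raw):
        # never disturb the start/stop codons the record invariants promise
        if any(c - plen < p <= c + 2 for c in codon_starts):
            continue
        if keep and p - keep[-1] < plen:  # keep plants intact: no overlap
            continue
        keep.append(p)
    return keep


def generate_transcripts(
    cfg: SyntheticConfig, truth: pd.DataFrame | None = None
) -> tuple[list[TranscriptRecord], list[GeneModel], dict[str, list[int]]]:
    """Generate transcript sequences and single-exon gene models.

    Returns ``(records, models, planted)`` where ``planted`` maps
    transcript_id to the sorted motif start offsets written into the
    sequence. Knockout targets receive ``Poisson(target_motif_rate)``
    plants at ``Normal(stop_start, motif_position_sd)`` clipped to the
    stop-codon window; other transcripts receive
    ``Poisson(background_motif_rate)`` plants uniform over the sequence.
    """
    cfg.validate()
    if truth is None:
        truth = assign_truth(cfg)
    rng = _rng(cfg, _STREAM_SEQ)
    tokens = parse_pattern(cfg.motif_pattern)
    plen = len(tokens)

    records: list[TranscriptRecord] = []
    models: list[GeneModel] = []
    planted: dict[str, list[int]] = {}
    for gene_id, row in truth.iterrows():
        utr5 = int(rng.integers(30, 300))
        cds_len = 3 * int(rng.integers(100, 501))
        # 3'UTR length spread so a sizeable fraction is shorter than the
        # default 400-nt flank and exercises N-padding downstream
        utr3 = int(np.clip(round(rng.exponential(450.0)), 20, 1500))
        length = utr5 + cds_len + utr3
        seq = _random_seq(rng, length)
        cds_start = utr5
        stop_start = utr5 + cds_len - 3
        seq[cds_start : cds_start + 3] = np.frombuffer(b"AUG", dtype="S1")
        stop = _STOPS[rng.integers(3)]
        seq[stop_start : stop_start + 3] = np.frombuffer(stop.encode(), dtype="S1")

        if row["is_ko_target"]:
            n_sites = rng.poisson(cfg.target_motif_rate)
            lo = max(0, stop_start - cfg.flank_len)
            hi = min(length - plen, stop_start + cfg.flank_len - plen)
            sites = _plant_positions(
                rng, n_sites, lo, hi, (cds_start, stop_start), plen,
                centered_at=stop_start, sd=cfg.motif_position_sd,
            )
        else:
            n_sites = rng.poisson(cfg.background_motif_rate)
            sites = _plant_positions(
                rng, n_sites, 0, length - plen, (cds_start, stop_start), plen,
                centered_at=None, sd=0.0,
            )
        for p in sites:
            seq[p : p + plen] = np.frombuffer(_concretize(tokens, rng), dtype="S1")

        tid = f"T{gene_id[1:]}"
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=str(gene_id),
            sequence=seq.tobytes().decode(),
            cds_start=cds_start,
            stop_start=stop_start,
        )
        rec.validate()
        records.append(rec)
        planted[tid] = sites
        model = GeneModel(
            gene_id=str(gene_id),
            contig=f"ctg_{gene_id}",
            strand="+",
            exons=[(_CONTIG_OFFSET, _CONTIG_OFFSET + length)],
            start_codon_pos=_CONTIG_OFFSET + cds_start,
            stop_codon_pos=_CONTIG_OFFSET + stop_start,
        )
        model.validate()
        models.append(model)
    return records, models, planted


def generate_expression(
    cfg: SyntheticConfig, genes: pd.DataFrame | None = None
) -> ExpressionStudy:
    """Generate the log2 expression study for GV/MII x CTL/mCKO.

    Per gene: GV log2 abundance ~ Normal(gv_mean_log2, gv_sd_log2);
    MII control = GV + log2(class retention x mean-one lognormal jitter);
    MII knockout adds log2(ko_retention_boost) for target genes only; GV
    is unaffected by genotype (the knockout transcriptome is normal
    before maturation). Independent Normal(0, noise_sd_log2) replicate
    noise is added to every sample value. The jitter is mean-one on the
    linear scale, so the expected total linear MII/GV mass ratio equals
    sum(fraction * retention) exactly (0.7996 at defaults, i.e. a ~20%
    degradation wave).
    """
    cfg.validate()
    if genes is None:
        genes = assign_truth(cfg)
    rng = _rng(cfg, _STREAM_EXPR)
    n = len(genes)

    gv = rng.normal(cfg.gv_mean_log2, cfg.gv_sd_log2, size=n)
    retention = np.array(
        [cfg.class_retention_means[c] for c in genes["maturation_class"]]
    )
    sd = cfg.retention_sd_log2
    jitter_mean = -(sd**2) * math.log(2.0) / 2.0  # mean-one on linear scale
    jitter = rng.normal(jitter_mean, sd, size=n) if sd > 0 else np.zeros(n)
    mii_ctl = gv + np.log2(retention) + jitter
    boost = np.where(genes["is_ko_target"], math.log2(cfg.ko_retention_boost), 0.0)
    base = {
        ("GV", "CTL"): gv,
        ("GV", "mCKO"): gv,
        ("MII", "CTL"): mii_ctl,
        ("MII", "mCKO"): mii_ctl + boost,
    }

    columns, meta, data = [], [], []
    for stage in ("GV", "MII"):
        for genotype in ("CTL", "mCKO"):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{stage}_{genotype}_{rep}"
                columns.append(sid)
                meta.append({"stage": stage, "genotype": genotype, "replicate": rep})
                noise = (
                    rng.normal(0.0, cfg.noise_sd_log2, size=n)
                    if cfg.noise_sd_log2 > 0
                    else np.zeros(n)
                )
                data.append(base[(stage, genotype)] + noise)

    matrix = pd.DataFrame(np.column_stack(data), index=genes.index, columns=columns)
    matrix.index.name = "gene_id"
    samples = pd.DataFrame(meta, index=pd.Index(columns, name="sample_id"))
    study = ExpressionStudy(matrix=matrix, samples=samples, truth=genes.copy())
    study.validate()
    return study


def generate_peaks(
    cfg: SyntheticConfig,
    models: list[GeneModel],
    targets: "set[str] | pd.DataFrame",
) -> list[PeakInterval]:
    """Simulate m6A peak calls from ``n_peak_samples`` public samples.

    Each sample gives every target gene one peak of width ``peak_width``
    centered Normal(stop_codon_pos, peak_position_sd) with a high
    enrichment score, plus Poisson(background_peak_rate) low-score
    background peaks uniform over each contig.
    """
    cfg.validate()
    if isinstance(targets, pd.DataFrame):
        targets = set(targets.index[targets["is_ko_target"]])
    rng = _rng(cfg, _STREAM_PEAKS)
    peaks: list[PeakInterval] = []
    w = cfg.peak_width
    for s in range(1, cfg.n_peak_samples + 1):
        sid = f"m6a_{s:02d}"
        for m in models:
            contig_len = m.exons[-1][1] + _CONTIG_OFFSET
            if m.gene_id in targets:
                center = int(round(rng.normal(m.stop_codon_pos, cfg.peak_position_sd)))
                start = int(np.clip(center - w // 2, 0, contig_len - w))
                peaks.append(
                    PeakInterval(m.contig, start, start + w,
                                 float(rng.uniform(4.0, 10.0)), sid)
                )
            for _ in range(rng.poisson(cfg.background_peak_rate)):
                start = int(rng.integers(0, max(1, contig_len - w)))
                peaks.append(
                    PeakInterval(m.contig, start, start + w,
                                 float(rng.uniform(0.5, 3.0)), sid)
                )
    for p in peaks:
        p.validate()
    return peaks


def simulate_cohort(cfg: SyntheticConfig) -> SimulatedCohort:
    """Run all generator stages with consistent truth labels."""
    truth = assign_truth(cfg)
    records, models, planted = generate_transcripts(cfg, truth)
    study = generate_expression(cfg, truth)
    peaks = generate_peaks(cfg, models, truth)
    return SimulatedCohort(
        transcripts=records, models=models, study=study, peaks=peaks, planted=planted
    )
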