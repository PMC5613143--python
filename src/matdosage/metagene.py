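"""Scale-regions metagene profiling of m6A peak occupancy.

Peak calls from multiple samples are merged into one disjoint-interval
occupancy track per contig. Each gene body (start codon to stop codon)
is rescaled to a fixed number of bins with fixed-width flank bins either
side, giving a genes x bins occupancy matrix whose group means are the
metagene profiles; occupancy is the covered-base fraction per bin by
default ("prevalence"), or the coverage-weighted mean enrichment score.
Group differences over a bin region (default: the downstream flank
block, i.e. the 400 nt after the stop codon) are tested with a Welch
two-sample t-test on per-gene mean occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import GeneModel, PeakInterval

logger = logging.getLogger(__name__)


def read_peaks_bed(path) -> list[PeakInterval]:
    """Parse a BED file (>= 5 columns) of scored peaks.

    0-based half-open coordinates; the name column is kept as the
    sample id. Malformed lines raise with their line number.
    """
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 5 BED columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            peaks.append(PeakInterval(fields[0], start, end, score, fields[3]))
    if not peaks:
        logger.warning("no peaks parsed from %s", path)
    return peaks


def write_peaks_bed(peaks: list[PeakInterval], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.sample_id}\t{p.score!r}\t+\n"
            )


@dataclass
class OccupancyTrack:
    """Disjoint sorted scored intervals per contig."""

    intervals: dict[str, list[tuple[int, int, float]]]

    def to_peaks(self, sample_id: str = "condensed") -> list[PeakInterval]:
        return [
            PeakInterval(ctg, s, e, score, sample_id)
            for ctg, ivals in sorted(self.intervals.items())
            for s, e, score in ivals
        ]

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def condense_samples(
    peak_lists: "list[PeakInterval] | list[list[PeakInterval]]",
    min_score: float | None = None,
    merge_score: str = "max",
) -> OccupancyTrack:
    """Merge peaks across samples into a disjoint occupancy track.

    Overlapping intervals are merged per contig; the merged score is the
    max of contributing scores by default (``merge_score`` may also be
    'mean' or 'count'). An optional minimum-score filter is applied
    before merging. Condensing an already-condensed track is a no-op.
    """
    if merge_score not in ("max", "mean", "count"):
        raise ValueError("merge_score must be 'max', 'mean' or 'count'")
    flat: list[PeakInterval] = []
    for item in peak_lists:
        if isinstance(item, PeakInterval):
            flat.append(item)
        else:
            flat.extend(item)
    if min_score is not None:
        flat = [p for p in flat if p.score >= min_score]

    by_contig: dict[str, list[PeakInterval]] = {}
    for p in flat:
        by_contig.setdefault(p.contig, []).append(p)

    out: dict[str, list[tuple[int, int, float]]] = {}
    for contig, plist in sorted(by_contig.items()):
        plist.sort(key=lambda p: (p.start, p.end))
        merged: list[tuple[int, int, list[float]]] = []
        for p in plist:
            if merged and p.start < merged[-1][1]:
                s, e, scores = merged[-1]
                merged[-1] = (s, max(e, p.end), scores + [p.score])
            else:
                merged.append((p.start, p.end, [p.score]))
        combine = {
            "max": max,
            "mean": lambda xs: sum(xs) / len(xs),
            "count": len,
        }[merge_score]
        out[contig] = [(s, e, float(combine(scores))) for s, e, scores in merged]
    return OccupancyTrack(intervals=out)


@dataclass
class MetageneMatrix:
    """Genes x (flank + scaled-body + flank) occupancy bins, 5'->3'."""

    values: pd.DataFrame
    body_bins: int
    flank_nt: int
    flank_bin_nt: int
    mode: str

    @property
    def n_flank_bins(self) -> int:
        return self.flank_nt // self.flank_bin_nt

    @property
    def upstream_columns(self) -> list[str]:
        return list(self.values.columns[: self.n_flank_bins])

    @property
    def body_columns(self) -> list[str]:
        f = self.n_flank_bins
        return list(self.values.columns[f : f + self.body_bins])

    @property
    def downstream_columns(self) -> list[str]:
        return list(self.values.columns[self.n_flank_bins + self.body_bins :])


def _per_base(
    track: OccupancyTrack, contig: str, span: tuple[int, int], mode: str
) -> np.ndarray:
    lo, hi = span
    arr = np.zeros(hi - lo, dtype=float)
    for s, e, score in track.intervals.get(contig, []):
        a, b = max(s, lo), min(e, hi)
        if a < b:
            arr[a - lo : b - lo] = 1.0 if mode == "binary" else score
    return arr


def _bin_means(arr: np.ndarray, n_bins: int) -> np.ndarray:
    width = arr.size // n_bins
    edges = [i * width for i in range(n_bins)] + [arr.size]  # last bin absorbs remainder
    return np.array([arr[edges[i] : edges[i + 1]].mean() for i in range(n_bins)])


def metagene_matrix(
    models: list[GeneModel],
    track: OccupancyTrack,
    body_bins: int = 100,
    flank_nt: int = 400,
    flank_bin_nt: int = 10,
    mode: str = "binary",
) -> MetageneMatrix:
    """Scale-regions occupancy matrix over gene bodies with fixed flanks.

    The body (start codon through the base before the stop codon) is
    split into ``body_bins`` equal-width bins (the last absorbs the
    remainder); each flank is ``flank_nt`` nt in fixed ``flank_bin_nt``
    bins. Minus-strand genes are reversed so columns always run 5'->3'.
    Genes with a body shorter than ``body_bins`` are skipped.
    """
    if mode not in ("binary", "score"):
        raise ValueError("mode must be 'binary' or 'score'")
    if flank_nt % flank_bin_nt:
        raise ValueError("flank_nt must be a multiple of flank_bin_nt")
    n_flank = flank_nt // flank_bin_nt

    rows, index = [], []
    skipped = 0
    for m in models:
        if m.strand == "+":
            body_span = (m.start_codon_pos, m.stop_codon_pos)
            span = (body_span[0] - flank_nt, body_span[1] + flank_nt)
        else:
            # codon positions are the lowest genomic base of each codon
            body_span = (m.stop_codon_pos + 3, m.start_codon_pos + 3)
            span = (body_span[0] - flank_nt, body_span[1] + flank_nt)
        body_len = body_span[1] - body_span[0]
        if body_len < body_bins:
            skipped += 1
            logger.warning(
                "skipping %s: body %d nt shorter than %d bins",
                m.gene_id, body_len, body_bins,
            )
            continue
        arr = _per_base(track, m.contig, span, mode)
        if m.strand == "-":
            arr = arr[::-1]
        upstream = arr[:flank_nt].reshape(n_flank, flank_bin_nt).mean(axis=1)
        body = _bin_means(arr[flank_nt : flank_nt + body_len], body_bins)
        downstream = arr[flank_nt + body_len :].reshape(n_flank, flank_bin_nt).mean(axis=1)
        rows.append(np.concatenate([upstream, body, downstream]))
        index.append(m.gene_id)
    if skipped:
        logger.warning("%d gene(s) skipped for short bodies", skipped)

    columns = (
        [f"up{i:03d}" for i in range(n_flank)]
        + [f"body{i:03d}" for i in range(body_bins)]
        + [f"down{i:03d}" for i in range(n_flank)]
    )
    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(columns))),
        index=pd.Index(index, name="gene_id"),
        columns=columns,
    )
    return MetageneMatrix(
        values=values,
        body_bins=body_bins,
        flank_nt=flank_nt,
        flank_bin_nt=flank_bin_nt,
        mode=mode,
    )


def group_profiles(
    mm: MetageneMatrix, gene_sets: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Column-wise mean and sd of the occupancy matrix per gene set."""
    out: dict[str, pd.DataFrame] = {}
    for name, genes in gene_sets.items():
        if len(genes) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in genes if g in mm.values.index]
        if len(present) < len(genes):
            logger.warning(
                "set %s: %d gene(s) absent from the metagene matrix",
                name, len(genes) - len(present),
            )
        if not present:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        sub = mm.values.loc[present]
        out[name] = pd.DataFrame(
            {"mean": sub.mean(axis=0), "sd": sub.std(axis=0, ddof=1)}
        )
        out[name].attrs["n_genes"] = len(present)
    return out


@dataclass
class RegionTTest:
    t: float
    df: float
    p_value: float
    region: list[str]
    n_A: int
    n_B: int


def stop_region_ttest(
    mm: MetageneMatrix,
    set_a: list[str],
    set_b: list[str],
    region_bins: list[str] | None = None,
    equal_var: bool = False,
) -> RegionTTest:
    """Two-sample t-test on per-gene mean occupancy over a bin region.

    The default region is the downstream-flank block (the 400 nt after
    the stop codon); the default test is Welch's (unequal variances).
    """
    if region_bins is None:
        region_bins = mm.downstream_columns
    if not region_bins:
        raise ValueError("empty bin region")
    a = [g for g in set_a if g in mm.values.index]
    b = [g for g in set_b if g in mm.values.index]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 genes per set in the matrix (got {len(a)} and {len(b)})"
        )
    xa = mm.values.loc[a, region_bins].mean(axis=1).to_numpy()
    xb = mm.values.loc[b, region_bins].mean(axis=1).to_numpy()
    res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return RegionTTest(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        region=list(region_bins),
        n_A=len(a),
        n_B=len(b),
    )
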