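"""Read-count quantification for DIP-seq style enrichment data.

Coverage tracks are normalised to reads per million mapped (RPM) and the
matched input library is subtracted bin-wise; negative net values are kept
(no clamping), since all downstream uses are ranking or averaging. Coverage
uses per-bin overlap counting (a read spanning k bins contributes to each),
whereas every count statistic (feature distribution, promoter scores,
probe-window counts) assigns each read once, by its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, promoter_window

__all__ = [
    "AlignedReadSet",
    "BinnedCoverage",
    "MetageneProfile",
    "FeatureDistribution",
    "normalized_coverage",
    "input_subtract",
    "tss_metagene",
    "feature_distribution",
    "count_reads_in_probe_windows",
    "read_bed_reads",
    "write_bed_reads",
]


@dataclass
class AlignedReadSet:
    """Aligned reads of one sequencing sample.

    ``reads`` holds chrom/start/end (0-based half-open). ``total_mapped`` may
    exceed the number of stored reads when a filtered subset is kept.
    """

    sample_id: str
    reads: pd.DataFrame
    total_mapped: int = -1

    def __post_init__(self) -> None:
        if self.total_mapped < 0:
            self.total_mapped = len(self.reads)
        if self.total_mapped < len(self.reads):
            raise ValueError("total_mapped smaller than stored read count")

    def midpoints(self, chrom: str) -> np.ndarray:
        sub = self.reads[self.reads["chrom"] == chrom]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)


@dataclass
class BinnedCoverage:
    """Per-chromosome binned coverage vectors (RPM scale; may be negative
    after input subtraction)."""

    bin_size: int
    data: dict[str, np.ndarray]

    def same_grid(self, other: "BinnedCoverage") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )


@dataclass
class MetageneProfile:
    positions: np.ndarray  # bp offsets of bin starts relative to the TSS
    mean_coverage: np.ndarray
    n_genes: int


@dataclass
class FeatureDistribution:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, Fraction]:
        """Exact rational fractions summing to 1."""
        t = self.total
        return {k: Fraction(v, t) for k, v in self.counts.items()}


def normalized_coverage(
    reads: AlignedReadSet, bin_size: int, chrom_lengths: dict[str, int]
) -> BinnedCoverage:
    """RPM-normalised binned coverage with per-bin overlap counting."""
    if reads.total_mapped <= 0:
        raise ValueError("total_mapped must be > 0 for RPM normalisation")
    scale = 1e6 / reads.total_mapped
    data: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        n_bins = -(-L // bin_size)
        sub = reads.reads[reads.reads["chrom"] == chrom]
        diff = np.zeros(n_bins + 1)
        if len(sub):
            start = np.clip(sub["start"].to_numpy(), 0, L - 1)
            end = np.clip(sub["end"].to_numpy(), 1, L)
            first = start // bin_size
            last = (end - 1) // bin_size
            np.add.at(diff, first, 1.0)
            np.add.at(diff, last + 1, -1.0)
        data[chrom] = np.cumsum(diff[:-1]) * scale
    return BinnedCoverage(bin_size=bin_size, data=data)


def input_subtract(ip: BinnedCoverage, input_: BinnedCoverage) -> BinnedCoverage:
    """Element-wise IP minus input; negatives retained."""
    if not ip.same_grid(input_):
        raise ValueError("coverage grids do not match")
    return BinnedCoverage(
        bin_size=ip.bin_size,
        data={c: ip.data[c] - input_.data[c] for c in ip.data},
    )


def tss_metagene(
    net: BinnedCoverage, genes: list[GeneModel], flank: int
) -> MetageneProfile:
    """Mean strand-oriented coverage in [TSS - flank, TSS + flank).

    Genes whose window would be truncated by a chromosome edge are excluded.
    """
    bs = net.bin_size
    if flank % bs:
        raise ValueError("flank must be a multiple of bin_size")
    nb = 2 * flank // bs
    rows = []
    for g in genes:
        vec = net.data.get(g.interval.chrom)
        if vec is None:
            continue
        b0 = g.tss // bs - flank // bs
        if b0 < 0 or b0 + nb > len(vec):
            continue
        w = vec[b0 : b0 + nb]
        rows.append(w[::-1] if g.strand == "-" else w)
    if not rows:
        raise ValueError("no gene windows fully inside chromosome bounds")
    mat = np.vstack(rows)
    positions = np.arange(-flank, flank, bs)
    return MetageneProfile(positions=positions, mean_coverage=mat.mean(axis=0), n_genes=len(rows))


def _merged_membership(intervals: list[tuple[int, int]]):
    """Merge intervals; return (starts, ends) arrays for membership queries."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    iv = sorted(intervals)
    starts, ends = [iv[0][0]], [iv[0][1]]
    for s, e in iv[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(points), dtype=bool)
    res[ok] = points[ok] < ends[idx[ok]]
    return res


def feature_distribution(
    reads: AlignedReadSet,
    genes: list[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
) -> FeatureDistribution:
    """Midpoint-assigned read fractions over promoter / gene body / intergenic.

    Promoters are TSS -1 kb/+0.5 kb strand-aware windows; gene bodies span
    TSS..TTS; assignment precedence is promoter > gene body > intergenic.
    """
    if len(reads.reads) == 0:
        raise ValueError("empty read set")
    prom: dict[str, list[tuple[int, int]]] = {}
    body: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        w = promoter_window(g, promoter_upstream, promoter_downstream)
        prom.setdefault(g.interval.chrom, []).append((w.start, w.end))
        body.setdefault(g.interval.chrom, []).append(
            (min(g.tss, g.tts), max(g.tss, g.tts))
        )
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    for chrom in reads.reads["chrom"].unique():
        mids = reads.midpoints(chrom)
        ps, pe = _merged_membership(prom.get(chrom, []))
        bs_, be = _merged_membership(body.get(chrom, []))
        in_p = _in_intervals(mids, ps, pe)
        in_b = _in_intervals(mids, bs_, be) & ~in_p
        counts["promoter"] += int(in_p.sum())
        counts["gene_body"] += int(in_b.sum())
        counts["intergenic"] += int((~in_p & ~in_b).sum())
    return FeatureDistribution(counts=counts)


def count_reads_in_probe_windows(
    read_sets: list[AlignedReadSet] | AlignedReadSet,
    probes: pd.DataFrame,
    window: int = 200,
    combine: str = "mean_rpm",
) -> pd.DataFrame:
    """Count read midpoints in [pos - window/2, pos + window/2) per probe.

    ``probes`` needs ``probe_id``, ``chrom``, ``pos`` columns. With several
    samples the per-sample counts are RPM-scaled then averaged
    (``combine='mean_rpm'``) or simply summed raw (``combine='pooled'``).
    Returns columns probe_id, count (raw pooled) and rpm_mean.
    """
    if window % 2:
        raise ValueError("window must be even")
    if isinstance(read_sets, AlignedReadSet):
        read_sets = [read_sets]
    if combine not in ("mean_rpm", "pooled"):
        raise ValueError(f"unknown combine rule {combine!r}")
    half = window // 2
    pos = probes["pos"].to_numpy()
    raw = np.zeros(len(probes), dtype=np.int64)
    rpm = np.zeros(len(probes))
    for rs in read_sets:
        scale = 1e6 / rs.total_mapped if rs.total_mapped > 0 else 0.0
        for chrom in probes["chrom"].unique():
            sel = (probes["chrom"] == chrom).to_numpy()
            mids = np.sort(rs.midpoints(chrom))
            lo = np.searchsorted(mids, pos[sel] - half, side="left")
            hi = np.searchsorted(mids, pos[sel] + half, side="left")
            c = hi - lo
            raw[sel] += c
            rpm[sel] += c * scale
    rpm_mean = rpm / len(read_sets)
    return pd.DataFrame(
        {"probe_id": probes["probe_id"].to_numpy(), "count": raw, "rpm_mean": rpm_mean}
    )


# ---------------------------------------------------------------------------
# I/O


def read_bed_reads(path, sample_id: str | None = None, total_mapped: int = -1) -> AlignedReadSet:
    """BED6 reader for read intervals (name/score columns ignored)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={0: str},
    )
    return AlignedReadSet(
        sample_id=sample_id or str(path), reads=df, total_mapped=total_mapped
    )


def write_bed_reads(reads: AlignedReadSet, path) -> None:
    df = reads.reads.copy()
    df["name"] = "read"
    df["score"] = 0
    df["strand"] = "+"
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(cov: BinnedCoverage, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov.data):
            vec = cov.data[chrom]
            for i, v in enumerate(vec):
                if v != 0:
                    fh.write(
                        f"{chrom}\t{i * cov.bin_size}\t{(i + 1) * cov.bin_size}\t{v:.6g}\n"
                    )
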