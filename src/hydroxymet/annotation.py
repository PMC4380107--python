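"""Genomic coordinates, gene models, CpG islands and promoter CpG classes.

All internal coordinates are 0-based half-open (BED convention). Array-manifest
positions are 1-based on disk and converted on read/write.

Promoter CpG-content classes follow the three-class windowed rule widely used
for mammalian promoters: a promoter is HCP (high CpG) when some 500 bp window
in its context reaches GC >= 0.55 and CpG observed/expected >= 0.75, LCP (low)
when no window reaches observed/expected 0.48, and ICP (intermediate)
otherwise. CpG islands are called with the Gardiner-Garden criteria
(>= 200 bp, GC >= 0.50, obs/exp CpG >= 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CpGIsland",
    "find_cpg_islands",
    "classify_promoter_cpg_content",
    "promoter_window",
    "assign_probes_to_promoters",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_manifest",
    "write_manifest",
]

MAX_PROBE_TSS_DISTANCE = 1499  # inclusive bound on |probe - TSS|


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Single-TSS gene model.

    The TSS/TTS are boundary coordinates of the gene interval: for a + strand
    gene tss == start and tts == end; for a - strand gene tss == end and
    tts == start, so in genome coordinates tss > tts on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_cpg: float


def _base_counts(seq: str):
    """Cumulative C, G and CpG counts for O(1) window queries.

    Returns arrays of length len(seq)+1; N (or any non-ACGT) counts as
    nothing and never forms a CpG.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    return cum(is_c), cum(is_g), cum(is_cpg)


def _window_stats(cc, cg, ccpg, start: int, end: int):
    """(gc_fraction, obs_exp_cpg) of seq[start:end]; CpGs straddling the right
    edge are excluded. Zero C or G count gives obs/exp = 0 by convention."""
    length = end - start
    n_c = int(cc[end] - cc[start])
    n_g = int(cg[end] - cg[start])
    n_cpg = int(ccpg[end - 1] - ccpg[start]) if length > 1 else 0
    gc = (n_c + n_g) / length
    oe = (n_cpg * length) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    sequence: str,
    chrom: str = "chr",
    window: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
) -> list[CpGIsland]:
    """Call CpG islands by the Gardiner-Garden sliding-window criteria.

    Every ``window``-bp window (step 1) with GC >= ``min_gc`` and CpG
    obs/exp >= ``min_obs_exp`` is marked; overlapping or adjacent passing
    windows are merged into maximal islands whose summary statistics are
    recomputed over the merged span.
    """
    L = len(sequence)
    if L < window:
        return []
    cc, cg, ccpg = _base_counts(sequence)
    length = window
    n_c = cc[length:] - cc[:-length]
    n_g = cg[length:] - cg[:-length]
    n_cpg = ccpg[length - 1 : L] - ccpg[: L - length + 1]
    gc_ok = (n_c + n_g) >= min_gc * length
    denom = n_c * n_g
    oe_ok = (denom > 0) & (n_cpg * length >= min_obs_exp * denom)
    passing = np.flatnonzero(gc_ok & oe_ok)
    if passing.size == 0:
        return []
    # merge windows [i, i+window) whose start runs are within `window` of each
    # other (overlapping or bookended)
    islands: list[CpGIsland] = []
    breaks = np.flatnonzero(np.diff(passing) > window)
    run_bounds = []
    s = passing[0]
    for b in breaks:
        run_bounds.append((s, passing[b]))
        s = passing[b + 1]
    run_bounds.append((s, passing[-1]))
    for first, last in run_bounds:
        start, end = int(first), int(last) + window
        gc, oe = _window_stats(cc, cg, ccpg, start, end)
        islands.append(
            CpGIsland(GenomicInterval(chrom, start, end), gc_fraction=gc, obs_exp_cpg=oe)
        )
    return islands


def classify_promoter_cpg_content(
    sequence: str,
    window: int = 500,
    step: int = 5,
    hcp_gc: float = 0.55,
    hcp_obs_exp: float = 0.75,
    lcp_obs_exp: float = 0.48,
) -> str:
    """Three-class promoter CpG content call ('HCP' | 'ICP' | 'LCP').

    ``sequence`` is the promoter context (by default generated for
    TSS -1300..+500); all ``window``-bp windows at ``step``-bp offsets are
    scanned, including a final window flush with the 3' end.
    """
    L = len(sequence)
    if L < window:
        raise ValueError(f"promoter sequence ({L} bp) shorter than {window} bp window")
    cc, cg, ccpg = _base_counts(sequence)
    starts = list(range(0, L - window + 1, step))
    if starts[-1] != L - window:
        starts.append(L - window)
    any_hcp = False
    any_mid = False
    for s in starts:
        gc, oe = _window_stats(cc, cg, ccpg, s, s + window)
        if gc >= hcp_gc and oe >= hcp_obs_exp:
            any_hcp = True
        if oe >= lcp_obs_exp:
            any_mid = True
    if any_hcp:
        return "HCP"
    if not any_mid:
        return "LCP"
    return "ICP"


def promoter_window(
    gene: GeneModel,
    upstream: int,
    downstream: int,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    For a + strand gene this is [tss - upstream, tss + downstream); the mirror
    image for - strand. Clipped to [0, chrom_length) when a length is given.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if gene.strand == "-":
        start, end = gene.tss - downstream, gene.tss + upstream
    else:
        start, end = gene.tss - upstream, gene.tss + downstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def signed_tss_distance(gene: GeneModel, position: int) -> int:
    """Strand-aware signed distance of a position to the gene's TSS
    (negative = upstream of the TSS)."""
    d = position - gene.tss
    return d if gene.strand == "+" else -d


def assign_probes_to_promoters(
    probes: pd.DataFrame,
    genes: list[GeneModel],
    max_distance: int = MAX_PROBE_TSS_DISTANCE,
) -> pd.DataFrame:
    """Assign each array probe to its nearest-TSS gene.

    ``probes`` needs columns ``probe_id``, ``chrom``, ``pos`` (0-based).
    Returns a copy with ``gene_id`` (empty string when unassigned, i.e. every
    TSS further than ``max_distance``, inclusive bound) and strand-aware
    ``distance_to_tss`` columns. Ties on |distance| break by lexicographic
    gene_id.
    """
    out = probes.copy()
    gene_ids = np.empty(len(out), dtype=object)
    dists = np.zeros(len(out), dtype=int)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: g.gene_id)
    for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
        best: tuple[int, str, int] | None = None
        for g in by_chrom.get(chrom, []):
            d = signed_tss_distance(g, int(pos))
            key = (abs(d), g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), g.gene_id, d)
        if best is not None and best[0] <= max_distance:
            gene_ids[i] = best[1]
            dists[i] = best[2]
        else:
            gene_ids[i] = ""
            dists[i] = 0
    out["gene_id"] = gene_ids
    out["distance_to_tss"] = dists
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneModel(r.gene_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand))
        for r in df.itertuples()
    ]


def write_gene_models(genes: list[GeneModel], path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.interval.chrom, g.interval.start, g.interval.end, g.strand)
            for g in genes
        ],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos_1based",
    "gene_id",
    "design_type",
    "cross_reactive",
    "snp",
    "sex_chrom",
]


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV; disk positions are 1-based, the returned
    frame carries a 0-based ``pos`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    df["gene_id"] = df["gene_id"].fillna("")
    df["pos"] = df["pos_1based"].astype(int) - 1
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "pos_1based" not in out.columns:
        out["pos_1based"] = out["pos"].astype(int) + 1
    out[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
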