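"""Promoter 5hmC profile classification and profile clustering.

Promoters are ranked twice: by read content inside a narrow window around the
TSS (-1 kb/+0.5 kb) and by read content across the gene body (TSS..TTS). The
top-N of each ranking define the 'narrow' and 'broad' profile candidates;
promoters appearing in both raw lists are assigned to the list where their
rank is better (tie goes to narrow), producing disjoint unique sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .annotation import CpGIsland, GeneModel, promoter_window
from .coverage import AlignedReadSet, BinnedCoverage

__all__ = [
    "score_promoters",
    "select_top_profiles",
    "ProfileSets",
    "island_shore_profile",
    "IslandShoreProfile",
    "cluster_joint_profiles",
]

logger = logging.getLogger(__name__)


def _window_counts(reads: AlignedReadSet, windows: dict[str, list[tuple[int, int, int]]]):
    """Midpoint counts for (gene_index, start, end) windows grouped by chrom."""
    n = sum(len(v) for v in windows.values())
    out = np.zeros(n, dtype=np.int64)
    for chrom, wins in windows.items():
        mids = np.sort(reads.midpoints(chrom))
        for gi, s, e in wins:
            out[gi] += np.searchsorted(mids, e, "left") - np.searchsorted(mids, s, "left")
    return out


def score_promoters(
    reads: AlignedReadSet,
    genes: list[GeneModel],
    narrow_upstream: int = 1000,
    narrow_downstream: int = 500,
) -> pd.DataFrame:
    """Per-gene read-midpoint counts and ranks in the narrow promoter window
    and the gene body.

    Ranks are 1 = highest count; ties break by ascending gene_id.
    """
    narrow: dict[str, list[tuple[int, int, int]]] = {}
    body: dict[str, list[tuple[int, int, int]]] = {}
    for gi, g in enumerate(genes):
        w = promoter_window(g, narrow_upstream, narrow_downstream)
        narrow.setdefault(g.interval.chrom, []).append((gi, w.start, w.end))
        body.setdefault(g.interval.chrom, []).append(
            (gi, min(g.tss, g.tts), max(g.tss, g.tts))
        )
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "narrow_count": _window_counts(reads, narrow),
            "body_count": _window_counts(reads, body),
        }
    )

    def rank_by(col: str) -> np.ndarray:
        order = df.sort_values([col, "gene_id"], ascending=[False, True]).index
        ranks = np.empty(len(df), dtype=np.int64)
        ranks[order] = np.arange(1, len(df) + 1)
        return ranks

    df["narrow_rank"] = rank_by("narrow_count")
    df["body_rank"] = rank_by("body_count")
    return df


@dataclass
class ProfileSets:
    narrow: set[str]          # unique narrow promoters
    broad: set[str]           # unique broad promoters
    raw_narrow: set[str]      # top-N by narrow rank before de-duplication
    raw_broad: set[str]

    def label(self, gene_id: str) -> str:
        if gene_id in self.narrow:
            return "narrow"
        if gene_id in self.broad:
            return "broad"
        if gene_id in self.raw_narrow or gene_id in self.raw_broad:
            return "both_candidate"
        return "unclassified"


def select_top_profiles(scores: pd.DataFrame, n: int, dedup: str = "rank") -> ProfileSets:
    """Top-N narrow and broad promoter sets.

    ``dedup='rank'`` assigns a promoter present in both raw top-N lists to the
    list where its rank is smaller (tie -> narrow); ``dedup='difference'``
    simply drops the intersection from both sets.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(scores):
        raise ValueError("n exceeds number of promoters")
    idx = scores.set_index("gene_id")
    raw_narrow = set(idx.index[idx["narrow_rank"] <= n])
    raw_broad = set(idx.index[idx["body_rank"] <= n])
    both = raw_narrow & raw_broad
    narrow, broad = set(raw_narrow), set(raw_broad)
    if dedup == "rank":
        for g in both:
            if idx.loc[g, "narrow_rank"] <= idx.loc[g, "body_rank"]:
                broad.discard(g)
            else:
                narrow.discard(g)
    elif dedup == "difference":
        narrow -= both
        broad -= both
    else:
        raise ValueError(f"unknown dedup rule {dedup!r}")
    return ProfileSets(narrow=narrow, broad=broad, raw_narrow=raw_narrow, raw_broad=raw_broad)


@dataclass
class IslandShoreProfile:
    upstream_shore: np.ndarray   # fixed-bp bins, 5' shore first
    island: np.ndarray           # length-normalised meta-bins
    downstream_shore: np.ndarray
    n_islands: int


def island_shore_profile(
    net: BinnedCoverage,
    islands: list[CpGIsland],
    shore_width: int = 2000,
    n_island_bins: int = 40,
) -> IslandShoreProfile:
    """Mean coverage meta-profile over upstream shore | island | downstream
    shore, orienting each island by its host promoter's strand (taken from
    ``island.interval.strand``). Islands shorter than the meta-bin count are
    excluded with a log notice."""
    bs = net.bin_size
    n_shore = shore_width // bs
    ups, isl, downs = [], [], []
    for ci in islands:
        vec = net.data.get(ci.interval.chrom)
        if vec is None:
            continue
        if len(ci.interval) < n_island_bins:
            logger.info("island %s shorter than %d meta-bins; excluded", ci.interval, n_island_bins)
            continue
        b0, b1 = ci.interval.start // bs, -(-ci.interval.end // bs)
        if b0 - n_shore < 0 or b1 + n_shore > len(vec):
            continue
        left = vec[b0 - n_shore : b0]
        mid = vec[b0:b1]
        right = vec[b1 : b1 + n_shore]
        # rescale island to fixed meta-bin grid
        meta = np.interp(
            np.linspace(0, len(mid) - 1, n_island_bins), np.arange(len(mid)), mid
        )
        if ci.interval.strand == "-":
            left, right = right[::-1], left[::-1]
            meta = meta[::-1]
        ups.append(left)
        isl.append(meta)
        downs.append(right)
    if not ups:
        raise ValueError("no islands usable for the meta-profile")
    return IslandShoreProfile(
        upstream_shore=np.vstack(ups).mean(axis=0),
        island=np.vstack(isl).mean(axis=0),
        downstream_shore=np.vstack(downs).mean(axis=0),
        n_islands=len(ups),
    )


def cluster_joint_profiles(
    matrix_5hmc: pd.DataFrame,
    matrix_5mc: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> pd.Series:
    """K-means clustering of promoters on their joint 5hmC/5mC positional
    profiles.

    Rows (promoters) of the two matrices must be aligned; each concatenated
    row is z-scored before clustering (constant rows pass through as zeros).
    Returns a gene_id -> cluster (1..k) Series.
    """
    if not matrix_5hmc.index.equals(matrix_5mc.index):
        raise ValueError("profile matrices are not row-aligned")
    x = np.hstack([matrix_5hmc.to_numpy(float), matrix_5mc.to_numpy(float)])
    if k > x.shape[0]:
        raise ValueError("k exceeds number of promoters")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(z) + 1
    return pd.Series(labels, index=matrix_5hmc.index, name="cluster")
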