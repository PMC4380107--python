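"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a matched normal/tumour colon study: a small
genome with CpG-island promoters, hydroxymethyl-DIP read sets with 'narrow'
(promoter-window) and 'broad' (gene-body) enrichment shapes and a global
tumour-wide 5hmC depletion, paired Infinium-style two-channel intensities
with design-type II compression and planted methylation gains/losses, a
TET2-like promoter peak set placed away from methylation-gain promoters, and
a bivalent promoter list with configured overlap fractions.

Every stochastic choice flows from ``SimConfig.seed`` through spawned
generators, so a fixed config yields byte-identical output files. The
defaults mirror the study design this generator emulates: 17 matched
normal/tumour array pairs, 5 normal and 5 tumour DIP libraries, a planted
beta shift of 0.25 at changed probes, loss-dominant changes (4:1) at
5hmC-marked promoters and mildly gain-dominant changes (1.3:1) at unmarked
ones, a tumour-wide 5hmC scale factor of 0.3, 65% bivalency among
methylation-gain promoters and 30% among 5hmC-marked promoters.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    GeneModel,
    GenomicInterval,
    write_fasta,
    write_gene_models,
    write_manifest,
)
from .coverage import AlignedReadSet, write_bed_reads

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_genome",
    "generate_dip_reads",
    "generate_infinium",
    "generate_peaks_and_bivalents",
    "simulate_cohort",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chromosomes: int = 1
    chrom_length: int = 5_000_000
    n_genes: int = 300
    gene_length_min: int = 2_000
    gene_length_max: int = 8_000
    min_gene_gap: int = 3_000
    edge_margin: int = 25_000
    # sequence composition
    background_gc: float = 0.38
    background_cpg_suppression: float = 0.90
    island_gc: float = 0.65
    island_cpg_suppression: float = 0.0
    weak_island_gc: float = 0.50
    weak_island_cpg_suppression: float = 0.45
    island_upstream: int = 400
    island_downstream: int = 600
    island_kind_narrow: str = "weak"   # narrow promoters -> intermediate CpG
    island_kind_broad: str = "strong"  # broad promoters -> high CpG
    island_kind_unmarked: str = "none"
    # promoter profile classes
    frac_narrow: float = 1 / 3
    frac_broad: float = 1 / 3
    frac_unmarked: float = 1 / 3
    # DIP-seq reads
    read_length: int = 36
    n_reads_ip: int = 200_000
    n_reads_input: int = 200_000
    n_dip_normals: int = 5
    n_dip_tumours: int = 5
    enrichment_weight: float = 0.7    # fraction of IP reads from promoter kernels
    tumour_5hmC_scale: float = 0.3    # multiplies enrichment in tumour samples
    narrow_upstream_center: int = -600
    narrow_downstream_center: int = 250
    narrow_sd: int = 120
    narrow_upstream_weight: float = 0.6
    tss_dip_halfwidth: int = 100      # reads are depleted at the TSS itself
    # Infinium-style arrays
    n_pairs: int = 17
    probes_per_gene: int = 2
    probe_min_offset: int = -800
    probe_max_offset: int = 400
    beta_mean_marked: float = 0.45    # intermediate methylation at 5hmC-high loci
    beta_sd_marked: float = 0.12
    beta_mean_unmarked: float = 0.12  # low methylation at 5hmC-low loci
    beta_sd_unmarked: float = 0.07
    # probes are 5hmC-'high' when the expected fraction of the host
    # promoter's enrichment reads falling in the probe window exceeds this
    probe_hmc_enrich_threshold: float = 0.01
    planted_gain_rate_high: float = 0.04
    planted_loss_rate_high: float = 0.16
    planted_gain_rate_low: float = 0.13
    planted_loss_rate_low: float = 0.10
    effect_size_beta: float = 0.25
    beta_noise_sd: float = 0.03
    typeII_compression: float = 0.8
    intensity_total: float = 2_000.0
    intensity_total_cv: float = 0.1
    detection_fail_rate: float = 0.005
    cross_reactive_rate: float = 0.02
    snp_rate: float = 0.02
    sex_chrom_rate: float = 0.02
    # peaks and bivalents
    tet2_fraction: float = 0.3
    peak_center_halfspan: int = 600
    peak_halfwidth_min: int = 100
    peak_halfwidth_max: int = 200
    bivalent_frac_gain: float = 0.65
    bivalent_frac_hmc: float = 0.30

    def __post_init__(self) -> None:
        if abs(self.frac_narrow + self.frac_broad + self.frac_unmarked - 1) > 1e-9:
            raise ValueError("promoter class fractions must sum to 1")
        if not (0 < self.tumour_5hmC_scale <= 1):
            raise ValueError("tumour_5hmC_scale must be in (0, 1]")
        for name in (
            "planted_gain_rate_high",
            "planted_loss_rate_high",
            "planted_gain_rate_low",
            "planted_loss_rate_low",
            "detection_fail_rate",
            "bivalent_frac_gain",
            "bivalent_frac_hmc",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    config: SimConfig
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: list[GeneModel]
    promoter_class: dict[str, str]           # gene_id -> narrow|broad|unmarked
    island_intervals: list[GenomicInterval]  # planted islands, strand = host gene
    manifest: pd.DataFrame | None = None
    probe_hmc_class: pd.Series | None = None   # probe -> high|low local 5hmC
    true_beta_normal: pd.Series | None = None  # probe -> class-level normal beta
    true_beta_tumour: pd.Series | None = None
    change_label: pd.Series | None = None      # probe -> gain|loss|none
    tet2_targets: set[str] = field(default_factory=set)
    bivalent: set[str] = field(default_factory=set)

    @property
    def marked_genes(self) -> list[str]:
        return [g for g, c in self.promoter_class.items() if c in ("narrow", "broad")]

    @property
    def gain_prone_genes(self) -> set[str]:
        if self.change_label is None or self.manifest is None:
            return set()
        gains = self.change_label[self.change_label == "gain"].index
        sub = self.manifest[self.manifest["probe_id"].isin(gains)]
        return set(sub["gene_id"])

    def to_json(self, path) -> None:
        payload = {
            "promoter_class": self.promoter_class,
            "probe_hmc_class": {}
            if self.probe_hmc_class is None
            else self.probe_hmc_class.to_dict(),
            "change_label": {} if self.change_label is None else self.change_label.to_dict(),
            "true_beta_normal": {}
            if self.true_beta_normal is None
            else {k: round(v, 6) for k, v in self.true_beta_normal.to_dict().items()},
            "true_beta_tumour": {}
            if self.true_beta_tumour is None
            else {k: round(v, 6) for k, v in self.true_beta_tumour.to_dict().items()},
            "tet2_targets": sorted(self.tet2_targets),
            "bivalent": sorted(self.bivalent),
            "islands": [
                [i.chrom, i.start, i.end, i.strand] for i in self.island_intervals
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome


def _random_sequence(rng, length: int, gc: float, cpg_suppression: float) -> np.ndarray:
    """Two-parameter dinucleotide sampler: iid bases at the given GC content,
    then each CpG's G mutated to A with the suppression probability (mutation
    can never create a new CpG)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = BASES[rng.choice(4, size=length, p=p)]
    if cpg_suppression > 0 and length > 1:
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        hit = cg[rng.random(len(cg)) < cpg_suppression]
        seq[hit + 1] = ord("A")
    return seq


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Synthesize chromosome sequences, non-overlapping gene models and
    planted CpG islands; returns a SimTruth seed object."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    footprint = config.gene_length_max + config.min_gene_gap
    if 2 * config.edge_margin + per_chrom * footprint > config.chrom_length:
        raise ValueError(
            "chrom_length too small to place the requested genes without overlap"
        )
    class_pool = (
        ["narrow"] * round(config.frac_narrow * config.n_genes)
        + ["broad"] * round(config.frac_broad * config.n_genes)
    )
    class_pool += ["unmarked"] * (config.n_genes - len(class_pool))
    classes = list(rng.permutation(class_pool))

    sequences: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    genes: list[GeneModel] = []
    islands: list[GenomicInterval] = []
    promoter_class: dict[str, str] = {}
    gi = 0
    island_params = {
        "strong": (config.island_gc, config.island_cpg_suppression),
        "weak": (config.weak_island_gc, config.weak_island_cpg_suppression),
    }
    kind_by_class = {
        "narrow": config.island_kind_narrow,
        "broad": config.island_kind_broad,
        "unmarked": config.island_kind_unmarked,
    }
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        seq = _random_sequence(
            rng, L, config.background_gc, config.background_cpg_suppression
        )
        cursor = config.edge_margin
        while gi < config.n_genes and gi < (ci + 1) * per_chrom:
            glen = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
            gap = int(rng.integers(config.min_gene_gap, 2 * config.min_gene_gap))
            if cursor + glen + config.edge_margin > L:
                raise ValueError("ran out of chromosome while placing genes")
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gi + 1:04d}"
            gene = GeneModel(gene_id, GenomicInterval(chrom, cursor, cursor + glen, strand))
            genes.append(gene)
            cls = classes[gi]
            promoter_class[gene_id] = cls
            kind = kind_by_class[cls]
            if kind not in ("none", None):
                gc, supp = island_params[kind]
                if strand == "+":
                    s = gene.tss - config.island_upstream
                    e = gene.tss + config.island_downstream
                else:
                    s = gene.tss - config.island_downstream
                    e = gene.tss + config.island_upstream
                seq[s:e] = _random_sequence(rng, e - s, gc, supp)
                islands.append(GenomicInterval(chrom, s, e, strand))
            cursor += glen + gap
            gi += 1
        sequences[chrom] = seq.tobytes().decode("ascii")
        chrom_lengths[chrom] = L
    return SimTruth(
        config=config,
        chrom_lengths=chrom_lengths,
        sequences=sequences,
        genes=genes,
        promoter_class=promoter_class,
        island_intervals=islands,
    )


# ---------------------------------------------------------------------------
# DIP reads


def _narrow_offsets(config: SimConfig, rng, n: int) -> np.ndarray:
    """Strand-relative read-midpoint offsets for a 'narrow' promoter: two
    Gaussian flanks inside -1 kb/+0.5 kb with the TSS bin itself depleted."""
    out = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        up = rng.random(m) < config.narrow_upstream_weight
        centers = np.where(up, config.narrow_upstream_center, config.narrow_downstream_center)
        off = np.rint(rng.normal(centers, config.narrow_sd)).astype(np.int64)
        ok = (off >= -1000) & (off < 500) & (np.abs(off) >= config.tss_dip_halfwidth)
        out[todo[ok]] = off[ok]
        todo = todo[~ok]
    return out


def generate_dip_reads(
    truth: SimTruth,
    sample_kind: str,
    sample_id: str,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AlignedReadSet:
    """Sample one DIP library: uniform background plus per-promoter
    enrichment kernels. ``sample_kind`` is 'normal', 'tumour' or 'input';
    tumour samples scale the enrichment weight by ``tumour_5hmC_scale`` (the
    displaced mass becomes background, as a less specific pull-down would
    produce); input libraries are background-only."""
    config = config or truth.config
    if rng is None:
        sid_key = zlib.crc32(sample_id.encode("utf-8"))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, sid_key]))
    if sample_kind not in ("normal", "tumour", "input"):
        raise ValueError(f"unknown sample kind {sample_kind!r}")
    n = config.n_reads_input if sample_kind == "input" else config.n_reads_ip
    if n == 0:
        empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
        return AlignedReadSet(sample_id=sample_id, reads=empty, total_mapped=0)
    if sample_kind == "input":
        enrich_w = 0.0
    elif sample_kind == "tumour":
        enrich_w = config.enrichment_weight * config.tumour_5hmC_scale
    else:
        enrich_w = config.enrichment_weight
    marked = [g for g in truth.genes if truth.promoter_class[g.gene_id] != "unmarked"]
    if not marked:
        enrich_w = 0.0

    is_enriched = rng.random(n) < enrich_w
    chroms = np.array(sorted(truth.chrom_lengths))
    chrom_choice = rng.integers(0, len(chroms), size=n)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms])
    mids = rng.integers(0, lengths[chrom_choice])
    if is_enriched.any():
        idx = np.flatnonzero(is_enriched)
        which = rng.integers(0, len(marked), size=idx.size)
        # group reads by promoter for vectorised kernel sampling
        for gidx in np.unique(which):
            g = marked[gidx]
            sel = idx[which == gidx]
            if truth.promoter_class[g.gene_id] == "narrow":
                off = _narrow_offsets(config, rng, sel.size)
            else:  # broad: uniform across the gene body
                off = rng.integers(0, len(g.interval), size=sel.size)
            sign = 1 if g.strand == "+" else -1
            pos = g.tss + sign * off
            mids[sel] = pos
            chrom_choice[sel] = np.searchsorted(chroms, g.interval.chrom)
    starts = mids - config.read_length // 2
    for ci, c in enumerate(chroms):
        m = chrom_choice == ci
        starts[m] = np.clip(starts[m], 0, truth.chrom_lengths[c] - config.read_length)
    df = pd.DataFrame(
        {
            "chrom": chroms[chrom_choice],
            "start": starts,
            "end": starts + config.read_length,
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return AlignedReadSet(sample_id=sample_id, reads=df, total_mapped=n)


# ---------------------------------------------------------------------------
# Infinium-style arrays


def _truncnorm(rng, mean, sd, lo, hi, size):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _expected_window_enrichment(
    config: SimConfig, promoter_class: str, offset: int, gene_length: int, half: int = 100
) -> float:
    """Expected fraction of the host promoter's enrichment reads whose
    midpoint falls in the probe window [offset - half, offset + half)
    (strand-relative coordinates), under the read-placement kernels."""
    from scipy.stats import norm

    lo, hi = offset - half, offset + half
    if promoter_class == "narrow":
        # kernel support: [-1000, -dip] U [dip, 500)
        dip = config.tss_dip_halfwidth
        segs = [(max(lo, -1000), min(hi, -dip)), (max(lo, dip), min(hi, 500))]
        total = 0.0
        for w, c in (
            (config.narrow_upstream_weight, config.narrow_upstream_center),
            (1 - config.narrow_upstream_weight, config.narrow_downstream_center),
        ):
            for s, e in segs:
                if s < e:
                    total += w * (
                        norm.cdf(e, c, config.narrow_sd) - norm.cdf(s, c, config.narrow_sd)
                    )
        return total
    if promoter_class == "broad":
        s, e = max(lo, 0), min(hi, gene_length)
        return max(e - s, 0) / gene_length
    return 0.0


def generate_infinium(
    truth: SimTruth, config: SimConfig | None = None, rng: np.random.Generator | None = None
):
    """Synthesize the probe manifest, paired normal/tumour channel
    intensities and the planted differential-methylation truth.

    Returns (manifest, intensities, pairing); the truth object is updated in
    place with per-probe class betas and change labels. Beta noise is a
    truncated (clipped) Gaussian on the beta scale; type II betas are
    compressed toward 0.5 by ``typeII_compression`` before intensity
    synthesis; channel intensities are float-valued with M + U equal to the
    drawn per-record total.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    rows = []
    for g in truth.genes:
        for k in range(config.probes_per_gene):
            off = int(rng.integers(config.probe_min_offset, config.probe_max_offset + 1))
            sign = 1 if g.strand == "+" else -1
            pos = g.tss + sign * off
            enrich = _expected_window_enrichment(
                config, truth.promoter_class[g.gene_id], off, len(g.interval)
            )
            rows.append((g.gene_id, g.interval.chrom, pos, enrich))
    n_probes = len(rows)
    manifest = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "_enrich"])
    enrich_frac = manifest.pop("_enrich").to_numpy()
    manifest.insert(0, "probe_id", [f"cg{i + 1:06d}" for i in range(n_probes)])
    manifest["pos_1based"] = manifest["pos"] + 1
    manifest["design_type"] = np.where(rng.random(n_probes) < 0.5, "I", "II")
    manifest["cross_reactive"] = rng.random(n_probes) < config.cross_reactive_rate
    manifest["snp"] = rng.random(n_probes) < config.snp_rate
    first_chrom = sorted(truth.chrom_lengths)[0]
    manifest["sex_chrom"] = (manifest["chrom"] == first_chrom) & (
        rng.random(n_probes) < config.sex_chrom_rate
    )

    # local 5hmC truth: a probe is 'high' when its 200 bp window is expected
    # to capture an appreciable share of the host promoter's enrichment reads
    hmc_high = enrich_frac > config.probe_hmc_enrich_threshold
    beta_n = np.where(
        hmc_high,
        _truncnorm(rng, config.beta_mean_marked, config.beta_sd_marked, 0.03, 0.97, n_probes),
        _truncnorm(rng, config.beta_mean_unmarked, config.beta_sd_unmarked, 0.02, 0.9, n_probes),
    )
    u = rng.random(n_probes)
    gain_r = np.where(hmc_high, config.planted_gain_rate_high, config.planted_gain_rate_low)
    loss_r = np.where(hmc_high, config.planted_loss_rate_high, config.planted_loss_rate_low)
    label = np.where(u < gain_r, "gain", np.where(u < gain_r + loss_r, "loss", "none"))
    shift = np.where(label == "gain", config.effect_size_beta, 0.0) - np.where(
        label == "loss", config.effect_size_beta, 0.0
    )
    beta_t = np.clip(beta_n + shift, 0.01, 0.99)

    normal_ids = [f"N{i + 1:02d}" for i in range(config.n_pairs)]
    tumour_ids = [f"T{i + 1:02d}" for i in range(config.n_pairs)]
    pairing = pd.DataFrame({"normal_id": normal_ids, "tumour_id": tumour_ids})

    recs = []
    is2 = (manifest["design_type"] == "II").to_numpy()
    for sid, true_beta in [(s, beta_n) for s in normal_ids] + [
        (s, beta_t) for s in tumour_ids
    ]:
        b = np.clip(rng.normal(true_beta, config.beta_noise_sd), 0.0, 1.0)
        b_obs = np.where(is2, 0.5 + (b - 0.5) * config.typeII_compression, b)
        total = np.maximum(
            rng.normal(
                config.intensity_total, config.intensity_total * config.intensity_total_cv, n_probes
            ),
            config.intensity_total * 0.1,
        )
        M = total * b_obs
        U = total - M
        fail = rng.random(n_probes) < config.detection_fail_rate
        det = np.where(fail, rng.uniform(0.05, 1.0, n_probes), rng.uniform(0.0, 0.0499, n_probes))
        recs.append(
            pd.DataFrame(
                {
                    "probe_id": manifest["probe_id"],
                    "sample_id": sid,
                    "M": M,
                    "U": U,
                    "detection_p": det,
                }
            )
        )
    intensities = pd.concat(recs, ignore_index=True)
    truth.manifest = manifest
    truth.probe_hmc_class = pd.Series(
        np.where(hmc_high, "high", "low"), index=manifest["probe_id"]
    )
    truth.true_beta_normal = pd.Series(beta_n, index=manifest["probe_id"])
    truth.true_beta_tumour = pd.Series(beta_t, index=manifest["probe_id"])
    truth.change_label = pd.Series(label, index=manifest["probe_id"])
    return manifest, intensities, pairing


# ---------------------------------------------------------------------------
# peaks and bivalent promoters


def generate_peaks_and_bivalents(
    truth: SimTruth, config: SimConfig | None = None, rng: np.random.Generator | None = None
):
    """Place TET2-like promoter peaks and draw the bivalent promoter list.

    Peaks land within +-1 kb of the TSS of TET2-flagged promoters, which are
    drawn preferentially from CpG-island promoters (strong islands first)
    that carry no planted methylation gain. The bivalent flag is assigned so
    that the configured fraction of methylation-gain-prone promoters and of
    5hmC-marked promoters is bivalent, exactly at the rounded counts.
    Returns (peaks DataFrame, bivalent gene-id list); truth is updated.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    if truth.change_label is None:
        raise ValueError("array truth must be generated before peaks/bivalents")
    gain_prone = truth.gain_prone_genes
    island_kind = {
        "narrow": config.island_kind_narrow,
        "broad": config.island_kind_broad,
        "unmarked": config.island_kind_unmarked,
    }
    strength = {"strong": 0, "weak": 1, "none": 2}
    candidates = [
        g.gene_id
        for g in truth.genes
        if island_kind[truth.promoter_class[g.gene_id]] != "none"
        and g.gene_id not in gain_prone
    ]
    n_tet2 = round(config.tet2_fraction * config.n_genes)
    if n_tet2 > len(candidates):
        raise ValueError(
            f"tet2_fraction requests {n_tet2} promoters but only "
            f"{len(candidates)} island promoters without planted gain exist"
        )
    order = sorted(
        rng.permutation(candidates).tolist(),
        key=lambda g: strength[island_kind[truth.promoter_class[g]]],
    )
    tet2 = set(order[:n_tet2])
    genes_by_id = {g.gene_id: g for g in truth.genes}
    peak_rows = []
    for gid in sorted(tet2):
        g = genes_by_id[gid]
        center = g.tss + int(
            rng.integers(-config.peak_center_halfspan, config.peak_center_halfspan + 1)
        )
        hw = int(rng.integers(config.peak_halfwidth_min, config.peak_halfwidth_max + 1))
        peak_rows.append((g.interval.chrom, center - hw, center + hw, f"peak_{gid}"))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    marked = set(truth.marked_genes)
    n_gain_biv = round(config.bivalent_frac_gain * len(gain_prone))
    n_hmc_biv = round(config.bivalent_frac_hmc * len(marked))
    gain_biv = set(
        rng.choice(sorted(gain_prone), size=n_gain_biv, replace=False).tolist()
    ) if n_gain_biv else set()
    already = len(marked & gain_biv)
    if already > n_hmc_biv:
        raise ValueError("bivalent fractions infeasible: gain-linked bivalents already exceed the 5hmC quota")
    remaining_pool = sorted(marked - gain_prone)
    extra = n_hmc_biv - already
    if extra > len(remaining_pool):
        raise ValueError("bivalent_frac_hmc infeasible for the marked promoter count")
    hmc_biv = set(rng.choice(remaining_pool, size=extra, replace=False).tolist()) if extra else set()
    bivalent = gain_biv | hmc_biv
    truth.tet2_targets = tet2
    truth.bivalent = bivalent
    return peaks, sorted(bivalent)


# ---------------------------------------------------------------------------
# full cohort emission


def simulate_cohort(config: SimConfig, outdir) -> dict[str, object]:
    """Generate the full synthetic cohort and write every file the pipeline
    consumes. Returns a dict of output paths (lists for the read sets)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(5)
    truth = generate_genome(config, np.random.default_rng(children[0]))

    read_rngs = np.random.default_rng(children[1]).spawn(
        config.n_dip_normals + config.n_dip_tumours + 2
    )
    paths: dict[str, object] = {}
    normal_beds, tumour_beds = [], []
    k = 0
    for i in range(config.n_dip_normals):
        rs = generate_dip_reads(truth, "normal", f"hmedip_N{i + 1}", config, read_rngs[k])
        p = outdir / f"hmedip_normal_{i + 1}.bed"
        write_bed_reads(rs, p)
        normal_beds.append(p)
        k += 1
    for i in range(config.n_dip_tumours):
        rs = generate_dip_reads(truth, "tumour", f"hmedip_T{i + 1}", config, read_rngs[k])
        p = outdir / f"hmedip_tumour_{i + 1}.bed"
        write_bed_reads(rs, p)
        tumour_beds.append(p)
        k += 1
    inp_n = generate_dip_reads(truth, "input", "input_normal", config, read_rngs[k])
    inp_t = generate_dip_reads(truth, "input", "input_tumour", config, read_rngs[k + 1])

    manifest, intensities, pairing = generate_infinium(
        truth, config, np.random.default_rng(children[2])
    )
    peaks, bivalent = generate_peaks_and_bivalents(
        truth, config, np.random.default_rng(children[3])
    )

    write_fasta(truth.sequences, outdir / "genome.fa")
    write_gene_models(truth.genes, outdir / "genes.tsv")
    write_bed_reads(inp_n, outdir / "input_normal.bed")
    write_bed_reads(inp_t, outdir / "input_tumour.bed")
    write_manifest(manifest, outdir / "manifest.tsv")
    intensities.to_csv(outdir / "intensities.tsv", sep="\t", index=False, float_format="%.4f")
    pairing.to_csv(outdir / "pairing.tsv", sep="\t", index=False)
    peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    pd.DataFrame({"gene_id": bivalent}).to_csv(outdir / "bivalent.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    config.to_yaml(outdir / "config.yaml")
    paths.update(
        {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.tsv",
            "normal_ip": normal_beds,
            "tumour_ip": tumour_beds,
            "input_normal": outdir / "input_normal.bed",
            "input_tumour": outdir / "input_tumour.bed",
            "manifest": outdir / "manifest.tsv",
            "intensities": outdir / "intensities.tsv",
            "pairing": outdir / "pairing.tsv",
            "peaks": outdir / "peaks.bed",
            "bivalent": outdir / "bivalent.tsv",
            "truth": outdir / "truth.json",
            "config": outdir / "config.yaml",
        }
    )
    return paths
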