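"""End-to-end pipeline: annotation -> coverage -> profiles -> arrays ->
integration, with a JSON summary of every headline statistic.

``run_pipeline`` consumes the file set produced by
:func:`hydroxymet.simulate.simulate_cohort` (or equivalently formatted real
data) and executes the stages in order, writing tabular outputs and a
deterministic ``summary.json``. Any stage failure aborts with the failing
stage named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import annotation, arrays, coverage, integrate, profiles

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Analysis parameters.

    Defaults are the canonical full-scale settings (3,000 top loci, 10
    clusters, alpha 0.01, 200 bp probe windows, 1 kb TET2 flank, 1,499 bp
    max probe-TSS distance); :meth:`desk_scale` returns a variant sized for
    the default synthetic cohort of a few hundred genes.
    """

    narrow_upstream: int = 1000
    narrow_downstream: int = 500
    probe_window: int = 200
    top_n: int = 3000            # 5hmC-high / 5hmC-low locus set size
    profile_top_n: int = 3000    # narrow/broad promoter list size
    tet2_tss_flank: int = 1000
    alpha: float = 0.01
    cluster_k: int = 10
    cluster_upstream: int = 3000
    cluster_downstream: int = 20000
    shore_width: int = 2000
    max_probe_tss_distance: int = 1499
    bin_size: int = 50
    metagene_flank: int = 3000
    detect_floor: float = 1.0
    detection_alpha: float = 0.05
    log_ratio_offset: float = 100.0
    seed: int = 0
    dedup_rule: str = "rank"
    probe_count_combine: str = "mean_rpm"
    # LCMS-style global modification percentages (% of cytosines) used for
    # the hmC-contamination estimate of bisulfite-based methylation calls.
    lcms_pct_hmc_normal: float = 0.118
    lcms_pct_mc_normal: float = 4.8
    lcms_pct_hmc_tumour: float = 0.031
    lcms_pct_mc_tumour: float = 4.4

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """Settings sized for the default synthetic cohort (300 genes,
        ~600 probes)."""
        base = dict(
            top_n=150,
            profile_top_n=100,
            cluster_downstream=3000,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _require(stage: str, inputs: dict, keys: list[str]) -> None:
    for k in keys:
        if k not in inputs:
            raise PipelineError(stage, f"missing input '{k}'")
        paths = inputs[k] if isinstance(inputs[k], (list, tuple)) else [inputs[k]]
        for p in paths:
            if not Path(p).exists():
                raise PipelineError(stage, f"input file not found: {p}")


def _promoter_context(seqs: dict[str, str], gene: annotation.GeneModel,
                      upstream: int = 1300, downstream: int = 500) -> str | None:
    """Strand-oriented promoter sequence TSS -upstream..+downstream; None
    when truncated by a chromosome edge."""
    seq = seqs[gene.interval.chrom]
    if gene.strand == "+":
        s, e = gene.tss - upstream, gene.tss + downstream
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = gene.tss - downstream, gene.tss + upstream
    if s < 0 or e > len(seq):
        return None
    return str(Seq(seq[s:e]).reverse_complement())


def run_pipeline(inputs: dict, config: PipelineConfig, outdir) -> dict:
    """Execute all stages and return (and write) the summary dict.

    ``inputs`` maps: genome, genes, normal_ip (list of BEDs), tumour_ip
    (list), input_normal, input_tumour, manifest, intensities, pairing,
    peaks, bivalent -- to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}
    timings: dict[str, float] = {}

    # ---------------- annotation ----------------
    stage = "annotation"
    t0 = time.time()
    _require(stage, inputs, ["genome", "genes", "manifest"])
    try:
        seqs = annotation.read_fasta(inputs["genome"])
        genes = annotation.read_gene_models(inputs["genes"])
        chrom_lengths = {c: len(s) for c, s in seqs.items()}
        islands_by_chrom = {
            c: annotation.find_cpg_islands(s, chrom=c) for c, s in seqs.items()
        }
        islands = [i for lst in islands_by_chrom.values() for i in lst]
        cpg_class = {}
        for g in genes:
            ctx = _promoter_context(seqs, g)
            cpg_class[g.gene_id] = (
                annotation.classify_promoter_cpg_content(ctx) if ctx else "NA"
            )
        manifest = annotation.read_manifest(inputs["manifest"])
        manifest = annotation.assign_probes_to_promoters(
            manifest.drop(columns=["gene_id"]), genes, config.max_probe_tss_distance
        )
        pd.Series(cpg_class, name="cpg_class").rename_axis("gene_id").to_frame().to_csv(
            outdir / "promoter_cpg_class.tsv", sep="\t"
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    timings[stage] = time.time() - t0

    # ---------------- coverage ----------------
    stage = "coverage"
    t0 = time.time()
    _require(stage, inputs, ["normal_ip", "tumour_ip", "input_normal", "input_tumour"])
    try:
        normal_sets = [
            coverage.read_bed_reads(p, sample_id=f"normal_{i}")
            for i, p in enumerate(inputs["normal_ip"])
        ]
        tumour_sets = [
            coverage.read_bed_reads(p, sample_id=f"tumour_{i}")
            for i, p in enumerate(inputs["tumour_ip"])
        ]
        input_n = coverage.read_bed_reads(inputs["input_normal"], sample_id="input_normal")
        pooled_normal = coverage.AlignedReadSet(
            sample_id="pooled_normal",
            reads=pd.concat([s.reads for s in normal_sets], ignore_index=True),
            total_mapped=sum(s.total_mapped for s in normal_sets),
        )
        cov_ip = coverage.normalized_coverage(pooled_normal, config.bin_size, chrom_lengths)
        cov_in = coverage.normalized_coverage(input_n, config.bin_size, chrom_lengths)
        net = coverage.input_subtract(cov_ip, cov_in)
        metagene = coverage.tss_metagene(net, genes, config.metagene_flank)
        feat = coverage.feature_distribution(
            pooled_normal, genes, config.narrow_upstream, config.narrow_downstream
        )
        probe_counts_normal = coverage.count_reads_in_probe_windows(
            normal_sets, manifest, config.probe_window, config.probe_count_combine
        )
        probe_counts_tumour = coverage.count_reads_in_probe_windows(
            tumour_sets, manifest, config.probe_window, config.probe_count_combine
        )
        probe_counts_normal.to_csv(outdir / "probe_counts_normal.tsv", sep="\t", index=False)
        probe_counts_tumour.to_csv(outdir / "probe_counts_tumour.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"position": metagene.positions, "mean_net_rpm": metagene.mean_coverage}
        ).to_csv(outdir / "tss_metagene.tsv", sep="\t", index=False)
        summary["feature_distribution"] = {
            k: float(v) for k, v in feat.fractions.items()
        }
        summary["metagene_n_genes"] = metagene.n_genes
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    timings[stage] = time.time() - t0

    # ---------------- profiles ----------------
    stage = "profiles"
    t0 = time.time()
    try:
        scores = profiles.score_promoters(
            pooled_normal, genes, config.narrow_upstream, config.narrow_downstream
        )
        sets = profiles.select_top_profiles(scores, config.profile_top_n, config.dedup_rule)
        scores["profile"] = [sets.label(g) for g in scores["gene_id"]]
        scores.to_csv(outdir / "promoter_scores.tsv", sep="\t", index=False)
        # orient islands by host promoter strand (nearest TSS)
        oriented = []
        for isl in islands:
            best = None
            for g in genes:
                if g.interval.chrom != isl.interval.chrom:
                    continue
                d = abs(g.tss - isl.interval.midpoint)
                if best is None or d < best[0]:
                    best = (d, g.strand)
            if best is not None and best[0] <= 5000:
                oriented.append(
                    annotation.CpGIsland(
                        annotation.GenomicInterval(
                            isl.interval.chrom, isl.interval.start, isl.interval.end, best[1]
                        ),
                        isl.gc_fraction,
                        isl.obs_exp_cpg,
                    )
                )
        shore = profiles.island_shore_profile(net, oriented, config.shore_width)
        summary["island_shore"] = {
            "n_islands": shore.n_islands,
            "upstream_shore_mean": float(shore.upstream_shore.mean()),
            "island_mean": float(shore.island.mean()),
            "downstream_shore_mean": float(shore.downstream_shore.mean()),
        }
        # joint profile clustering around the TSS
        bs = config.bin_size
        up_b, down_b = config.cluster_upstream // bs, config.cluster_downstream // bs
        rows_h, row_ids = [], []
        for g in genes:
            vec = net.data[g.interval.chrom]
            b0 = g.tss // bs
            if b0 - up_b < 0 or b0 + down_b > len(vec):
                continue
            w = vec[b0 - up_b : b0 + down_b]
            rows_h.append(w[::-1] if g.strand == "-" else w)
            row_ids.append(g.gene_id)
        mat_h = pd.DataFrame(np.vstack(rows_h), index=row_ids)
        summary["n_narrow_unique"] = len(sets.narrow)
        summary["n_broad_unique"] = len(sets.broad)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    timings[stage] = time.time() - t0

    # ---------------- arrays ----------------
    stage = "arrays"
    t0 = time.time()
    _require(stage, inputs, ["intensities", "pairing"])
    try:
        intensities = pd.read_csv(inputs["intensities"], sep="\t")
        pairing = pd.read_csv(inputs["pairing"], sep="\t")
        retained = arrays.filter_probes(intensities, manifest, config.detection_alpha)
        betas = retained.assign(
            beta=arrays.beta_value(retained["M"].to_numpy(), retained["U"].to_numpy())
        ).pivot(index="probe_id", columns="sample_id", values="beta")
        design = manifest.set_index("probe_id")["design_type"]
        betas_complete = betas.dropna()
        corrected = arrays.peak_based_correction(betas_complete, design)
        corrected.to_csv(outdir / "beta_corrected.tsv", sep="\t", float_format="%.5f")
        qc = arrays.beta_density_qc(betas_complete, corrected, design)
        qc.to_csv(outdir / "qc_beta_density.tsv", sep="\t", index=False,
                  float_format="%.6g")
        _plot_density_qc(qc, outdir / "qc_beta_density.png")
        # probes must be measured in every paired sample
        sample_ids = pairing["normal_id"].tolist() + pairing["tumour_id"].tolist()
        counts = retained.groupby("probe_id")["sample_id"].nunique()
        complete = counts.index[counts == len(sample_ids)]
        diffmeth = arrays.differential_methylation(
            retained[retained["probe_id"].isin(complete)],
            pairing,
            offset=config.log_ratio_offset,
            alpha=config.alpha,
        )
        diffmeth.to_csv(outdir / "diffmeth.tsv", sep="\t", float_format="%.6g")
        summary["n_probes_retained"] = int(betas.shape[0])
        summary["n_probes_tested"] = int(len(diffmeth))
        summary["n_gain_probes"] = int((diffmeth["label"] == "gain").sum())
        summary["n_loss_probes"] = int((diffmeth["label"] == "loss").sum())
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    timings[stage] = time.time() - t0

    # ---------------- integration ----------------
    stage = "integration"
    t0 = time.time()
    _require(stage, inputs, ["peaks", "bivalent"])
    try:
        tested = set(diffmeth.index)
        pc_n = probe_counts_normal.set_index("probe_id")["rpm_mean"]
        pc_n = pc_n[pc_n.index.isin(tested)]
        high, low = integrate.select_high_low_5hmc_loci(pc_n, config.top_n)
        ct_high = integrate.crosstab_5hmc_methylation(high, diffmeth)
        ct_low = integrate.crosstab_5hmc_methylation(low, diffmeth)

        probe_gene = manifest.set_index("probe_id")["gene_id"]
        assigned = probe_gene[probe_gene != ""]
        universe = set(assigned[assigned.index.isin(tested)])
        gain_probes = diffmeth.index[diffmeth["label"] == "gain"]
        loss_probes = diffmeth.index[diffmeth["label"] == "loss"]
        gain_genes = set(assigned.reindex(gain_probes).dropna()) & universe
        loss_genes = set(assigned.reindex(loss_probes).dropna()) & universe

        peaks = pd.read_csv(
            inputs["peaks"], sep="\t", header=None,
            names=["chrom", "start", "end", "name"], dtype={0: str},
        )
        tet2 = integrate.tet2_target_promoters(peaks, genes, config.tet2_tss_flank) & universe
        depletion = integrate.overlap_depletion_test(gain_genes, tet2, universe)

        bivalent = set(
            pd.read_csv(inputs["bivalent"], sep="\t")["gene_id"].astype(str)
        ) & universe
        hmc_genes = (sets.narrow | sets.broad) & universe
        venn = integrate.venn_three_way(hmc_genes, bivalent, gain_genes, universe)

        tum_counts = probe_counts_tumour.set_index("probe_id")["rpm_mean"]
        tum_gene = (
            tum_counts[tum_counts.index.isin(assigned.index)]
            .groupby(assigned)
            .mean()
        )
        tum_gene = tum_gene[tum_gene.index.isin(universe)]
        promoter_labels = pd.DataFrame(
            {
                "gain": [g in gain_genes for g in tum_gene.index],
                "loss": [g in loss_genes for g in tum_gene.index],
            },
            index=tum_gene.index,
        )
        persistent = integrate.persistent_5hmc_crosstab(
            tum_gene, promoter_labels, config.detect_floor
        )
        hmc_frac_n = integrate.hmc_fraction_of_bisulfite_signal(
            config.lcms_pct_hmc_normal, config.lcms_pct_mc_normal
        )
        hmc_frac_t = integrate.hmc_fraction_of_bisulfite_signal(
            config.lcms_pct_hmc_tumour, config.lcms_pct_mc_tumour
        )
        cluster = profiles.cluster_joint_profiles(
            mat_h,
            _promoter_beta_matrix(mat_h.index, assigned, betas_complete, pairing, mat_h.shape[1]),
            k=min(config.cluster_k, mat_h.shape[0]),
            seed=config.seed,
        )
        cluster.rename_axis("gene_id").to_frame().to_csv(
            outdir / "profile_clusters.tsv", sep="\t"
        )
        summary.update(
            {
                "crosstab_high": ct_high.to_dict(),
                "crosstab_low": ct_low.to_dict(),
                "n_gain_promoters": len(gain_genes),
                "n_loss_promoters": len(loss_genes),
                "n_tet2_promoters": len(tet2),
                "tet2_overlap": depletion.to_dict(),
                "venn": venn.to_dict(),
                "persistent_5hmc": persistent,
                "hmc_fraction_of_bisulfite_signal": {
                    "normal": round(hmc_frac_n, 4),
                    "tumour": round(hmc_frac_t, 4),
                },
                "cluster_sizes": cluster.value_counts().sort_index().to_dict(),
            }
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    timings[stage] = time.time() - t0

    for name, dt in timings.items():
        logger.info("stage %s finished in %.2f s", name, dt)
    serializable = _jsonify(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_stable(serializable), fh, indent=1, sort_keys=True)
    return serializable


def _plot_density_qc(qc: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, stage in zip(axes, ("pre", "post")):
        for t, style in (("I", "-"), ("II", "--")):
            sub = qc[(qc["stage"] == stage) & (qc["design_type"] == t)]
            ax.plot(sub["beta"], sub["density"], style, label=f"type {t}")
        ax.set_title(f"{stage}-correction")
        ax.set_xlabel("beta")
    axes[0].set_ylabel("density")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _promoter_beta_matrix(gene_ids, assigned: pd.Series, betas: pd.DataFrame,
                          pairing: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Constant-per-promoter methylation track: mean normal beta of the
    promoter's probes, broadcast across the positional bins (stand-in for a
    positional 5mC profile; see docs/methods.md)."""
    normals = [c for c in pairing["normal_id"] if c in betas.columns]
    probe_mean = betas[normals].mean(axis=1)
    gene_mean = probe_mean.groupby(assigned.reindex(probe_mean.index)).mean()
    vals = gene_mean.reindex(gene_ids).fillna(float(probe_mean.mean())).to_numpy()
    return pd.DataFrame(np.tile(vals[:, None], (1, n_bins)), index=gene_ids)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stable(obj):
    """Round floats for byte-stable JSON output."""
    if isinstance(obj, dict):
        return {k: _stable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_stable(v) for v in obj]
    if isinstance(obj, float):
        return round(obj, 10)
    return obj


def summary_is_deterministic_copy(a: dict, b: dict) -> bool:
    """Compare two summaries ignoring wall-clock timings."""
    a, b = dict(a), dict(b)
    a.pop("timings_s", None)
    b.pop("timings_s", None)
    return json.dumps(_stable(a), sort_keys=True) == json.dumps(_stable(b), sort_keys=True)
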