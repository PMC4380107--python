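"""Synthetic cohort generator: determinism, conservation and planted-truth
recovery from the emitted files."""

import filecmp
import json
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from hydroxymet.annotation import classify_promoter_cpg_content
from hydroxymet.arrays import beta_value
from hydroxymet.pipeline import _promoter_context
from hydroxymet.simulate import (
    SimConfig,
    generate_dip_reads,
    generate_genome,
    generate_infinium,
    generate_peaks_and_bivalents,
    simulate_cohort,
)


def test_config_invariants():
    with pytest.raises(ValueError):
        SimConfig(frac_narrow=0.5, frac_broad=0.5, frac_unmarked=0.5)
    with pytest.raises(ValueError):
        SimConfig(tumour_5hmC_scale=0.0)
    with pytest.raises(ValueError):
        SimConfig(planted_gain_rate_high=1.5)


def test_genome_sizing_error():
    with pytest.raises(ValueError):
        generate_genome(SimConfig(n_genes=200, chrom_length=100_000))


def test_cohort_determinism_byte_identical(small_config, tmp_path):
    a = tmp_path / "a"
    b = tmp_path / "b"
    simulate_cohort(small_config, a)
    simulate_cohort(small_config, b)
    for name in (
        "genome.fa",
        "genes.tsv",
        "hmedip_normal_1.bed",
        "intensities.tsv",
        "manifest.tsv",
        "peaks.bed",
        "bivalent.tsv",
        "truth.json",
    ):
        assert filecmp.cmp(a / name, b / name, shallow=False), name


def test_read_count_conservation(small_config):
    truth = generate_genome(small_config)
    rs = generate_dip_reads(truth, "normal", "n1", small_config)
    assert len(rs.reads) == small_config.n_reads_ip == rs.total_mapped
    empty_cfg = SimConfig(**{**small_config.__dict__, "n_reads_input": 0})
    empty = generate_dip_reads(truth, "input", "i1", empty_cfg)
    assert empty.total_mapped == 0 and len(empty.reads) == 0


def test_island_regime_disabled_gives_all_lcp(small_config):
    cfg = SimConfig(
        **{
            **small_config.__dict__,
            "island_kind_narrow": "none",
            "island_kind_broad": "none",
            "island_kind_unmarked": "none",
        }
    )
    truth = generate_genome(cfg)
    assert truth.island_intervals == []
    for g in truth.genes:
        ctx = _promoter_context(truth.sequences, g)
        assert classify_promoter_cpg_content(ctx) == "LCP"


def test_island_promoter_classes_match_sequence_oracle(small_config):
    """Planted island regimes produce the promoter classes a direct window
    scan of the emitted sequence reports (trivially: the classifier is a
    pure function of the sequence; here we pin the planted pattern)."""
    truth = generate_genome(small_config)
    calls = Counter()
    for g in truth.genes:
        ctx = _promoter_context(truth.sequences, g)
        calls[(truth.promoter_class[g.gene_id], classify_promoter_cpg_content(ctx))] += 1
    # broad (strong island) promoters must all be HCP; unmarked all LCP
    for (cls, call), n in calls.items():
        if cls == "broad":
            assert call == "HCP"
        if cls == "unmarked":
            assert call == "LCP"


def test_unenriched_ip_indistinguishable_from_input(small_config):
    from scipy.stats import mannwhitneyu

    cfg = SimConfig(**{**small_config.__dict__, "enrichment_weight": 0.0})
    truth = generate_genome(cfg)
    ip = generate_dip_reads(truth, "normal", "n1", cfg)
    inp = generate_dip_reads(truth, "input", "i1", cfg)
    bins = np.arange(0, cfg.chrom_length + 10_000, 10_000)
    h_ip = np.histogram(ip.reads["start"], bins=bins)[0]
    h_in = np.histogram(inp.reads["start"], bins=bins)[0]
    assert mannwhitneyu(h_ip, h_in).pvalue > 0.01


def test_narrow_promoter_reads_concentrate_in_window(default_cohort):
    """For planted narrow promoters the promoter-window read fraction
    exceeds the gene-body fraction (interval oracle on emitted reads)."""
    import hydroxymet.annotation as ann
    import hydroxymet.coverage as cov

    paths = default_cohort["paths"]
    genes = ann.read_gene_models(paths["genes"])
    reads = cov.read_bed_reads(paths["normal_ip"][0])
    mids = ((reads.reads["start"] + reads.reads["end"]) // 2).to_numpy()
    pclass = default_cohort["truth"]["promoter_class"]
    checked = 0
    for g in genes:
        if pclass[g.gene_id] != "narrow":
            continue
        w = ann.promoter_window(g, 1000, 500)
        in_w = ((mids >= w.start) & (mids < w.end)).sum()
        lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
        in_body = ((mids >= lo) & (mids < hi)).sum()
        if in_w + in_body >= 200:
            assert in_w > in_body
            checked += 1
    assert checked >= 50


def test_tumour_scale_recovered_from_reads(default_cohort):
    """Input-subtracted promoter-window RPM in tumour vs normal recovers the
    configured global 5hmC depletion factor."""
    import hydroxymet.annotation as ann
    import hydroxymet.coverage as cov

    paths = default_cohort["paths"]
    cfg = default_cohort["config"]
    genes = ann.read_gene_models(paths["genes"])
    marked = [
        g
        for g in genes
        if default_cohort["truth"]["promoter_class"][g.gene_id] != "unmarked"
    ]
    assert len(marked) >= 100
    windows = [ann.promoter_window(g, 1000, 500) for g in marked]

    def window_rpm(path):
        rs = cov.read_bed_reads(path)
        mids = np.sort(((rs.reads["start"] + rs.reads["end"]) // 2).to_numpy())
        scale = 1e6 / rs.total_mapped
        return sum(
            (np.searchsorted(mids, w.end) - np.searchsorted(mids, w.start)) * scale
            for w in windows
        )

    rpm_n = np.mean([window_rpm(p) for p in paths["normal_ip"]])
    rpm_t = np.mean([window_rpm(p) for p in paths["tumour_ip"]])
    rpm_bg_n = window_rpm(paths["input_normal"])
    rpm_bg_t = window_rpm(paths["input_tumour"])
    ratio = (rpm_t - rpm_bg_t) / (rpm_n - rpm_bg_n)
    assert ratio == pytest.approx(cfg.tumour_5hmC_scale, abs=0.05)


def test_infinium_identity_when_noiseless(small_config):
    cfg = SimConfig(
        **{
            **small_config.__dict__,
            "beta_noise_sd": 0.0,
            "typeII_compression": 1.0,
        }
    )
    truth = generate_genome(cfg)
    man, inten, _ = generate_infinium(truth, cfg)
    normals = inten[inten["sample_id"] == "N01"].set_index("probe_id")
    recovered = beta_value(normals["M"].to_numpy(), normals["U"].to_numpy())
    expected = truth.true_beta_normal.reindex(normals.index).to_numpy()
    np.testing.assert_allclose(recovered, expected, atol=1e-12)


def test_infinium_planted_gain_effect(default_cohort):
    """Tumour - normal mean beta difference at planted gain probes matches
    the configured effect size, recomputed from the emitted table."""
    inten = pd.read_csv(default_cohort["paths"]["intensities"], sep="\t")
    man = pd.read_csv(default_cohort["paths"]["manifest"], sep="\t")
    cfg = default_cohort["config"]
    labels = default_cohort["truth"]["change_label"]
    typeI = set(man.loc[man["design_type"] == "I", "probe_id"])
    gains = [p for p, l in labels.items() if l == "gain" and p in typeI]
    assert len(gains) >= 5
    inten["beta"] = beta_value(inten["M"].to_numpy(), inten["U"].to_numpy())
    sub = inten[inten["probe_id"].isin(gains)]
    is_t = sub["sample_id"].str.startswith("T")
    diff = sub.loc[is_t, "beta"].mean() - sub.loc[~is_t, "beta"].mean()
    assert diff == pytest.approx(cfg.effect_size_beta, abs=0.05)


def test_m_plus_u_equals_total_and_positive(default_cohort):
    inten = pd.read_csv(default_cohort["paths"]["intensities"], sep="\t")
    total = inten["M"] + inten["U"]
    assert (total > 0).all()
    assert (inten["M"] >= 0).all() and (inten["U"] >= 0).all()


def test_peaks_within_1kb_of_some_tss(default_cohort):
    import hydroxymet.annotation as ann

    peaks = pd.read_csv(
        default_cohort["paths"]["peaks"], sep="\t", header=None,
        names=["chrom", "start", "end", "name"],
    )
    genes = ann.read_gene_models(default_cohort["paths"]["genes"])
    tss = {g.interval.chrom: [] for g in genes}
    for g in genes:
        tss[g.interval.chrom].append(g.tss)
    for r in peaks.itertuples():
        assert any(
            r.start < t + 1000 and r.end > t - 1000 for t in tss[r.chrom]
        ), f"peak {r.name} not within 1 kb of any TSS"


def test_tet2_fraction_zero_gives_empty_peaks(small_config):
    cfg = SimConfig(**{**small_config.__dict__, "tet2_fraction": 0.0})
    truth = generate_genome(cfg)
    generate_infinium(truth, cfg)
    peaks, _ = generate_peaks_and_bivalents(truth, cfg)
    assert len(peaks) == 0


def test_bivalent_fractions_realized_exactly(default_cohort):
    truth = default_cohort["truth"]
    cfg = default_cohort["config"]
    bivalent = set(truth["bivalent"])
    marked = {g for g, c in truth["promoter_class"].items() if c != "unmarked"}
    probe_gene = {}  # reconstruct gain-prone promoters from probe labels
    man = pd.read_csv(default_cohort["paths"]["manifest"], sep="\t")
    for r in man.itertuples():
        probe_gene[r.probe_id] = r.gene_id
    gain_prone = {
        probe_gene[p] for p, l in truth["change_label"].items() if l == "gain"
    }
    n_gain_biv = len(gain_prone & bivalent)
    assert abs(n_gain_biv - cfg.bivalent_frac_gain * len(gain_prone)) <= 1
    n_hmc_biv = len(marked & bivalent)
    assert abs(n_hmc_biv - cfg.bivalent_frac_hmc * len(marked)) <= 1


def test_infeasible_bivalent_fraction_raises(small_config):
    cfg = SimConfig(
        **{**small_config.__dict__, "tet2_fraction": 0.95}
    )
    truth = generate_genome(cfg)
    generate_infinium(truth, cfg)
    with pytest.raises(ValueError):
        generate_peaks_and_bivalents(truth, cfg)
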