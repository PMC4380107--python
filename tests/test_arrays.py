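"""Array-processing operations: beta values, filtering, peak-based type
correction, moderated differential methylation and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from hydroxymet.arrays import (
    beta_value,
    differential_methylation,
    filter_probes,
    gene_set_rank_test,
    mu_log_ratio,
    peak_based_correction,
    rank_sum_compare,
    weighted_diffmeth,
)


# ---------------------------------------------------------------------------
# beta values


@pytest.mark.parametrize(
    "m, u, expected", [(500, 500, 0.5), (0, 800, 0.0), (300, 100, 0.75)]
)
def test_beta_value_examples(m, u, expected):
    assert beta_value(m, u) == pytest.approx(expected)


def test_beta_value_zero_total_is_missing():
    assert math.isnan(beta_value(0, 0))


def test_beta_value_monotone_in_channels(rng):
    u = 400.0
    ms = np.sort(rng.uniform(0, 1000, 50))
    assert np.all(np.diff(beta_value(ms, u)) >= 0)
    m = 400.0
    us = np.sort(rng.uniform(0, 1000, 50))
    assert np.all(np.diff(beta_value(m, us)) <= 0)


# ---------------------------------------------------------------------------
# filtering


def _manifest(flags):
    n = len(flags)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": range(n),
            "design_type": "I",
            "cross_reactive": [f == "x" for f in flags],
            "snp": [f == "s" for f in flags],
            "sex_chrom": [f == "y" for f in flags],
        }
    )


def _records(probe_ids, det=0.001):
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "sample_id": "s1",
            "M": 500.0,
            "U": 500.0,
            "detection_p": det,
        }
    )


def test_filter_clean_set_is_identity():
    man = _manifest(["-"] * 5)
    rec = _records([f"p{i}" for i in range(5)])
    out = filter_probes(rec, man)
    pd.testing.assert_frame_equal(out, rec)


def test_filter_detection_threshold_is_strict():
    man = _manifest(["-"])
    assert len(filter_probes(_records(["p0"], det=0.05), man)) == 0
    assert len(filter_probes(_records(["p0"], det=0.0499), man)) == 1


def test_filter_flagged_probes_vs_hand_enumeration():
    flags = ["-", "x", "-", "s", "y", "-", "x", "s", "-", "y", "-", "-"]
    man = _manifest(flags)
    rec = _records([f"p{i}" for i in range(12)])
    out = filter_probes(rec, man)
    survivors = {f"p{i}" for i, f in enumerate(flags) if f == "-"}
    assert set(out["probe_id"]) == survivors
    # idempotent and never grows
    again = filter_probes(out, man)
    assert len(again) == len(out)


def test_filter_unknown_probe_is_error():
    man = _manifest(["-"])
    with pytest.raises(ValueError):
        filter_probes(_records(["p0", "zz"]), man)


# ---------------------------------------------------------------------------
# peak-based correction


def _bimodal_betas(rng, n=4000, compression=1.0):
    true = np.where(
        rng.random(n) < 0.5, rng.normal(0.10, 0.05, n), rng.normal(0.85, 0.05, n)
    ).clip(0.01, 0.99)
    design = pd.Series(
        np.where(rng.random(n) < 0.5, "I", "II"), index=[f"p{i}" for i in range(n)]
    )
    obs = np.where(design == "II", 0.5 + (true - 0.5) * compression, true)
    return pd.DataFrame({"s1": obs}, index=design.index), design


def _beta_modes(x):
    kde = st.gaussian_kde(x, bw_method="silverman")
    g = np.linspace(0.001, 0.999, 2001)
    d = kde(g)
    lo, hi = g < 0.5, g > 0.5
    return g[lo][np.argmax(d[lo])], g[hi][np.argmax(d[hi])]


def test_pbc_identity_when_types_agree(rng):
    # identical type I / type II value sets: the rescale factors are exactly 1
    vals = np.concatenate(
        [rng.normal(0.10, 0.05, 500), rng.normal(0.85, 0.05, 500)]
    ).clip(0.01, 0.99)
    betas = pd.DataFrame({"s1": np.concatenate([vals, vals])},
                         index=[f"p{i}" for i in range(2000)])
    design = pd.Series(["I"] * 1000 + ["II"] * 1000, index=betas.index)
    out = peak_based_correction(betas, design)
    assert np.max(np.abs(out["s1"] - betas["s1"])) < 1e-6


def test_pbc_aligns_compressed_type_ii_modes(rng):
    betas, design = _bimodal_betas(rng, compression=0.8)
    out = peak_based_correction(betas, design)
    is2 = (design == "II").to_numpy()
    pre = _beta_modes(betas.loc[is2, "s1"])
    post = _beta_modes(out.loc[is2, "s1"])
    ref = _beta_modes(betas.loc[~is2, "s1"])
    assert max(abs(pre[0] - ref[0]), abs(pre[1] - ref[1])) > 0.05  # bias present
    assert max(abs(post[0] - ref[0]), abs(post[1] - ref[1])) < 0.02


def test_pbc_type_i_bit_identical_and_rank_preserving(rng):
    betas, design = _bimodal_betas(rng, compression=0.8)
    out = peak_based_correction(betas, design)
    is2 = (design == "II").to_numpy()
    assert np.array_equal(
        out.loc[~is2, "s1"].to_numpy(), betas.loc[~is2, "s1"].to_numpy()
    )
    pre = betas.loc[is2, "s1"].rank().to_numpy()
    post = out.loc[is2, "s1"].rank().to_numpy()
    np.testing.assert_allclose(pre, post)


# ---------------------------------------------------------------------------
# log ratio


def test_log_ratio_symmetry_and_limit():
    lr, se = mu_log_ratio(500.0, 500.0)
    assert lr == 0 and se > 0
    a = 100.0
    u = 100_000.0
    lr, _ = mu_log_ratio(2 * u + a, u, offset=a)
    assert lr == pytest.approx(1.0, abs=1e-3)


def test_log_ratio_se_matches_monte_carlo():
    rng = np.random.default_rng(42)
    m_true, u_true, phi = 1500.0, 600.0, 1.0
    n = 10_000
    # channel variance proportional to intensity: Gamma(shape=X*phi, scale=1/phi)
    m = rng.gamma(m_true * phi, 1 / phi, n)
    u = rng.gamma(u_true * phi, 1 / phi, n)
    lr, _ = mu_log_ratio(m, u, offset=0.0, dispersion=phi)
    _, se = mu_log_ratio(m_true, u_true, offset=0.0, dispersion=phi)
    assert abs(lr.std(ddof=1) - se) / se < 0.10


# ---------------------------------------------------------------------------
# moderated differential methylation


def test_diffmeth_all_zero_differences():
    diffs = pd.DataFrame(np.zeros((5, 6)), index=[f"p{i}" for i in range(5)])
    res = weighted_diffmeth(diffs, alpha=0.01)
    assert np.all(res["t"] == 0)
    assert np.all(res["p"] == 1)
    assert set(res["label"]) == {"none"}


def test_diffmeth_no_moderation_equals_paired_t(rng):
    d = rng.normal(0.1, 0.5, size=(200, 10))
    diffs = pd.DataFrame(d, index=[f"p{i}" for i in range(200)])
    res = weighted_diffmeth(diffs, d0_override=0.0)
    # closed-form paired t oracle
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t_oracle = mean / (sd / math.sqrt(10))
    p_oracle = 2 * st.t.sf(np.abs(t_oracle), 9)
    np.testing.assert_allclose(res["t"].to_numpy(), t_oracle, rtol=1e-10)
    np.testing.assert_allclose(res["p"].to_numpy(), p_oracle, rtol=1e-10)


def test_diffmeth_equal_weights_reduce_to_unweighted(rng):
    d = rng.normal(0, 1, size=(50, 8))
    diffs = pd.DataFrame(d)
    ones = pd.DataFrame(np.ones_like(d))
    a = weighted_diffmeth(diffs)
    b = weighted_diffmeth(diffs, weights=ones)
    assert np.array_equal(a["t"].to_numpy(), b["t"].to_numpy())
    assert np.array_equal(a["p"].to_numpy(), b["p"].to_numpy())


def test_diffmeth_requires_two_pairs():
    with pytest.raises(ValueError):
        weighted_diffmeth(pd.DataFrame(np.zeros((3, 1))))


def test_differential_methylation_recovers_planted_shift(rng):
    """A 0.3 beta gain planted at half the probes is called with the right
    sign and magnitude from raw intensities."""
    n_probes, n_pairs = 120, 8
    gain = np.arange(n_probes) < 60
    beta_n = np.full(n_probes, 0.3)
    beta_t = beta_n + np.where(gain, 0.3, 0.0)
    rows = []
    for i in range(n_pairs):
        for sid, beta in ((f"N{i}", beta_n), (f"T{i}", beta_t)):
            b = np.clip(beta + rng.normal(0, 0.02, n_probes), 0, 1)
            total = 2000.0
            rows.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"p{j:03d}" for j in range(n_probes)],
                        "sample_id": sid,
                        "M": total * b,
                        "U": total * (1 - b),
                        "detection_p": 0.001,
                    }
                )
            )
    inten = pd.concat(rows, ignore_index=True)
    pairing = pd.DataFrame(
        {"normal_id": [f"N{i}" for i in range(n_pairs)], "tumour_id": [f"T{i}" for i in range(n_pairs)]}
    )
    res = differential_methylation(inten, pairing)
    assert (res.loc[[f"p{j:03d}" for j in range(60)], "label"] == "gain").all()
    assert (res.loc[[f"p{j:03d}" for j in range(60, 120)], "label"] == "none").mean() > 0.9
    assert res.loc["p000", "delta_beta"] == pytest.approx(0.3, abs=0.05)


# ---------------------------------------------------------------------------
# rank tests


def test_gene_set_exact_matches_enumeration(rng):
    stats_ = rng.normal(size=8)
    mask = np.zeros(8, dtype=bool)
    mask[np.argsort(stats_)[-3:]] = True  # top 3 of 8
    p = gene_set_rank_test(stats_, mask, alternative="greater")
    ranks = st.rankdata(stats_)
    w_obs = ranks[mask].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, 3)]
    p_oracle = np.mean([s >= w_obs for s in sums])
    assert p == pytest.approx(p_oracle)
    assert p == pytest.approx(1 / math.comb(8, 3))


def test_gene_set_degenerate_inputs():
    with pytest.raises(ValueError):
        gene_set_rank_test(np.arange(5), np.ones(5, dtype=bool))
    with pytest.raises(ValueError):
        gene_set_rank_test(np.arange(5), np.zeros(5, dtype=bool))


def test_rank_sum_exact_two_sided():
    w, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
    assert w == 6.0
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements as extreme


def test_rank_sum_identical_multisets():
    _, p = rank_sum_compare([1, 2, 2, 3], [1, 2, 2, 3])
    assert p == 1.0


def test_rank_sum_all_tied_gives_p_one():
    _, p = rank_sum_compare([5.0] * 20, [5.0] * 20)
    assert p == 1.0


def test_rank_sum_large_shift_is_significant(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(2, 1, 200)
    _, p = rank_sum_compare(a, b)
    assert p < 1e-6


def test_bh_adjustment_is_more_conservative(rng):
    d = rng.normal(0.02, 0.3, size=(500, 10))
    diffs = pd.DataFrame(d, index=[f"p{i}" for i in range(500)])
    raw = weighted_diffmeth(diffs, alpha=0.05)
    bh = weighted_diffmeth(diffs, alpha=0.05, adjust="bh")
    n_raw = (raw["label"] != "none").sum()
    n_bh = (bh["label"] != "none").sum()
    assert n_bh <= n_raw
    with pytest.raises(ValueError):
        weighted_diffmeth(diffs, adjust="bonferroni")


def test_moderated_t_matches_limma_reference(tmp_path):
    """Dual-route check of the weighted empirical-Bayes moderated t against
    the reference implementation in Bioconductor limma (via Rscript)."""
    import subprocess

    rng = np.random.default_rng(0)
    n, k = 80, 6
    d = rng.normal(0.05, 0.4, size=(n, k)) * rng.uniform(0.5, 2, size=(n, 1))
    w = rng.uniform(0.5, 2.0, size=(n, k))
    pd.DataFrame(d).to_csv(tmp_path / "D.csv", index=False)
    pd.DataFrame(w).to_csv(tmp_path / "W.csv", index=False)
    (tmp_path / "cmp.R").write_text(
        'suppressMessages(library(limma))\n'
        'D <- as.matrix(read.csv("D.csv")); W <- as.matrix(read.csv("W.csv"))\n'
        "fit <- lmFit(D, design=matrix(1, ncol(D), 1), weights=W)\n"
        "fit <- eBayes(fit)\n"
        'write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1]),'
        ' "limma_out.csv", row.names=FALSE)\n'
    )
    subprocess.run(["Rscript", "cmp.R"], cwd=tmp_path, check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma_out.csv")
    mine = weighted_diffmeth(pd.DataFrame(d), pd.DataFrame(w))
    np.testing.assert_allclose(mine["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-10)
    np.testing.assert_allclose(mine["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-10)
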