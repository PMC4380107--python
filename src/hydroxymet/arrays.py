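"""Infinium-style methylation array processing.

Implements the standard two-channel quantities and tests used for promoter
methylation arrays:

* beta values, beta = M/(U + M), the methylated fraction of total signal;
* a stabilised channel log-ratio log2((M+a)/(U+a)) with a delta-method
  standard error, used as the modelling scale;
* probe filtering on detection p values and manifest flags;
* peak-based correction of the type I / type II design bias, which rescales
  type II M-values so that the unmethylated and methylated density peaks of
  the two chemistries coincide;
* paired differential methylation by weighted least squares with
  empirical-Bayes variance moderation (moderated t statistics);
* mean-rank gene-set tests and Wilcoxon rank-sum comparisons.

The empirical-Bayes step models the per-probe sample variances s^2 as
s0^2 * F(d, d0) under the null; (d0, s0^2) are fitted by matching the mean
and variance of log s^2 to the digamma/trigamma moments of the log scaled-F
distribution, and the posterior variance is the precision-weighted blend
s~^2 = (d0*s0^2 + d*s^2)/(d0 + d) on d0 + d degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "beta_value",
    "filter_probes",
    "peak_based_correction",
    "mu_log_ratio",
    "weighted_diffmeth",
    "differential_methylation",
    "gene_set_rank_test",
    "rank_sum_compare",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


def beta_value(M, U):
    """Methylation fraction M/(U + M); NaN where M + U == 0."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(total > 0, M / total, np.nan)
    return b if b.ndim else float(b)


def filter_probes(
    records: pd.DataFrame, manifest: pd.DataFrame, detection_alpha: float = 0.05
) -> pd.DataFrame:
    """Quality filtering of intensity records.

    Drops individual records with detection_p >= ``detection_alpha`` (strict
    threshold) and removes entirely any probe flagged cross_reactive, snp or
    sex_chrom in the manifest. A record whose probe is absent from the
    manifest is an error.
    """
    flags = manifest.set_index("probe_id")[["cross_reactive", "snp", "sex_chrom"]]
    unknown = set(records["probe_id"]) - set(flags.index)
    if unknown:
        raise ValueError(f"{len(unknown)} probes absent from manifest, e.g. {sorted(unknown)[:3]}")
    bad_probes = flags.index[flags.any(axis=1)]
    out = records[~records["probe_id"].isin(bad_probes)]
    out = out[out["detection_p"] < detection_alpha]
    return out.reset_index(drop=True)


def _beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def _m_to_beta(m: np.ndarray) -> np.ndarray:
    return np.clip(2.0 ** m / (1.0 + 2.0 ** m), 0.0, 1.0)


def _density_modes(m: np.ndarray, grid: np.ndarray):
    """(unmethylated, methylated) density peaks of M-values: the KDE argmax
    below and above M = 0. Returns None when either side is empty."""
    if (m < 0).sum() < 2 or (m > 0).sum() < 2:
        return None
    kde = stats.gaussian_kde(m, bw_method="silverman")
    dens = kde(grid)
    neg, pos = grid < 0, grid > 0
    return grid[neg][np.argmax(dens[neg])], grid[pos][np.argmax(dens[pos])]


def peak_based_correction(
    betas: pd.DataFrame,
    design_types: pd.Series,
    grid_span: float = 8.0,
    grid_points: int = 4001,
) -> pd.DataFrame:
    """Peak-based rescaling of type II betas onto the type I scale, per sample.

    For each sample the beta values of each design type are mapped to
    M-values; the unmethylated (M < 0) and methylated (M > 0) density peaks
    are located by Gaussian KDE (Silverman bandwidth); type II M-values are
    rescaled by separate positive factors on each branch so its two peaks
    land on type I's, then mapped back to beta. Type I probes are returned
    bit-identical. Samples where either type lacks a detectable peak on one
    side of 0 are passed through with a warning.
    """
    types = design_types.reindex(betas.index)
    if types.isna().any():
        raise ValueError("design type missing for some probes")
    for t in ("I", "II"):
        if (types == t).sum() < 50:
            raise ValueError(f"need >= 50 type {t} probes for peak detection")
    is2 = (types == "II").to_numpy()
    grid = np.linspace(-grid_span, grid_span, grid_points)
    out = betas.copy()
    for col in betas.columns:
        b = betas[col].to_numpy(float)
        m1 = _beta_to_m(b[~is2])
        m2 = _beta_to_m(b[is2])
        p1 = _density_modes(m1[np.isfinite(m1)], grid)
        p2 = _density_modes(m2[np.isfinite(m2)], grid)
        if p1 is None or p2 is None:
            logger.warning("sample %s: fewer than two density modes; correction skipped", col)
            continue
        (u1, me1), (u2, me2) = p1, p2
        corrected = m2.copy()
        neg = m2 < 0
        corrected[neg] = m2[neg] * (u1 / u2)
        corrected[~neg] = m2[~neg] * (me1 / me2)
        b2 = _m_to_beta(corrected)
        new = b.copy()
        new[is2] = b2
        out[col] = new
    return out


def beta_density_qc(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    design_types: pd.Series,
    sample: str | None = None,
    grid_points: int = 256,
) -> pd.DataFrame:
    """Beta-density QC table for the peak-based correction: per design type,
    KDE densities before and after correction for one sample (the first
    column by default)."""
    col = sample or pre.columns[0]
    grid = np.linspace(0.001, 0.999, grid_points)
    rows = []
    types = design_types.reindex(pre.index)
    for stage, df in (("pre", pre), ("post", post)):
        for t in ("I", "II"):
            vals = df.loc[(types == t).to_numpy(), col].dropna().to_numpy()
            dens = stats.gaussian_kde(vals, bw_method="silverman")(grid)
            rows.append(
                pd.DataFrame(
                    {"sample_id": col, "stage": stage, "design_type": t,
                     "beta": grid, "density": dens}
                )
            )
    return pd.concat(rows, ignore_index=True)


def mu_log_ratio(M, U, offset: float = 100.0, dispersion: float = 1.0):
    """Stabilised channel log-ratio and its delta-method standard error.

    log_ratio = log2((M + a)/(U + a)) with stabilising offset a. Assuming
    channel variance proportional to intensity, var(X) = X/phi with
    dispersion phi, the delta method gives
    var(log2 X) ~ 1/(X * phi * ln(2)^2), summed over the two channels.
    Returns (log_ratio, se).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    a = offset
    lr = np.log2((M + a) / (U + a))
    var = (1.0 / (M + a) + 1.0 / (U + a)) / (dispersion * LN2 ** 2)
    return lr, np.sqrt(var)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iteration on the log scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: int):
    """Fit (d0, s0^2) so that s2 ~ s0^2 * F(df, d0), by log-moment matching.
    Returns d0 = inf when the observed spread of log s2 is no larger than
    expected from chi-square sampling alone."""
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return math.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0


def weighted_diffmeth(
    diffs: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    alpha: float = 0.01,
    d0_override: float | None = None,
    beta_diffs: pd.DataFrame | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Moderated paired differential methylation.

    ``diffs`` holds per-probe paired differences (tumour - normal), one
    column per pair, on the modelling scale; ``weights`` the matching
    precision weights (1/se^2; all-ones when omitted). Per probe a weighted
    least-squares mean and residual variance are computed, probe variances
    are shrunk toward a common prior fitted across probes
    (empirical Bayes; ``d0_override`` forces the prior degrees of freedom,
    0 = no moderation), and a moderated t with two-sided p on d0 + d df is
    reported. Labels: 'gain' when p < alpha and the mean difference is
    positive, 'loss' when negative, else 'none'.

    ``beta_diffs``, when given, supplies the mean paired beta difference for
    reporting (otherwise the modelling-scale mean is reported as delta_beta).
    """
    d_mat = diffs.to_numpy(float)
    n_probes, n_pairs = d_mat.shape
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    w_mat = np.ones_like(d_mat) if weights is None else weights.to_numpy(float)
    if w_mat.shape != d_mat.shape:
        raise ValueError("weights shape mismatch")
    wsum = w_mat.sum(axis=1)
    mu = (w_mat * d_mat).sum(axis=1) / wsum
    resid = d_mat - mu[:, None]
    df = n_pairs - 1
    s2 = (w_mat * resid ** 2).sum(axis=1) / df
    if d0_override is not None:
        d0 = float(d0_override)
        s0 = 0.0
    else:
        d0, s0 = _fit_f_dist(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / np.sqrt(s2_post / wsum)
    t = np.where((s2_post == 0) & (mu == 0), 0.0, t)  # degenerate all-equal case
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    delta = (
        beta_diffs.to_numpy(float).mean(axis=1) if beta_diffs is not None else mu
    )
    # raw p thresholding by default; Benjamini-Hochberg available as an option
    if adjust is None:
        crit = p
    elif adjust == "bh":
        crit = stats.false_discovery_control(np.clip(p, 0, 1), method="bh")
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    label = np.where(crit < alpha, np.where(delta > 0, "gain", "loss"), "none")
    return pd.DataFrame(
        {
            "probe_id": diffs.index,
            "delta_beta": delta,
            "t": t,
            "p": p,
            "label": label,
        }
    ).set_index("probe_id")


def differential_methylation(
    intensities: pd.DataFrame,
    pairing: pd.DataFrame,
    offset: float = 100.0,
    dispersion: float = 1.0,
    alpha: float = 0.01,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Paired tumour-vs-normal differential methylation from raw intensities.

    ``intensities`` is a long table (probe_id, sample_id, M, U);
    ``pairing`` has normal_id/tumour_id columns. Each probe is modelled on
    the channel log-ratio scale with delta-method precision weights; the
    reported delta_beta is the mean paired beta difference. ``strata``
    (probe_id -> label, e.g. a colour-channel column) splits the probes into
    independently moderated analyses.
    """
    if strata is not None:
        parts = []
        for _, ids in strata.groupby(strata):
            sub = intensities[intensities["probe_id"].isin(ids.index)]
            parts.append(
                differential_methylation(sub, pairing, offset, dispersion, alpha)
            )
        return pd.concat(parts).sort_index()
    lr, se = mu_log_ratio(intensities["M"], intensities["U"], offset, dispersion)
    work = intensities[["probe_id", "sample_id"]].copy()
    work["lr"] = lr
    work["var"] = se ** 2
    work["beta"] = beta_value(intensities["M"].to_numpy(), intensities["U"].to_numpy())
    lr_w = work.pivot(index="probe_id", columns="sample_id", values="lr")
    var_w = work.pivot(index="probe_id", columns="sample_id", values="var")
    beta_w = work.pivot(index="probe_id", columns="sample_id", values="beta")
    normals = pairing["normal_id"].tolist()
    tumours = pairing["tumour_id"].tolist()
    diffs = pd.DataFrame(
        lr_w[tumours].to_numpy() - lr_w[normals].to_numpy(), index=lr_w.index
    )
    weights = pd.DataFrame(
        1.0 / (var_w[tumours].to_numpy() + var_w[normals].to_numpy()), index=lr_w.index
    )
    beta_diffs = pd.DataFrame(
        beta_w[tumours].to_numpy() - beta_w[normals].to_numpy(), index=beta_w.index
    )
    keep = diffs.notna().all(axis=1)
    return weighted_diffmeth(
        diffs[keep], weights[keep], alpha=alpha, beta_diffs=beta_diffs[keep]
    )


# ---------------------------------------------------------------------------
# Rank tests


def _ranksum_p(ranks: np.ndarray, in_set: np.ndarray, alternative: str, exact: bool):
    """P value for the rank-sum of the flagged subset within pooled ranks."""
    n = len(ranks)
    n_set = int(in_set.sum())
    w = float(ranks[in_set].sum())
    e_w = n_set * (n + 1) / 2.0
    if exact:
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, n_set)], dtype=float
        )
        if alternative == "greater":
            p = float((sums >= w - 1e-9).mean())
        elif alternative == "less":
            p = float((sums <= w + 1e-9).mean())
        else:
            p = float((np.abs(sums - e_w) >= abs(w - e_w) - 1e-9).mean())
        return w, min(p, 1.0)
    # tie-corrected normal approximation with continuity correction
    n_comp = n - n_set
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_w = n_set * n_comp / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    sd = math.sqrt(var_w)
    if alternative == "greater":
        p = stats.norm.sf((w - e_w - 0.5) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((w - e_w + 0.5) / sd)
    else:
        p = 2.0 * stats.norm.sf((abs(w - e_w) - 0.5) / sd)
    return w, float(min(max(p, 0.0), 1.0))


def gene_set_rank_test(
    statistics: np.ndarray | pd.Series,
    in_set: np.ndarray | pd.Series,
    alternative: str = "two-sided",
    exact_limit: int = 10,
) -> float:
    """Mean-rank gene-set test.

    Tests whether the probes in the set have systematically larger
    (``alternative='greater'``), smaller ('less') or different ('two-sided')
    statistics than the rest, via the Wilcoxon rank-sum equivalence of the
    mean-rank statistic. Exact by enumeration of all same-size subsets when
    both the set and its complement have <= ``exact_limit`` members;
    otherwise a tie-corrected continuity-corrected normal approximation.
    """
    stat = np.asarray(statistics, dtype=float)
    mask = np.asarray(in_set, dtype=bool)
    n_set = int(mask.sum())
    if n_set == 0:
        raise ValueError("gene set is empty")
    if n_set == len(stat):
        raise ValueError("gene set equals the probe universe")
    ranks = stats.rankdata(stat)
    exact = n_set <= exact_limit and (len(stat) - n_set) <= exact_limit
    _, p = _ranksum_p(ranks, mask, alternative, exact)
    return p


def rank_sum_compare(
    group_a: np.ndarray, group_b: np.ndarray, alternative: str = "two-sided"
):
    """Two-sample Wilcoxon rank-sum comparison.

    Exact enumeration when the pooled size is <= 12, otherwise tie-corrected
    normal approximation with continuity correction. Returns
    (rank-sum of group A, p). All values tied across both groups gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mask = np.zeros(len(pooled), dtype=bool)
    mask[: len(a)] = True
    if np.all(pooled == pooled[0]):
        return float(ranks[mask].sum()), 1.0
    exact = len(pooled) <= 12
    return _ranksum_p(ranks, mask, alternative, exact)
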