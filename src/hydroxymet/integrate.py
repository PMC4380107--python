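"""Cross-analysis statistics linking 5hmC content, methylation change,
TET2 binding and bivalency.

These are the set-level statistics that carry the biological claims: the
top/bottom ranking of array loci by promoter 5hmC content, the gain/loss
split of significant methylation changes within each set, the binomial
depletion test for overlap between TET2-bound promoters and
methylation-gain promoters, the three-way Venn of 5hmC / bivalent / gain
promoter sets, and the fraction of bisulfite-resistant signal attributable
to 5hmC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .coverage import _in_intervals, _merged_membership

__all__ = [
    "CrossTab",
    "OverlapResult",
    "VennCounts",
    "select_high_low_5hmc_loci",
    "crosstab_5hmc_methylation",
    "tet2_target_promoters",
    "overlap_depletion_test",
    "venn_three_way",
    "hmc_fraction_of_bisulfite_signal",
    "persistent_5hmc_crosstab",
]


@dataclass
class CrossTab:
    n_selected: int
    n_significant: int
    n_gain: int
    n_loss: int

    def __post_init__(self) -> None:
        if self.n_gain + self.n_loss != self.n_significant:
            raise ValueError("gain + loss must equal significant count")

    @property
    def prop_gain(self) -> float | None:
        return None if self.n_significant == 0 else round(self.n_gain / self.n_significant, 3)

    @property
    def prop_loss(self) -> float | None:
        return None if self.n_significant == 0 else round(self.n_loss / self.n_significant, 3)

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_significant": self.n_significant,
            "n_gain": self.n_gain,
            "n_loss": self.n_loss,
            "prop_gain": self.prop_gain,
            "prop_loss": self.prop_loss,
        }


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    expected: float
    p_depletion: float
    p_enrichment: float

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_overlap": self.n_overlap,
            "universe": self.universe,
            "expected": self.expected,
            "p_depletion": self.p_depletion,
            "p_enrichment": self.p_enrichment,
        }


@dataclass
class VennCounts:
    """Counts of the 7 regions of three sets plus the outside remainder."""

    regions: dict[str, int]
    fraction_gain_bivalent: float | None
    fraction_hmc_bivalent: float | None

    def to_dict(self) -> dict:
        return {
            "regions": self.regions,
            "fraction_gain_bivalent": self.fraction_gain_bivalent,
            "fraction_hmc_bivalent": self.fraction_hmc_bivalent,
        }


def select_high_low_5hmc_loci(
    probe_counts: pd.Series, top_n: int, low_floor: float | None = None
):
    """Top-N loci by 5hmC read content ('high') and the low/undetected set.

    By default 'low' is the bottom-N ranking (zeros first, ties by
    probe_id) over the loci not already selected as high, so the two sets
    are disjoint even under heavy count ties; with ``low_floor`` set it is
    instead every locus with count strictly below the floor.
    """
    n = len(probe_counts)
    if 2 * top_n > n and low_floor is None:
        raise ValueError(f"2*top_n = {2 * top_n} exceeds the {n} available probes")
    df = probe_counts.rename("count").rename_axis("probe_id").reset_index()
    high = set(
        df.sort_values(["count", "probe_id"], ascending=[False, True]).head(top_n)["probe_id"]
    )
    if low_floor is None:
        rest = df[~df["probe_id"].isin(high)]
        low = set(
            rest.sort_values(["count", "probe_id"], ascending=[True, True]).head(top_n)["probe_id"]
        )
    else:
        low = set(df.loc[df["count"] < low_floor, "probe_id"])
        if high & low:
            raise ValueError("high and low locus sets overlap")
    return high, low


def crosstab_5hmc_methylation(locus_set: set, diffmeth: pd.DataFrame) -> CrossTab:
    """Gain/loss split of significant methylation changes within a locus set.

    ``diffmeth`` is indexed by probe_id with a 'label' column
    (gain|loss|none). Proportions are reported to 3 decimals and are missing
    when no probe in the set is significant.
    """
    if not locus_set:
        raise ValueError("empty locus set")
    sub = diffmeth.loc[diffmeth.index.isin(locus_set)]
    n_gain = int((sub["label"] == "gain").sum())
    n_loss = int((sub["label"] == "loss").sum())
    return CrossTab(
        n_selected=len(locus_set),
        n_significant=n_gain + n_loss,
        n_gain=n_gain,
        n_loss=n_loss,
    )


def tet2_target_promoters(
    peaks: pd.DataFrame, genes: list[GeneModel], flank: int = 1000
) -> set[str]:
    """Promoters whose TSS +- flank window overlaps at least one peak by
    >= 1 bp. ``peaks`` needs chrom/start/end columns."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in peaks.itertuples():
        by_chrom.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
    merged = {c: _merged_membership(iv) for c, iv in by_chrom.items()}
    targets = set()
    for g in genes:
        starts, ends = merged.get(g.interval.chrom, (np.empty(0), np.empty(0)))
        if starts.size == 0:
            continue
        lo, hi = g.tss - flank, g.tss + flank
        # any merged peak with start < hi and end > lo
        idx = np.searchsorted(ends, lo, side="right")
        if idx < len(starts) and starts[idx] < hi:
            targets.add(g.gene_id)
    return targets


def overlap_depletion_test(
    set_a: set, set_b: set, universe: set, model: str = "binomial"
) -> OverlapResult:
    """Depletion/enrichment of |A intersect B| under a null where each of
    A's members lands in B independently with probability |B|/|universe|
    (``model='binomial'``) or by sampling without replacement
    (``model='hypergeometric'``).

    p_depletion = P(overlap <= observed); p_enrichment = P(>= observed).
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    n_a, n_b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    q = n_b / n
    if model == "binomial":
        p_dep = float(stats.binom.cdf(k, n_a, q))
        p_enr = float(stats.binom.sf(k - 1, n_a, q))
    elif model == "hypergeometric":
        p_dep = float(stats.hypergeom.cdf(k, n, n_b, n_a))
        p_enr = float(stats.hypergeom.sf(k - 1, n, n_b, n_a))
    else:
        raise ValueError(f"unknown null model {model!r}")
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_overlap=k,
        universe=n,
        expected=n_a * n_b / n,
        p_depletion=min(p_dep, 1.0),
        p_enrichment=min(p_enr, 1.0),
    )


def venn_three_way(
    set_hmc: set, set_bivalent: set, set_gain: set, universe: set
) -> VennCounts:
    """Three-way Venn counts over a shared gene-id universe, with the two
    headline fractions: bivalent share of methylation-gain promoters and
    bivalent share of 5hmC promoters."""
    a, b, c = set_hmc & universe, set_bivalent & universe, set_gain & universe
    regions = {
        "hmc_only": len(a - b - c),
        "bivalent_only": len(b - a - c),
        "gain_only": len(c - a - b),
        "hmc_bivalent": len((a & b) - c),
        "hmc_gain": len((a & c) - b),
        "bivalent_gain": len((b & c) - a),
        "all_three": len(a & b & c),
        "outside": len(universe - a - b - c),
    }
    fg = len(c & b) / len(c) if c else None
    fh = len(a & b) / len(a) if a else None
    return VennCounts(regions=regions, fraction_gain_bivalent=fg, fraction_hmc_bivalent=fh)


def hmc_fraction_of_bisulfite_signal(pct_hmc: float, pct_mc: float) -> float:
    """Fraction of combined bisulfite-resistant signal attributable to 5hmC:
    pct_hmC / (pct_hmC + pct_mC). Bisulfite-based assays read 5hmC as 5mC,
    so this is the share of apparent methylation that is actually
    hydroxymethylation."""
    if pct_hmc < 0 or pct_mc < 0:
        raise ValueError("percentages must be >= 0")
    if pct_hmc + pct_mc == 0:
        raise ValueError("at least one percentage must be positive")
    return pct_hmc / (pct_hmc + pct_mc)


def persistent_5hmc_crosstab(
    tumour_counts: pd.Series,
    promoter_labels: pd.DataFrame,
    detect_floor: float = 1.0,
) -> dict:
    """Methylation gain/loss fractions among promoters where tumour 5hmC is
    still detected (count >= ``detect_floor``).

    ``tumour_counts`` maps gene_id -> tumour probe-window 5hmC signal;
    ``promoter_labels`` is indexed by gene_id with boolean 'gain' and 'loss'
    columns. Fractions use the persistent-set size as denominator.
    """
    persistent = set(tumour_counts.index[tumour_counts >= detect_floor])
    n = len(persistent)
    if n == 0:
        return {"n_persistent": 0, "n_gain": 0, "n_loss": 0, "frac_gain": None, "frac_loss": None}
    sub = promoter_labels.loc[promoter_labels.index.isin(persistent)]
    n_gain = int(sub["gain"].sum())
    n_loss = int(sub["loss"].sum())
    return {
        "n_persistent": n,
        "n_gain": n_gain,
        "n_loss": n_loss,
        "frac_gain": round(n_gain / n, 3),
        "frac_loss": round(n_loss / n, 3),
    }
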