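"""Population summaries and group comparisons for per-cell mRNA counts.

Summaries follow the conventions of the smFISH figures they feed: the
fraction of qc-pass cells expressing at least one mature mRNA, the median
count among expressors, transcription-site activity and bi-allelic fraction
among transcribing cells, single/double-positive classification across the
two probed transcripts, and the per-cell cytoplasm:nucleus log-ratio with a
0.5 pseudocount so zero counts stay finite.

Group comparisons use the Kruskal-Wallis omnibus test with post hoc
Tukey-HSD applied to rank-transformed values (Dunn's test available as the
conventional alternative), and a two-tailed ratio t-test (t-test on
log-transformed values) for two-group designs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("smfish3d")


# ---------------------------------------------------------------------------
# per-cell quantities
# ---------------------------------------------------------------------------

def classify_sp_dp(mature_ch1: int, mature_ch2: int,
                   names: tuple[str, str] = ("RNA1", "RNA2")) -> str:
    """DN / SP_<ch> / DP classification from the two channels' mature counts."""
    if mature_ch1 < 0 or mature_ch2 < 0:
        raise ValueError("counts must be nonnegative")
    if mature_ch1 >= 1 and mature_ch2 >= 1:
        return "DP"
    if mature_ch1 >= 1:
        return f"SP_{names[0]}"
    if mature_ch2 >= 1:
        return f"SP_{names[1]}"
    return "DN"


def cyto_nuc_log_ratio(cyto: int, nuc: int, pseudocount: float = 0.5) -> float:
    """log10((C + p) / (N + p)); equal distribution maps to 0.

    Intended for cells with at least one mature mRNA; zero-count cells are
    excluded upstream.
    """
    if cyto < 0 or nuc < 0:
        raise ValueError("counts must be nonnegative")
    if cyto + nuc == 0:
        # pseudocounts cancel; defined for completeness but flagged upstream
        return 0.0
    return math.log10((cyto + pseudocount) / (nuc + pseudocount))


def pct_cytoplasmic(cyto: int, nuc: int) -> float:
    """Percentage of a cell's mature mRNA located in the cytoplasm."""
    total = cyto + nuc
    if total <= 0:
        raise ValueError("cell has no mature mRNA")
    return 100.0 * cyto / total


# ---------------------------------------------------------------------------
# population summary
# ---------------------------------------------------------------------------

def summarize_population(
    cell_table: pd.DataFrame,
    grouping: str | None = None,
    channels: tuple[str, ...] = ("RNA1", "RNA2"),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """One summary row per (group, channel) over qc-pass cells.

    Medians are computed only over the stated subpopulation: mature counts
    over expressors (>= 1 mature mRNA), nascent counts over active sites,
    the bi-allelic percentage over transcribing cells.  Empty groups yield
    n = 0 with missing medians.
    """
    df = cell_table.copy()
    if grouping is None:
        df["_group"] = "all"
        grouping = "_group"
    rows = []
    for group, gdf in df.groupby(grouping, sort=True):
        passing = gdf[gdf["qc_pass"].astype(bool)]
        for ch in channels:
            total = passing[f"{ch}_mature_total"]
            expressing = passing[total >= 1]
            n_tsx = passing[f"{ch}_n_tsx"]
            transcribing = passing[n_tsx >= 1]
            nascent = transcribing[f"{ch}_nascent_total"]
            row = {
                "group": group, "channel": ch,
                "n_cells_pass_qc": int(len(passing)),
                "pct_expressing": (100.0 * len(expressing) / len(passing)
                                   if len(passing) else np.nan),
                "median_mature_per_expressor": (
                    float(expressing[f"{ch}_mature_total"].median())
                    if len(expressing) else np.nan),
                "pct_cells_with_active_tsx": (
                    100.0 * len(transcribing) / len(passing)
                    if len(passing) else np.nan),
                "median_nascent_per_tsx": (
                    float((nascent / transcribing[f"{ch}_n_tsx"]).median())
                    if len(transcribing) else np.nan),
                "pct_biallelic_among_transcribing": (
                    100.0 * (transcribing[f"{ch}_allelic_state"] == "bi").mean()
                    if len(transcribing) else np.nan),
                "median_pct_cytoplasmic": (
                    float(np.median([
                        pct_cytoplasmic(c, n) for c, n in zip(
                            expressing[f"{ch}_mature_cytoplasmic"],
                            expressing[f"{ch}_mature_nuclear"])
                    ])) if len(expressing) else np.nan),
                "median_cyto_nuc_log_ratio": (
                    float(np.median([
                        cyto_nuc_log_ratio(c, n, pseudocount) for c, n in zip(
                            expressing[f"{ch}_mature_cytoplasmic"],
                            expressing[f"{ch}_mature_nuclear"])
                    ])) if len(expressing) else np.nan),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def add_per_cell_stats(cell_table: pd.DataFrame,
                       channels: tuple[str, str] = ("RNA1", "RNA2"),
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Append sp_dp_class and per-channel localization ratios to a cell table."""
    out = cell_table.copy()
    out["sp_dp_class"] = [
        classify_sp_dp(a, b, channels)
        for a, b in zip(out[f"{channels[0]}_mature_total"],
                        out[f"{channels[1]}_mature_total"])
    ]
    for ch in channels:
        c = out[f"{ch}_mature_cytoplasmic"]
        n = out[f"{ch}_mature_nuclear"]
        expressed = (c + n) >= 1
        out[f"{ch}_cyto_nuc_log_ratio"] = [
            cyto_nuc_log_ratio(ci, ni, pseudocount) if e else np.nan
            for ci, ni, e in zip(c, n, expressed)
        ]
        out[f"{ch}_pct_cytoplasmic"] = [
            pct_cytoplasmic(ci, ni) if e else np.nan
            for ci, ni, e in zip(c, n, expressed)
        ]
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Omnibus and pairwise results of a multi-group comparison."""

    omnibus_test: str
    statistic: float
    p_value: float
    posthoc_method: str
    pairwise: pd.DataFrame  # group_a, group_b, p_value (+ estimate columns)


def _tukey_on_ranks(values_by_group: dict) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names, pooled = [], []
    for g, vals in values_by_group.items():
        names.extend([str(g)] * len(vals))
        pooled.extend(vals)
    ranks = sps.rankdata(pooled)
    res = pairwise_tukeyhsd(ranks, names)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return pd.DataFrame({
        "group_a": frame["group1"], "group_b": frame["group2"],
        "p_value": frame["p-adj"].astype(float),
        "mean_rank_diff": frame["meandiff"].astype(float),
    })


def _dunn(values_by_group: dict) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with Bonferroni adjustment."""
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in groups])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in groups:
        k = len(values_by_group[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            se = math.sqrt(
                (n * (n + 1) / 12.0 - tie_term)
                * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
            rows.append({"group_a": str(a), "group_b": str(b),
                         "p_value": p, "z": z})
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: dict,
    posthoc: str = "tukey_ranks",
    min_group_size: int = 3,
) -> ComparisonReport:
    """Kruskal-Wallis omnibus test with post hoc pairwise comparisons.

    ``posthoc`` is "tukey_ranks" (Tukey-HSD on rank-transformed values) or
    "dunn" (Dunn's z-tests, Bonferroni-adjusted).  With exactly two groups
    of positive values, use :func:`ratio_t_test` for the ratio t-test
    instead.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for g, vals in values_by_group.items():
        if len(vals) < min_group_size:
            raise ValueError(
                f"group {g!r} has {len(vals)} values; need >= {min_group_size}")
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    stat, p = sps.kruskal(*arrays)
    if posthoc == "tukey_ranks":
        pairwise = _tukey_on_ranks(values_by_group)
        method = "Tukey-HSD on rank-transformed values"
    elif posthoc == "dunn":
        pairwise = _dunn(values_by_group)
        method = "Dunn's test, Bonferroni-adjusted"
    else:
        raise ValueError(f"unknown posthoc method {posthoc!r}")
    return ComparisonReport(
        omnibus_test="Kruskal-Wallis", statistic=float(stat),
        p_value=float(p), posthoc_method=method, pairwise=pairwise,
    )


def ratio_t_test(a, b, paired: bool = False) -> dict:
    """Two-tailed ratio Student's t-test: a t-test on log-transformed values.

    Suitable for strictly positive measurements compared as fold changes
    between two groups.  Returns the t statistic, p value and the geometric
    mean ratio a/b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ratio t-test requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length samples")
        t, p = sps.ttest_rel(la, lb)
    else:
        t, p = sps.ttest_ind(la, lb)
    return {
        "test": "two-tailed ratio t-test (t-test on log values)",
        "paired": paired,
        "t": float(t), "p_value": float(p),
        "geometric_mean_ratio": float(np.exp(la.mean() - lb.mean())),
    }
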