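"""Group- and pair-level statistics for duplicate retention analyses.

Covers the singleton / SSD / WGD contrasts (rank-sum tests with
Benjamini–Hochberg adjustment and Cliff's delta effect sizes), the
within-pair min/max decomposition, selection of the most
NEV-divergent pairs, the transcription-factor contingency analysis,
and the derived/ancestral age-asymmetry analysis based on
phylostratigraphic clade numbers (higher clade = younger stratum =
inferred derived copy).

All operations accept any per-gene score, not just NEV, so controls
that swap NEV for e.g. mean expression level reuse the same code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ParalogTable

__all__ = [
    "GroupComparison",
    "cliffs_delta",
    "cliffs_delta_ci",
    "compare_groups",
    "pair_scores",
    "pair_min_max",
    "select_top_divergent",
    "tf_contingency",
    "pair_divergence",
    "age_asymmetry",
    "validate_synteny_orientation",
]

logger = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Cliff's delta
# ---------------------------------------------------------------------------


def cliffs_delta(x, y) -> float:
    """Cliff's delta = (#{x > y} − #{x < y}) / (n·m), in [−1, 1].

    Computed in O((n+m) log(n+m)) via sorted ranks; equals the
    brute-force double loop exactly (ties contribute 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("cliffs_delta needs non-empty samples")
    ys = np.sort(y)
    less = np.searchsorted(ys, x, side="left")      # y strictly below each x
    greater = m - np.searchsorted(ys, x, side="right")
    return float((less.sum() - greater.sum()) / (n * m))


def _dominance_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row means d_i. (over y) and column means d_.j (over x) of sign(x−y)."""
    ys = np.sort(y)
    di = (np.searchsorted(ys, x, "left") - (y.size - np.searchsorted(ys, x, "right"))) / y.size
    xs = np.sort(x)
    dj = ((x.size - np.searchsorted(xs, y, "right")) - np.searchsorted(xs, y, "left")) / x.size
    return di, dj


def cliffs_delta_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """(delta, lower, upper) with the consistent variance estimator.

    Variance follows Cliff (1996): combines the between-row, between-
    column and cell variances of the dominance matrix.  The interval is
    the asymmetric (Fisher-z-style) transform with a normal critical
    value; degenerate samples (|delta| = 1 or zero variance) return a
    point interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    d = cliffs_delta(x, y)
    di, dj = _dominance_rows(x, y)
    # E[d_ij^2] via tie counts: d_ij^2 = 1 unless x_i == y_j
    ys = np.sort(y)
    ties = (np.searchsorted(ys, x, "right") - np.searchsorted(ys, x, "left")).sum()
    sum_dij2 = n * m - ties
    s_di = np.sum((di - d) ** 2)
    s_dj = np.sum((dj - d) ** 2)
    sum_dev2 = sum_dij2 - 2 * d * (n * m * d) + n * m * d * d  # Σ(d_ij − d)²
    if n < 2 or m < 2:
        return d, -1.0, 1.0
    var = (m * m * s_di + n * n * s_dj - sum_dev2) / (n * m * (n - 1) * (m - 1))
    var = max(var, 0.0)
    z = sps.norm.ppf(0.5 + level / 2)
    if var == 0.0 or abs(d) == 1.0:
        return d, d, d
    denom = 1 - d * d + z * z * var
    half = z * math.sqrt(var) * math.sqrt((1 - d * d) ** 2 + z * z * var)
    lower = (d - d ** 3 - half) / denom
    upper = (d - d ** 3 + half) / denom
    return d, float(max(lower, -1.0)), float(min(upper, 1.0))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    p: float
    p_adjusted: float
    delta: float
    delta_low: float
    delta_high: float
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_groups(scores: pd.Series, groups: pd.Series,
                   label_pairs: list[tuple[str, str]],
                   adjust: str = "fdr_bh") -> list[GroupComparison]:
    """Rank-sum contrasts with Cliff's delta for each label pair.

    ``scores`` is any per-gene score (NEV, expression level, ...);
    ``groups`` maps gene → group label.  Each contrast uses the
    two-sided Mann–Whitney/Wilcoxon rank-sum test; p-values are
    adjusted across the tested pairs (Benjamini–Hochberg by default,
    ``adjust='holm'`` available).
    """
    df = pd.concat({"score": scores, "group": groups}, axis=1, join="inner").dropna()
    samples = {}
    for a, b in label_pairs:
        for label in (a, b):
            if label not in samples:
                vals = df.loc[df["group"] == label, "score"].to_numpy()
                if vals.size < 2:
                    raise ValueError(f"group {label!r} has < 2 scored genes")
                samples[label] = vals
    results = []
    raw_p = []
    for a, b in label_pairs:
        x, y = samples[a], samples[b]
        stat = sps.mannwhitneyu(x, y, alternative="two-sided")
        d, lo, hi = cliffs_delta_ci(x, y)
        raw_p.append(stat.pvalue)
        results.append(GroupComparison(a, b, x.size, y.size,
                                       float(stat.pvalue), np.nan, d, lo, hi))
    adj = multipletests(raw_p, method=adjust)[1]
    for res, pa in zip(results, adj):
        res.p_adjusted = float(pa)
    return results


# ---------------------------------------------------------------------------
# Pair-level operations
# ---------------------------------------------------------------------------


def pair_scores(scores: pd.Series, pairs: ParalogTable) -> pd.DataFrame:
    """Per-pair score table with divergence columns.

    Columns: gene_a/gene_b, mode, score_a/score_b, abs_dscore, dscore
    (= score_a − score_b).  Pairs with a missing score are excluded and
    counted in the ``n_excluded`` attribute of the returned frame.
    """
    df = pairs.pairs.copy()
    df["score_a"] = df["gene_a"].map(scores)
    df["score_b"] = df["gene_b"].map(scores)
    keep = df["score_a"].notna() & df["score_b"].notna()
    n_excluded = int((~keep).sum())
    out = df[keep].copy()
    out["dscore"] = out["score_a"] - out["score_b"]
    out["abs_dscore"] = out["dscore"].abs()
    out["pair_id"] = out["gene_a"] + "|" + out["gene_b"]
    out = out.reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def pair_min_max(scores: pd.Series, pairs: ParalogTable
                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Within-pair decomposition into the lower- and higher-scoring copy.

    Returns the per-pair table plus the pooled min-group and max-group
    samples (one value per pair each), for three-way comparison against
    singletons.
    """
    ps = pair_scores(scores, pairs)
    ps["score_min"] = ps[["score_a", "score_b"]].min(axis=1)
    ps["score_max"] = ps[["score_a", "score_b"]].max(axis=1)
    return ps, ps["score_min"].to_numpy(), ps["score_max"].to_numpy()


def select_top_divergent(pair_table: pd.DataFrame, fraction: float = 0.05,
                         by_mode_class: bool = True) -> pd.DataFrame:
    """Most score-divergent pairs, deduplicated so no gene repeats.

    Takes the output of :func:`pair_scores`.  Within each duplication
    class (SSD pooled vs WGD by default; per mode when
    ``by_mode_class=False``), keeps the floor(fraction × n) pairs with
    the largest |Δscore| (ties broken by pair id), then greedily drops,
    in descending |Δscore| order, any pair re-using an already selected
    gene.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    df = pair_table.copy()
    df["dup_class"] = np.where(df["mode"] == "wgd", "wgd", "ssd") \
        if by_mode_class else df["mode"]
    chunks = []
    for _, grp in df.groupby("dup_class", sort=True):
        grp = grp.sort_values(["abs_dscore", "pair_id"],
                              ascending=[False, True], kind="mergesort")
        k = math.floor(fraction * len(grp))
        top = grp.head(k)
        seen: set[str] = set()
        keep_rows = []
        for _, row in top.iterrows():
            if row["gene_a"] in seen or row["gene_b"] in seen:
                continue
            seen.update((row["gene_a"], row["gene_b"]))
            keep_rows.append(row)
        if keep_rows:
            chunks.append(pd.DataFrame(keep_rows))
    if not chunks:
        return df.iloc[0:0]
    return pd.concat(chunks).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Transcription-factor contingency
# ---------------------------------------------------------------------------


def tf_contingency(pairs: ParalogTable, meta: pd.DataFrame,
                   pool_ssd: bool = True) -> tuple[pd.DataFrame, float, float, int]:
    """TF vs non-TF pair counts by duplication class, with chi-squared.

    A pair is a TF pair when both members are TFs and a non-TF pair
    when neither is; mixed pairs are rare and excluded (their count is
    returned).  Pearson chi-squared without continuity correction;
    classes with zero pairs are dropped with a logged note, and a
    warning is logged when any expected cell falls below 1 (the
    statistic is still returned).

    Returns (counts table, chi2, p, n_mixed_excluded).
    """
    df = pairs.pairs.copy()
    is_tf = meta["is_tf"]
    tf_a = df["gene_a"].map(is_tf)
    tf_b = df["gene_b"].map(is_tf)
    both = tf_a.astype(bool) & tf_b.astype(bool)
    neither = ~tf_a.astype(bool) & ~tf_b.astype(bool)
    mixed = ~(both | neither)
    n_mixed = int(mixed.sum())
    df = df[~mixed].copy()
    df["pair_tf"] = np.where(both[~mixed], "tf", "non_tf")
    df["dup_class"] = np.where(df["mode"] == "wgd", "wgd", "ssd") \
        if pool_ssd else df["mode"]
    counts = pd.crosstab(df["pair_tf"], df["dup_class"])
    empty = [c for c in counts.columns if counts[c].sum() == 0]
    if empty:
        logger.info("dropping duplication classes with no pairs: %s", empty)
        counts = counts.drop(columns=empty)
    if counts.shape[1] < 2:
        raise ValueError("need at least two duplication classes with pairs")
    counts = counts.reindex(index=["tf", "non_tf"], fill_value=0)
    chi2, p, _, expected = sps.chi2_contingency(counts.to_numpy(),
                                                correction=False)
    if (expected < 1).any():
        logger.warning("chi-squared expected cell below 1; statistic unreliable")
    return counts, float(chi2), float(p), n_mixed


# ---------------------------------------------------------------------------
# Age asymmetry (derived vs ancestral)
# ---------------------------------------------------------------------------


def pair_divergence(scores: pd.Series, pairs: ParalogTable,
                    clades: pd.Series) -> pd.DataFrame:
    """Per-pair ΔNEV and ΔClade table (A − B, arbitrary orientation)."""
    ps = pair_scores(scores, pairs)
    ps["clade_a"] = ps["gene_a"].map(clades)
    ps["clade_b"] = ps["gene_b"].map(clades)
    ps["dclade"] = ps["clade_a"] - ps["clade_b"]
    return ps


def age_asymmetry(divergence: pd.DataFrame, modes=None,
                  low_power_threshold: int = 10) -> dict:
    """Derived/ancestral score asymmetry from clade numbers.

    Pairs with missing or zero ΔClade are excluded (equal clades carry
    no derived/ancestral signal).  Each remaining pair is oriented so
    the copy with the higher clade number (younger stratum, inferred
    derived) comes first; the derived-vs-ancestral comparison is a
    two-sided paired Wilcoxon signed-rank test on the scores, reported
    with the median paired difference.  The ΔClade–Δscore association
    is the Spearman correlation over both orientations of every pair,
    which makes it exactly invariant to the arbitrary A/B labelling.
    """
    df = divergence
    if modes is not None:
        df = df[df["mode"].isin(set(modes))]
    usable = df["dclade"].notna() & (df["dclade"] != 0)
    df = df[usable]
    n = len(df)
    out = {"n_pairs": n, "low_power": n < low_power_threshold,
           "n_excluded_tied_or_missing": int((~usable).sum())}
    if n == 0:
        raise ValueError("no usable pairs (all ΔClade missing or zero)")
    flip = df["dclade"] < 0
    derived = np.where(flip, df["score_b"], df["score_a"])
    ancestral = np.where(flip, df["score_a"], df["score_b"])
    diff = derived - ancestral
    out["median_paired_diff"] = float(np.median(diff))
    if np.all(diff == 0):
        out["wilcoxon_p"] = 1.0
    else:
        out["wilcoxon_p"] = float(
            sps.wilcoxon(derived, ancestral, alternative="two-sided").pvalue)
    dc = np.concatenate([df["dclade"], -df["dclade"]])
    dn = np.concatenate([df["dscore"], -df["dscore"]])
    rho, rho_p = sps.spearmanr(dc, dn)
    out["spearman_rho"] = float(rho)
    out["spearman_p"] = float(rho_p)
    return out


def validate_synteny_orientation(pairs: ParalogTable, clades: pd.Series,
                                 alternative: str = "greater") -> dict:
    """Check that synteny-defined daughter loci sit in younger strata.

    Uses pairs (typically transposed duplicates) whose parent/daughter
    orientation is annotated.  Paired Wilcoxon signed-rank of daughter
    clade vs parent clade, one-sided (daughter > parent) by default;
    equal-clade pairs drop out per the signed-rank convention and the
    effective n is reported.
    """
    df = pairs.pairs
    df = df[df["orientation"].isin({"A_is_parent", "B_is_parent"})].copy()
    if df.empty:
        raise ValueError("no pairs with parent/daughter orientation labels")
    df["clade_a"] = df["gene_a"].map(clades)
    df["clade_b"] = df["gene_b"].map(clades)
    df = df.dropna(subset=["clade_a", "clade_b"])
    parent = np.where(df["orientation"] == "A_is_parent",
                      df["clade_a"], df["clade_b"])
    daughter = np.where(df["orientation"] == "A_is_parent",
                        df["clade_b"], df["clade_a"])
    nonzero = daughter != parent
    n_used = int(nonzero.sum())
    if n_used == 0:
        return {"n_pairs": len(df), "n_used": 0, "p": 1.0,
                "median_diff": 0.0}
    res = sps.wilcoxon(daughter[nonzero], parent[nonzero],
                       alternative=alternative)
    return {"n_pairs": len(df), "n_used": n_used, "p": float(res.pvalue),
            "median_diff": float(np.median(daughter - parent))}
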