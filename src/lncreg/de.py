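"""Gene-level differential expression with dual-method confirmation.

Two independent tests per feature and comparison: a negative-binomial Wald
test (median-of-ratios library normalization, method-of-moments common-trend
dispersion) and an exact two-sided Wilcoxon rank-sum test on FPKM. P-values
are Benjamini-Hochberg adjusted within each comparison, and a feature is
called differentially expressed only when *both* methods pass
(q < 0.01 for each) and |log2FC| > 1. Features significant against both
other tissues with a consistent sign form the three tissue-specific profile
groups T/(E+DD), E/(T+DD) and DD/(T+E).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, ExpressionMatrix, ValidationError

COMPARISONS = ("E_vs_T", "DD_vs_T", "E_vs_DD")

DEFAULT_Q = 0.01
DEFAULT_MIN_ABS_LOG2FC = 1.0
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DeResult:
    feature_id: str
    comparison: str
    log2fc: float           # group1 over group2
    p_primary: float
    p_secondary: float
    q_primary: float
    q_secondary: float
    confirmed_both: bool
    direction: str          # up | down
    is_de: bool


# ---------------------------------------------------------------------------
# normalization and dispersion


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors; falls back to total-count ratios when no
    feature is positive in every sample."""
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.sum() >= 1:
        logg = np.log(counts[allpos])
        ref = logg.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logg - ref, axis=0))
    else:
        tot = counts.sum(axis=0)
        sf = tot / np.exp(np.log(np.clip(tot, 1e-12, None)).mean())
    sf = np.where(sf <= 0, 1.0, sf)  # empty samples: leave counts unscaled
    return sf / np.exp(np.log(sf).mean())


def trend_dispersion(norm: np.ndarray, group_sizes: tuple[int, int]) -> np.ndarray:
    """Common-trend dispersion alpha(m) = max(a + b/m, floor) fitted by least
    squares to per-feature method-of-moments estimates pooled within groups."""
    n1, _ = group_sizes
    g1, g2 = norm[:, :n1], norm[:, n1:]
    mean = norm.mean(axis=1)
    pooled_var = (g1.var(axis=1, ddof=1) * (g1.shape[1] - 1)
                  + g2.var(axis=1, ddof=1) * (g2.shape[1] - 1)) / (
        g1.shape[1] + g2.shape[1] - 2
    )
    gmean = (g1.mean(axis=1) + g2.mean(axis=1)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mm = (pooled_var - gmean) / gmean**2
    ok = np.isfinite(alpha_mm) & (alpha_mm > 0) & (gmean > 0)
    floor = 1e-8
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / gmean[ok]])
        beta, *_ = np.linalg.lstsq(X, alpha_mm[ok], rcond=None)
        a, b = float(beta[0]), float(beta[1])
    else:
        a, b = float(np.median(alpha_mm[ok])) if ok.any() else 0.1, 0.0
    with np.errstate(divide="ignore"):
        trend = a + b / np.clip(gmean, 1e-12, None)
    return np.clip(trend, floor, 10.0)


# ---------------------------------------------------------------------------
# the two tests


def de_test_primary(
    counts_g1: np.ndarray, counts_g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial Wald test per feature (vectorized over features).

    Returns (log2fc, p). log2FC is computed on normalized group means with a
    0.5 pseudo-count (finite even when one group is all zero); an all-zero
    feature gets log2fc 0 and p 1.
    """
    g1 = np.atleast_2d(np.asarray(counts_g1, dtype=float))
    g2 = np.atleast_2d(np.asarray(counts_g2, dtype=float))
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValidationError("each group needs >= 2 replicates")
    joint = np.concatenate([g1, g2], axis=1)
    sf = median_of_ratios_size_factors(joint)
    norm = joint / sf
    n1 = g1.shape[1]
    m1, m2 = norm[:, :n1].mean(axis=1), norm[:, n1:].mean(axis=1)
    alpha = trend_dispersion(norm, (n1, norm.shape[1] - n1))

    log2fc = np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT))
    var1 = (m1 + alpha * m1**2) / n1
    var2 = (m2 + alpha * m2**2) / (norm.shape[1] - n1)
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var1 / ((m1 + PSEUDOCOUNT) ** 2 * ln2sq) + var2 / ((m2 + PSEUDOCOUNT) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    zero = (m1 == 0) & (m2 == 0)
    log2fc[zero], p[zero] = 0.0, 1.0
    return log2fc, np.clip(p, 0.0, 1.0)


def de_test_secondary(fpkm_g1: np.ndarray, fpkm_g2: np.ndarray) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value on FPKM values.

    Exact null distribution for n <= 10 per group without ties; midranks and
    the normal approximation with ties."""
    x = np.asarray(fpkm_g1, dtype=float)
    y = np.asarray(fpkm_g2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "asymptotic" if (ties or max(len(x), len(y)) > 10) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-comparison calling


def call_de(
    counts: CountMatrix,
    fpkm: ExpressionMatrix,
    q_threshold: float = DEFAULT_Q,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    comparisons: Sequence[str] = COMPARISONS,
) -> pd.DataFrame:
    """Run both tests for every feature and comparison; one row per pair.

    Features with zero total count over the two groups of a comparison are
    not tested in that comparison. BH adjustment is applied within each
    comparison, separately per method.
    """
    tissues = set(counts.samples["tissue"])
    rows = []
    for comparison in comparisons:
        num, den = comparison.split("_vs_")
        if num not in tissues or den not in tissues:
            raise ValidationError(f"tissue missing for comparison {comparison}")
        s1 = counts.samples_for_tissue(num)
        s2 = counts.samples_for_tissue(den)
        c1 = counts.values[s1].to_numpy(dtype=float)
        c2 = counts.values[s2].to_numpy(dtype=float)
        tested = (c1.sum(axis=1) + c2.sum(axis=1)) > 0
        idx = np.where(tested)[0]
        lfc, p1 = de_test_primary(c1[idx], c2[idx])
        f1 = fpkm.values[s1].to_numpy(dtype=float)
        f2 = fpkm.values[s2].to_numpy(dtype=float)
        p2 = np.array([de_test_secondary(f1[i], f2[i]) for i in idx])
        q1, q2 = adjust_bh(p1), adjust_bh(p2)
        feats = [counts.feature_ids[i] for i in idx]
        for j, fid in enumerate(feats):
            confirmed = bool(q1[j] < q_threshold and q2[j] < q_threshold)
            is_de = bool(confirmed and abs(lfc[j]) > min_abs_log2fc)
            rows.append(
                {
                    "feature_id": fid,
                    "comparison": comparison,
                    "log2fc": float(lfc[j]),
                    "p_primary": float(p1[j]),
                    "p_secondary": float(p2[j]),
                    "q_primary": float(q1[j]),
                    "q_secondary": float(q2[j]),
                    "confirmed_both": confirmed,
                    "direction": "up" if lfc[j] > 0 else "down",
                    "is_de": is_de,
                }
            )
    return pd.DataFrame(rows)


def group_profiles(de_results: pd.DataFrame) -> dict[str, list[str]]:
    """Tissue-specific profile groups from the three pairwise comparisons.

    A feature joins X_vs_rest iff it is DE in both comparisons involving
    tissue X with a consistent sign relative to X. A feature qualifying for
    more than one group (possible when it separates all three tissues) is
    assigned to the group where its mean |log2FC| is largest.
    """
    # sign of the feature's change *relative to tissue X* in each comparison
    relevant = {
        "T": [("E_vs_T", -1), ("DD_vs_T", -1)],
        "E": [("E_vs_T", +1), ("E_vs_DD", +1)],
        "DD": [("DD_vs_T", +1), ("E_vs_DD", -1)],
    }
    de = de_results[de_results["is_de"]]
    by_feat = {}
    for fid, sub in de.groupby("feature_id"):
        comp = dict(zip(sub["comparison"], sub["log2fc"]))
        scores = {}
        for tissue, specs in relevant.items():
            if all(c in comp for c, _ in specs):
                signs = [np.sign(comp[c]) * s for c, s in specs]
                if len(set(signs)) == 1:
                    scores[tissue] = np.mean([abs(comp[c]) for c, _ in specs])
        if scores:
            order = {"T": 0, "E": 1, "DD": 2}
            best = max(scores, key=lambda t: (scores[t], -order[t]))
            by_feat[fid] = best
    groups = {"T_vs_rest": [], "E_vs_rest": [], "DD_vs_rest": []}
    for fid, tissue in sorted(by_feat.items()):
        groups[f"{tissue}_vs_rest"].append(fid)
    return groups


def zscore_matrix(fpkm: ExpressionMatrix, features: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-feature Z-scores of FPKM (ddof = 1); constant rows map to zeros."""
    vals = fpkm.values if features is None else fpkm.values.loc[list(features)]
    arr = vals.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=vals.index, columns=vals.columns)


def ma_table(counts: CountMatrix, de_results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Mean-expression vs log2FC coordinates (MA-plot data)."""
    sub = de_results[de_results["comparison"] == comparison]
    mean_expr = counts.values.mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": sub["feature_id"],
            "mean_expression": [float(mean_expr[f]) for f in sub["feature_id"]],
            "log2fc": sub["log2fc"].to_numpy(),
        }
    )


def volcano_table(de_results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """log2FC vs -log10(q) coordinates (volcano-plot data)."""
    sub = de_results[de_results["comparison"] == comparison]
    q = np.clip(sub["q_primary"].to_numpy(), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "feature_id": sub["feature_id"],
            "log2fc": sub["log2fc"].to_numpy(),
            "neg_log10_q": -np.log10(q),
        }
    )
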