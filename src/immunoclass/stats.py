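"""Cross-class statistics.

Implements the statistical toolbox the four-class comparison relies on:
Benjamini–Hochberg FDR adjustment, Kruskal–Wallis tests across classes
(vectorised over features, BH within the feature family), two-group
differential expression (Wilcoxon rank-sum on log2 values with a mean
log2-fold-change — a deliberate, documented substitute for count-model Wald
tests), one-sided hypergeometric over-representation, preranked GSEA on
hallmark-style sets with gene-permutation NES/FDR, Fisher's exact test for
2×K response-by-class tables by fixed-margin enumeration, and the
likelihood-ratio comparison of nested logistic response models (CPS alone vs
CPS plus the immune class).

BH is applied within each analysis family separately, mirroring per-panel
adjusted-p reporting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .io import ExpressionMatrix, SignatureCollection

__all__ = [
    "GroupTestResult",
    "DEResult",
    "EnrichmentResult",
    "ModelComparison",
    "benjamini_hochberg",
    "kruskal_wallis_by_class",
    "differential_expression",
    "hypergeometric_ora",
    "preranked_gsea",
    "fisher_exact_association",
    "logistic_lrt_comparison",
]


@dataclass
class GroupTestResult:
    feature: str
    statistic: float
    p: float
    p_adj: float
    group_medians: dict[str, float]


@dataclass
class DEResult:
    gene: str
    log2fc: float
    statistic: float
    p: float
    p_adj: float
    significant: bool


@dataclass
class EnrichmentResult:
    set_name: str
    mode: str  # "ora" or "gsea"
    p: float
    fdr_q: float
    overlap_k: int | None = None  # ora
    es: float | None = None  # gsea
    nes: float | None = None  # gsea


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested response models."""

    loglik_null: float
    loglik_full: float
    lr_statistic: float
    df: int
    p: float
    separation_flag: bool = False


def benjamini_hochberg(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up BH adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis_by_class(
    values: pd.DataFrame | pd.Series | Mapping[str, float],
    classes: Mapping[str, str],
) -> list[GroupTestResult]:
    """Kruskal–Wallis H test of each feature across the immune classes.

    ``values`` is a feature × sample DataFrame (or a single feature as a
    Series / mapping); ``classes`` maps sample -> class label.  Classes with
    no matched sample are dropped with a warning; fewer than two remaining
    classes is an error.  Tie-corrected H, p from the chi-square reference
    distribution with (#classes − 1) df, BH across the feature list.
    """
    if isinstance(values, Mapping) and not isinstance(values, pd.Series):
        values = pd.Series(values)
    if isinstance(values, pd.Series):
        values = values.to_frame().T
        if values.index[0] in (0, None):
            values.index = ["feature"]
    common = [s for s in values.columns if s in classes]
    levels = sorted(set(classes.values()))
    groups_idx = {lv: [s for s in common if classes[s] == lv] for lv in levels}
    empty = [lv for lv, ss in groups_idx.items() if not ss]
    if empty:
        warnings.warn(f"dropping classes with no samples: {empty}", stacklevel=2)
        for lv in empty:
            del groups_idx[lv]
    if len(groups_idx) < 2:
        raise ValueError("need at least 2 non-empty classes")
    results: list[GroupTestResult] = []
    for feat in values.index:
        row = values.loc[feat]
        groups = [row[ss].to_numpy(dtype=float) for ss in groups_idx.values()]
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*groups)
        medians = {lv: float(np.median(g)) for lv, g in zip(groups_idx, groups)}
        results.append(GroupTestResult(str(feat), float(h), float(p), np.nan, medians))
    padj = benjamini_hochberg([r.p for r in results])
    for r, q in zip(results, padj):
        r.p_adj = float(q)
    return results


def differential_expression(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha_de: float = 0.05,
    lfc_threshold: float = 1.0,
) -> list[DEResult]:
    """Two-group differential expression on log2-normalised values.

    Per gene: log2FC = mean(group B) − mean(group A); two-sided Wilcoxon
    rank-sum p (exact when the smaller group has ≤ 8 samples and the gene has
    no ties, normal approximation with tie and continuity correction
    otherwise); BH across genes.  A gene is significant when
    p_adj < ``alpha_de`` and |log2FC| > ``lfc_threshold``.

    This rank-based statistic is a declared substitution for count-model Wald
    differential expression; thresholds and the significance rule are
    unchanged.
    """
    if expr.scale != "log2norm":
        raise ValueError("differential_expression expects log2norm scale")
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    A = expr.values[group_a].to_numpy(dtype=float)
    B = expr.values[group_b].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    log2fc = B.mean(axis=1) - A.mean(axis=1)
    n_min = min(n_a, n_b)
    stats_u = np.empty(A.shape[0])
    pvals = np.empty(A.shape[0])
    # vectorised asymptotic pass
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(B, A, axis=1, alternative="two-sided", method="asymptotic")
    stats_u[:] = res.statistic
    pvals[:] = res.pvalue
    for i in range(A.shape[0]):
        combined = np.concatenate([A[i], B[i]])
        if np.all(combined == combined[0]):
            stats_u[i] = n_a * n_b / 2.0
            pvals[i] = 1.0
        elif n_min <= 8 and len(np.unique(combined)) == len(combined):
            r = sps.mannwhitneyu(B[i], A[i], alternative="two-sided", method="exact")
            stats_u[i], pvals[i] = r.statistic, r.pvalue
    padj = benjamini_hochberg(pvals)
    out = []
    for i, g in enumerate(expr.gene_ids):
        sig = bool(padj[i] < alpha_de and abs(log2fc[i]) > lfc_threshold)
        out.append(DEResult(g, float(log2fc[i]), float(stats_u[i]), float(pvals[i]), float(padj[i]), sig))
    return out


def hypergeometric_ora(
    hit_genes: set[str],
    universe: set[str],
    sets: SignatureCollection,
) -> list[EnrichmentResult]:
    """One-sided (upper tail) hypergeometric over-representation analysis.

    Each gene set is intersected with the universe before testing; sets
    disjoint from the universe are dropped with a warning.  BH across sets.
    """
    hit_genes, universe = set(hit_genes), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hit_genes:
        raise ValueError("empty hit list")
    if not hit_genes <= universe:
        raise ValueError(f"hits outside universe: {sorted(hit_genes - universe)[:5]}")
    N, n = len(universe), len(hit_genes)
    results: list[EnrichmentResult] = []
    for sig in sets:
        inset = sig.genes & universe
        if not inset:
            warnings.warn(f"set {sig.name!r} disjoint from universe; dropped", stacklevel=2)
            continue
        K = len(inset)
        k = len(inset & hit_genes)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(sig.name, "ora", p=min(p, 1.0), fdr_q=np.nan, overlap_k=k))
    if not results:
        raise ValueError("no set overlaps the universe")
    q = benjamini_hochberg([r.p for r in results])
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
    return results


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(is_hit: np.ndarray, weights: np.ndarray) -> float:
    """Weighted KS enrichment score: max-deviation of the running sum.

    ``is_hit`` marks set members along the ranked list (best rank first);
    ``weights`` are |ranking stat| values.  Falls back to unweighted steps
    when every in-set weight is zero.
    """
    w = np.where(is_hit, weights, 0.0)
    total = w.sum()
    if total == 0:
        w = is_hit.astype(float)
        total = w.sum()
    n_out = len(is_hit) - int(is_hit.sum())
    running = np.cumsum(w / total - (~is_hit) / n_out)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked_stats: pd.Series | Mapping[str, float],
    gene_sets: SignatureCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> list[EnrichmentResult]:
    """Preranked GSEA with gene-label permutation.

    Genes are ordered by the ranking metric (descending; ties broken by gene
    id for determinism).  The enrichment score is the maximum deviation of
    the weighted running sum (in-set steps proportional to |stat|, out-set
    steps uniform).  The null is built by permuting gene labels ``n_perm``
    times per set (seeded); NES = ES / mean |null ES| of the same sign, and
    FDR q follows the positive/negative pooling rule: the fraction of pooled
    same-sign null NES at least as extreme, divided by the fraction of
    observed same-sign NES at least as extreme.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (q-value undefined below that resolution)")
    if not isinstance(ranked_stats, pd.Series):
        ranked_stats = pd.Series(ranked_stats, dtype=float)
    order = sorted(ranked_stats.index, key=lambda g: (-ranked_stats[g], str(g)))
    stats_sorted = ranked_stats[order].to_numpy(dtype=float)
    weights = np.abs(stats_sorted)
    pos = {g: i for i, g in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)

    kept = []
    for sig in gene_sets:
        idx = np.array(sorted(pos[g] for g in sig.genes if g in pos), dtype=int)
        if len(idx) < min_size:
            warnings.warn(f"set {sig.name!r}: {len(idx)} matched genes (<{min_size}); dropped",
                          stacklevel=2)
            continue
        kept.append((sig.name, idx))
    if not kept:
        raise ValueError("no gene set passed the size filter")

    results = []
    null_nes_all: list[np.ndarray] = []
    for name, idx in kept:
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es = _enrichment_score(hit, weights)
        k = len(idx)
        es_null = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(n, size=k, replace=False)
            h = np.zeros(n, dtype=bool)
            h[perm_idx] = True
            es_null[b] = _enrichment_score(h, weights)
        pos_null = es_null[es_null >= 0]
        neg_null = es_null[es_null < 0]
        if es >= 0:
            denom = pos_null.mean() if pos_null.size else np.nan
            p = (1 + np.sum(pos_null >= es)) / (1 + pos_null.size) if pos_null.size else 1.0
        else:
            denom = np.abs(neg_null).mean() if neg_null.size else np.nan
            p = (1 + np.sum(neg_null <= es)) / (1 + neg_null.size) if neg_null.size else 1.0
        nes = es / denom if denom and np.isfinite(denom) else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null = np.where(
                es_null >= 0,
                es_null / (pos_null.mean() if pos_null.size else np.nan),
                es_null / (np.abs(neg_null).mean() if neg_null.size else np.nan),
            )
        null_nes_all.append(nes_null[np.isfinite(nes_null)])
        results.append(EnrichmentResult(name, "gsea", p=float(p), fdr_q=np.nan, es=es, nes=float(nes)))

    pooled = np.concatenate(null_nes_all)
    obs = np.array([r.nes for r in results])
    for r in results:
        if r.nes >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= r.nes) if (pooled >= 0).any() else 1.0
            obs_frac = np.mean(obs[obs >= 0] >= r.nes)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= r.nes) if (pooled < 0).any() else 1.0
            obs_frac = np.mean(obs[obs < 0] <= r.nes)
        r.fdr_q = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 1.0
    return results


# ---------------------------------------------------------------------------
# Fisher's exact test for 2 x K tables
# ---------------------------------------------------------------------------

def _log_table_prob(row1: np.ndarray, cols: np.ndarray, n_total: int, r1: int) -> float:
    """log multivariate hypergeometric probability of a 2xK table given margins."""
    lp = -(gammaln(n_total + 1) - gammaln(r1 + 1) - gammaln(n_total - r1 + 1))
    for a, c in zip(row1, cols):
        lp += gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
    return float(lp)


def fisher_exact_association(table) -> float:
    """Exact conditional test of independence in a 2×K contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables whose point probability does not exceed the
    observed one (the probability-mass two-sided rule; for 2×2 this is the
    classical two-sided Fisher test).  Any zero row or column margin leaves
    the test undefined and raises.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2 x K table with K >= 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: test undefined")
    n_total = int(t.sum())
    r1 = int(rows[0])
    lp_obs = _log_table_prob(t[0], cols, n_total, r1)
    k = len(cols)

    total_p = 0.0
    # enumerate row-1 allocations a_1..a_K with 0 <= a_j <= col_j, sum = r1
    def recurse(j: int, remaining: int, lp: float) -> None:
        nonlocal total_p
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                a = remaining
                lp_full = lp + gammaln(cols[j] + 1) - gammaln(a + 1) - gammaln(cols[j] - a + 1)
                if lp_full <= lp_obs + 1e-9:
                    total_p += np.exp(lp_full)
            return
        lo = max(0, remaining - int(cols[j + 1:].sum()))
        hi = min(int(cols[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(
                j + 1,
                remaining - a,
                lp + gammaln(cols[j] + 1) - gammaln(a + 1) - gammaln(cols[j] - a + 1),
            )

    base = -(gammaln(n_total + 1) - gammaln(r1 + 1) - gammaln(n_total - r1 + 1))
    recurse(0, r1, base)
    return float(min(total_p, 1.0))


def logistic_lrt_comparison(
    response: Mapping[str, int],
    cps: Mapping[str, float],
    class_label: Mapping[str, str],
) -> ModelComparison:
    """Does the immune class add response information beyond CPS?

    Fits the null logistic model logit P(response) = b0 + b1*CPS and the full
    model adding immune-class indicator terms, by maximum likelihood; reports
    the likelihood-ratio statistic 2*(loglik_full − loglik_null) against a
    chi-square with df = number of added indicators.  If the class adds no
    parameters (a single observed level) the statistic is 0 with p = 1.
    Suspected separation (non-converged or exploding coefficients) is flagged
    but the LR statistic is still reported.
    """
    samples = [s for s in response if s in cps and s in class_label]
    y = np.array([int(response[s]) for s in samples])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one responder and one non-responder")
    x_cps = np.array([float(cps[s]) for s in samples])
    labels = pd.Series([class_label[s] for s in samples], index=samples)
    levels = sorted(labels.unique())

    X_null = sm.add_constant(pd.DataFrame({"cps": x_cps}, index=samples))
    dummies = pd.get_dummies(labels, prefix="class", drop_first=True, dtype=float)
    X_full = pd.concat([X_null, dummies], axis=1)

    flag = False

    def fit(X):
        nonlocal flag
        model = sm.Logit(y, np.asarray(X, dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", maxiter=200, disp=0, tol=1e-10)
            except Exception:
                res = model.fit(method="bfgs", maxiter=500, disp=0)
                flag = True
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 20:
            flag = True
        return res

    res_null = fit(X_null)
    df_added = dummies.shape[1]
    if df_added == 0:
        return ModelComparison(float(res_null.llf), float(res_null.llf), 0.0, 0, 1.0, flag)
    res_full = fit(X_full)
    lr = max(0.0, 2.0 * (res_full.llf - res_null.llf))
    p = float(sps.chi2.sf(lr, df_added)) if lr > 0 else 1.0
    if flag:
        warnings.warn("possible separation in logistic fit; LR reported with caution",
                      stacklevel=2)
    return ModelComparison(
        float(res_null.llf), float(res_full.llf), float(lr), int(df_added), p, flag
    )
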