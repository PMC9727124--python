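"""Per-sample signature scoring.

Three operations turn an expression matrix and gene-set collections into the
per-sample quantities the classification works on:

* :func:`normalize_housekeeping` — housekeeping-control normalisation of raw
  counts onto a log2 scale, emulating panel-style housekeeping normalisation:
  each sample is rescaled by the geometric mean of its housekeeping-gene
  counts relative to the cohort-average factor, then log2(x + 1) transformed.
* :func:`marker_mean_scores` — cell-type / functional signature scores as the
  arithmetic mean of log2 expression over each signature's matched genes
  (median available via ``statistic="median"``).
* :func:`ssgsea_scores` — a single-sample GSEA enrichment score (difference
  of the rank-weighted in-set ECDF and the unweighted out-of-set ECDF, summed
  over the ranked gene list), used for the ESTIMATE-style immune score.

All scores are deterministic; ranking ties take average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSignature, SignatureCollection

__all__ = ["ScoreMatrix", "normalize_housekeeping", "marker_mean_scores", "ssgsea_scores"]


@dataclass
class ScoreMatrix:
    """Signature × sample score matrix.

    ``method`` records how the scores were computed (``marker_mean`` or
    ``ssgsea``); ``matched_genes`` maps each signature to the number of its
    genes found in the source expression matrix.
    """

    values: pd.DataFrame
    method: str
    matched_genes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("marker_mean", "ssgsea"):
            raise ValueError(f"unknown score method {self.method!r}")
        if np.isnan(self.values.to_numpy(dtype=float)).any():
            raise ValueError("score matrix contains missing values")

    @property
    def signature_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# method={self.method}\n")
            self.values.to_csv(fh, sep="\t", index_label="signature")


def normalize_housekeeping(
    expr: ExpressionMatrix, housekeeping_genes: Iterable[str]
) -> ExpressionMatrix:
    """Housekeeping-control normalisation of a counts matrix to log2 scale.

    The per-sample scale factor is the geometric mean of the sample's
    housekeeping-gene counts; each sample is multiplied by (cohort geometric
    mean factor) / (its own factor) so that housekeeping content is equalised,
    then values are log2(x + 1) transformed.  Housekeeping rows are retained
    in the output.

    Raises ``ValueError`` if no requested housekeeping gene is present, or if
    a housekeeping count is zero (the geometric mean would degenerate).
    """
    if expr.scale != "counts":
        raise ValueError("normalize_housekeeping expects a counts-scale matrix")
    requested = list(dict.fromkeys(housekeeping_genes))
    present = [g for g in requested if g in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"no housekeeping gene found in matrix; requested: {requested}")
    hk = expr.values.loc[present].to_numpy(dtype=float)
    if (hk <= 0).any():
        bad = [
            f"{present[i]}/{expr.sample_ids[j]}" for i, j in zip(*np.nonzero(hk <= 0))
        ]
        raise ValueError(f"zero housekeeping counts (geometric mean undefined): {bad[:5]}")
    # per-sample factor s_j, cohort factor m = geometric mean of the s_j
    log_s = np.log(hk).mean(axis=0)
    m = np.exp(log_s.mean())
    scale = m / np.exp(log_s)  # multiply sample j by scale_j
    normalized = np.log2(expr.values.to_numpy(dtype=float) * scale[np.newaxis, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=expr.gene_ids, columns=expr.sample_ids), "log2norm"
    )


def marker_mean_scores(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    statistic: str = "mean",
) -> ScoreMatrix:
    """Signature scores as the per-sample mean (or median) of matched genes.

    Signatures with no gene in the matrix are dropped with a warning;
    an entirely empty collection (or one with no matches at all) is an error.
    """
    if len(sigs) == 0:
        raise ValueError("empty signature collection")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    gene_index = set(expr.gene_ids)
    rows: list[np.ndarray] = []
    names: list[str] = []
    matched: dict[str, int] = {}
    for sig in sigs:
        genes = [g for g in sig.genes if g in gene_index]
        if not genes:
            warnings.warn(f"signature {sig.name!r}: no genes matched, dropped", stacklevel=2)
            continue
        sub = expr.values.loc[genes].to_numpy(dtype=float)
        rows.append(sub.mean(axis=0) if statistic == "mean" else np.median(sub, axis=0))
        names.append(sig.name)
        matched[sig.name] = len(genes)
    if not rows:
        raise ValueError("no signature matched any gene in the matrix")
    values = pd.DataFrame(np.vstack(rows), index=names, columns=expr.sample_ids)
    return ScoreMatrix(values, method="marker_mean", matched_genes=matched)


def ssgsea_scores(
    expr: ExpressionMatrix, gene_set: GeneSignature, alpha: float = 0.25
) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    For each sample, genes are ranked by expression (average ranks for ties).
    Walking the list from the highest-expressed gene down, the running score
    accumulates the difference between the weighted in-set ECDF (steps
    proportional to rank^alpha, ranks ascending in expression so the
    top-expressed gene carries the largest weight) and the unweighted
    out-of-set ECDF; the score is the sum of this difference over the whole
    list.  ``alpha = 0`` reduces to the unweighted Kolmogorov–Smirnov
    running-sum integral.  Rank-based, hence invariant to any strictly
    monotone transform of a sample's values.
    """
    genes = expr.gene_ids
    in_set = np.array([g in gene_set.genes for g in genes])
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == len(genes):
        raise ValueError(
            f"gene set {gene_set.name!r} covers {n_in} of {len(genes)} genes; "
            "enrichment score undefined"
        )
    X = expr.values.to_numpy(dtype=float)
    scores = np.empty(X.shape[1])
    n = len(genes)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j])  # ascending: highest expression -> rank n
        order = np.argsort(-ranks, kind="stable")  # walk from top expression down
        hit = in_set[order]
        w = ranks[order] ** alpha
        w_in = np.where(hit, w, 0.0)
        denom_in = w_in.sum()
        p_in = np.cumsum(w_in) / denom_in
        p_out = np.cumsum(~hit) / (n - n_in)
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=expr.sample_ids, name=gene_set.name)
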