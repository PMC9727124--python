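"""Two-level unsupervised immune classification.

The procedure labels each tumour sample along two axes and crosses them:

1. **Infiltrate** — unsupervised hierarchical clustering of the immune
   cell-type score matrix, cut at two clusters; the cluster with the higher
   mean total cell score is the high-infiltrate class **IIH**, the other
   **IIL**.
2. **Function** — for every functional signature (T/NK/B/macrophage/leucocyte
   function, cytokines, chemokines, interleukins, complement), samples are
   clustered on the submatrix of that signature's genes and the higher-mean
   cluster is "high"; a sample is high-function **FH** when a strict majority
   of its per-signature labels are high (ties broken by the sign of its mean
   z-score over all functional-signature genes).  A second-level clustering
   consensus is available as an alternative rule.

Crossing the two axes yields the four-class label IIL-FL / IIL-FH / IIH-FL /
IIH-FH.  Everything is deterministic: no randomness enters the classification,
and ties are resolved by fixed, logged rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, SignatureCollection
from .scoring import ScoreMatrix

__all__ = [
    "ClusterCut",
    "ImmuneClassification",
    "INFILTRATE_LEVELS",
    "FUNCTION_LEVELS",
    "COMBINED_CLASSES",
    "two_group_hierarchical_cut",
    "assign_infiltrate_class",
    "assign_function_labels",
    "combine_immune_class",
    "classification_frame",
]

INFILTRATE_LEVELS = ("IIL", "IIH")
FUNCTION_LEVELS = ("FL", "FH")
COMBINED_CLASSES = ("IIL-FL", "IIL-FH", "IIH-FL", "IIH-FH")

_LINKAGES = ("ward", "complete", "average")
_DISTANCES = ("euclidean", "correlation")


@dataclass
class ClusterCut:
    """A two-cluster cut of a sample dendrogram."""

    labels: dict[str, int]  # sample -> 1 or 2
    linkage: str
    distance: str
    cophenetic_height: float

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


@dataclass
class ImmuneClassification:
    """Per-sample immune class: infiltrate level, function level, combined label."""

    sample_id: str
    infiltrate: str
    function: str
    combined: str
    per_signature_function: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.infiltrate not in INFILTRATE_LEVELS:
            raise ValueError(f"infiltrate must be in {INFILTRATE_LEVELS}")
        if self.function not in FUNCTION_LEVELS:
            raise ValueError(f"function must be in {FUNCTION_LEVELS}")
        if self.combined != f"{self.infiltrate}-{self.function}":
            raise ValueError("combined label must concatenate infiltrate and function")


def _as_frame(matrix) -> pd.DataFrame:
    """Feature × sample DataFrame from a ScoreMatrix / ExpressionMatrix / DataFrame."""
    if isinstance(matrix, (ScoreMatrix, ExpressionMatrix)):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"cannot cluster object of type {type(matrix).__name__}")


def _row_zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance rows before z-scoring", stacklevel=3
        )
        df = df.loc[~flat]
        sd = sd[~flat]
    if df.empty:
        raise ValueError("no rows left after dropping zero-variance rows")
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)


def two_group_hierarchical_cut(
    matrix,
    linkage: str = "ward",
    distance: str = "euclidean",
    row_zscore: bool = True,
) -> ClusterCut:
    """Agglomerative clustering of samples, dendrogram cut at exactly 2 clusters.

    Samples are columns; features (scores or genes) are rows and are
    optionally z-scored across samples first.  Ward linkage requires the
    Euclidean metric.  Deterministic given the inputs and options.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    df = _as_frame(matrix)
    samples = list(df.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if row_zscore:
        df = _row_zscore(df)
    obs = df.to_numpy(dtype=float).T  # samples x features
    dists = pdist(obs, metric=distance)
    if np.allclose(dists, 0):
        raise ValueError("all pairwise sample distances are zero (degenerate matrix)")
    Z = scipy_linkage(obs, method=linkage, metric=distance)
    raw = fcluster(Z, t=2, criterion="maxclust")
    if len(set(raw)) < 2:
        raise ValueError("dendrogram cut did not produce two clusters (degenerate)")
    # canonical numbering: cluster containing the first sample is 1
    first = raw[0]
    labels = {s: (1 if c == first else 2) for s, c in zip(samples, raw)}
    return ClusterCut(
        labels=labels,
        linkage=linkage,
        distance=distance,
        cophenetic_height=float(Z[-1, 2]),
    )


def assign_infiltrate_class(cell_scores: ScoreMatrix, cut: ClusterCut) -> dict[str, str]:
    """Label the two clusters IIH / IIL by mean total cell score.

    The cluster whose mean score — over all cell-type signatures and member
    samples — is higher is the high-infiltrate class.  An exact tie is broken
    toward the smaller cluster being IIH, with a warning.
    """
    samples = set(cell_scores.sample_ids)
    if set(cut.labels) != samples:
        raise ValueError("cluster cut samples do not match score matrix samples")
    means = {}
    for c in (1, 2):
        members = cut.members(c)
        means[c] = float(cell_scores.values[members].to_numpy(dtype=float).mean())
    if means[1] == means[2]:
        warnings.warn("cluster mean scores tied; smaller cluster labelled IIH", stacklevel=2)
        high = min((1, 2), key=lambda c: (len(cut.members(c)), c))
    else:
        high = max((1, 2), key=lambda c: means[c])
    return {s: ("IIH" if c == high else "IIL") for s, c in cut.labels.items()}


def assign_function_labels(
    expr: ExpressionMatrix,
    function_sigs: SignatureCollection,
    linkage: str = "ward",
    distance: str = "euclidean",
    consensus: str = "majority",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-signature high/low calls and the FH/FL consensus.

    For each functional signature, samples are clustered on the submatrix of
    that signature's genes (row z-scored) and the cluster with the higher mean
    expression of those genes is "high".  With ``consensus="majority"`` a
    sample is FH iff strictly more than half of its per-signature labels are
    high; exact ties follow the sign of the sample's mean z-score over all
    functional-signature genes (>= 0 -> FH).  ``consensus="cluster"`` instead
    re-clusters the per-signature score matrix (mean expression of each
    signature's genes) with a second two-group cut.

    Returns ``(per_signature, consensus_labels)`` where ``per_signature`` is a
    signature × sample DataFrame of "low"/"high" and ``consensus_labels`` maps
    sample -> "FL"/"FH".
    """
    sigs = [s for s in function_sigs if s.category == "function"] or list(function_sigs)
    if not sigs:
        raise ValueError("no functional signatures provided")
    if consensus not in ("majority", "cluster"):
        raise ValueError("consensus must be 'majority' or 'cluster'")
    gene_index = set(expr.gene_ids)
    samples = expr.sample_ids
    calls: dict[str, pd.Series] = {}
    sig_means: dict[str, np.ndarray] = {}
    for sig in sigs:
        genes = sig.matched(expr.gene_ids)
        if len(genes) < 2:
            warnings.warn(
                f"functional signature {sig.name!r} matches {len(genes)} gene(s) (<2); skipped",
                stacklevel=2,
            )
            continue
        sub = expr.values.loc[genes]
        cut = two_group_hierarchical_cut(sub, linkage=linkage, distance=distance, row_zscore=True)
        means = {
            c: float(sub[cut.members(c)].to_numpy(dtype=float).mean()) for c in (1, 2)
        }
        if means[1] == means[2]:
            warnings.warn(
                f"signature {sig.name!r}: cluster means tied; smaller cluster called high",
                stacklevel=2,
            )
            high = min((1, 2), key=lambda c: (len(cut.members(c)), c))
        else:
            high = max((1, 2), key=lambda c: means[c])
        calls[sig.name] = pd.Series(
            {s: ("high" if c == high else "low") for s, c in cut.labels.items()}
        )
        sig_means[sig.name] = sub.to_numpy(dtype=float).mean(axis=0)
    if not calls:
        raise ValueError("no functional signature matched >=2 genes")
    per_signature = pd.DataFrame(calls).T[samples]  # signatures x samples

    all_genes = [g for g in expr.gene_ids if any(g in s.genes for s in sigs)]
    zsub = _row_zscore(expr.values.loc[all_genes])
    tie_break = zsub.mean(axis=0)  # mean z over functional genes, per sample

    if consensus == "majority":
        n_sig = per_signature.shape[0]
        n_high = (per_signature == "high").sum(axis=0)
        labels = {}
        for s in samples:
            if 2 * n_high[s] > n_sig:
                labels[s] = "FH"
            elif 2 * n_high[s] < n_sig:
                labels[s] = "FL"
            else:
                labels[s] = "FH" if tie_break[s] >= 0 else "FL"
    else:
        score_df = pd.DataFrame(sig_means, index=samples).T  # signatures x samples
        cut = two_group_hierarchical_cut(
            score_df, linkage=linkage, distance=distance, row_zscore=True
        )
        cmeans = {c: float(tie_break[cut.members(c)].mean()) for c in (1, 2)}
        high = max((1, 2), key=lambda c: cmeans[c])
        labels = {s: ("FH" if c == high else "FL") for s, c in cut.labels.items()}
    return per_signature, labels


def combine_immune_class(
    infiltrate_labels: Mapping[str, str],
    function_labels: Mapping[str, str],
    per_signature: pd.DataFrame | None = None,
) -> list[ImmuneClassification]:
    """Cross the infiltrate and function axes into the four-class label."""
    a, b = set(infiltrate_labels), set(function_labels)
    if a != b:
        raise ValueError(
            f"sample sets differ: only-infiltrate={sorted(a - b)}, only-function={sorted(b - a)}"
        )
    out = []
    for s in infiltrate_labels:
        inf, fun = infiltrate_labels[s], function_labels[s]
        per_sig = {} if per_signature is None else per_signature[s].to_dict()
        out.append(
            ImmuneClassification(
                sample_id=s,
                infiltrate=inf,
                function=fun,
                combined=f"{inf}-{fun}",
                per_signature_function=per_sig,
            )
        )
    return out


def classification_frame(classification: Sequence[ImmuneClassification]) -> pd.DataFrame:
    """Tabular view: sample_id, infiltrate, function, combined, one column per signature."""
    rows = []
    for c in classification:
        row = {
            "sample_id": c.sample_id,
            "infiltrate": c.infiltrate,
            "function": c.function,
            "combined": c.combined,
        }
        row.update(c.per_signature_function)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
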