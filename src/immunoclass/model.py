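"""Model/Results front door for the immune transcriptomic classification.

:class:`ImmuneProfileModel` is built from an expression matrix, the
signature collections and (optionally) sample annotations; :meth:`fit`
performs the two-level unsupervised classification and returns an
:class:`ImmuneProfileResults` carrying the per-sample labels, the scores
behind them and a :meth:`~ImmuneProfileResults.summary` table.  Downstream
analyses — class-wise gene tests, differential expression, enrichment,
survival screening and the response-prediction comparison — hang off the
results object and draw clinical covariates from the annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import scoring as _scoring
from . import stats as _stats
from . import survival as _survival
from .io import ExpressionMatrix, SampleAnnotations, SignatureCollection, annotations_to_frame
from .synth import SyntheticCohort

__all__ = ["ImmuneProfileModel", "ImmuneProfileResults"]


class ImmuneProfileModel:
    """Two-level immune microenvironment classification model.

    Parameters
    ----------
    expr
        Gene × sample expression matrix.  A counts-scale matrix is
        housekeeping-normalised during :meth:`fit` (``housekeeping_genes``
        required in that case).
    signatures
        Signature collection containing at least one ``cell_type`` and one
        ``function`` signature; an ``immune_estimate`` set, if present, adds
        the ssGSEA immune score to the results.
    annotations
        Optional clinical records; required only by the downstream response
        and survival analyses.
    linkage, distance, row_zscore, consensus
        Clustering options (defaults: Ward linkage, Euclidean distance on
        row-z-scored values, majority-vote function consensus).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        signatures: SignatureCollection,
        annotations: Sequence[SampleAnnotations] | None = None,
        *,
        linkage: str = "ward",
        distance: str = "euclidean",
        row_zscore: bool = True,
        consensus: str = "majority",
        function_within_infiltrate: bool = False,
        housekeeping_genes: Sequence[str] | None = None,
        score_statistic: str = "mean",
    ) -> None:
        self.expr = expr
        self.signatures = signatures
        self.annotations = list(annotations) if annotations is not None else None
        self.linkage = linkage
        self.distance = distance
        self.row_zscore = row_zscore
        self.consensus = consensus
        self.function_within_infiltrate = function_within_infiltrate
        self.housekeeping_genes = list(housekeeping_genes) if housekeeping_genes else None
        self.score_statistic = score_statistic

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **options) -> "ImmuneProfileModel":
        """Build the model from a synthetic cohort (expression + planted signatures)."""
        return cls(cohort.expr, cohort.signatures, cohort.annotations, **options)

    def fit(self) -> "ImmuneProfileResults":
        expr = self.expr
        if expr.scale == "counts":
            if not self.housekeeping_genes:
                raise ValueError("counts input requires housekeeping_genes for normalisation")
            expr = _scoring.normalize_housekeeping(expr, self.housekeeping_genes)

        cell_sigs = self.signatures.by_category("cell_type")
        if len(cell_sigs) == 0:
            raise ValueError("no cell_type signatures provided")
        cell_scores = _scoring.marker_mean_scores(expr, cell_sigs, statistic=self.score_statistic)
        cut = _classify.two_group_hierarchical_cut(
            cell_scores, linkage=self.linkage, distance=self.distance, row_zscore=self.row_zscore
        )
        infiltrate = _classify.assign_infiltrate_class(cell_scores, cut)

        func_sigs = self.signatures.by_category("function")
        if self.function_within_infiltrate:
            # function clustering run separately inside each infiltrate stratum
            per_parts, function = [], {}
            for level in ("IIL", "IIH"):
                members = [s for s, lab in infiltrate.items() if lab == level]
                if len(members) < 4:
                    warnings.warn(
                        f"stratum {level} has {len(members)} samples (<4); "
                        "falling back to cohort-wide function clustering",
                        stacklevel=2,
                    )
                    per_parts, function = [], {}
                    break
                sub = ExpressionMatrix(expr.values[members], expr.scale)
                ps, labels = _classify.assign_function_labels(
                    sub, func_sigs, linkage=self.linkage, distance=self.distance,
                    consensus=self.consensus,
                )
                per_parts.append(ps)
                function.update(labels)
            if function:
                per_sig = pd.concat(per_parts, axis=1)[expr.sample_ids]
            else:
                per_sig, function = _classify.assign_function_labels(
                    expr, func_sigs, linkage=self.linkage, distance=self.distance,
                    consensus=self.consensus,
                )
        else:
            per_sig, function = _classify.assign_function_labels(
                expr, func_sigs, linkage=self.linkage, distance=self.distance,
                consensus=self.consensus,
            )
        # agreement between the two consensus rules, recorded for the report
        alt_rule = "cluster" if self.consensus == "majority" else "majority"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, alt = _classify.assign_function_labels(
                    expr, func_sigs, linkage=self.linkage, distance=self.distance,
                    consensus=alt_rule,
                )
                agree = float(np.mean([function[s] == alt[s] for s in function]))
            except ValueError:
                agree = np.nan

        classification = _classify.combine_immune_class(infiltrate, function, per_sig)

        immune_score = None
        est = self.signatures.by_category("immune_estimate")
        if len(est) > 0:
            try:
                immune_score = _scoring.ssgsea_scores(expr, est.signatures[0])
            except ValueError as exc:
                warnings.warn(f"immune score skipped: {exc}", stacklevel=2)

        return ImmuneProfileResults(
            model=self,
            expr=expr,
            cell_scores=cell_scores,
            infiltrate_cut=cut,
            classification=classification,
            per_signature_function=per_sig,
            immune_score=immune_score,
            consensus_agreement=agree,
        )


@dataclass
class ImmuneProfileResults:
    """Fitted classification: labels, scores and downstream analyses."""

    model: ImmuneProfileModel
    expr: ExpressionMatrix  # log2norm, post-normalisation
    cell_scores: _scoring.ScoreMatrix
    infiltrate_cut: _classify.ClusterCut
    classification: list[_classify.ImmuneClassification]
    per_signature_function: pd.DataFrame
    immune_score: pd.Series | None = None
    consensus_agreement: float = np.nan

    @property
    def frame(self) -> pd.DataFrame:
        return _classify.classification_frame(self.classification)

    @property
    def combined(self) -> dict[str, str]:
        return {c.sample_id: c.combined for c in self.classification}

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in _classify.COMBINED_CLASSES}
        for c in self.classification:
            counts[c.combined] += 1
        return counts

    def _annotation_frame(self) -> pd.DataFrame:
        if not self.model.annotations:
            raise ValueError("no sample annotations attached to the model")
        return annotations_to_frame(self.model.annotations)

    def samples_in(self, *classes: str) -> list[str]:
        want = set(classes)
        return [c.sample_id for c in self.classification if c.combined in want]

    # ------------------------------------------------------------------
    # downstream analyses
    # ------------------------------------------------------------------

    def gene_class_tests(self, genes: Sequence[str]) -> list[_stats.GroupTestResult]:
        """Kruskal–Wallis (BH-adjusted) of each gene across the four classes."""
        present = [g for g in genes if g in set(self.expr.gene_ids)]
        if not present:
            raise ValueError("none of the requested genes is in the matrix")
        return _stats.kruskal_wallis_by_class(self.expr.values.loc[present], self.combined)

    def differential_expression(
        self,
        contrast: tuple[str, str] = ("IIL-FL", "IIH-FH"),
        alpha_de: float = 0.05,
        lfc_threshold: float = 1.0,
    ) -> list[_stats.DEResult]:
        """DE between two combined classes; log2FC is second minus first class."""
        a = self.samples_in(contrast[0])
        b = self.samples_in(contrast[1])
        return _stats.differential_expression(self.expr, a, b, alpha_de, lfc_threshold)

    def log_rank(self) -> _survival.LogRankResult:
        """K-group log-rank over the combined classes on annotated PFS."""
        ann = self._annotation_frame()
        mask = ann["pfs_time"].notna()
        cls = pd.Series(self.combined)[ann.index[mask]]
        return _survival.log_rank_test(
            cls, ann.loc[mask, "pfs_time"], ann.loc[mask, "pfs_event"].astype(bool)
        )

    def response_table(self) -> pd.DataFrame:
        """2 × K contingency of response (rows) by combined class (columns)."""
        ann = self._annotation_frame()
        known = ann[ann["response"].isin(["responder", "non_responder"])]
        cls = pd.Series(self.combined)[known.index]
        tab = pd.crosstab(known["response"], cls)
        tab = tab.reindex(index=["responder", "non_responder"], fill_value=0)
        return tab.loc[:, tab.sum(axis=0) > 0]

    def fisher_response_association(self) -> float:
        return _stats.fisher_exact_association(self.response_table().to_numpy())

    def response_lrt(self) -> _stats.ModelComparison:
        """Does the immune class add to CPS in predicting CPI response?"""
        ann = self._annotation_frame()
        known = ann[ann["response"].isin(["responder", "non_responder"]) & ann["cps"].notna()]
        response = {s: int(known.loc[s, "response"] == "responder") for s in known.index}
        cps = {s: float(known.loc[s, "cps"]) for s in known.index}
        cls = {s: self.combined[s] for s in known.index}
        return _stats.logistic_lrt_comparison(response, cps, cls)

    def summary(self) -> str:
        counts = self.class_counts
        lines = [
            "Immune transcriptomic classification",
            "=" * 52,
            f"samples: {len(self.classification)}    genes: {len(self.expr.gene_ids)}",
            f"clustering: {self.infiltrate_cut.linkage} linkage, "
            f"{self.infiltrate_cut.distance} distance, "
            f"row z-score: {self.model.row_zscore}",
            f"function consensus: {self.model.consensus} "
            f"(agreement with alternative rule: {self.consensus_agreement:.2f})",
            "-" * 52,
            "class      n      fraction",
        ]
        n = max(1, len(self.classification))
        for c in _classify.COMBINED_CLASSES:
            lines.append(f"{c:<9} {counts[c]:>4}      {counts[c] / n:.2f}")
        if self.immune_score is not None:
            by_inf = {}
            for c in self.classification:
                by_inf.setdefault(c.infiltrate, []).append(self.immune_score[c.sample_id])
            lines.append("-" * 52)
            for k in ("IIL", "IIH"):
                if k in by_inf:
                    lines.append(f"immune score mean ({k}): {np.mean(by_inf[k]):.3f}")
        return "\n".join(lines)
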