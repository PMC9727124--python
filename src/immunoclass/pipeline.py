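"""Configuration-driven end-to-end orchestration.

:func:`run_pipeline` reproduces the full analysis order on any cohort:
normalisation (if counts) → signature scores → two-level classification →
class-wise checkpoint-gene statistics → differential expression (IIH-FH vs
IIL-FL by default) → over-representation and preranked hallmark GSEA →
survival screening of the platinum-exposed subgroup (penalised Cox,
maximally selected cutpoints, log-rank) → response association (Fisher) →
the CPS vs CPS+class likelihood-ratio comparison.

Every stage is seeded from one master seed by fixed offsets, every stage
either produces results or records an explicit skip reason, and the report's
provenance block suffices to re-run the pipeline identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import stats as _stats
from . import survival as _survival
from .model import ImmuneProfileModel, ImmuneProfileResults
from .synth import CHECKPOINT_GENES, CTLA4_GENE, CDH1_GENE

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

# seed fan-out offsets per randomised stage
_SEED_GSEA = 1
_SEED_LASSO = 2
_SEED_MAXSTAT = 3


@dataclass
class PipelineConfig:
    """All options of one pipeline run; serialisable to/from YAML."""

    expr_path: str
    cell_gmt: str
    function_gmt: str
    annotations_path: str | None = None
    estimate_gmt: str | None = None
    hallmark_gmt: str | None = None
    scale_hint: str = "log2norm"
    housekeeping_genes: list[str] = field(default_factory=list)
    linkage: str = "ward"
    distance: str = "euclidean"
    row_zscore: bool = True
    consensus: str = "majority"
    function_within_infiltrate: bool = False
    alpha_de: float = 0.05
    lfc_threshold: float = 1.0
    de_contrast: tuple[str, str] = ("IIL-FL", "IIH-FH")
    checkpoint_genes: list[str] = field(
        default_factory=lambda: ["PDCD1", "CD274", CTLA4_GENE] + CHECKPOINT_GENES[2:] + [CDH1_GENE]
    )
    gsea_n_perm: int = 1000
    ora_alpha: float = 0.05
    survival_features: list[str] = field(default_factory=list)  # empty: signature genes
    n_folds: int = 10
    n_lambda: int = 30
    quantile_bounds: tuple[float, float] = (0.1, 0.9)
    maxstat_n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_de < 1:
            raise ValueError("alpha_de must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["de_contrast"] = list(self.de_contrast)
        data["quantile_bounds"] = list(self.quantile_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("de_contrast", "quantile_bounds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineReport:
    class_counts: dict[str, int]
    consensus_agreement: float
    stages: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serialisable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=default)


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> str:
    path = out_dir / name
    df.to_csv(path, sep="\t")
    return str(path.name)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    """Execute every stage whose preconditions hold; skip the rest with reasons."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expr = _io.read_expression_table(config.expr_path, scale_hint=config.scale_hint)
    signatures = _io.read_gmt(config.cell_gmt, "cell_type").extend(
        _io.read_gmt(config.function_gmt, "function")
    )
    if config.estimate_gmt:
        signatures = signatures.extend(_io.read_gmt(config.estimate_gmt, "immune_estimate"))
    if config.hallmark_gmt:
        signatures = signatures.extend(_io.read_gmt(config.hallmark_gmt, "hallmark"))
    annotations = (
        _io.read_sample_annotations(config.annotations_path)
        if config.annotations_path
        else None
    )

    model = ImmuneProfileModel(
        expr,
        signatures,
        annotations,
        linkage=config.linkage,
        distance=config.distance,
        row_zscore=config.row_zscore,
        consensus=config.consensus,
        function_within_infiltrate=config.function_within_infiltrate,
        housekeeping_genes=config.housekeeping_genes or None,
    )
    results = model.fit()
    report = PipelineReport(
        class_counts=results.class_counts,
        consensus_agreement=results.consensus_agreement,
        provenance={"config": asdict(config), "package": "immunoclass"},
    )
    report.stages["classification"] = {
        "table": _write(results.frame, out_dir, "classification.tsv")
    }
    results.cell_scores.to_tsv(out_dir / "cell_scores.tsv")
    if results.immune_score is not None:
        report.stages["immune_score"] = {
            "table": _write(results.immune_score.to_frame("immune_score"), out_dir,
                            "immune_score.tsv")
        }

    # class-wise checkpoint / immunomodulatory gene tests
    genes = [g for g in config.checkpoint_genes if g in set(expr.gene_ids)]
    observed = {c for c in results.combined.values()}
    if not genes:
        report.skipped["checkpoint_tests"] = "no checkpoint gene present in matrix"
    elif len(observed) < 2:
        report.skipped["checkpoint_tests"] = "fewer than 2 observed classes"
    else:
        kw = results.gene_class_tests(genes)
        df = pd.DataFrame(
            [
                {"feature": r.feature, "H": r.statistic, "p": r.p, "p_adj": r.p_adj,
                 **{f"median_{k}": v for k, v in r.group_medians.items()}}
                for r in kw
            ]
        ).set_index("feature")
        report.stages["checkpoint_tests"] = {
            "table": _write(df, out_dir, "checkpoint_kruskal_wallis.tsv")
        }

    # differential expression
    de_results = None
    a, b = config.de_contrast
    n_a = len(results.samples_in(a))
    n_b = len(results.samples_in(b))
    if n_a < 2 or n_b < 2:
        report.skipped["differential_expression"] = (
            f"contrast {a} vs {b} needs >=2 samples per class (got {n_a}, {n_b})"
        )
    else:
        de_results = results.differential_expression(
            (a, b), config.alpha_de, config.lfc_threshold
        )
        df = pd.DataFrame([asdict(r) for r in de_results]).set_index("gene")
        n_sig = int(df["significant"].sum())
        report.stages["differential_expression"] = {
            "table": _write(df, out_dir, "differential_expression.tsv"),
            "contrast": [a, b],
            "n_significant": n_sig,
            "method": "wilcoxon_rank_sum (method-substituted)",
        }
        volcano = df[["log2fc"]].copy()
        volcano["neg_log10_p_adj"] = -np.log10(np.maximum(df["p_adj"], 1e-300))
        _write(volcano, out_dir, "volcano.tsv")

    # enrichment: ORA on significant DE genes, preranked GSEA on hallmark sets
    hallmark = signatures.by_category("hallmark")
    if de_results is None:
        report.skipped["ora"] = "differential expression not run"
        report.skipped["gsea"] = "differential expression not run"
    else:
        hits = {r.gene for r in de_results if r.significant}
        universe = set(expr.gene_ids)
        if not hits:
            report.skipped["ora"] = "no significant DE genes"
        elif len(hallmark) == 0:
            report.skipped["ora"] = "no hallmark/pathway gene sets provided"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ora = _stats.hypergeometric_ora(hits, universe, hallmark)
            df = pd.DataFrame(
                [{"set": r.set_name, "overlap_k": r.overlap_k, "p": r.p, "fdr_q": r.fdr_q}
                 for r in ora]
            ).set_index("set")
            report.stages["ora"] = {"table": _write(df, out_dir, "ora.tsv")}
        if len(hallmark) == 0:
            report.skipped["gsea"] = "no hallmark gene sets provided"
        else:
            ranked = pd.Series({r.gene: r.log2fc for r in de_results})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gsea = _stats.preranked_gsea(
                    ranked, hallmark, n_perm=config.gsea_n_perm,
                    seed=config.seed + _SEED_GSEA,
                )
            df = pd.DataFrame(
                [{"set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p, "fdr_q": r.fdr_q}
                 for r in gsea]
            ).set_index("set")
            report.stages["gsea"] = {
                "table": _write(df, out_dir, "gsea_hallmark.tsv"),
                "n_upregulated": int((df["nes"] > 0).sum()),
                "n_upregulated_fdr25": int(((df["nes"] > 0) & (df["fdr_q"] < 0.25)).sum()),
            }

    # survival: platinum-exposed subgroup
    if annotations is None:
        report.skipped["survival"] = "no sample annotations"
    else:
        ann = _io.annotations_to_frame(annotations)
        ann = ann.loc[[s for s in ann.index if s in results.combined]]
        surv = ann[ann["pfs_time"].notna()]
        if surv["pfs_event"].fillna(False).astype(bool).sum() < 2:
            report.skipped["survival"] = "fewer than 2 PFS events"
        else:
            time = surv["pfs_time"].astype(float)
            event = surv["pfs_event"].astype(bool)
            cls = pd.Series(results.combined)[surv.index]
            lr = _survival.log_rank_test(cls, time, event)
            report.stages["log_rank"] = {
                "groups": lr.groups, "statistic": lr.statistic, "df": lr.df, "p": lr.p,
            }
            for g, km in lr.km_tables.items():
                _write(km.set_index("time"), out_dir, f"km_{g}.tsv")

            # feature panel: explicit list; else the whole matrix when it is
            # panel-sized, else the union of signature genes
            if config.survival_features:
                features = [g for g in config.survival_features if g in set(expr.gene_ids)]
            elif len(expr.gene_ids) <= 600:
                features = list(expr.gene_ids)
            else:
                features = sorted(set(signatures.all_genes()) & set(expr.gene_ids))
            X = expr.values.loc[features, surv.index].T
            X = X.loc[:, X.std(axis=0, ddof=0) > 0]
            fit = _survival.fit_lasso_cox(
                X, time.to_numpy(), event.to_numpy(),
                n_folds=min(config.n_folds, int(event.sum())),
                seed=config.seed + _SEED_LASSO,
                n_lambda=config.n_lambda,
            )
            coef = pd.Series(fit.coefficients, name="coefficient")
            _write(coef[coef != 0].to_frame(), out_dir, "lasso_cox_selected.tsv")
            _write(fit.coef_path, out_dir, "lasso_cox_path.tsv")
            report.stages["lasso_cox"] = {
                "selected_lambda": fit.selected_lambda,
                "selected_genes": sorted(fit.selected_genes),
            }
            cut_rows = []
            for g in sorted(fit.selected_genes):
                feat = expr.values.loc[g, surv.index]
                if feat.nunique() < 2:
                    continue
                try:
                    cp = _survival.maxstat_cutpoint(
                        feat, time, event,
                        quantile_bounds=config.quantile_bounds,
                        n_perm=config.maxstat_n_perm,
                        seed=config.seed + _SEED_MAXSTAT,
                        feature_name=g,
                    )
                except ValueError:
                    continue
                direction = "worse_if_high" if fit.coefficients[g] > 0 else "better_if_high"
                cut_rows.append(
                    {"feature": g, "cutpoint": cp.cutpoint, "statistic": cp.max_statistic,
                     "p": cp.p, "direction": direction}
                )
            if cut_rows:
                df = pd.DataFrame(cut_rows).set_index("feature")
                report.stages["maxstat"] = {"table": _write(df, out_dir, "maxstat_cutpoints.tsv")}
            else:
                report.skipped["maxstat"] = "no gene selected by the penalised Cox screen"

    # response association and CPS model comparison
    if annotations is None:
        report.skipped["response_association"] = "no response annotation"
        report.skipped["model_comparison"] = "no response annotation"
    else:
        try:
            tab = results.response_table()
            if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
                raise ValueError("degenerate response table")
            report.stages["response_association"] = {
                "table": tab.to_dict(),
                "fisher_p": results.fisher_response_association(),
            }
        except ValueError as exc:
            report.skipped["response_association"] = str(exc) or "no response annotation"
        try:
            mc = results.response_lrt()
            report.stages["model_comparison"] = {
                "loglik_null": mc.loglik_null,
                "loglik_full": mc.loglik_full,
                "lr_statistic": mc.lr_statistic,
                "df": mc.df,
                "p": mc.p,
                "separation_flag": mc.separation_flag,
            }
        except ValueError as exc:
            report.skipped["model_comparison"] = str(exc) or "no response annotation"

    report.to_json(out_dir / "report.json")
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    return report
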