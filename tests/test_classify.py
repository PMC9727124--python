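import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from immunoclass.classify import (
    assign_function_labels,
    assign_infiltrate_class,
    combine_immune_class,
    two_group_hierarchical_cut,
)
from immunoclass.io import ExpressionMatrix, GeneSignature, SignatureCollection
from immunoclass.scoring import ScoreMatrix, marker_mean_scores


def blob_matrix(rng, n_per=10, n_feat=6, shift=4.0):
    """Two planted sample blobs along all features."""
    a = rng.normal(0, 1, size=(n_feat, n_per))
    b = rng.normal(shift, 1, size=(n_feat, n_per))
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    df = pd.DataFrame(np.hstack([a, b]), index=[f"f{i}" for i in range(n_feat)], columns=cols)
    truth = [0] * n_per + [1] * n_per
    return df, dict(zip(cols, truth))


class TestTwoGroupCut:
    def test_recovers_planted_blobs(self, rng):
        df, truth = blob_matrix(rng)
        cut = two_group_hierarchical_cut(df)
        pred = [cut.labels[s] for s in df.columns]
        assert adjusted_rand_score(list(truth.values()), pred) == 1.0

    def test_sample_order_invariance(self, rng):
        df, _ = blob_matrix(rng)
        cut1 = two_group_hierarchical_cut(df)
        perm = rng.permutation(df.columns)
        cut2 = two_group_hierarchical_cut(df[perm])
        agree = [
            (cut1.labels[s] == cut1.labels[t]) == (cut2.labels[s] == cut2.labels[t])
            for s in df.columns
            for t in df.columns
        ]
        assert all(agree)

    def test_duplicated_samples_cluster_together(self, rng):
        df, _ = blob_matrix(rng, n_per=5)
        dup = df.copy()
        dup.columns = [f"{c}_dup" for c in df.columns]
        both = pd.concat([df, dup], axis=1)
        cut = two_group_hierarchical_cut(both)
        for c in df.columns:
            assert cut.labels[c] == cut.labels[f"{c}_dup"]

    def test_single_sample_errors(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="2 samples"):
            two_group_hierarchical_cut(df)

    def test_constant_matrix_is_degenerate(self):
        df = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            two_group_hierarchical_cut(df, row_zscore=False)

    def test_ward_requires_euclidean(self, rng):
        df, _ = blob_matrix(rng)
        with pytest.raises(ValueError, match="ward"):
            two_group_hierarchical_cut(df, linkage="ward", distance="correlation")

    def test_zero_variance_rows_dropped_with_warning(self, rng):
        df, _ = blob_matrix(rng)
        df.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            two_group_hierarchical_cut(df)


class TestInfiltrateAssignment:
    def _scores(self, rng, shift=2.0):
        df, truth = blob_matrix(rng, n_per=8, n_feat=5, shift=shift)
        return ScoreMatrix(df, "marker_mean"), truth

    def test_high_cluster_is_iih(self, rng):
        scores, truth = self._scores(rng)
        cut = two_group_hierarchical_cut(scores)
        labels = assign_infiltrate_class(scores, cut)
        for s, t in truth.items():
            assert labels[s] == ("IIH" if t == 1 else "IIL")

    def test_invariant_to_cluster_index_swap(self, rng):
        scores, _ = self._scores(rng)
        cut = two_group_hierarchical_cut(scores)
        swapped = type(cut)(
            labels={s: 3 - c for s, c in cut.labels.items()},
            linkage=cut.linkage,
            distance=cut.distance,
            cophenetic_height=cut.cophenetic_height,
        )
        assert assign_infiltrate_class(scores, cut) == assign_infiltrate_class(scores, swapped)

    def test_sample_mismatch_rejected(self, rng):
        scores, _ = self._scores(rng)
        cut = two_group_hierarchical_cut(scores)
        del cut.labels[scores.sample_ids[0]]
        with pytest.raises(ValueError, match="match"):
            assign_infiltrate_class(scores, cut)


def function_cohort(rng, n_per=10, n_sigs=9, genes_per=4, effect=1.5):
    """Expression with n_sigs functional signatures elevated in the FH half."""
    genes, sig_list = [], []
    for k in range(n_sigs):
        gs = [f"sig{k}_g{j}" for j in range(genes_per)]
        genes += gs
        sig_list.append(GeneSignature(f"fsig{k}", "function", frozenset(gs)))
    cols = [f"fl{i}" for i in range(n_per)] + [f"fh{i}" for i in range(n_per)]
    base = rng.normal(5, 1, size=(len(genes), 2 * n_per))
    base[:, n_per:] += effect
    expr = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=cols), "log2norm")
    truth = {c: ("FH" if c.startswith("fh") else "FL") for c in cols}
    return expr, SignatureCollection(sig_list), truth


class TestFunctionLabels:
    def test_single_signature_consensus_is_its_label(self, rng):
        expr, sigs, truth = function_cohort(rng, n_sigs=1, genes_per=6, effect=3.0)
        per_sig, consensus = assign_function_labels(expr, SignatureCollection(sigs.signatures[:1]))
        for s, lab in consensus.items():
            expected = "FH" if per_sig.iloc[0][s] == "high" else "FL"
            assert lab == expected

    def test_planted_fh_recovered(self, rng):
        expr, sigs, truth = function_cohort(rng, effect=1.5)
        _, consensus = assign_function_labels(expr, sigs)
        pred = [consensus[s] for s in truth]
        assert adjusted_rand_score([truth[s] for s in truth], pred) == 1.0

    def test_minority_high_is_fl(self, rng):
        """A group high in only 4 of 9 signatures lands in FL under strict majority."""
        n_per, genes_per = 8, 4
        genes, sig_list = [], []
        for k in range(9):
            gs = [f"sig{k}_g{j}" for j in range(genes_per)]
            genes += gs
            sig_list.append(GeneSignature(f"fsig{k}", "function", frozenset(gs)))
        cols = (
            [f"partial{i}" for i in range(n_per)]
            + [f"full{i}" for i in range(n_per)]
            + [f"none{i}" for i in range(n_per)]
        )
        base = rng.normal(5, 0.5, size=(len(genes), 3 * n_per))
        # signatures 0-3 elevated in 'partial' and 'full'; 4-8 in 'full' only
        for k in range(4):
            base[k * genes_per:(k + 1) * genes_per, : 2 * n_per] += 3.0
        for k in range(4, 9):
            base[k * genes_per:(k + 1) * genes_per, n_per: 2 * n_per] += 3.0
        expr = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=cols), "log2norm")
        per_sig, consensus = assign_function_labels(expr, SignatureCollection(sig_list))
        partial = [c for c in cols if c.startswith("partial")]
        assert all((per_sig[s] == "high").sum() == 4 for s in partial)
        assert all(consensus[s] == "FL" for s in partial)
        assert all(consensus[s] == "FH" for s in cols if s.startswith("full"))

    def test_no_signatures_errors(self, tiny_expr):
        with pytest.raises(ValueError):
            assign_function_labels(tiny_expr, SignatureCollection([]))

    def test_consensus_rules_agree_on_clean_structure(self, rng):
        expr, sigs, truth = function_cohort(rng, effect=2.5)
        _, maj = assign_function_labels(expr, sigs, consensus="majority")
        _, clu = assign_function_labels(expr, sigs, consensus="cluster")
        assert maj == clu


class TestCombine:
    def test_cross_product_label(self):
        out = combine_immune_class({"s1": "IIH"}, {"s1": "FH"})
        assert out[0].combined == "IIH-FH"

    def test_three_class_cohort_allowed(self):
        inf = {"a": "IIL", "b": "IIH", "c": "IIH"}
        fun = {"a": "FL", "b": "FL", "c": "FH"}
        out = combine_immune_class(inf, fun)
        observed = {c.combined for c in out}
        assert observed == {"IIL-FL", "IIH-FL", "IIH-FH"}

    def test_disjoint_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            combine_immune_class({"a": "IIL"}, {"b": "FL"})


class TestEndToEndRecovery:
    def test_gene_and_sample_order_invariance(self, small_cohort, rng):
        from immunoclass.model import ImmuneProfileModel

        res1 = ImmuneProfileModel.from_cohort(small_cohort).fit()
        expr = small_cohort.expr
        gperm = rng.permutation(expr.gene_ids)
        sperm = rng.permutation(expr.sample_ids)
        shuffled = ExpressionMatrix(expr.values.loc[gperm, sperm], expr.scale)
        res2 = ImmuneProfileModel(
            shuffled, small_cohort.signatures, small_cohort.annotations
        ).fit()
        assert res1.combined == res2.combined

    def test_monotone_in_infiltrate_effect(self):
        """Stronger planted infiltrate separation never hurts recovery."""
        from immunoclass.model import ImmuneProfileModel
        from immunoclass.synth import SyntheticCohortSpec, generate_cohort

        aris = []
        for effect in (0.5, 1.25, 2.5):
            vals = []
            for seed in range(3):
                cohort = generate_cohort(
                    SyntheticCohortSpec(
                        n_samples=40, n_genes=300, infiltrate_effect=effect, seed=100 + seed
                    )
                )
                res = ImmuneProfileModel.from_cohort(cohort).fit()
                truth_inf = {s: t[0] for s, t in cohort.truth.items()}
                pred = {c.sample_id: c.infiltrate for c in res.classification}
                vals.append(
                    adjusted_rand_score(
                        [truth_inf[s] for s in truth_inf], [pred[s] for s in truth_inf]
                    )
                )
            aris.append(np.mean(vals))
        assert aris[0] <= aris[1] + 0.05 and aris[1] <= aris[2] + 0.05
        assert aris[2] > 0.9


class TestWithinStratumFunctionMode:
    def test_flag_produces_labels_for_every_sample(self, small_cohort):
        from immunoclass.model import ImmuneProfileModel

        res = ImmuneProfileModel.from_cohort(
            small_cohort, function_within_infiltrate=True
        ).fit()
        assert len(res.classification) == 40
        assert set(res.per_signature_function.columns) == set(small_cohort.expr.sample_ids)

    def test_matches_cohort_wide_on_strong_structure(self, default_cohort):
        from immunoclass.model import ImmuneProfileModel

        cohort_wide = ImmuneProfileModel.from_cohort(default_cohort).fit()
        stratified = ImmuneProfileModel.from_cohort(
            default_cohort, function_within_infiltrate=True
        ).fit()
        agree = np.mean(
            [cohort_wide.combined[s] == stratified.combined[s] for s in cohort_wide.combined]
        )
        assert agree >= 0.9
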