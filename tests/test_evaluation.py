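"""Grouped cross-validation and all evaluation summaries."""

import numpy as np
import pandas as pd
import pytest

from nonsenseq import evaluation
from nonsenseq.evaluation import (
    auc,
    balanced_accuracy,
    composition_logratio,
    confusion_metrics,
    content_histogram,
    correlate_dc_nc,
    grouped_kfold,
    per_protein_metrics,
    per_sequence_content,
    stratified_evaluation,
    threshold_sweep,
    total_content_margins,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == "NONSENSE"]
    neg = scores[labels == "TRUE"]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestGroupedKFold:
    def test_equal_fold_sizes(self):
        ids = [f"s{i}" for i in range(100)]
        fa = grouped_kfold(ids, k=10, seed=0)
        sizes = np.bincount(list(fa.folds.values()), minlength=10)
        assert (sizes == 10).all()

    def test_grouping_keeps_gene_together(self):
        ids = [f"g{i}|{j}" for i in range(20) for j in range(3)]
        groups = {s: s.split("|")[0] for s in ids}
        fa = grouped_kfold(ids, k=5, seed=1, groups=groups)
        for g in range(20):
            folds = {fa.folds[f"g{g}|{j}"] for j in range(3)}
            assert len(folds) == 1

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(57)]
        assert grouped_kfold(ids, seed=4).folds == grouped_kfold(ids, seed=4).folds

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b"], k=10)


class TestConfusionMetrics:
    def test_balanced_accuracy_is_mean_of_class_accuracies(self):
        assert balanced_accuracy(0.8228, 0.8328) == pytest.approx(0.8278)

    def test_perfect_separation(self):
        scores = np.r_[np.full(50, 0.1), np.full(50, 0.9)]
        labels = np.array(["TRUE"] * 50 + ["NONSENSE"] * 50)
        m = confusion_metrics(scores, labels)
        assert m.specificity == m.sensitivity == m.balanced_accuracy == 1.0
        assert m.auc == 1.0

    def test_random_scores_give_chance_level(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = rng.random(2 * n)
        labels = np.array(["TRUE"] * n + ["NONSENSE"] * n)
        m = confusion_metrics(scores, labels)
        assert abs(m.balanced_accuracy - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([0.4]), np.array(["TRUE"]))


class TestAuc:
    def test_tied_scores_give_half(self):
        labels = np.array(["TRUE"] * 5 + ["NONSENSE"] * 5)
        assert auc(np.full(10, 0.3), labels) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for n in (10, 50, 200):
            # quantize so ties occur
            scores = np.round(rng.random(n), 2)
            labels = rng.choice(["TRUE", "NONSENSE"], size=n)
            if len(set(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestStratifiedEvaluation:
    @pytest.fixture()
    def frame_scores(self):
        rng = np.random.default_rng(2)
        n = 2000
        klass = rng.choice(["TRUE", "NONSENSE"], size=n)
        frame = pd.DataFrame({
            "klass": klass,
            "disorder_bin": rng.choice(["ordered", "disordered"], size=n),
            "origin_bin": np.where(
                klass == "NONSENSE",
                rng.choice(["coding", "noncoding"], size=n), None
            ),
        })
        scores = np.clip(
            rng.normal(np.where(klass == "NONSENSE", 0.7, 0.3), 0.2), 0, 1
        )
        return frame, scores

    def test_origin_strata_share_specificity(self, frame_scores):
        frame, scores = frame_scores
        rep = stratified_evaluation(scores, frame)
        assert rep.strata["nonsense_from_noncoding"].specificity == \
               rep.strata["nonsense_from_exons"].specificity == \
               rep.overall.specificity

    def test_strata_equal_direct_recomputation(self, frame_scores):
        frame, scores = frame_scores
        rep = stratified_evaluation(scores, frame)
        sel = (frame["disorder_bin"] == "ordered").to_numpy()
        direct = confusion_metrics(scores[sel], frame["klass"].to_numpy()[sel])
        assert rep.strata["ordered"].balanced_accuracy == direct.balanced_accuracy
        assert rep.strata["ordered"].auc == direct.auc

    def test_trivial_stratum_equals_overall(self, frame_scores):
        frame, scores = frame_scores
        uniform = frame.copy()
        uniform["disorder_bin"] = "ordered"
        rep = stratified_evaluation(scores, uniform)
        assert rep.strata["ordered"].as_dict() == rep.overall.as_dict()


class TestContentSummaries:
    def test_threshold_sweep_example(self):
        df = threshold_sweep({"NP": np.array([0.45, 0.55, 0.65])})
        at = dict(zip(df["threshold"], df["fraction_above"]))
        assert at[0.5] == pytest.approx(2 / 3)
        assert at[0.4] >= at[0.5] >= at[0.6]

    def test_sweep_matches_recount(self):
        rng = np.random.default_rng(3)
        nc = rng.random(200)
        df = threshold_sweep({"x": nc})
        for _, r in df.iterrows():
            assert r["fraction_above"] == np.count_nonzero(nc > r["threshold"]) / 200

    def test_margin_of_identical_sets_is_zero(self):
        s = np.random.default_rng(4).random(100)
        df = total_content_margins({"a": s, "b": s.copy()})
        margin = df.loc[df["set"] == "a - b", "total_nonsense_content"].item()
        assert margin == 0.0

    def test_margin_equals_sens_plus_spec_minus_one(self, small_cv, small_built):
        frame = small_built.dataset.frame
        scores = small_cv.oof_scores
        labels = frame["klass"].to_numpy()
        m = confusion_metrics(scores, labels, with_auc=False)
        df = total_content_margins({
            "nons": scores[labels == "NONSENSE"],
            "true": scores[labels == "TRUE"],
        })
        margin = df.loc[df["set"] == "nons - true", "total_nonsense_content"].item()
        assert margin == pytest.approx(m.sensitivity + m.specificity - 1, abs=1e-12)

    def test_histogram_conserves_sequences(self):
        rng = np.random.default_rng(5)
        nc = rng.random(137)
        h = content_histogram(nc)
        assert h["count"].sum() == 137
        assert h["fraction"].sum() == pytest.approx(1.0)


class TestCorrelation:
    def test_perfect_correlation(self):
        dc = np.linspace(0.1, 0.9, 50)
        rep = correlate_dc_nc(dc, dc.copy())
        assert rep.pearson_rho == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(6)
        rep = correlate_dc_nc(rng.random(1000), rng.random(1000))
        assert abs(rep.pearson_rho) < 0.1
        assert rep.p_value > 0.001

    def test_rho_squared_identity(self):
        rng = np.random.default_rng(7)
        dc = rng.random(80)
        nc = 0.3 * dc + rng.normal(0, 0.1, 80)
        rep = correlate_dc_nc(dc, nc)
        assert rep.r_squared == pytest.approx(rep.pearson_rho**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_dc_nc(np.full(10, 0.5), np.random.default_rng(8).random(10))


class TestCompositionLogratio:
    def test_identical_sets_give_zero(self):
        df = composition_logratio(["MAKEMAKE"], ["MAKEMAKE"])
        assert np.allclose(df["log2_ratio"].dropna(), 0.0)

    def test_doubled_frequency_gives_ratio_one(self):
        a = ["PP" + "ACDEFGHIKLMNQRSTVWY" * 2]
        b = ["P" + "ACDEFGHIKLMNQRSTVWY" * 2]
        df = composition_logratio(a, b).set_index("amino_acid")
        fa = 2 / len(a[0])
        fb = 1 / len(b[0])
        assert df.loc["P", "log2_ratio"] == pytest.approx(np.log2(fa / fb))


class TestCrossValidation:
    def test_every_residue_scored_once_out_of_fold(self, small_cv, small_built):
        assert np.isfinite(small_cv.oof_scores).all()
        assert len(small_cv.oof_scores) == len(small_built.dataset)

    def test_no_leakage_between_folds(self, small_cv, small_built):
        frame = small_built.dataset.frame
        fold_of = frame["sequence_id"].map(small_cv.assignment.folds)
        # a gene's protein and all its nonsense segments share a fold
        per_gene = frame.groupby("gene_id").apply(
            lambda g: g["sequence_id"].map(small_cv.assignment.folds).nunique(),
            include_groups=False,
        )
        assert (per_gene == 1).all()
        # each fold model saw no test-fold sequence (fold index partition)
        assert set(fold_of.unique()) == set(range(5))

    def test_oof_close_to_heldout_split_estimate(self, small_cv, small_built):
        from nonsenseq.nonsense_predictor import TrainConfig, train_ensemble

        ds = small_built.dataset
        labels = ds.frame["klass"].to_numpy()
        m_cv = confusion_metrics(small_cv.oof_scores, labels, with_auc=False)

        genes = sorted(ds.frame["gene_id"].unique())
        rng = np.random.default_rng(0)
        held = set(rng.choice(genes, size=len(genes) // 5, replace=False))
        test_rows = ds.frame["gene_id"].isin(held).to_numpy()
        ens = train_ensemble(ds, n_members=2, base_seed=5,
                             indices=np.flatnonzero(~test_rows),
                             config=TrainConfig(max_epochs=80, patience=10))
        scores = ens.predict(ds.features[test_rows])
        m_split = confusion_metrics(scores, labels[test_rows], with_auc=False)
        assert abs(m_cv.balanced_accuracy - m_split.balanced_accuracy) <= 0.05

    def test_per_protein_aggregation(self, small_cv, small_built):
        content = per_sequence_content(small_built.dataset.frame, small_cv.oof_scores)
        assert content["nonsense_content"].between(0, 1).all()
        m = per_protein_metrics(content)
        assert m.balanced_accuracy == pytest.approx(
            (m.specificity + m.sensitivity) / 2
        )
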