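import itertools

import numpy as np
import pytest

from snpsib.classify import lda_fit
from snpsib.genio import GenotypeMatrix
from snpsib.metrics import confusion, hmss
from snpsib.select import (
    ClassifierSpec,
    constrained_search,
    cv_hmss,
    evaluate_on_test,
    exhaustive_search,
    filter_rank,
    forward_selection,
    make_folds,
    sffs,
)
from snpsib.simdata import SimConfig, simulate_cohorts

LDA = ClassifierSpec(kind="lda", base_seed=0)


def _gm(codes, prefix="rs"):
    codes = np.asarray(codes, dtype=np.int8)
    return GenotypeMatrix(
        codes=codes,
        sample_ids=[f"s{i}" for i in range(codes.shape[0])],
        snp_ids=[f"{prefix}{j}" for j in range(codes.shape[1])],
    )


class TestFolds:
    def test_balanced_stratified(self):
        y = np.array([1] * 10 + [0] * 10)
        folds = make_folds(y, k=5, seed=0)
        for f in range(5):
            held = folds.held_out(f)
            assert y[held].sum() == 2 and len(held) == 4

    def test_seeded_deterministic(self):
        y = np.array([1] * 12 + [0] * 9)
        a = make_folds(y, k=3, seed=5)
        b = make_folds(y, k=3, seed=5)
        assert np.array_equal(a.fold_index, b.fold_index)

    def test_class_smaller_than_k_errors(self):
        with pytest.raises(ValueError):
            make_folds(np.array([1, 1, 1, 0, 0]), k=3)


class TestCVHMSS:
    def test_separating_snp_is_perfect(self):
        y = np.array([1] * 10 + [0] * 10)
        G = _gm(np.where(y[:, None] == 1, 0, 2))
        folds = make_folds(y, k=5, seed=0)
        value, _ = cv_hmss(LDA, G, y, ["rs0"], folds)
        assert value == 1.0

    def test_constant_snp_is_zero(self):
        y = np.array([1] * 10 + [0] * 10)
        G = _gm(np.ones((20, 1)))
        folds = make_folds(y, k=5, seed=0)
        value, (yt, yp) = cv_hmss(LDA, G, y, ["rs0"], folds)
        assert value == 0.0
        assert len(yt) == 20  # pooled over all held-out folds

    def test_matches_hand_rolled_two_fold(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        codes = rng.integers(0, 3, (8, 1))
        G = _gm(codes)
        folds = make_folds(y, k=2, seed=3)
        value, _ = cv_hmss(LDA, G, y, ["rs0"], folds)
        parts = []
        for f in range(2):
            tr, te = folds.held_in(f), folds.held_out(f)
            model = lda_fit(codes[tr].astype(float), y[tr])
            parts.append((y[te], model.predict(codes[te].astype(float))))
        yt = np.concatenate([p[0] for p in parts])
        yp = np.concatenate([p[1] for p in parts])
        assert value == pytest.approx(hmss(confusion(yt, yp)))

    def test_empty_subset_errors(self, small_study):
        G_tr, y_tr, *_ = small_study
        with pytest.raises(ValueError):
            cv_hmss(LDA, G_tr, y_tr, [], make_folds(y_tr, seed=0))


class TestFilterRank:
    def test_planted_causal_ranks_first(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_snps=200, n_cases_train=900, n_controls_train=700,
                            n_cases_test=5, n_controls_test=5, causal_indices=(50,),
                            causal_log_odds=(1.5,), missing_rate=0.0, seed=seed)
            (tr, y), _, _ = simulate_cohorts(cfg)
            ranked = filter_rank(tr, y, top_k=200)
            if ranked["snp_id"].iloc[0] == tr.snp_ids[50]:
                hits += 1
        assert hits >= 9

    def test_monomorphic_scores_zero_and_ranks_last(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, (60, 4))
        codes[:, 2] = 2  # monomorphic
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        ranked = filter_rank(_gm(codes), y, top_k=10)
        row = ranked[ranked.snp_id == "rs2"]
        assert row["hmss"].iloc[0] == 0.0
        assert row.index[-1] >= 2  # not ahead of any positive-scoring SNP

    def test_top_k_exceeding_m_returns_all(self, small_study):
        G_tr, y_tr, *_ = small_study
        assert len(filter_rank(G_tr, y_tr, top_k=10_000)) == G_tr.n_snps

    def test_scores_equal_resubstitution_oracle(self, small_study):
        # filter scores are exactly the exhaustive size-1 training-HMSS values
        G_tr, y_tr, *_ = small_study
        ranked = filter_rank(G_tr, y_tr, top_k=5)
        for _, row in ranked.iterrows():
            x = G_tr.column(row.snp_id).reshape(-1, 1).astype(float)
            model = lda_fit(x, y_tr)
            assert row.hmss == pytest.approx(hmss(confusion(y_tr, model.predict(x))))


class TestForwardSelection:
    @pytest.fixture()
    def fs_inputs(self, small_study):
        G_tr, y_tr, G_te, y_te, truth = small_study
        folds = make_folds(y_tr, k=5, seed=2)
        cand = filter_rank(G_tr, y_tr, top_k=10)["snp_id"].tolist()
        return G_tr, y_tr, G_te, y_te, folds, cand

    def test_first_step_is_exhaustive_size1_argmax(self, fs_inputs):
        G_tr, y_tr, G_te, y_te, folds, cand = fs_inputs
        trace = forward_selection(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                  max_size=2, n_boot=30)
        best1 = exhaustive_search(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                  sizes=(1,), n_boot=30, n_report=1)[0]
        assert trace.records[0].snp_ids == best1.snp_ids

    def test_subsets_nested(self, fs_inputs):
        G_tr, y_tr, G_te, y_te, folds, cand = fs_inputs
        trace = forward_selection(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                  max_size=4, n_boot=30)
        for prev, cur in zip(trace.records, trace.records[1:]):
            assert set(prev.snp_ids) < set(cur.snp_ids)
            assert cur.size == prev.size + 1

    def test_recovers_planted_causal_pair(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_snps=50, n_cases_train=400, n_controls_train=300,
                            n_cases_test=50, n_controls_test=50,
                            causal_indices=(10, 30), causal_log_odds=(1.2, 1.2),
                            missing_rate=0.0, seed=100 + seed)
            (tr, ytr), (te, yte), truth = simulate_cohorts(cfg)
            causal = {tr.snp_ids[i] for i in truth.causal_indices}
            folds = make_folds(ytr, k=5, seed=seed)
            trace = forward_selection(LDA, list(tr.snp_ids), tr, ytr, te, yte,
                                      folds, max_size=4, n_boot=10)
            if causal <= set(trace.records[-1].snp_ids):
                hits += 1
        assert hits >= 8

    def test_max_size_exceeding_candidates_errors(self, fs_inputs):
        G_tr, y_tr, G_te, y_te, folds, cand = fs_inputs
        with pytest.raises(ValueError):
            forward_selection(LDA, cand[:3], G_tr, y_tr, G_te, y_te, folds,
                              max_size=5)


class TestSFFS:
    def test_size2_entry_is_exhaustive_pair_optimum(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=2)
        cand = filter_rank(G_tr, y_tr, top_k=6)["snp_id"].tolist()
        trace = sffs(LDA, cand, G_tr, y_tr, G_te, y_te, folds, max_size=3, n_boot=30)
        pair_vals = {
            frozenset(p): cv_hmss(LDA, G_tr, y_tr, list(p), folds)[0]
            for p in itertools.combinations(cand, 2)
        }
        rec2 = next(r for r in trace.records if r.size == 2)
        assert pair_vals[frozenset(rec2.snp_ids)] == pytest.approx(max(pair_vals.values()))

    def test_never_beats_brute_force_per_size(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=2)
        cand = filter_rank(G_tr, y_tr, top_k=6)["snp_id"].tolist()
        trace = sffs(LDA, cand, G_tr, y_tr, G_te, y_te, folds, max_size=3, n_boot=30)
        for rec in trace.records:
            if rec.size > 3:
                continue
            brute = max(
                cv_hmss(LDA, G_tr, y_tr, list(sub), folds)[0]
                for sub in itertools.combinations(cand, rec.size)
            )
            assert rec.cv_hmss.point <= brute + 1e-12
        rec2 = next(r for r in trace.records if r.size == 2)
        brute2 = max(cv_hmss(LDA, G_tr, y_tr, list(p), folds)[0]
                     for p in itertools.combinations(cand, 2))
        assert rec2.cv_hmss.point == pytest.approx(brute2)

    def test_max_size_below_two_errors(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        with pytest.raises(ValueError):
            sffs(LDA, list(G_tr.snp_ids[:4]), G_tr, y_tr, G_te, y_te,
                 make_folds(y_tr, seed=0), max_size=1)


class TestExhaustive:
    def test_pair_count(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=0)
        cand = list(G_tr.snp_ids[:3])
        recs = exhaustive_search(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                 sizes=(2,), n_boot=10, n_report=10)
        assert len(recs) == 3  # C(3,2)

    def test_ranking_invariant_to_candidate_order(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=0)
        cand = filter_rank(G_tr, y_tr, top_k=6)["snp_id"].tolist()
        a = exhaustive_search(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                              n_boot=10, n_report=3)
        b = exhaustive_search(LDA, cand[::-1], G_tr, y_tr, G_te, y_te, folds,
                              n_boot=10, n_report=3)
        assert [r.snp_ids for r in a] == [r.snp_ids for r in b]

    def test_large_sizes_need_override(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, seed=0)
        with pytest.raises(ValueError, match="allow_large"):
            exhaustive_search(LDA, list(G_tr.snp_ids[:5]), G_tr, y_tr, G_te, y_te,
                              folds, sizes=(3,))


class TestConstrained:
    def test_vacuous_floor_reduces_to_unconstrained(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=1)
        cand = filter_rank(G_tr, y_tr, top_k=5)["snp_id"].tolist()
        res = constrained_search(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                 constrained_group="cases", min_acc=0.0,
                                 top_n=3, sizes=(1,), n_boot=10)
        from snpsib.select import _Evaluator
        ev = _Evaluator(LDA, G_tr, y_tr, folds)
        best_ctrl = max(
            (confusion(*ev.cv([c])[1:]).tn / (y_tr == 0).sum(), c) for c in cand
        )
        assert res.records[0].snp_ids == (best_ctrl[1],)

    def test_floor_is_respected(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=1)
        cand = filter_rank(G_tr, y_tr, top_k=8)["snp_id"].tolist()
        res = constrained_search(LDA, cand, G_tr, y_tr, G_te, y_te, folds,
                                 constrained_group="cases", min_acc=0.4,
                                 top_n=5, n_boot=10)
        for rec in res.records:
            assert rec.cv_case_acc.point >= 0.4

    def test_unsatisfiable_floor_warns_empty(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=1)
        with pytest.warns(UserWarning):
            res = constrained_search(LDA, list(G_tr.snp_ids[:4]), G_tr, y_tr,
                                     G_te, y_te, folds, constrained_group="cases",
                                     min_acc=1.01, n_boot=10)
        assert res.status == "empty" and res.best is None


class TestEvaluateOnTest:
    def test_train_as_test_equals_resubstitution(self, small_study):
        G_tr, y_tr, *_ = small_study
        snp = filter_rank(G_tr, y_tr, top_k=1)["snp_id"].iloc[0]
        rec = evaluate_on_test(LDA, [snp], G_tr, y_tr, G_tr, y_tr, n_boot=20, seed=0)
        x = G_tr.column(snp).reshape(-1, 1).astype(float)
        model = lda_fit(x, y_tr)
        assert rec.test_hmss.point == pytest.approx(
            hmss(confusion(y_tr, model.predict(x)))
        )

    def test_bit_reproducible(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        spec = ClassifierSpec(kind="sib", base_seed=4)
        a = evaluate_on_test(spec, [G_tr.snp_ids[0]], G_tr, y_tr, G_te, y_te,
                             n_boot=50, seed=9)
        b = evaluate_on_test(spec, [G_tr.snp_ids[0]], G_tr, y_tr, G_te, y_te,
                             n_boot=50, seed=9)
        assert a == b

    def test_separable_pair_scores_high(self):
        cfg = SimConfig(n_snps=20, n_cases_train=300, n_controls_train=300,
                        n_cases_test=200, n_controls_test=200,
                        causal_indices=(4, 9), causal_log_odds=(3.0, 3.0),
                        maf_low=0.25, maf_high=0.4, missing_rate=0.0,
                        intercept=-2.5, seed=8)
        (tr, ytr), (te, yte), truth = simulate_cohorts(cfg)
        subset = [tr.snp_ids[i] for i in truth.causal_indices]
        rec = evaluate_on_test(ClassifierSpec(kind="sib", base_seed=0), subset,
                               tr, ytr, te, yte, n_boot=50, seed=1)
        assert rec.test_hmss.point > 0.75


class TestTestBlindness:
    def test_perturbed_test_labels_change_no_selection(self, small_study):
        G_tr, y_tr, G_te, y_te, _ = small_study
        folds = make_folds(y_tr, k=5, seed=3)
        cand = filter_rank(G_tr, y_tr, top_k=6)["snp_id"].tolist()
        rng = np.random.default_rng(0)
        y_perturbed = rng.permutation(y_te)
        for spec in (LDA, ClassifierSpec(kind="sib", base_seed=5)):
            fs_a = forward_selection(spec, cand, G_tr, y_tr, G_te, y_te, folds,
                                     max_size=3, n_boot=10)
            fs_b = forward_selection(spec, cand, G_tr, y_tr, G_te, y_perturbed,
                                     folds, max_size=3, n_boot=10)
            assert [r.snp_ids for r in fs_a.records] == [r.snp_ids for r in fs_b.records]
            sf_a = sffs(spec, cand, G_tr, y_tr, G_te, y_te, folds, max_size=3,
                        n_boot=10)
            sf_b = sffs(spec, cand, G_tr, y_tr, G_te, y_perturbed, folds,
                        max_size=3, n_boot=10)
            assert [r.snp_ids for r in sf_a.records] == [r.snp_ids for r in sf_b.records]
            ex_a = exhaustive_search(spec, cand, G_tr, y_tr, G_te, y_te, folds,
                                     n_boot=10, n_report=3)
            ex_b = exhaustive_search(spec, cand, G_tr, y_tr, G_te, y_perturbed,
                                     folds, n_boot=10, n_report=3)
            assert [r.snp_ids for r in ex_a] == [r.snp_ids for r in ex_b]


class TestNullCalibration:
    def test_fs_best_subset_is_chance_level_under_permuted_labels(self):
        # permuting labels breaks all genotype-phenotype association; the
        # FS-selected best subset should then score near chance on test data
        vals = []
        for seed in range(20):
            cfg = SimConfig(n_snps=30, n_cases_train=150, n_controls_train=150,
                            n_cases_test=100, n_controls_test=100,
                            causal_indices=(), causal_log_odds=(),
                            missing_rate=0.0, intercept=0.0, seed=seed)
            (tr, ytr), (te, yte), _ = simulate_cohorts(cfg)
            rng = np.random.default_rng(seed)
            ytr = rng.permutation(ytr)
            yte = rng.permutation(yte)
            folds = make_folds(ytr, k=5, seed=seed)
            cand = filter_rank(tr, ytr, top_k=10)["snp_id"].tolist()
            trace = forward_selection(LDA, cand, tr, ytr, te, yte, folds,
                                      max_size=3, n_boot=10)
            best = max(trace.records, key=lambda r: r.cv_hmss.point)
            vals.append(best.test_hmss.point)
        assert 0.40 <= np.mean(vals) <= 0.60
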