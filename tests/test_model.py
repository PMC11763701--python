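import json
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasma_surv import (
    MultiOmicsCollection,
    Plasma,
    PlasmaConfig,
    PlasmaModel,
    PlasmaResults,
    harmonize,
    plasma_predict,
    predict_risk,
)
from plasma_surv.model import (
    fit_extensions,
    fit_final,
    fit_single_models,
    predict_components,
)
from plasma_surv.simulate import BlockSpec, SimulationConfig, simulate_study

from conftest import make_block, make_outcome


@pytest.fixture(scope="module")
def fitted(small_study):
    res = Plasma(small_study.collection).fit(seed=1)
    return small_study, res


class TestSingleModels:
    def test_one_model_per_block_with_table_style_names(self, fitted):
        study, res = fitted
        singles = res.plasma_model.singles
        assert [s.name for s in singles] == ["A", "B"]
        assert singles[0].component_names == ["A1", "A2"]

    def test_scores_cover_exactly_the_assayed_samples(self, fitted):
        study, res = fitted
        for s in res.plasma_model.singles:
            assayed = study.collection.block(s.name).assayed_samples
            assert s.scores.index.equals(assayed)

    def test_split_model_logrank_available_per_block(self, fitted):
        from plasma_surv import log_rank

        study, res = fitted
        for s in res.plasma_model.singles:
            ds = study.collection.block(s.name)
            X = ds.values.loc[:, ds.assayed_samples].T
            risk, group = predict_risk(s.pls, X)
            out = study.collection.outcome.subset(risk.index)
            lr = log_rank(out, group)
            assert 0.0 < lr.p_value <= 1.0

    def test_zero_event_block_excluded_with_warning(self, rng):
        ids = [f"s{i}" for i in range(40)]
        b1 = make_block("good", rng.normal(size=(10, 40)), ids)
        vals = rng.normal(size=(5, 40))
        vals[:, 20:] = np.nan  # assayed only on the censored half
        b2 = make_block("dead", vals, ids)
        outcome = make_outcome(
            rng.exponential(size=40) + 0.1, [0] * 20 + [1] * 20, ids
        )
        coll = harmonize([b1, b2], outcome)
        with pytest.warns(UserWarning, match="zero events"):
            singles = fit_single_models(coll, PlasmaConfig())
        assert [s.name for s in singles] == ["good"]


class TestExtensions:
    def test_pair_count_includes_self(self, fitted):
        _, res = fitted
        exts = res.plasma_model.extensions
        assert len(exts) == 2
        assert all(set(e.models) == {"A", "B"} for e in exts)

    def test_self_pair_reproduces_scores_exactly(self, fitted):
        study, res = fitted
        for es in res.plasma_model.extensions:
            tgt = next(s for s in res.plasma_model.singles if s.name == es.target)
            ds = study.collection.block(es.target)
            X = ds.values.loc[:, ds.assayed_samples].T
            rec = es.models[es.target].model.predict(X)
            assert np.abs(rec - tgt.scores).max().max() < 1e-6

    def test_small_intersection_skipped(self, rng):
        ids = [f"s{i}" for i in range(60)]
        v1 = rng.normal(size=(8, 60))
        v2 = rng.normal(size=(8, 60))
        v1[:, 30:] = np.nan  # disjoint-ish coverage: overlap of 5 samples
        v2[:, :25] = np.nan
        b1 = make_block("b1", v1, ids)
        b2 = make_block("b2", v2, ids)
        outcome = make_outcome(rng.exponential(size=60) + 0.1, np.ones(60), ids)
        coll = harmonize([b1, b2], outcome)
        singles = fit_single_models(coll, PlasmaConfig())
        with pytest.warns(UserWarning, match="skipped"):
            exts = fit_extensions(coll, singles, PlasmaConfig(min_intersection=10))
        by_target = {e.target: set(e.models) for e in exts}
        assert by_target == {"b1": {"b1"}, "b2": {"b2"}}


class TestComponentMatrix:
    def test_fully_assayed_cohort_has_no_missing_cells(self, fitted):
        study, res = fitted
        pred = res.predict()
        fully = study.collection.assayed_any()
        assert fully.all()
        assert pred.components.values.notna().all().all()

    def test_single_source_sample_equals_that_sources_prediction(self, fitted):
        study, res = fitted
        pm = res.plasma_model
        cm = pred = res.predict().components
        only_a = study.collection.block("A").assayed & ~study.collection.block("B").assayed
        sample = only_a.index[only_a][0]
        ds = study.collection.block("A")
        X = ds.values[[sample]].T
        for es in pm.extensions:
            direct = es.models["A"].model.predict(X)
            for c in direct.columns:
                assert cm.values.loc[sample, c] == pytest.approx(
                    float(direct[c].iloc[0]), abs=1e-10
                )

    def test_source_counts_reflect_assay_pattern(self, fitted):
        study, res = fitted
        cm = res.predict().components
        n_blocks_per_sample = (
            study.collection.block("A").assayed.astype(int)
            + study.collection.block("B").assayed.astype(int)
        )
        for comp in cm.values.columns:
            pd.testing.assert_series_equal(
                cm.n_sources[comp].astype(int), n_blocks_per_sample,
                check_names=False,
            )


class TestFinalModel:
    def test_duplicated_component_collapses(self, fitted):
        study, res = fitted
        cm = res.predict().components
        X = cm.values.copy()
        X["dup"] = X.iloc[:, 0]
        from plasma_surv.model import ComponentMatrix

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, model = fit_final(
                ComponentMatrix(X, cm.n_sources.assign(dup=1)),
                study.collection.outcome,
            )
        assert not (X.columns[0] in retained and "dup" in retained)

    def test_report_has_conventional_columns(self, fitted):
        _, res = fitted
        cols = list(res.plasma_model.final_cox.summary().columns)
        assert cols == ["coef", "exp(coef)", "se(coef)", "z", "p"]


class TestEndToEnd:
    def test_training_scores_reproduce_stored_cutpoint(self, fitted):
        _, res = fitted
        risk = res.risk
        assert np.median(risk.dropna()) == pytest.approx(res.cutpoint, abs=1e-12)

    def test_deterministic_given_seed(self, small_study):
        r1 = Plasma(small_study.collection).fit(seed=4)
        r2 = Plasma(small_study.collection).fit(seed=4)
        assert json.dumps(r1.plasma_model.to_dict()) == json.dumps(
            r2.plasma_model.to_dict()
        )

    def test_every_sample_assayed_anywhere_gets_risk(self, fitted):
        study, res = fitted
        pred = res.predict()
        assert pred.risk.notna().all()

    def test_cohort_missing_a_whole_block_still_scored(self, fitted):
        study, res = fitted
        coll = study.collection
        keep = coll.block("A").assayed
        reduced = MultiOmicsCollection(
            [coll.block("A").subset_samples(keep.index[keep])],
            coll.outcome.subset(keep.index[keep]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = res.predict(reduced)
        assert pred.risk.notna().all()

    def test_no_shared_blocks_rejected(self, fitted, rng):
        study, res = fitted
        ids = study.collection.samples[:30]
        other = make_block("unrelated", rng.normal(size=(5, 30)), ids)
        coll = harmonize([other], study.collection.outcome.subset(ids))
        with pytest.raises(ValueError, match="no omics blocks"):
            plasma_predict(res.plasma_model, coll)

    def test_single_block_collection_reduces_to_pls_cox(self, rng):
        # with one fully-assayed block the integration must agree with the
        # plain single-block model up to a monotone transform
        ids = [f"s{i}" for i in range(150)]
        X = rng.normal(size=(150, 30))
        lh = X[:, 0] + X[:, 1]
        t = rng.exponential(scale=np.exp(-lh))
        b = make_block("solo", X.T, ids)
        outcome = make_outcome(t, np.ones(150), ids)
        coll = harmonize([b], outcome)
        res = Plasma(coll).fit(seed=0)
        single = res.plasma_model.singles[0]
        risk_single, _ = predict_risk(
            single.pls, coll.block("solo").values.T
        )
        rho = stats.spearmanr(res.risk, risk_single).statistic
        assert abs(rho) >= 0.99

    def test_save_load_round_trip_scores_identically(self, fitted, tmp_path):
        study, res = fitted
        path = tmp_path / "model.json"
        res.save(path)
        loaded = PlasmaResults.load(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred1 = res.predict(study.collection, seed=3)
            pred2 = loaded.predict(study.collection, seed=3)
        pd.testing.assert_series_equal(pred1.risk, pred2.risk)

    def test_summary_mentions_components_and_blocks(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "retained" in text and "A[" in text and "log-rank" in text
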