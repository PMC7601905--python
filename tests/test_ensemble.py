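"""Split-pair ensemble mechanics: splits, training, cutoffs, validation."""

import numpy as np
import pytest

from saspsurv import (SimulationConfig, bootstrap_validate, dichotomize,
                      evaluate_split, external_validate, generate_cohorts,
                      sample_split_pairs, select_models, train_model)
from saspsurv.ensemble import (SASP_HIGH, SASP_LOW, ModelRecord,
                               SplitEvaluation, _percentile_cutoff)


class TestSplitPairs:
    def test_half_partition_arithmetic(self, rtbt2):
        events = rtbt2.patients["event"].to_numpy()
        pairs = sample_split_pairs(276, events, 5, 50.0, seed=1)
        for train, test in pairs:
            assert len(train) == 138 and len(test) == 138
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 276
            assert events[train].sum() > 0 and events[test].sum() > 0

    def test_same_seed_identical(self, rtbt2):
        events = rtbt2.patients["event"].to_numpy()
        a = sample_split_pairs(276, events, 3, 50.0, seed=7)
        b = sample_split_pairs(276, events, 3, 50.0, seed=7)
        for (ta, _), (tb, _) in zip(a, b):
            assert np.array_equal(ta, tb)

    def test_train_membership_binomial(self, rtbt2):
        events = rtbt2.patients["event"].to_numpy()
        pairs = sample_split_pairs(276, events, 1000, 50.0, seed=2)
        counts = np.zeros(276)
        for train, _ in pairs:
            counts[train] += 1
        sigma = np.sqrt(1000 * 0.25)
        assert (np.abs(counts - 500) < 3.5 * sigma).all()

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            sample_split_pairs(10, np.zeros(10), 1, 50.0, seed=0)


class TestTrainModel:
    def test_cutoff_percentile_contract(self, rtbt2):
        tr = rtbt2.patients.iloc[:138]
        model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                            rtbt2.analytes.iloc[:138], "p8",
                            cutoff_percentile=40.0, seed=0)
        scores = model.score(rtbt2.analytes.iloc[:138])
        assert np.unique(scores).size == 138  # tie-free
        n_at_or_below = int(np.sum(scores <= model.cutoff_value))
        assert n_at_or_below == int(np.ceil(0.4 * 138))
        # frozen cutoff equals the training percentile to machine precision
        assert model.cutoff_value == _percentile_cutoff(scores, 40.0)

    def test_null_training_flagged_unstable(self, null_cohorts):
        c = null_cohorts[0]
        tr = c.patients.iloc[:138]
        model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                            c.analytes.iloc[:138], "p8", seed=1)
        assert model.unstable

    def test_signal_training_orients_high_worse(self, rtbt2):
        tr = rtbt2.patients.iloc[:138]
        model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                            rtbt2.analytes.iloc[:138], "p8", seed=2)
        ev = evaluate_split(model, tr, rtbt2.analytes.iloc[:138],
                            rtbt2.patients.iloc[138:],
                            rtbt2.analytes.iloc[138:])
        assert ev.train["hr"] >= 1.0


class TestDichotomize:
    @pytest.fixture(scope="class")
    def model(self, rtbt2):
        tr = rtbt2.patients.iloc[:138]
        return train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                           rtbt2.analytes.iloc[:138], "p8",
                           cutoff_percentile=40.0, seed=3)

    def test_training_label_proportions(self, model, rtbt2):
        labels = dichotomize(model, rtbt2.analytes.iloc[:138])
        assert int(np.sum(labels == SASP_LOW)) == int(np.ceil(0.4 * 138))

    def test_tie_at_cutoff_goes_low(self, model, rtbt2):
        analytes = rtbt2.analytes.iloc[:1].copy()
        scores = model.score(analytes)
        # shift one analyte so the score lands exactly on the cutoff
        j = list(model.proteins)[0]
        delta = (model.cutoff_value - scores[0]) / (
            model.fit.beta[0] / model.fit.scale[0])
        analytes[j] = analytes[j] + delta
        assert dichotomize(model, analytes)[0] == SASP_LOW

    def test_constant_shift_changes_labels(self, model, rtbt2):
        shifted = rtbt2.analytes.iloc[138:] + 5.0
        a = dichotomize(model, rtbt2.analytes.iloc[138:])
        b = dichotomize(model, shifted)
        assert not np.array_equal(a, b)  # no re-centering on new data

    def test_missing_protein_rejected(self, model, rtbt2):
        with pytest.raises(ValueError, match="missing"):
            dichotomize(model, rtbt2.analytes.drop(columns=["CRP"]))


def _record(train_hr, test_hr, p=0.01):
    ev = {"hr": train_hr, "ci_lo": train_hr / 2, "ci_hi": train_hr * 2,
          "p": p, "flagged": False}
    et = {**ev, "hr": test_hr}
    return ModelRecord(model=None, split_eval=SplitEvaluation(ev, et, 0))


class TestSelectModels:
    def test_unattainable_gate_empty(self):
        assert select_models([_record(5.0, 5.0)], hr_min=10.0) == []

    def test_gate_arithmetic(self):
        kept = select_models([_record(3.2, 3.1), _record(2.9, 5.0),
                              _record(3.5, 3.5, p=0.2)])
        assert len(kept) == 1
        assert kept[0].split_eval.train["hr"] == 3.2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_models([])


class TestValidation:
    @pytest.fixture(scope="class")
    def model(self, rtbt2):
        tr = rtbt2.patients.iloc[:138]
        return train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                           rtbt2.analytes.iloc[:138], "p8", seed=4,
                           trained_on="RTBT2")

    def test_bootstrap_bins_conserved(self, model, rtbt2):
        summary = bootstrap_validate(model, rtbt2.patients, rtbt2.analytes,
                                     n_boot=10, seed=0)
        assert sum(summary.bins.values()) == 10
        assert np.isfinite(summary.mean_hr)

    def test_bootstrap_deterministic(self, model, rtbt2):
        a = bootstrap_validate(model, rtbt2.patients, rtbt2.analytes,
                               n_boot=20, seed=5)
        b = bootstrap_validate(model, rtbt2.patients, rtbt2.analytes,
                               n_boot=20, seed=5)
        assert a.bins == b.bins and a.mean_hr == b.mean_hr

    def test_external_validation_guard(self, model, default_cohorts):
        with pytest.raises(ValueError, match="training cohort"):
            external_validate(model, [default_cohorts[0]])

    def test_external_validation_transfers(self, model, default_cohorts):
        results = external_validate(model, default_cohorts[1:])
        assert [r["cohort"] for r in results] == ["RTBT3", "RT3"]
        for r in results:
            assert np.isfinite(r["hr"])


def test_logistic_score_family_trains_and_dichotomizes(rtbt2):
    tr = rtbt2.patients.iloc[:138]
    model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                        rtbt2.analytes.iloc[:138], "p8", seed=8,
                        score_family="logistic")
    labels = dichotomize(model, rtbt2.analytes.iloc[:138])
    assert int(np.sum(labels == SASP_LOW)) == int(np.ceil(0.4 * 138))
    # the two score families agree on orientation under shared signal
    cox_model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                            rtbt2.analytes.iloc[:138], "p8", seed=8)
    agree = np.mean(labels == dichotomize(cox_model,
                                          rtbt2.analytes.iloc[:138]))
    assert agree > 0.7


def test_null_evaluation_hr_near_one(null_cohorts):
    c = null_cohorts[0]
    tr, te = c.patients.iloc[:138], c.patients.iloc[138:]
    model = train_model(tr["time"].to_numpy(), tr["event"].to_numpy(),
                        c.analytes.iloc[:138], "p8", seed=6)
    ev = evaluate_split(model, tr, c.analytes.iloc[:138], te,
                        c.analytes.iloc[138:])
    # held-out half is independent of the (noise-fit) score
    assert ev.test["p"] > 0.001 or 0.3 < ev.test["hr"] < 3.0
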