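"""SVR concentration predictor: learnability, null behavior, schema safety."""

import numpy as np
import pandas as pd
import pytest

from spotquant.chemometrics import (
    AssayDataset,
    SchemaMismatch,
    predict_concentration,
    train_predictor,
)
from spotquant.features import FEATURE_NAMES

SMALL_GRID = [
    {"sel__k": [12], "svr__C": [10.0], "svr__epsilon": [0.01], "svr__gamma": [1 / 12]}
]


def make_table(concentrations, replicates=3, noise_sd=0.0, seed=0, junk_sd=0.1):
    """Feature table whose response-linked columns follow the log model.

    The mean-type columns carry the signal a*ln(x)+b (plus optional noise);
    the remaining columns are irrelevant random values of spread
    ``junk_sd``, mimicking moment features dominated by per-image noise
    (``junk_sd=0`` makes the whole table deterministic in x).
    """
    rng = np.random.default_rng(seed)
    rows, concs, groups = [], [], []
    for c in concentrations:
        for rep in range(replicates):
            resp = 36.958 * np.log(c) + 61.367 + rng.normal(0.0, noise_sd)
            row = dict(zip(FEATURE_NAMES, rng.normal(0.0, junk_sd, len(FEATURE_NAMES))))
            row["gray_intensity"] = 255.0 - resp
            for name in ("R_mean", "G_mean", "B_mean", "Yn_mean", "V_mean"):
                row[name] = resp / 255.0
            row["Lstar_mean"] = resp / 2.0
            rows.append(row)
            concs.append(c)
            groups.append(rep)
    return AssayDataset(
        features=pd.DataFrame(rows),
        concentrations=np.array(concs),
        groups=np.array(groups),
    )


DESIGN = [0.5, 1, 2, 5, 8, 11, 14, 17, 20]


class TestTrainPredictor:
    def test_noiseless_target_is_learnable(self):
        data = make_table(DESIGN, replicates=3, noise_sd=0.0, seed=1, junk_sd=0.0)
        _, report = train_predictor(data, seed=1)
        assert report.r_squared >= 0.99

    def test_permuted_targets_have_no_skill(self):
        """Shuffling concentrations against features destroys the R^2."""
        rng = np.random.default_rng(2)
        scores = []
        for _ in range(20):
            data = make_table(DESIGN, replicates=3, noise_sd=0.0, seed=3)
            data.concentrations = rng.permutation(data.concentrations)
            _, report = train_predictor(data, seed=0, param_grid=SMALL_GRID)
            scores.append(report.r_squared)
        assert np.mean(scores) <= 0.2

    def test_no_leakage_in_standardization(self):
        """Scaler and selector parameters come from the training split only."""
        data = make_table(DESIGN, replicates=3, noise_sd=1.0, seed=4)
        model, report = train_predictor(data, seed=4, param_grid=SMALL_GRID)
        x = data.features.to_numpy(dtype=float)
        scaler = model.pipeline.named_steps["scale"]
        np.testing.assert_allclose(
            scaler.mean_, x[report.train_idx].mean(axis=0), rtol=1e-12
        )

    def test_groups_never_straddle_split(self):
        data = make_table(DESIGN, replicates=3, noise_sd=1.0, seed=5)
        _, report = train_predictor(data, seed=5, param_grid=SMALL_GRID)
        train_groups = set(data.groups[report.train_idx])
        test_groups = set(data.groups[report.test_idx])
        assert not train_groups & test_groups

    def test_single_concentration_rejected(self):
        data = make_table([5.0], replicates=3)
        with pytest.raises(ValueError):
            train_predictor(data)

    def test_report_pairs_cover_test_split(self):
        data = make_table(DESIGN, replicates=3, noise_sd=0.5, seed=6)
        _, report = train_predictor(data, seed=6, param_grid=SMALL_GRID)
        assert len(report.pairs) == report.n_test == len(report.test_idx)


@pytest.fixture(scope="module")
def trained():
    data = make_table(DESIGN, replicates=3, noise_sd=0.2, seed=7)
    model, report = train_predictor(data, seed=7, param_grid=SMALL_GRID)
    return data, model, report


class TestPredictConcentration:

    def test_training_samples_predicted_sanely(self, trained):
        data, model, _ = trained
        preds = predict_concentration(model, data.features)
        rel = np.abs(preds - data.concentrations) / data.concentrations
        assert np.median(rel) < 0.1

    def test_wrong_length_raises_schema_error(self, trained):
        _, model, _ = trained
        with pytest.raises(SchemaMismatch):
            model.predict(np.zeros(50))

    def test_column_order_invariance(self, trained):
        data, model, _ = trained
        shuffled = data.features[list(reversed(data.features.columns))]
        np.testing.assert_allclose(
            model.predict(shuffled), model.predict(data.features), rtol=1e-12
        )

    def test_extrapolation_flagged(self):
        data = make_table(DESIGN, replicates=3, noise_sd=0.0, seed=8)
        grid = [{"sel__k": [12], "svr__C": [10.0], "svr__epsilon": [0.01]}]
        model, _ = train_predictor(data, kernel="linear", seed=8, param_grid=grid)
        row = data.features.iloc[[0]].copy()
        # push the response features far above anything seen in training
        for name in ("R_mean", "G_mean", "B_mean", "Yn_mean", "V_mean"):
            row[name] = 10.0
        row["Lstar_mean"] = 1000.0
        row["gray_intensity"] = -2000.0
        _, flag = model.predict(row, with_flag=True)
        assert flag[0]
        _, flags_in = model.predict(data.features, with_flag=True)
        assert flags_in.mean() < 0.5  # interior samples are not extrapolations

    def test_persistence_round_trip(self, trained, tmp_path):
        data, model, _ = trained
        path = tmp_path / "model.joblib"
        model.save(path)
        again = type(model).load(path)
        np.testing.assert_allclose(
            again.predict(data.features), model.predict(data.features), rtol=1e-12
        )
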