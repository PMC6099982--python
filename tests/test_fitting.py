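"""Design matrix, Gauss-Seidel solver, statistics and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grouptension import (
    GroupContributionModel,
    SyntheticSpec,
    build_design_matrix,
    compute_statistics,
    cross_validate,
    fit_gauss_seidel,
    gauss_seidel_normal_equations,
    generate_synthetic,
    read_smiles,
)
from grouptension.fitting import (
    ConvergenceError,
    SingularityError,
    StatisticsError,
)
from grouptension.params import CONST


def _direct_lstsq(a, y):
    """Independent oracle: dense least squares via numpy."""
    return np.linalg.lstsq(np.asarray(a, float), np.asarray(y, float), rcond=None)[0]


class TestDesignMatrix:
    def test_three_alkane_columns(self):
        mols = [read_smiles(s, s) for s in ("CC", "CCC", "CCCC")]
        dm = build_design_matrix([(m, 20.0) for m in mols])
        assert dm.columns == ["C sp3/H2C2", "C sp3/H3C", "Alkane", CONST]
        assert dm.counts.shape == (3, 4)
        assert (dm.counts[CONST] == 1).all()
        assert list(dm.counts["C sp3/H3C"]) == [2, 2, 2]
        assert list(dm.counts["C sp3/H2C2"]) == [0, 1, 2]
        assert list(dm.counts["Alkane"]) == [2, 3, 4]

    def test_single_molecule_matrix(self):
        dm = build_design_matrix([(read_smiles("CC", "ethane"), 5.0)])
        assert dm.counts.shape[0] == 1

    def test_missing_observation_dropped(self):
        dm = build_design_matrix(
            [(read_smiles("CC", "a"), 5.0), (read_smiles("CCC", "b"), None)]
        )
        assert dm.n_molecules == 1 and dm.n_dropped == 1

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError, match="empty dataset"):
            build_design_matrix([(read_smiles("CC", "a"), None)])


class TestGaussSeidel:
    def test_diagonal_system_matches_closed_form(self):
        # each molecule bears exactly one count of a distinct group; with a
        # centred response the system is effectively diagonal
        a = np.hstack([np.eye(4), np.ones((4, 1))])
        a = np.vstack([a, [0, 0, 0, 0, 1]])  # pin the constant
        y = np.array([3.0, -1.0, 2.0, 5.0, 1.0])
        x, _ = gauss_seidel_normal_equations(a, y, tol=1e-12)
        assert np.allclose(x, _direct_lstsq(a, y), atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_solve_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=(50, 8)).astype(float)
        a[:, -1] = 1.0
        y = rng.normal(25.0, 5.0, size=50)
        x, _ = gauss_seidel_normal_equations(a, y, tol=1e-12, max_iter=100_000)
        assert np.abs(x - _direct_lstsq(a, y)).max() < 1e-6

    def test_noise_free_recovery_is_exact(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=10, n_molecules=60, noise_sd=0.0, seed=3)
        )
        model = GroupContributionModel.from_counts(data.counts, data.response)
        res = model.fit(tol=1e-12, max_iter=100_000)
        for sig, truth in data.true_coefficients.items():
            assert res.params[sig] == pytest.approx(truth, abs=1e-8)

    def test_underdetermined_raises(self):
        a = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 1.0]])  # rank 2 < 3 columns
        with pytest.raises(SingularityError):
            gauss_seidel_normal_equations(a, np.array([1.0, 2.0]))

    def test_nonconvergence_carries_diagnostics(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(30, 5))
        with pytest.raises(ConvergenceError) as err:
            gauss_seidel_normal_equations(a, rng.normal(size=30), tol=1e-14, max_iter=2)
        assert err.value.iterations == 2
        assert err.value.last_delta > 0

    def test_fit_gauss_seidel_recomputes_validity(self):
        # chloroalkanes break the alkane count identity, making this full rank
        smis = ("CC", "CCC", "CCCC", "CCCCC", "C1CCCCC1",
                "CCCCCl", "CCCCCCl", "CCCCCCCl")
        mols = [read_smiles(s, s) for s in smis]
        dm = build_design_matrix([(m, 18.0 + i) for i, m in enumerate(mols)])
        table = fit_gauss_seidel(dm, tol=1e-10)
        assert table.lookup("C sp3/H3C").molecule_count == 7
        assert table.lookup("C sp3/H3C").valid
        assert table.lookup("C sp3/H2CCl").molecule_count == 3
        assert table.lookup("Alkane").molecule_count == 5


class TestStatistics:
    def test_perfect_predictions(self):
        s = compute_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r_squared == pytest.approx(1.0)
        assert s.average_deviation == 0.0
        assert s.standard_deviation == 0.0

    def test_hand_computed_case(self):
        # observed (1,2,3) vs calculated (1,1,1): residuals 0,1,2
        s = compute_statistics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert s.standard_deviation == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert s.average_deviation == pytest.approx(1.0, abs=1e-12)

    def test_single_pair_raises(self):
        with pytest.raises(StatisticsError):
            compute_statistics([1.0], [1.0])

    def test_exclusion_bookkeeping(self):
        s = compute_statistics(
            [1.0, 2.0, 3.0, 9.0], [1.0, 2.0, 3.0, 4.0], exclude=[0, 0, 0, 1]
        )
        assert s.n_used == 3 and s.n_excluded == 1
        assert s.n_used + s.n_excluded == 4
        assert s.standard_deviation == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        resid=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=40
        ),
        base=st.floats(10, 60),
    )
    def test_deviations_match_numpy_oracle(self, resid, base):
        """Average/standard deviation agree with direct numpy formulas for
        arbitrary residual patterns."""
        obs = np.asarray(resid) + base
        pred = np.full_like(obs, base)
        s = compute_statistics(pred, obs)
        r = obs - pred
        assert s.average_deviation == pytest.approx(np.abs(r).mean(), rel=1e-12)
        assert s.standard_deviation == pytest.approx(
            np.sqrt((r**2).sum() / (len(r) - 1)), rel=1e-12, abs=1e-12
        )

    def test_regression_line_of_predicted_on_experimental(self):
        obs = np.array([10.0, 20.0, 30.0, 40.0])
        pred = 0.5 * obs + 3.0
        s = compute_statistics(pred, obs)
        assert s.regression_slope == pytest.approx(0.5)
        assert s.regression_intercept == pytest.approx(3.0)


class TestCrossValidation:
    def test_partition_property(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=5, n_molecules=20, noise_sd=0.5, seed=7)
        )
        dm = GroupContributionModel.from_counts(data.counts, data.response).design
        cv = cross_validate(dm, k=10, seed=1)
        folds = list(cv.fold_assignments.values())
        assert len(folds) == 20
        assert sorted(set(folds)) == list(range(10))
        assert all(folds.count(f) == 2 for f in range(10))
        assert cv.n_test_used + cv.n_test_skipped == 20

    def test_seed_determinism(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=5, n_molecules=30, noise_sd=1.0, seed=2)
        )
        dm = GroupContributionModel.from_counts(data.counts, data.response).design
        a, b = cross_validate(dm, k=5, seed=9), cross_validate(dm, k=5, seed=9)
        assert a.fold_assignments == b.fold_assignments
        assert a.q_squared == b.q_squared and a.s == b.s

    def test_noise_free_q_squared_is_one(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=8, n_molecules=120, noise_sd=0.0, seed=11)
        )
        dm = GroupContributionModel.from_counts(data.counts, data.response).design
        cv = cross_validate(dm, k=10, seed=4, tol=1e-10)
        assert cv.q_squared == pytest.approx(1.0, abs=1e-6)
        assert cv.s == pytest.approx(0.0, abs=1e-4)

    def test_k_bounds(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=3, n_molecules=10, noise_sd=0.1, seed=5)
        )
        dm = GroupContributionModel.from_counts(data.counts, data.response).design
        with pytest.raises(ValueError):
            cross_validate(dm, k=1)
        with pytest.raises(ValueError):
            cross_validate(dm, k=11)

    def test_q_squared_rarely_exceeds_r_squared(self):
        """Held-out fit should (almost always) be no better than training."""
        wins = 0
        trials = 10
        for seed in range(trials):
            data = generate_synthetic(
                SyntheticSpec(n_groups=6, n_molecules=80, noise_sd=2.0, seed=seed)
            )
            model = GroupContributionModel.from_counts(data.counts, data.response)
            res = model.fit(tol=1e-8)
            cv = cross_validate(model.design, k=10, seed=seed)
            if cv.q_squared <= res.statistics.r_squared:
                wins += 1
        assert wins >= int(0.9 * trials)


class TestValidityGatingInFit:
    """A group backed by <3 molecules is invalid; its compounds are excluded
    from the statistics and skipped by strict prediction."""

    @pytest.fixture()
    def toy(self):
        counts = pd.DataFrame(
            {
                "common": [1, 2, 1, 2, 1],
                "rare": [0, 0, 0, 1, 1],  # present in only 2 of 5 molecules
            }
        )
        y = [10.0, 12.0, 10.0, 14.0, 13.0]
        return GroupContributionModel.from_counts(counts, y)

    def test_rare_group_flagged_invalid(self, toy):
        res = toy.fit(tol=1e-10)
        assert not res.table.lookup("rare").valid
        assert res.table.lookup("common").valid

    def test_compounds_with_invalid_group_excluded(self, toy):
        res = toy.fit(tol=1e-10)
        stats = res.statistics
        assert stats.n_used == 3 and stats.n_excluded == 2
        assert stats.n_used + stats.n_excluded == toy.design.n_molecules

    def test_strict_prediction_skips_invalid(self, toy):
        from grouptension import CoverageError, GroupCountVector, predict

        res = toy.fit(tol=1e-10)
        vec = GroupCountVector(atom_group_counts={"common": 1, "rare": 1})
        with pytest.raises(CoverageError, match="rare"):
            predict(vec, res.table, strict=True)
        lenient = predict(vec, res.table)
        assert lenient.invalid_groups == ["rare"]


class TestModelResultsFrontDoor:
    def test_from_dataframe_and_summary(self):
        y = [18.0, 19.0, 20.1, 21.0, 25.2, 26.1, 27.4, 28.0]
        df = pd.DataFrame(
            {
                "id": list("abcdefgh"),
                "smiles": ["CC", "CCC", "CCCC", "CCCCC", "C1CCCCC1",
                           "CCCCCl", "CCCCCCl", "CCCCCCCl"],
                "st_exp": y,
            }
        )
        res = GroupContributionModel.from_dataframe(df).fit(tol=1e-10)
        text = res.summary()
        assert "R^2" in text and "Alkane" in text and "Const" in text
        assert res.fittedvalues.shape == (8,)
        assert np.allclose(res.resid, np.asarray(y) - res.fittedvalues)

    def test_results_cross_validate_shortcut(self):
        data = generate_synthetic(
            SyntheticSpec(n_groups=4, n_molecules=40, noise_sd=0.5, seed=6)
        )
        res = GroupContributionModel.from_counts(data.counts, data.response).fit()
        cv = res.cross_validate(k=5, seed=3)
        assert cv.k == 5 and 0.0 <= cv.q_squared <= 1.0
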