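"""LIE model arithmetic, least-squares fit, validation metrics, splits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protolie.lie_core import (
    ABETA_PARAMETERS,
    STANDARD_PARAMETERS,
    AffinityRecord,
    ComplexEnergies,
    LIEParameters,
    MethodColumn,
    compare_methods,
    delta_energies,
    evaluate,
    fit_lie,
    ki_to_dg,
    lie_predict,
    pearson_r,
    random_split,
    read_method_table,
    standard_error,
)
from protolie.synthetic_data import GroundTruth, gen_lie_dataset

finite = st.floats(-100, 100, allow_nan=False)


class TestDeltaEnergies:
    def test_symmetric_zero(self):
        ce = ComplexEnergies("L", -5, -5, -3, -3)
        assert delta_energies(ce) == (0.0, 0.0)

    def test_arithmetic_with_weakened_electrostatics(self):
        # bound-state electrostatics weaker than free: positive d_elec
        ce = ComplexEnergies("L", -50, -10, -5, -20)
        assert delta_energies(ce) == (-40.0, 15.0)

    @given(finite, finite, finite, finite)
    def test_matches_direct_resubtraction(self, vb, vf, eb, ef):
        ce = ComplexEnergies("L", vb, vf, eb, ef)
        d_vdw, d_elec = delta_energies(ce)
        assert d_vdw == vb - vf and d_elec == eb - ef


class TestLiePredict:
    def test_zero_differences_return_intercept(self):
        ce = ComplexEnergies("L", -5, -5, -3, -3)
        assert lie_predict(ce, ABETA_PARAMETERS) == pytest.approx(-5.880)

    def test_calibrated_parameters_arithmetic(self):
        ce = ComplexEnergies("L", -15, -5, 3, -2)  # d_vdw=-10, d_elec=+5
        assert lie_predict(ce, ABETA_PARAMETERS) == pytest.approx(-9.005)

    def test_standard_parameters_arithmetic(self):
        ce = ComplexEnergies("L", -15, -5, -4, -2)  # d_vdw=-10, d_elec=-2
        assert lie_predict(ce, STANDARD_PARAMETERS) == pytest.approx(-2.8)

    @given(finite, finite, st.floats(-3, 3))
    def test_affine_in_each_component(self, d_vdw, d_elec, lam):
        p = ABETA_PARAMETERS
        base = ComplexEnergies("L", d_vdw, 0.0, d_elec, 0.0)
        scaled = ComplexEnergies("L", lam * d_vdw, 0.0, lam * d_elec, 0.0)
        assert lie_predict(scaled, p) - p.gamma == pytest.approx(
            lam * (lie_predict(base, p) - p.gamma), rel=1e-9, abs=1e-9
        )


class TestPearson:
    def test_perfect_positive(self):
        assert pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.integers(-50, 50).map(float), min_size=4, max_size=12,
                 unique=True),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    def test_invariant_under_positive_affine_and_flips_under_negation(
        self, xs, a, b
    ):
        ys = [math.sin(1.7 * x) + 0.3 * x for x in xs]  # generic partner
        r = pearson_r(xs, ys)
        assert pearson_r([a * x + b for x in xs], ys) == pytest.approx(r, abs=1e-9)
        assert pearson_r([-x for x in xs], ys) == pytest.approx(-r, abs=1e-9)


class TestStandardError:
    def test_zero_residuals(self):
        assert standard_error([0, 0, 0, 0], 0, "rmse") == 0.0
        assert standard_error([0, 0, 0, 0], 3, "dof_corrected") == 0.0

    def test_rmse_arithmetic(self):
        assert standard_error([1, -1, 1, -1], definition="rmse") == pytest.approx(1.0)
        assert standard_error([3, 4], definition="rmse") == pytest.approx(
            3.5355339059327378
        )

    def test_dof_correction(self):
        # ssr=4 over n-k = 4-2 = 2
        assert standard_error([1, -1, 1, -1], 2, "dof_corrected") == pytest.approx(
            math.sqrt(2.0)
        )

    def test_degenerate_lengths(self):
        with pytest.raises(ValueError):
            standard_error([], definition="rmse")
        with pytest.raises(ValueError):
            standard_error([1, 2, 3], 3, "dof_corrected")


class TestKiToDg:
    def test_standard_state_identity(self):
        assert ki_to_dg(1.0, 250.0) == 0.0
        assert ki_to_dg(1.0, 400.0) == 0.0

    def test_micromolar_at_300K(self):
        assert ki_to_dg(1e-6, 300.0) == pytest.approx(-8.2363, abs=1e-3)

    def test_log_linearity(self):
        t = 310.0
        shift = ki_to_dg(5e-7, t) - ki_to_dg(1e-6, t)
        assert shift == pytest.approx(1.98720425e-3 * t * math.log(0.5), rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ki_to_dg(0.0, 300.0)
        with pytest.raises(ValueError):
            ki_to_dg(1e-6, -1.0)


class TestAffinityRecord:
    def test_requires_some_affinity(self):
        with pytest.raises(ValueError):
            AffinityRecord("L")

    def test_rejects_inconsistent_ki_dg(self):
        with pytest.raises(ValueError, match="inconsistent"):
            AffinityRecord("L", dg_exp=-8.0, ki=1e-3)

    def test_dg_precedence_and_conversion(self):
        assert AffinityRecord("L", dg_exp=-7.5, ki=None).dg == -7.5
        assert AffinityRecord("L", ki=1e-6).dg == pytest.approx(-8.2363, abs=1e-3)


def _noiseless(n=12, seed=0, params=ABETA_PARAMETERS):
    gt = GroundTruth(seed=seed, residual_sd=0.0, params=params)
    return gen_lie_dataset(gt, n)


class TestFitLie:
    def test_noiseless_recovery_is_exact(self):
        res = fit_lie(_noiseless())
        assert res.params.alpha == pytest.approx(0.288, abs=1e-8)
        assert res.params.beta == pytest.approx(-0.049, abs=1e-8)
        assert res.params.gamma == pytest.approx(-5.880, abs=1e-8)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_four_points_interpolate_exactly(self):
        res = fit_lie(_noiseless(n=4, seed=3))
        assert max(abs(r) for r in res.residuals) < 1e-8
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_complexes(self):
        with pytest.raises(ValueError, match="need >= 4"):
            fit_lie(_noiseless()[:3])

    def test_id_mismatch(self):
        ds = _noiseless()
        bad = [(ds[0][0], ds[1][1])] + ds[1:]
        with pytest.raises(ValueError, match="mismatch"):
            fit_lie(bad)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(0)
        ds = []
        for i in range(6):
            d = rng.uniform(-40, -10)
            ce = ComplexEnergies(f"L{i}", d, 0.0, 2 * d, 0.0)  # d_elec = 2 d_vdw
            ds.append((ce, AffinityRecord(f"L{i}", dg_exp=0.1 * d - 3)))
        with pytest.raises(ValueError, match="collinear"):
            fit_lie(ds)

    def test_rmse_identity_invariant(self, dataset30):
        res = fit_lie(dataset30, se_definition="rmse")
        ssr = sum(r * r for r in res.residuals)
        assert res.se**2 * res.n == pytest.approx(ssr, rel=1e-9)

    def test_agrees_with_nelder_mead_oracle(self):
        gt = GroundTruth(seed=8, residual_sd=1.5)
        ds = gen_lie_dataset(gt, 10)
        res = fit_lie(ds)
        from scipy.optimize import minimize

        X = np.array([[*delta_energies(ce), 1.0] for ce, _ in ds])
        y = np.array([aff.dg for _, aff in ds])

        def ssr(p):
            return float(np.sum((X @ p - y) ** 2))

        opt = minimize(ssr, x0=np.zeros(3), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-14, maxfev=50_000))
        opt = minimize(ssr, x0=opt.x, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-14, maxfev=50_000))
        np.testing.assert_allclose(res.params.as_array(), opt.x, atol=1e-4)

    def test_agrees_with_statsmodels_ols(self, dataset30):
        import statsmodels.api as sm
        from protolie.lie_core import delta_energies as de

        res = fit_lie(dataset30)
        X = sm.add_constant(np.array([de(ce) for ce, _ in dataset30]), prepend=False)
        y = np.array([aff.dg for _, aff in dataset30])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.params.as_array(), ols.params, rtol=1e-8)
        assert res.r**2 == pytest.approx(ols.rsquared, rel=1e-8)


class TestEvaluate:
    def test_consistent_with_fit_on_training_data(self, dataset30):
        fitres = fit_lie(dataset30)
        ev = evaluate(dataset30, fitres.params)
        assert ev.r == pytest.approx(fitres.r, rel=1e-12)
        assert ev.se == pytest.approx(fitres.se, rel=1e-12)  # both rmse

    def test_least_squares_se_is_minimal(self, dataset30):
        fitres = fit_lie(dataset30)
        best = evaluate(dataset30, fitres.params).se
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = LIEParameters(*(fitres.params.as_array() + rng.normal(0, 0.05, 3)))
            assert evaluate(dataset30, p).se >= best

    def test_needs_three_points(self, dataset30):
        with pytest.raises(ValueError, match="need >= 3"):
            evaluate(dataset30[:2], ABETA_PARAMETERS)


class TestCompareMethods:
    def test_exact_column_has_unit_correlation(self, dataset30):
        exp = [aff for _, aff in dataset30]
        ids = tuple(a.ligand_id for a in exp)
        col = MethodColumn("oracle", ids, tuple(a.dg for a in exp))
        [comp] = compare_methods([col], exp)
        assert comp.r == pytest.approx(1.0) and comp.se == pytest.approx(0.0)

    def test_permutation_null_has_zero_mean_correlation(self, dataset30):
        exp = [aff for _, aff in dataset30]
        ids = tuple(a.ligand_id for a in exp)
        dgs = np.array([a.dg for a in exp])
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(1000):
            col = MethodColumn("perm", ids, tuple(rng.permutation(dgs)))
            rs.append(compare_methods([col], exp)[0].r)
        assert abs(np.mean(rs)) < 0.05

    def test_ranking_orders_by_correlation(self, dataset30):
        exp = [aff for _, aff in dataset30]
        ids = tuple(a.ligand_id for a in exp)
        dgs = np.array([a.dg for a in exp])
        rng = np.random.default_rng(1)
        cols = [
            MethodColumn("noisy", ids, tuple(dgs + rng.normal(0, 6, dgs.size))),
            MethodColumn("exact", ids, tuple(dgs)),
        ]
        comps = compare_methods(cols, exp)
        assert [c.method for c in comps] == ["exact", "noisy"]

    def test_misaligned_ids_rejected(self, dataset30):
        exp = [aff for _, aff in dataset30]
        col = MethodColumn("m", ("X", "Y", "Z"), (-1.0, -2.0, -3.0))
        with pytest.raises(ValueError, match="align"):
            compare_methods([col], exp)

    def test_method_table_csv(self, tmp_path, dataset30):
        exp = [aff for _, aff in dataset30]
        lines = ["ligand_id,dg_exp,dg_lie,dg_fep"]
        for a in exp:
            lines.append(f"{a.ligand_id},{a.dg:.4f},{a.dg:.4f},{a.dg - 1:.4f}")
        p = tmp_path / "methods.csv"
        p.write_text("\n".join(lines) + "\n")
        cols, exp2 = read_method_table(p)
        comps = compare_methods(cols, exp2)
        assert {c.method for c in comps} == {"lie", "fep"}
        for c in comps:
            assert c.r == pytest.approx(1.0)


class TestRandomSplit:
    def test_sizes(self, dataset30):
        train, test = random_split(dataset30, 20, seed=1)
        assert len(train) == 20 and len(test) == 10

    def test_deterministic(self, dataset30):
        a = random_split(dataset30, 20, seed=1)
        b = random_split(dataset30, 20, seed=1)
        assert [ce.ligand_id for ce, _ in a[0]] == [ce.ligand_id for ce, _ in b[0]]

    def test_partition(self, dataset30):
        train, test = random_split(dataset30, 20, seed=2)
        all_ids = {ce.ligand_id for ce, _ in dataset30}
        got = {ce.ligand_id for ce, _ in train} | {ce.ligand_id for ce, _ in test}
        assert got == all_ids
        assert not ({ce.ligand_id for ce, _ in train}
                    & {ce.ligand_id for ce, _ in test})

    def test_invalid_n_train(self, dataset30):
        with pytest.raises(ValueError):
            random_split(dataset30, 0, seed=1)
        with pytest.raises(ValueError):
            random_split(dataset30, 30, seed=1)
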