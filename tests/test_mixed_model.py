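"""Design construction, MME solutions and EM-REML against dense oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ssgblup as sg
from ssgblup.mixed_model import _AbsorbedMME


def _phenotypes(df, trait="FD"):
    return sg.PhenotypeTable(pd.DataFrame(df), trait=trait)


def _founder_pedigree(n):
    return sg.Pedigree(
        sire=np.zeros(n, np.int64), dam=np.zeros(n, np.int64),
        original_ids=np.array([str(i + 1) for i in range(n)], dtype=object),
    )


class TestHeritability:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ((2.824, 1.289, 4.332), 0.334),   # fiber diameter
            ((0.354, 0.144, 0.431), 0.381),   # fiber SD
            ((27.416, 39.509, 106.316), 0.158),  # medullation
            ((2.842, 1.280, 4.331), 0.336),
        ],
    )
    def test_reported_component_triples(self, components, expected):
        vc = sg.VarianceComponents(*components)
        assert round(sg.heritability(vc), 3) == expected

    def test_zero_additive(self):
        assert sg.heritability(sg.VarianceComponents(0.0, 1.0, 1.0)) == 0.0

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            sg.heritability(sg.VarianceComponents(0.0, 0.0, 0.0))


class TestBuildDesign:
    def test_column_count_full_structure(self):
        """19 years + 9 colors + 3 statuses + age,age² -> 1+18+8+2+2 = 31."""
        rng = np.random.default_rng(0)
        n = 4000
        ped = _founder_pedigree(200)
        df = {
            "animal": rng.integers(1, 201, n),
            "value": rng.normal(size=n),
            "year": [f"y{i}" for i in rng.integers(1, 20, n)],
            "color": [f"c{i}" for i in rng.integers(1, 10, n)],
            "age_days": rng.uniform(365, 3000, n),
            "sex_status": rng.choice(
                ["male", "female-empty", "female-lactating"], n
            ),
        }
        mm = sg.build_design(_phenotypes(df), ped)
        assert mm.X.shape[1] == 31

    def test_degenerate_collapses_to_intercept(self, caplog):
        ped = _founder_pedigree(3)
        df = {
            "animal": [1, 2, 3],
            "value": [1.0, 2.0, 3.0],
            "year": ["y1"] * 3,
            "color": ["c1"] * 3,
            "age_days": [500.0] * 3,
            "sex_status": ["male"] * 3,
        }
        with caplog.at_level("WARNING", logger="ssgblup"):
            mm = sg.build_design(_phenotypes(df), ped)
        assert mm.x_columns == ["intercept"]

    def test_z_rows_sum_to_one(self, small_dataset):
        _, data, _, _ = small_dataset
        mm = sg.build_design(data.phenotypes, data.pedigree)
        np.testing.assert_array_equal(
            np.asarray(mm.Z.sum(axis=1)).ravel(), 1.0
        )
        np.testing.assert_array_equal(
            np.asarray(mm.W.sum(axis=1)).ravel(), 1.0
        )

    def test_aliased_columns_named(self):
        ped = _founder_pedigree(4)
        # color copies year exactly -> aliased after reference dropping
        df = {
            "animal": [1, 2, 3, 4],
            "value": [1.0, 2.0, 3.0, 4.0],
            "year": ["y1", "y1", "y2", "y2"],
            "color": ["c1", "c1", "c2", "c2"],
            "age_days": [400.0] * 4,
            "sex_status": ["male"] * 4,
        }
        with pytest.raises(ValueError, match="aliased"):
            sg.build_design(_phenotypes(df), ped)


def _tiny_model():
    """3 founder animals, 4 records, intercept-only fixed structure."""
    ped = _founder_pedigree(3)
    df = {
        "animal": [1, 1, 2, 3],
        "value": [10.0, 12.0, 9.0, 11.5],
        "year": ["y1"] * 4,
        "color": ["c1"] * 4,
        "age_days": [500.0] * 4,
        "sex_status": ["male"] * 4,
    }
    mm = sg.build_design(_phenotypes(df), ped)
    return ped, mm


class TestSolveMME:
    def test_tiny_system_matches_dense_oracle(self):
        ped, mm = _tiny_model()
        vc = sg.VarianceComponents(2.0, 1.0, 3.0)
        Ainv = sg.a_inverse(ped)
        res = sg.solve_mme(mm, vc, Ainv)

        # dense normal-equations oracle
        X, Z, W, y = mm.X, mm.Z.toarray(), mm.W.toarray(), mm.y
        lam_u = vc.sigma_e2 / vc.sigma_u2
        lam_c = vc.sigma_e2 / vc.sigma_c2
        top = np.hstack([X.T @ X, X.T @ Z, X.T @ W])
        mid = np.hstack([Z.T @ X, Z.T @ Z + lam_u * np.eye(3), Z.T @ W])
        bot = np.hstack([W.T @ X, W.T @ Z, W.T @ W + lam_c * np.eye(3)])
        lhs = np.vstack([top, mid, bot])
        rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        got = np.concatenate([res.b, res.u, res.p])
        np.testing.assert_allclose(got, sol, atol=1e-10)

    def test_shrinkage_to_zero_in_small_sigma_u_limit(self):
        ped, mm = _tiny_model()
        vc = sg.VarianceComponents(1e-12, 1.0, 1.0)  # lambda_u = 1e12
        res = sg.solve_mme(mm, vc, sg.a_inverse(ped))
        assert np.abs(res.u).max() < 1e-6

    def test_residual_check_recorded(self):
        ped, mm = _tiny_model()
        res = sg.solve_mme(mm, sg.VarianceComponents(1.0, 0.5, 1.0),
                           sg.a_inverse(ped))
        assert res.diagnostics["residual_max"] < 1e-8

    def test_record_order_invariance(self, small_dataset):
        _, data, _, _ = small_dataset
        vc = sg.VarianceComponents(2.824, 1.289, 4.332)
        Ainv = sg.a_inverse(data.pedigree)
        mm1 = sg.build_design(data.phenotypes, data.pedigree)
        res1 = sg.solve_mme(mm1, vc, Ainv)
        rng = np.random.default_rng(1)
        shuffled = data.phenotypes.subset(
            rng.permutation(data.phenotypes.n_records)
        )
        mm2 = sg.build_design(shuffled, data.pedigree)
        res2 = sg.solve_mme(mm2, vc, Ainv)
        np.testing.assert_allclose(res1.u, res2.u, atol=1e-10)

    def test_shift_in_y_moves_intercept_only(self, small_dataset):
        _, data, _, _ = small_dataset
        vc = sg.VarianceComponents(2.824, 1.289, 4.332)
        Ainv = sg.a_inverse(data.pedigree)
        mm = sg.build_design(data.phenotypes, data.pedigree)
        res1 = sg.solve_mme(mm, vc, Ainv)
        shifted = data.phenotypes.data.copy()
        shifted["value"] += 100.0
        mm2 = sg.build_design(
            sg.PhenotypeTable(shifted, data.phenotypes.trait), data.pedigree
        )
        res2 = sg.solve_mme(mm2, vc, Ainv)
        assert res2.b[0] - res1.b[0] == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(res2.u, res1.u, atol=1e-8)

    def test_no_genotypes_h_kernel_identical_to_a_kernel(self, small_dataset):
        _, data, _, _ = small_dataset
        vc = sg.VarianceComponents(2.824, 1.289, 4.332)
        Ainv = sg.a_inverse(data.pedigree)
        Hinv = sg.h_inverse(Ainv, None, None)
        mm = sg.build_design(data.phenotypes, data.pedigree)
        res_a = sg.solve_mme(mm, vc, Ainv)
        res_h = sg.solve_mme(mm, vc, Hinv)
        np.testing.assert_array_equal(res_a.u, res_h.u)  # bit-for-bit

    def test_animals_without_records_predicted_through_kernel(self, toy_pedigree):
        df = {
            "animal": [1, 1, 2, 2, 3, 3],
            "value": [12.0, 13.0, 8.0, 9.0, 11.0, 10.5],
            "year": ["y1", "y2", "y1", "y2", "y1", "y2"],
            "color": ["c1"] * 6,
            "age_days": [400.0, 710.0, 450.0, 800.0, 380.0, 760.0],
            "sex_status": ["male"] * 6,
        }
        mm = sg.build_design(_phenotypes(df), toy_pedigree)
        res = sg.solve_mme(mm, sg.VarianceComponents(2.0, 1.0, 2.0),
                           sg.a_inverse(toy_pedigree))
        # animal 4 = (1,3) has no records; prediction flows from parents
        assert res.u[3] != 0.0
        assert res.u[3] == pytest.approx(0.5 * (res.u[0] + res.u[2]), abs=1e-9)


class TestAbsorbedWorkspaceOracle:
    """The p-absorbed workspace must match the full dense MME inverse."""

    def test_traces_and_solutions_match_full_inverse(self, small_dataset):
        _, data, _, _ = small_dataset
        mm = sg.build_design(data.phenotypes, data.pedigree)
        Ainv = sg.a_inverse(data.pedigree)
        vc = sg.VarianceComponents(2.0, 1.0, 4.0)
        work = _AbsorbedMME(mm, Ainv, include_pe=True)
        state = work.iterate(vc)

        X, Z, W, y = mm.X, mm.Z, mm.W, mm.y
        lam_u = vc.sigma_e2 / vc.sigma_u2
        lam_c = vc.sigma_e2 / vc.sigma_c2
        px, q, qp = X.shape[1], Z.shape[1], W.shape[1]
        Xs = sp.csr_matrix(X)
        lhs = sp.bmat(
            [
                [Xs.T @ Xs, Xs.T @ Z, Xs.T @ W],
                [Z.T @ Xs, Z.T @ Z + lam_u * Ainv.matrix, Z.T @ W],
                [W.T @ Xs, W.T @ Z, W.T @ W + lam_c * sp.identity(qp)],
            ]
        ).toarray()
        rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])
        C = np.linalg.inv(lhs)
        sol = C @ rhs
        np.testing.assert_allclose(state["b"], sol[:px], atol=1e-8)
        np.testing.assert_allclose(state["u"], sol[px:px + q], atol=1e-8)
        np.testing.assert_allclose(state["p"], sol[px + q:], atol=1e-8)

        Cuu = C[px:px + q, px:px + q]
        Cpp = C[px + q:, px + q:]
        tr_KiCuu = float(np.sum(Ainv.matrix.toarray() * Cuu))
        np.testing.assert_allclose(state["tr_KiCuu"], tr_KiCuu, rtol=1e-8)
        np.testing.assert_allclose(state["tr_Cpp"], np.trace(Cpp), rtol=1e-8)
        sign, logdet = np.linalg.slogdet(lhs)
        assert sign > 0
        # logdet enters the likelihood; recompute from the state's pieces
        e_ty = float(y @ y) - float(sol[:px] @ (X.T @ y)) \
            - float(sol[px:px + q] @ (Z.T @ y)) - float(sol[px + q:] @ (W.T @ y))
        np.testing.assert_allclose(state["e_ty"], e_ty, rtol=1e-8)


class TestEMREML:
    def test_reduced_mode_equals_ols_mean_square(self):
        rng = np.random.default_rng(2)
        ped = _founder_pedigree(50)
        df = {
            "animal": np.arange(1, 51),
            "value": rng.normal(10, 2, 50),
            "year": rng.choice(["y1", "y2", "y3"], 50),
            "color": ["c1"] * 50,
            "age_days": rng.uniform(400, 3000, 50),
            "sex_status": ["male"] * 50,
        }
        mm = sg.build_design(_phenotypes(df), ped)
        res = sg.em_reml(mm, None)
        b, *_ = np.linalg.lstsq(mm.X, mm.y, rcond=None)
        rss = float(np.sum((mm.y - mm.X @ b) ** 2))
        assert res.components.sigma_e2 == pytest.approx(
            rss / (50 - mm.X.shape[1]), rel=1e-12
        )

    def test_single_records_fix_sigma_c2_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        ped = _founder_pedigree(40)
        df = {
            "animal": np.arange(1, 41),
            "value": rng.normal(size=40),
            "year": rng.choice(["y1", "y2"], 40),
            "color": ["c1"] * 40,
            "age_days": rng.uniform(400, 3000, 40),
            "sex_status": ["male"] * 40,
        }
        mm = sg.build_design(_phenotypes(df), ped)
        with caplog.at_level("WARNING", logger="ssgblup"):
            res = sg.em_reml(mm, sg.a_inverse(ped), maxiter=50, tol=1e-6)
        assert res.components.sigma_c2 == 0.0
        assert any("unidentifiable" in r.message for r in caplog.records)

    def test_plain_and_accelerated_agree(self, small_dataset):
        _, data, _, _ = small_dataset
        mm = sg.build_design(data.phenotypes, data.pedigree)
        Ainv = sg.a_inverse(data.pedigree)
        fast = sg.em_reml(mm, Ainv, tol=1e-8, maxiter=400, accelerate=True)
        slow = sg.em_reml(mm, Ainv, tol=1e-8, maxiter=2000, accelerate=False)
        assert fast.converged and slow.converged
        assert fast.n_iter < slow.n_iter
        for attr in ("sigma_u2", "sigma_c2", "sigma_e2"):
            a = getattr(fast.components, attr)
            b = getattr(slow.components, attr)
            assert a == pytest.approx(b, rel=5e-3)

    def test_loglik_monotone(self, small_dataset):
        _, data, _, _ = small_dataset
        mm = sg.build_design(data.phenotypes, data.pedigree)
        res = sg.em_reml(mm, sg.a_inverse(data.pedigree), tol=1e-8, maxiter=300)
        ll = np.array(res.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_pure_noise_gives_near_zero_heritability(self):
        """Null simulation: with no genetic or permanent-environment truth
        the estimated h2 collapses towards 0."""
        for seed in (0, 1):
            cfg = sg.SimulationConfig(
                n_founders=150, n_generations=2, n_snps=60, n_qtl=10,
                sigma_u2=0.0, sigma_c2=0.0, sigma_e2=4.0,
                n_years=5, seed=seed,
            )
            ped = sg.simulate_pedigree(cfg)
            gm, p = sg.simulate_genotypes(ped, cfg)
            phe, _ = sg.simulate_phenotypes(ped, gm, cfg, p)
            mm = sg.build_design(phe, ped)
            res = sg.em_reml(mm, sg.a_inverse(ped), tol=1e-6, maxiter=200)
            assert res.h2 < 0.05
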