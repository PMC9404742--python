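"""Design assembly and the EM/AI-REML engine.

The engine is validated against independent oracles: the dense-covariance
REML likelihood (no mixed-model equations), central finite differences of
that likelihood for the scores, and closed-form one-way ANOVA on balanced
designs of unrelated cows.
"""

import numpy as np
import pandas as pd
import pytest

from methaherd import genparams as gp
from methaherd import reml as rm
from methaherd import simulate as sim
from methaherd.pedigree import Pedigree, build_nrm, build_nrm_inverse

from .oracles import anova_oneway, dense_reml_logL

NO_FIXED = rm.ModelSpec(fixed_factors=(), covariates=())


@pytest.fixture(scope="module")
def tiny_problem():
    """25 animals / ~35 records with herd + covariate; dense-oracle scale."""
    rng = np.random.default_rng(3)
    ids = [f"A{i}" for i in range(25)]
    parents = {}
    for i, a in enumerate(ids):
        if i < 6:
            parents[a] = (None, None)
        else:
            s, d = rng.choice(i, size=2, replace=False)
            parents[a] = (ids[s], ids[d])
    ped = Pedigree.from_parent_map(parents)
    rows = []
    for c in ped.ids[10:]:
        for par in range(1, int(rng.integers(1, 4)) + 1):
            rows.append(
                {
                    "cow": c,
                    "parity": par,
                    "herd": int(rng.integers(1, 3)),
                    "lactation_length": int(rng.integers(200, 401)),
                    "y1": float(rng.normal(10, 2)),
                    "y2": float(rng.normal(-5, 3)),
                }
            )
    rec = pd.DataFrame(rows)
    spec = rm.ModelSpec(fixed_factors=("herd",), covariates=("lactation_length",))
    dm = rm.build_design(rec, ped, spec)
    return ped, rec, dm, build_nrm_inverse(ped), build_nrm(ped).matrix


class TestBuildDesign:
    @pytest.fixture()
    def mini(self):
        ped = Pedigree.from_parent_map(
            {"S": (None, None), "C1": ("S", None), "C2": ("S", None)}
        )
        rec = pd.DataFrame(
            {
                "cow": ["C1", "C1", "C2"],
                "parity": [1, 2, 1],
                "herd": [1, 1, 1],
                "year": [1, 1, 1],
                "season": [1, 1, 1],
                "lactation_length": [290, 310, 330],
            }
        )
        return ped, rec

    def test_dimension_bookkeeping(self, mini):
        ped, rec = mini
        dm = rm.build_design(rec, ped, rm.ModelSpec())
        # single-level factors contribute no columns after reference coding
        assert dm.x_columns == ["intercept", "parity[2]", "lactation_length"]
        assert dm.Z.shape == (3, len(ped))
        assert dm.W.shape == (3, 2)
        assert dm.W.sum(axis=0).tolist() == [[2.0, 1.0]]
        # covariate is centered
        assert dm.X.toarray()[:, -1].sum() == pytest.approx(0.0)

    def test_single_cow_repeated_records(self, mini):
        ped, rec = mini
        rec = rec[rec.cow == "C1"]
        dm = rm.build_design(rec, ped, NO_FIXED)
        assert dm.W.sum(axis=0).tolist() == [[2.0]]

    def test_duplicate_rows_identical_design(self, mini):
        ped, rec = mini
        rec2 = pd.concat([rec, rec.iloc[[0]]], ignore_index=True)
        dm = rm.build_design(rec2, ped, rm.ModelSpec())
        X = dm.X.toarray()
        assert np.array_equal(X[0], X[3])
        assert dm.animal_idx[0] == dm.animal_idx[3]

    def test_unseen_level_at_transform_errors(self, mini):
        ped, rec = mini
        dm = rm.build_design(rec, ped, rm.ModelSpec(fixed_factors=("parity",)))
        with pytest.raises(ValueError, match="unseen"):
            dm.transform(pd.DataFrame({"parity": [9], "lactation_length": [300]}))

    def test_cow_missing_from_pedigree_errors(self, mini):
        ped, rec = mini
        rec = rec.assign(cow=["C1", "C1", "ghost"])
        with pytest.raises(ValueError, match="absent from pedigree"):
            rm.build_design(rec, ped, rm.ModelSpec())

    def test_too_few_records_errors(self, mini):
        ped, rec = mini
        with pytest.raises(ValueError):
            rm.build_design(rec.iloc[:1], ped, rm.ModelSpec())


class TestAgainstDenseOracle:
    """The MME engine reproduces the dense-V restricted likelihood exactly."""

    UNI = (np.array([[2.0]]), np.array([[1.5]]), np.array([[3.0]]))
    BIV = (
        np.array([[2.0, 0.5], [0.5, 3.0]]),
        np.array([[1.0, -0.2], [-0.2, 1.5]]),
        np.array([[4.0, 1.0], [1.0, 5.0]]),
    )

    @pytest.mark.parametrize("k", [1, 2])
    def test_logL_matches_dense(self, tiny_problem, k):
        ped, rec, dm, Ainv, A = tiny_problem
        Y = rec[["y1", "y2"]].to_numpy()[:, :k]
        theta = self.UNI if k == 1 else self.BIV
        eng = rm._Engine(dm, Ainv, Y)
        st = eng.evaluate(theta)
        ref = dense_reml_logL(
            dm.X.toarray(), dm.Z.toarray(), dm.W.toarray(), A, Y, *theta
        )
        assert st["logL"] == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("k", [1, 2])
    def test_scores_match_finite_differences(self, tiny_problem, k):
        ped, rec, dm, Ainv, A = tiny_problem
        Y = rec[["y1", "y2"]].to_numpy()[:, :k]
        theta = self.UNI if k == 1 else self.BIV
        eng = rm._Engine(dm, Ainv, Y)
        score = eng.score(eng.evaluate(theta))
        X, Z, W = dm.X.toarray(), dm.Z.toarray(), dm.W.toarray()
        eps = 1e-6
        fd = []
        for b in range(3):
            for s, t, _ in eng.basis:

                def at(h):
                    ms = [m.copy() for m in theta]
                    ms[b][s, t] += h
                    ms[b][t, s] = ms[b][s, t]
                    return dense_reml_logL(X, Z, W, A, Y, *ms)

                fd.append((at(eps) - at(-eps)) / (2 * eps))
        assert np.allclose(score, fd, rtol=1e-4, atol=1e-6)


class TestUnivariate:
    def test_balanced_unrelated_equals_anova(self):
        """On a balanced one-way design REML reduces to the ANOVA estimator.

        With A = I the additive/permanent split is unidentifiable; only the
        between-cow sum and the residual are compared.
        """
        rng = np.random.default_rng(42)
        parents = {f"C{i}": (None, None) for i in range(100)}
        ped = Pedigree.from_parent_map(parents)
        y = np.repeat(rng.normal(0, np.sqrt(3.0), 100), 2)
        y = y + rng.normal(0, np.sqrt(5.0), 200)
        rec = pd.DataFrame(
            {"cow": np.repeat(list(parents), 2), "parity": np.tile([1, 2], 100), "y": y}
        )
        dm = rm.build_design(rec, ped, NO_FIXED)
        vc = rm.reml_univariate(
            dm, build_nrm_inverse(ped), y, rtol=1e-12, ltol=1e-13, max_iter=5000
        )
        between, within = anova_oneway(y, 2)
        assert vc.sigma2_a + vc.sigma2_pe == pytest.approx(between, rel=1e-6)
        assert vc.sigma2_e == pytest.approx(within, rel=1e-6)

    def test_em_loglik_monotone(self, halfsib_small):
        ped, rec, dm, Ainv = halfsib_small
        vc = rm.reml_univariate(dm, Ainv, rec["y"], method="em", max_iter=150)
        hist = np.asarray(vc.logL_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_record_reordering_invariance(self, halfsib_small):
        ped, rec, dm, Ainv = halfsib_small
        base = rm.reml_univariate(dm, Ainv, rec["y"], trait="y")
        perm = np.random.default_rng(5).permutation(len(rec))
        rec2 = rec.iloc[perm].reset_index(drop=True)
        dm2 = rm.build_design(rec2, ped, NO_FIXED)
        other = rm.reml_univariate(dm2, Ainv, rec2["y"], trait="y")
        for attr in ("sigma2_a", "sigma2_pe", "sigma2_e", "logL"):
            assert getattr(other, attr) == pytest.approx(
                getattr(base, attr), rel=1e-6
            )

    def test_covariate_affine_rescaling_invariance(self, halfsib_small):
        """Component estimates are unchanged when the covariate is affinely
        rescaled (the restricted likelihood itself shifts by log|c|, a
        well-known property of REML under reparametrisation of X)."""
        ped, rec, dm_, Ainv = halfsib_small
        rng = np.random.default_rng(11)
        rec = rec.assign(ll=rng.integers(200, 401, size=len(rec)))
        spec = rm.ModelSpec(fixed_factors=(), covariates=("ll",))
        base = rm.reml_univariate(rm.build_design(rec, ped, spec), Ainv, rec["y"])
        rec2 = rec.assign(ll=3.0 * rec["ll"] - 100.0)
        other = rm.reml_univariate(rm.build_design(rec2, ped, spec), Ainv, rec2["y"])
        for attr in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            assert getattr(other, attr) == pytest.approx(
                getattr(base, attr), rel=1e-6
            )
        assert other.logL == pytest.approx(base.logL - np.log(3.0), abs=1e-4)

    def test_response_scaling_scales_components(self, halfsib_small):
        """y -> c y multiplies every component by c^2; h2 and r unchanged."""
        ped, rec, dm, Ainv = halfsib_small
        base = rm.reml_univariate(dm, Ainv, rec["y"])
        scaled = rm.reml_univariate(dm, Ainv, 2.0 * rec["y"])
        for attr in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            assert getattr(scaled, attr) == pytest.approx(
                4.0 * getattr(base, attr), rel=1e-6
            )
        assert gp.heritability(scaled) == pytest.approx(
            gp.heritability(base), rel=1e-6
        )
        assert gp.repeatability(scaled) == pytest.approx(
            gp.repeatability(base), rel=1e-6
        )

    def test_null_additive_variance_detected(self):
        """Data with no sire-family signal: the additive estimate collapses.

        With the truth on the boundary, REML puts ~half its mass exactly at
        the variance floor and the rest at small positive values (half-
        normal); the check asserts that signature: several replicates land
        exactly on the floor, every estimate is small, and the replicate
        mean is within the boundary-theory expectation.
        """
        at_floor = 0
        h2s = []
        for seed in range(1, 11):
            ped, rec = sim.simulate_single_trait(200, 10, 2, 0.0, 2.0, 5.0, seed=seed)
            dm = rm.build_design(rec, ped, NO_FIXED)
            vc = rm.reml_univariate(
                dm, build_nrm_inverse(ped), rec["y"], max_iter=80
            )
            floor = 1e-8 * rec["y"].var(ddof=1)
            at_floor += vc.sigma2_a <= 2.0 * floor
            h2s.append(gp.heritability(vc))
        assert at_floor >= 2
        assert np.mean(h2s) < 0.04
        assert max(h2s) < 0.15

    def test_bad_start_errors(self, halfsib_small):
        ped, rec, dm, Ainv = halfsib_small
        with pytest.raises(ValueError, match="positive"):
            rm.reml_univariate(dm, Ainv, rec["y"], start=(0.0, 1.0, 1.0))


class TestAic:
    @pytest.mark.parametrize(
        "logL, k, expected", [(0.0, 3, 6.0), (-100.0, 3, 206.0), (-340_238.0, 3, 680_482.0)]
    )
    def test_values(self, logL, k, expected):
        assert rm.aic(logL, k) == expected

    def test_invalid_param_count(self):
        with pytest.raises(ValueError):
            rm.aic(-10.0, 0)

    def test_fit_reports_consistent_aic(self, halfsib_small):
        ped, rec, dm, Ainv = halfsib_small
        vc = rm.reml_univariate(dm, Ainv, rec["y"])
        assert vc.aic == pytest.approx(-2.0 * vc.logL + 2 * vc.n_params)


class TestBivariate:
    def test_affine_copy_has_unit_correlations(self, halfsib_small):
        """y2 = 2 y1 + 5 forces genetic and phenotypic correlations of 1."""
        ped, rec, dm, Ainv = halfsib_small
        with pytest.warns(UserWarning):
            fit = rm.reml_bivariate(
                dm, Ainv, rec["y"], 2.0 * rec["y"] + 5.0, max_iter=60
            )
        assert fit.rg() == pytest.approx(1.0, abs=1e-3)
        assert fit.rp() == pytest.approx(1.0, abs=1e-3)

    def test_independent_traits_give_near_zero_rg(self, null_bivariate_fits):
        """True cross-covariances of 0: mean genetic correlation near zero."""
        rgs = np.array([biv.rg() for biv, _ in null_bivariate_fits])
        se = np.array([biv.rg_se() for biv, _ in null_bivariate_fits])
        # each estimate individually consistent with zero ...
        assert np.all(np.abs(rgs) < 3.0 * se)
        # ... and the mean inside the sampling band of the experiment
        assert abs(rgs.mean()) < 2.5 * np.sqrt((se**2).mean() / len(rgs))

    def test_marginals_match_univariate_fits(self, null_bivariate_fits):
        """With true zero cross-covariances the marginal components agree."""
        for biv, (u1, u2) in null_bivariate_fits:
            for i, uni in ((0, u1), (1, u2)):
                marg = biv.marginal(i)
                for attr in ("sigma2_a", "sigma2_pe", "sigma2_e"):
                    assert getattr(marg, attr) == pytest.approx(
                        getattr(uni, attr), rel=1e-3
                    )

    def test_recovers_known_genetic_correlation(self):
        """rg = 0.8, equal variances: recovered within +/-0.05 on average."""
        Ga = np.array([[4.0, 3.2], [3.2, 4.0]])
        Gpe = np.array([[2.0, 0.6], [0.6, 2.0]])
        R0 = np.array([[6.0, 1.2], [1.2, 6.0]])
        from methaherd.experiments import bivariate_recovery

        df = bivariate_recovery(range(1, 4), Ga, Gpe, R0)
        assert df["converged"].all()
        assert df["rg"].mean() == pytest.approx(0.8, abs=0.05)
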