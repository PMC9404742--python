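"""The synthetic-herd generator: structure, calibration, determinism."""

import numpy as np
import pytest

from methaherd import simulate as sim
from methaherd.pedigree import build_nrm_inverse


class TestPedigreeSimulation:
    def test_one_generation_counts(self):
        cfg = sim.SimulationConfig(seed=1, n_sires=2, daughters_per_sire=3)
        ped = sim.simulate_pedigree(cfg)
        cows = [a for a in ped.ids if a.startswith("C")]
        assert len(cows) == 6
        assert len(ped) == 8  # plus the two founder sires

    def test_same_seed_identical(self):
        cfg = sim.SimulationConfig(seed=9, n_sires=5, daughters_per_sire=4,
                                   n_generations=2, use_founder_dams=True)
        assert sim.simulate_pedigree(cfg) == sim.simulate_pedigree(cfg)

    def test_two_generations_reach_depth_two(self):
        cfg = sim.SimulationConfig(seed=2, n_sires=3, daughters_per_sire=2,
                                   n_generations=2)
        ped = sim.simulate_pedigree(cfg)
        assert ped.generation.max() == 2

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_sires=0)


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_effects(self, fullsib_ped):
        u = sim.simulate_breeding_values(fullsib_ped, [[0.0]], seed=1)
        assert np.all(u == 0.0)

    def test_founder_variance(self):
        from methaherd.pedigree import Pedigree

        ped = Pedigree.from_parent_map({f"F{i}": (None, None) for i in range(10_000)})
        u = sim.simulate_breeding_values(ped, [[4.0]], seed=2)[:, 0]
        assert u.var(ddof=1) == pytest.approx(4.0, abs=0.2)

    def test_parent_offspring_covariance_is_half(self):
        """Cov(sire BV, daughter BV) = 0.5 sigma_a^2 (a_ij = 0.5)."""
        ped = sim._halfsib_pedigree(5000, 1)
        u = sim.simulate_breeding_values(ped, [[1.0]], seed=3)[:, 0]
        sires = np.array([ped.index(f"S_{j}") for j in range(5000)])
        kids = np.array([ped.index(f"C_{j}_0") for j in range(5000)])
        cov = np.cov(u[sires], u[kids])[0, 1]
        assert cov == pytest.approx(0.5, abs=0.03)

    def test_non_psd_matrix_errors(self, trio_ped):
        with pytest.raises(ValueError, match="PSD"):
            sim.simulate_breeding_values(trio_ped, [[1.0, 2.0], [2.0, 1.0]], seed=1)


class TestRecordCounts:
    def test_truncated_geometric_hits_target_mean(self):
        p = sim.truncated_geometric_p(38011.0 / 17468.0, 6)
        k = np.arange(1, 7)
        w = p * (1 - p) ** (k - 1)
        w /= w.sum()
        assert float(k @ w) == pytest.approx(38011.0 / 17468.0, abs=1e-9)

    def test_realised_mean_records_per_cow(self):
        cfg = sim.small_preset(seed=4)
        herd = sim.simulate_records(sim.simulate_pedigree(cfg), cfg)
        counts = herd.records.groupby("cow").size()
        assert counts.between(1, 6).all()
        assert counts.mean() == pytest.approx(38011.0 / 17468.0, abs=0.06)


class TestRecords:
    def test_pure_residual_variance(self):
        """sigma_a = sigma_pe = 0 and no fixed effects: Var(y) ~ sigma_e^2."""
        _, rec = sim.simulate_single_trait(200, 10, 2, 0.0, 0.0, 4.0, seed=5)
        assert rec["y"].var(ddof=1) == pytest.approx(4.0, rel=0.06)

    def test_methane_phenotypic_variance_matches_published_total(self):
        """Default small preset: Var(mpe1) within 10% of the published
        component sum (additive + permanent + residual)."""
        cfg = sim.small_preset(seed=1)
        herd = sim.simulate_records(sim.simulate_pedigree(cfg), cfg)
        target = sum(sim.MPE1_TRUE_COMPONENTS)
        assert herd.records["mpe1"].var(ddof=1) == pytest.approx(target, rel=0.10)

    def test_single_record_per_cow_degenerate_design(self):
        """With one record per cow, W equals Z restricted to phenotyped cows
        (the additive/permanent split is unidentifiable downstream)."""
        cfg = sim.SimulationConfig(seed=6, records_fixed=1, n_sires=20,
                                   daughters_per_sire=5)
        herd = sim.simulate_records(sim.simulate_pedigree(cfg), cfg)
        from methaherd import reml as rm

        dm = rm.build_design(herd.records, herd.pedigree, rm.ModelSpec(trait="milk"))
        Z = dm.Z.toarray()[:, [herd.pedigree.index(c) for c in dm.cow_ids]]
        assert np.array_equal(Z, dm.W.toarray())

    def test_composition_constraints_hold(self):
        cfg = sim.small_preset(seed=7)
        r = sim.simulate_records(sim.simulate_pedigree(cfg), cfg).records
        assert (r[["milk", "fat", "protein", "lactose", "dry_matter"]] > 0).all().all()
        assert ((r.fat + r.protein + r.lactose) <= r.dry_matter).all()
        assert (r.dry_matter <= r.milk).all()
        assert r["lactation_length"].between(200, 400).all()
        assert r["parity"].between(1, 6).all()

    def test_methane_is_deterministic_function_of_milk_by_default(self):
        cfg = sim.small_preset(seed=8)
        r = sim.simulate_records(sim.simulate_pedigree(cfg), cfg).records
        assert np.corrcoef(r["mpe1"], r["milk"])[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_optional_methane_noise_breaks_perfect_correlation(self):
        cfg = sim.small_preset(seed=8, methane_noise_sd=500.0)
        r = sim.simulate_records(sim.simulate_pedigree(cfg), cfg).records
        assert np.corrcoef(r["mpe1"], r["milk"])[0, 1] < 1.0 - 1e-6

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = sim.SimulationConfig(seed=12, n_sires=10, daughters_per_sire=5)
        for d in ("a", "b"):
            herd = sim.simulate_records(sim.simulate_pedigree(cfg), cfg)
            herd.write(tmp_path / d)
        for name in ("pedigree.csv", "phenotypes.csv", "true_breeding_values.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_generated_means_match_configuration(self):
        """Across seeds, realised trait means sit within 2 SE of the
        configured means, with the SE derived from the realised design
        (factor-level shares, sire families, residual counts)."""
        seeds = tuple(range(1, 13))
        traits = ("milk", "fat", "protein", "lactose")
        devs = {t: [] for t in traits}
        se2s = {t: [] for t in traits}
        for seed in seeds:
            cfg = sim.small_preset(seed=seed)
            herd = sim.simulate_records(sim.simulate_pedigree(cfg), cfg)
            rec = herd.records
            n = len(rec)
            cow_share = rec["cow"].value_counts(normalize=True)
            ped = herd.pedigree
            sire_share = (
                rec["cow"].map(lambda c: ped.ids[ped.sire[ped.index(c)]])
                .value_counts(normalize=True)
            )
            for t in traits:
                s2a, s2pe, s2e = cfg.component_variances()[t]
                fe_sd = cfg.fixed_effect_sd_fraction * cfg.trait_means[t]
                se2 = 0.0
                for fac in ("herd", "year", "season", "parity"):
                    w = rec[fac].value_counts(normalize=True).to_numpy()
                    se2 += fe_sd**2 * float((w**2).sum())
                slope = cfg.lactation_slope_fraction * cfg.trait_means[t] / 310.0
                se2 += slope**2 * float(rec["lactation_length"].var(ddof=1)) / n
                se2 += s2a * (
                    0.25 * float((sire_share**2).sum())
                    + 0.75 * float((cow_share**2).sum())
                )
                se2 += s2pe * float((cow_share**2).sum()) + s2e / n
                devs[t].append(rec[t].mean() - cfg.trait_means[t])
                se2s[t].append(se2)
        for t in traits:
            grand_dev = np.mean(devs[t])
            se_grand = np.sqrt(np.mean(se2s[t]) / len(seeds))
            assert abs(grand_dev) < 2.0 * se_grand, f"{t}: {grand_dev} vs {se_grand}"


class TestRecoveryLoop:
    def test_direct_simulation_matches_published_component_scale(self):
        """A directly simulated methane phenotype at the published truth has
        the intended phenotypic variance (sanity of the recovery setup)."""
        a, pe, e = sim.MPE1_TRUE_COMPONENTS
        _, rec = sim.simulate_single_trait(200, 10, 2, a, pe, e, mean=30934.0, seed=9)
        assert rec["y"].var(ddof=1) == pytest.approx(a + pe + e, rel=0.10)
        assert rec["y"].mean() == pytest.approx(30934.0, rel=0.01)
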