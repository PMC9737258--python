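"""Synthetic generators: determinism, placement fidelity, coupling structure."""

import numpy as np
import pytest
from scipy import stats

from hma.synthetic import (
    PhenotypeCoupling,
    PopulationSpec,
    RadialPlacementModel,
    SimulationConfig,
    generate_aggregate_image,
    generate_phenotype_tables,
    generate_survival,
)
from hma.zonation import WellGeometry, quantify_zones
from hma.phenotypes import resistance_metric


def _config(populations, **kw):
    defaults = dict(
        geometry=WellGeometry(diameter_um=100.0, um_per_px=1.0),
        populations=populations,
        z_slices=1,
        noise_sd=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


INNER = RadialPlacementModel.from_zone_probs((1.0, 0.0, 0.0, 0.0, 0.0))


class TestAggregateImage:
    def test_no_cells_no_noise_gives_all_zero_image(self):
        cfg = _config((PopulationSpec("a", "red", 0, 3.0, INNER),))
        stack = generate_aggregate_image(cfg)
        assert not stack.pixels.any()

    def test_same_seed_is_bit_identical(self):
        pops = (
            PopulationSpec("a", "red", 40, 3.0, INNER),
            PopulationSpec("b", "green", 40, 3.0, RadialPlacementModel.core_shell_model(0.5, 0.8)),
        )
        s1 = generate_aggregate_image(_config(pops, noise_sd=0.1, z_slices=2))
        s2 = generate_aggregate_image(_config(pops, noise_sd=0.1, z_slices=2))
        assert np.array_equal(s1.pixels, s2.pixels)

    def test_different_seed_differs(self):
        pops = (PopulationSpec("a", "red", 40, 3.0, INNER),)
        s1 = generate_aggregate_image(_config(pops, seed=1))
        s2 = generate_aggregate_image(_config(pops, seed=2))
        assert not np.array_equal(s1.pixels, s2.pixels)

    def test_innermost_zone_probs_confine_cells_and_signal(self):
        """All-zone-I placement: every center within R/5, occupancy ≥ 0.99.

        Sparse sub-resolution markers keep disk spill across the zone
        boundary below the 1% budget (cell-sized disks straddle it).
        """
        g = WellGeometry(diameter_um=500.0, um_per_px=0.25)
        cfg = SimulationConfig(
            geometry=g,
            populations=(PopulationSpec("a", "red", 2000, 0.5, INNER),),
            noise_sd=0.0,
            seed=9,
        )
        stack, positions = generate_aggregate_image(cfg, return_positions=True)
        assert (positions["a"]["r_um"] <= g.radius_um / 5).all()
        profile = quantify_zones(stack, g, threshold=0.5)
        assert profile.fractions("red")[0] >= 0.99

    def test_channel_collision_rejected(self):
        pops = (
            PopulationSpec("a", "red", 5, 3.0, INNER),
            PopulationSpec("b", "red", 5, 3.0, INNER),
        )
        with pytest.raises(ValueError, match="channel"):
            generate_aggregate_image(_config(pops))

    def test_cell_radius_at_least_well_radius_rejected(self):
        pops = (PopulationSpec("a", "red", 5, 50.0, INNER),)
        with pytest.raises(ValueError, match="cell_radius_um"):
            generate_aggregate_image(_config(pops))

    def test_zone_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="zone_probs"):
            RadialPlacementModel.from_zone_probs((0.5, 0.4, 0.0, 0.0, 0.0))

    def test_noise_keeps_intensities_nonnegative(self):
        pops = (PopulationSpec("a", "red", 10, 3.0, INNER),)
        stack = generate_aggregate_image(_config(pops, noise_sd=0.5))
        assert float(stack.pixels.min()) >= 0.0


class TestExpectedZoneProfile:
    def test_zone_probabilities_mode_is_identity(self):
        probs = (0.1, 0.2, 0.3, 0.25, 0.15)
        np.testing.assert_allclose(
            RadialPlacementModel.from_zone_probs(probs).expected_zone_profile(5), probs
        )

    def test_core_shell_profile_sums_to_one_and_matches_sampling(self):
        model = RadialPlacementModel.core_shell_model(0.45, 0.7)
        expected = model.expected_zone_profile(5, well_radius_um=250.0)
        assert expected.sum() == pytest.approx(1.0, abs=1e-12)
        # Monte-Carlo check against the actual sampler
        from hma.synthetic import _sample_polar

        g = WellGeometry(diameter_um=500.0, um_per_px=1.0)
        r, _ = _sample_polar(model, g, 200_000, np.random.default_rng(0))
        counts = np.histogram(r, bins=np.linspace(0, 250, 6))[0]
        np.testing.assert_allclose(counts / counts.sum(), expected, atol=0.005)


class TestPhenotypeTables:
    SCORES = {"p1": 1.3, "p2": 2.0, "p3": 2.9, "p4": 4.1}

    def test_noiseless_coupling_reproduces_score_order(self):
        doses, _, _ = generate_phenotype_tables(
            self.SCORES, PhenotypeCoupling("resistant_when_external", 0.0, seed=1)
        )
        metrics = {
            l: resistance_metric(g["dose_uM"], g["viability"])
            for l, g in doses.groupby("label")
        }
        order = sorted(metrics, key=metrics.get)
        assert order == sorted(self.SCORES, key=self.SCORES.get)

    def test_equal_scores_give_equal_metrics(self):
        doses, _, _ = generate_phenotype_tables(
            {"a": 2.0, "b": 2.0}, PhenotypeCoupling("resistant_when_external", 0.0)
        )
        va = doses[doses.label == "a"]["viability"].to_numpy()
        vb = doses[doses.label == "b"]["viability"].to_numpy()
        np.testing.assert_array_equal(va, vb)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="two labels"):
            generate_phenotype_tables({"only": 1.0}, PhenotypeCoupling())

    def test_independent_direction_has_null_rank_correlation(self):
        """Decoupled drug response: Spearman(score, resistance) centred at 0."""
        rhos = []
        for seed in range(300):
            doses, _, _ = generate_phenotype_tables(
                self.SCORES, PhenotypeCoupling("independent", 0.0, seed=seed)
            )
            metrics = {
                l: resistance_metric(g["dose_uM"], g["viability"])
                for l, g in doses.groupby("label")
            }
            labels = sorted(self.SCORES)
            rho = stats.spearmanr(
                [self.SCORES[l] for l in labels], [metrics[l] for l in labels]
            ).statistic
            rhos.append(rho)
        # mean of 300 null Spearman rhos (sd ≈ 0.58/√300 ≈ 0.033)
        assert abs(np.mean(rhos)) < 0.12

    def test_determinism(self):
        c = PhenotypeCoupling("resistant_when_external", 0.05, seed=8)
        t1 = generate_phenotype_tables(self.SCORES, c)
        t2 = generate_phenotype_tables(self.SCORES, c)
        for a, b in zip(t1, t2):
            assert a.equals(b)


class TestSurvivalGenerator:
    GROUPS = {"p1": "internal", "p2": "internal", "p3": "external", "p4": "external"}

    def test_all_censored_when_censor_prob_is_one(self):
        df = generate_survival(self.GROUPS, 1.0, censor_prob=1.0, n_per_group=20, seed=4)
        assert not df["event"].any()
        assert (df["time"] > 0).all()

    def test_sample_median_matches_exponential_median(self):
        df = generate_survival(
            self.GROUPS, 1.0, baseline_median=30.0, censor_prob=0.0, n_per_group=10_000, seed=5
        )
        assert float(df["time"].median()) == pytest.approx(30.0, rel=0.05)

    def test_group_sizes_and_determinism(self):
        df1 = generate_survival(self.GROUPS, 2.0, n_per_group=15, seed=6)
        df2 = generate_survival(self.GROUPS, 2.0, n_per_group=15, seed=6)
        assert df1.equals(df2)
        assert df1.groupby("group").size().tolist() == [15, 15]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="hazard_ratio"):
            generate_survival(self.GROUPS, 0.0)
        with pytest.raises(ValueError, match="two distinct groups"):
            generate_survival({"a": "g1"}, 1.0)
        with pytest.raises(ValueError, match="censor_prob"):
            generate_survival(self.GROUPS, 1.0, censor_prob=1.5)
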