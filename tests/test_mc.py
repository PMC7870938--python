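"""Monte-Carlo plasmid irradiation: geometry, sampler, scoring, clustering."""

import math

import numpy as np
import pytest

from conftest import brute_force_max_pairing
from plasmidrbe.mc import (
    DamageTally,
    EnergyDeposit,
    PlasmidGeometry,
    ScoringModel,
    SimulationConfig,
    build_plasmid,
    cluster_dsb,
    parameter_scan,
    sample_path_deposits,
    sample_track_deposits,
    score_ssb,
    simulate_yields,
    truncated_exp_mean,
)
from plasmidrbe.synthetic import generate_ssb_fixture


class TestGeometry:
    def test_pbr322_ring_radius(self):
        g = build_plasmid(4361, 0.34)
        assert g.ring_radius_nm == pytest.approx(236.0, rel=0.005)

    def test_segment_spacing(self):
        g = build_plasmid(100)
        assert math.degrees(g.segment_angle_rad) == pytest.approx(3.6)

    def test_backbone_volume_additivity(self):
        g = build_plasmid(500)
        assert g.backbone_volume_nm3 == pytest.approx(500 * 2 * g.half_cylinder_volume_nm3)

    def test_too_few_bp(self):
        with pytest.raises(ValueError):
            build_plasmid(2)

    def test_segment_centres_on_ring(self):
        g = build_plasmid(50)
        centres = g.segment_centres()
        radii = np.hypot(centres[:, 0], centres[:, 1])
        assert np.allclose(radii, g.ring_radius_nm)


class TestDepositSampler:
    def test_zero_electrons_empty(self):
        g = build_plasmid()
        assert sample_track_deposits(g, 300.0, 0.22, 0, seed=1) == []

    def test_seed_required(self):
        g = build_plasmid()
        with pytest.raises(ValueError, match="seed"):
            sample_track_deposits(g, 300.0, 0.22, 10, seed=None)

    def test_beam_must_cover_ring(self):
        g = build_plasmid()
        with pytest.raises(ValueError, match="cover"):
            sample_track_deposits(g, 100.0, 0.22, 10, seed=1)

    def test_fixed_seed_reproducible(self):
        g = build_plasmid()
        a = sample_track_deposits(g, 300.0, 0.22, 5000, seed=12)
        b = sample_track_deposits(g, 300.0, 0.22, 5000, seed=12)
        assert a == b

    def test_let_calibration_on_slab(self):
        """Energy per unit path over many slab traversals matches LET within 2%."""
        rng = np.random.default_rng(5)
        lengths = np.full(100_000, 50.0)  # thick slab: enough events to resolve 2%
        _, _, energies = sample_path_deposits(lengths, 0.2202, rng)
        linear_energy = energies.sum() / lengths.sum()
        assert linear_energy == pytest.approx(0.2202, rel=0.02)

    def test_truncated_exp_mean_matches_samples(self):
        rng = np.random.default_rng(9)
        lengths = np.full(50_000, 10.0)
        _, _, e = sample_path_deposits(lengths, 1.0, rng)
        assert e.mean() == pytest.approx(truncated_exp_mean(34.0), rel=0.02)
        assert e.min() >= 1.0 and e.max() <= 500.0

    def test_deposits_carry_valid_tags(self):
        g = build_plasmid()
        deps = sample_track_deposits(g, 300.0, 5.0, 20000, seed=3)
        assert len(deps) > 0
        assert all(0 <= d.bp_index < g.n_bp and d.strand in (1, 2) and d.energy_ev > 0 for d in deps)


class TestScoring:
    def test_threshold_above_and_below(self):
        deps = [EnergyDeposit(100, 1, 10.0)]
        assert score_ssb(deps, ScoringModel.threshold(8.22)) == {(100, 1)}
        assert score_ssb(deps, ScoringModel.threshold(17.5)) == frozenset()

    def test_accumulation_across_deposits(self):
        deps = [EnergyDeposit(7, 2, 9.0), EnergyDeposit(7, 2, 9.0)]
        assert score_ssb(deps, ScoringModel.threshold(17.5)) == {(7, 2)}
        # per-deposit mode requires a single event over threshold
        assert score_ssb(deps, ScoringModel.threshold(17.5), per_deposit=True) == frozenset()

    def test_ramp_midpoint_probability_half(self):
        """21.25 eV sits midway on the 5-37.5 eV ramp: empirical rate ~0.5."""
        deps = [EnergyDeposit(1, 1, 21.25)]
        rng = np.random.default_rng(0)
        hits = sum(
            bool(score_ssb(deps, ScoringModel.linear_ramp(), rng=rng)) for _ in range(4000)
        )
        assert hits / 4000 == pytest.approx(0.5, abs=0.03)

    def test_ramp_clamps(self):
        rng = np.random.default_rng(0)
        assert score_ssb([EnergyDeposit(1, 1, 4.0)], ScoringModel.linear_ramp(), rng=rng) == frozenset()
        assert score_ssb([EnergyDeposit(1, 1, 50.0)], ScoringModel.linear_ramp(), rng=rng) == {(1, 1)}

    def test_ramp_requires_rng(self):
        with pytest.raises(ValueError):
            score_ssb([EnergyDeposit(1, 1, 20.0)], ScoringModel.linear_ramp())


class TestClustering:
    @pytest.mark.parametrize(
        "ssb, expected",
        [
            ({(100, 1), (105, 2)}, 1),
            ({(100, 1), (105, 1)}, 0),
            ({(4360, 1), (3, 2)}, 1),  # wrap-around: circular distance 4
            ({(100, 1), (111, 2)}, 0),  # distance 11 > 10
            (set(), 0),
        ],
    )
    def test_constructed_cases(self, ssb, expected):
        assert cluster_dsb(ssb, 10, 4361) == expected

    def test_greedy_counterexample_handled_optimally(self):
        """The nearest-pair greedy rule would find 1 here; optimal pairing finds 2."""
        ssb = {(0, 1), (8, 1), (2, 2), (4361 - 9, 2)}
        assert cluster_dsb(ssb, 10, 4361) == 2

    def test_matches_brute_force_on_random_fixtures(self):
        """Maximum-pairing count equals the exhaustive oracle on 300 fixtures."""
        for seed in range(300):
            n_bp = 200 if seed % 3 else 40  # small rings force wrap-around cases
            n_ssb = int(np.random.default_rng(seed).integers(0, 21))
            ssb = generate_ssb_fixture(n_bp, min(n_ssb, 2 * n_bp), seed=seed)
            assert cluster_dsb(ssb, 10, n_bp) == brute_force_max_pairing(ssb, 10, n_bp)

    def test_separation_monotonicity_on_shared_sets(self):
        for seed in range(50):
            ssb = generate_ssb_fixture(4361, 20, seed=seed)
            assert cluster_dsb(ssb, 10, 4361) >= cluster_dsb(ssb, 3, 4361)

    def test_tally_invariant(self):
        with pytest.raises(ValueError):
            DamageTally(ssb_positions=frozenset({(1, 1), (2, 2)}), n_dsb=2)


class TestSimulation:
    def _cfg(self, **kw):
        base = dict(scoring=ScoringModel.threshold(8.22), dose_gy=6000.0, n_runs=60)
        base.update(kw)
        return SimulationConfig(**base)

    def test_deterministic_under_fixed_seed(self):
        r1 = simulate_yields(self._cfg(), 99)
        r2 = simulate_yields(self._cfg(), 99)
        assert r1.dsb_yield == r2.dsb_yield
        assert [t.ssb_positions for t in r1.tallies] == [t.ssb_positions for t in r2.tallies]

    def test_threshold_monotonicity_shared_seeds(self):
        yields = [
            simulate_yields(self._cfg(scoring=ScoringModel.threshold(t)), 31).dsb_yield
            for t in (8.22, 17.5, 22.5)
        ]
        assert yields[0] >= yields[1] >= yields[2]

    def test_separation_monotonicity_shared_seeds(self):
        y3 = simulate_yields(self._cfg(separation_bp=3), 17).dsb_yield
        y10 = simulate_yields(self._cfg(separation_bp=10), 17).dsb_yield
        assert y10 >= y3

    def test_zero_damage_when_beam_misses(self):
        """A single electron forced through an enormous beam almost surely
        misses the plasmid: yield 0."""
        cfg = self._cfg(dose_gy=1e-7, beam_radius_nm=1e5, n_runs=5)
        res = simulate_yields(cfg, 4)
        assert res.n_electrons_per_run == 1
        assert res.dsb_yield == 0.0

    def test_dose_required_positive(self):
        with pytest.raises(ValueError):
            simulate_yields(self._cfg(dose_gy=0.0), 1)


class TestParameterScan:
    def test_grid_shape_and_single_cell(self):
        base = SimulationConfig(dose_gy=6000.0, n_runs=30)
        models = [ScoringModel.threshold(t) for t in (8.22, 17.5)]
        table = parameter_scan(models, [3, 10], base, seed=8)
        assert len(table) == 4
        one = parameter_scan([models[0]], [10], base, seed=8)
        direct = simulate_yields(
            SimulationConfig(dose_gy=6000.0, n_runs=30, scoring=models[0], separation_bp=10), 8
        )
        assert one.loc[0, "dsb_yield_mbp_kgy"] == direct.dsb_yield

    def test_deviation_minimal_at_reference_cell(self):
        base = SimulationConfig(dose_gy=6000.0, n_runs=40)
        models = [ScoringModel.threshold(t) for t in (8.22, 22.5)]
        ref = simulate_yields(
            SimulationConfig(dose_gy=6000.0, n_runs=40, scoring=models[0], separation_bp=10), 21
        ).dsb_yield
        table = parameter_scan(models, [3, 10], base, seed=21, reference_yield=ref)
        cell = table[(table["threshold_ev"] == 8.22) & (table["separation_bp"] == 10)]
        assert cell["deviation"].iloc[0] == 0.0
        assert table["deviation"].min() == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            parameter_scan([], [10], SimulationConfig(), seed=1)
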