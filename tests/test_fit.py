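"""Fit-engine tests: scoring, grid search, best-n selection, condition deltas."""

import numpy as np
import pytest

from polfrap import (
    AcquisitionConfig,
    FitSummary,
    InputError,
    KineticModel,
    MeanCurve,
    ParameterGrid,
    ScoredFit,
    SimulatedCurve,
    SimulationConfig,
    compare_conditions,
    grid_fit,
    score,
    select_best,
)
from polfrap.errors import ModelError


def _curves(rfi_sim, rfi_meas, t0_frames=5):
    n = len(rfi_sim)
    times = 0.4 * (np.arange(n) - t0_frames)
    model = KineticModel(f_free=1.0, f_prom=0.0, f_elong=0.0)
    sim = SimulatedCurve(times=times, rfi=np.asarray(rfi_sim, float), model=model, seed=0)
    meas = MeanCurve(
        times=times,
        rfi_mean=np.asarray(rfi_meas, float),
        rfi_sd=np.zeros(n),
        n_cells=1,
    )
    return sim, meas


class TestScore:
    def test_identical_curves_score_zero(self):
        sim, meas = _curves([100.0] * 20, [100.0] * 20)
        assert score(sim, meas) == 0.0

    def test_unit_offset_counts_postbleach_frames_only(self):
        """+1 RFI on every frame scores 1 per post-bleach frame."""
        n, pre = 25, 5
        sim, meas = _curves([101.0] * n, [100.0] * n, t0_frames=pre)
        assert score(sim, meas) == pytest.approx(n - pre)  # frames with t >= 0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = 100 * rng.random(30)
        b = 100 * rng.random(30)
        sim_a, meas_b = _curves(a, b)
        sim_b, meas_a = _curves(b, a)
        assert score(sim_a, meas_b) == pytest.approx(score(sim_b, meas_a))

    def test_mismatched_grids_rejected(self):
        sim, _ = _curves([1.0] * 10, [1.0] * 10)
        _, meas = _curves([1.0] * 12, [1.0] * 12)
        with pytest.raises(InputError):
            score(sim, meas)


class TestParameterGrid:
    def test_enumeration_size(self):
        grid = ParameterGrid(
            f_prom=(0.2, 0.4), f_elong=(0.3,), t_prom=(30.0,), t_elong=(60.0, 120.0),
            seed_offsets=(0, 1),
        )
        assert grid.size == 8
        assert len(grid.models()) == 4

    def test_implied_free_fraction_validated(self):
        with pytest.raises(ModelError):
            ParameterGrid(f_prom=(0.8,), f_elong=(0.5,), t_prom=(1.0,), t_elong=(1.0,))

    def test_empty_axis_rejected(self):
        with pytest.raises(InputError):
            ParameterGrid(f_prom=(), f_elong=(0.3,), t_prom=(1.0,), t_elong=(1.0,))


@pytest.fixture(scope="module")
def small_fit_problem():
    """Tiny grid fit against a synthetic target generated at a grid point."""
    from polfrap import NoiseSpec, average_curves, generate_cells, preprocess_trace

    sim = SimulationConfig(
        n_particles=4000, dt=0.1, seed=5,
        acquisition=AcquisitionConfig(recovery_duration=120.0),
    )
    truth = KineticModel(f_free=0.25, f_prom=0.45, f_elong=0.30, t_prom=30.0, t_elong=23 * 60)
    noise = NoiseSpec(frame_noise_sd=1.0, cell_scale_sd=0.05, seed=31)
    cells = generate_cells(truth, noise, 6, sim, condition_label="0 J")
    target = average_curves([preprocess_trace(t) for t in cells])
    grid = ParameterGrid(
        f_prom=(0.1125, 0.45), f_elong=(0.30,), t_prom=(30.0,),
        t_elong=(10 * 60.0, 23 * 60.0, 45 * 60.0),
    )
    scored = grid_fit(target, grid, sim)
    return truth, grid, sim, target, scored


class TestGridFit:
    def test_exact_generating_model_among_best(self, small_fit_problem):
        """Self-recovery: the generating grid point outranks distant competitors."""
        truth, grid, sim, target, scored = small_fit_problem
        best_two = scored[:2]
        assert any(
            s.model.f_prom == truth.f_prom and s.model.t_elong == truth.t_elong
            for s in best_two
        )

    def test_sorted_ascending(self, small_fit_problem):
        *_, scored = small_fit_problem
        values = [s.score for s in scored]
        assert values == sorted(values)

    def test_grid_of_size_one(self, small_fit_problem):
        truth, _, sim, target, _ = small_fit_problem
        grid = ParameterGrid(
            f_prom=(truth.f_prom,), f_elong=(truth.f_elong,),
            t_prom=(truth.t_prom,), t_elong=(truth.t_elong,),
        )
        scored = grid_fit(target, grid, sim)
        assert len(scored) == 1
        best = scored[0].model
        assert best.f_prom == truth.f_prom and best.t_elong == truth.t_elong
        assert best.f_free == pytest.approx(truth.f_free)

    def test_permuting_grid_order_leaves_result_unchanged(self, small_fit_problem):
        truth, grid, sim, target, scored = small_fit_problem
        permuted = ParameterGrid(
            f_prom=tuple(reversed(grid.f_prom)),
            f_elong=grid.f_elong,
            t_prom=grid.t_prom,
            t_elong=tuple(reversed(grid.t_elong)),
            seed_offsets=grid.seed_offsets,
        )
        scored_p = grid_fit(target, permuted, sim)
        original = [(s.model, round(s.score, 9)) for s in scored]
        shuffled = [(s.model, round(s.score, 9)) for s in scored_p]
        assert original == shuffled

    def test_reproducible_given_seeds(self, small_fit_problem):
        truth, grid, sim, target, scored = small_fit_problem
        again = grid_fit(target, grid, sim)
        assert [(s.score, s.seed) for s in again] == [(s.score, s.seed) for s in scored]


class TestScoreGridAggregation:
    def test_mean_curve_mode_gives_one_score_per_grid_point(self, small_fit_problem):
        """Replicates of a grid point carry the SSE of their averaged curve."""
        from polfrap import score_grid, simulate_grid

        truth, _, sim, target, _ = small_fit_problem
        grid = ParameterGrid(
            f_prom=(0.45,), f_elong=(0.30,), t_prom=(30.0,),
            t_elong=(23 * 60.0, 45 * 60.0), seed_offsets=(0, 1, 2),
        )
        curves = simulate_grid(grid, sim)
        scored = score_grid(curves, target, aggregate="mean_curve")
        by_model = {}
        for s in scored:
            by_model.setdefault(s.model.t_elong, set()).add(round(s.score, 9))
        assert all(len(v) == 1 for v in by_model.values())
        assert len(by_model) == 2

    def test_mean_curve_score_below_mean_of_replicate_scores(self, small_fit_problem):
        """Averaging before scoring removes the replicates' own variance, so
        the aggregated score undercuts the average per-replicate score."""
        from polfrap import score_grid, simulate_grid

        truth, _, sim, target, _ = small_fit_problem
        grid = ParameterGrid(
            f_prom=(0.45,), f_elong=(0.30,), t_prom=(30.0,),
            t_elong=(23 * 60.0,), seed_offsets=(0, 1, 2, 3),
        )
        curves = simulate_grid(grid, sim)
        per_rep = [s.score for s in score_grid(curves, target, aggregate="per_replicate")]
        mean_curve = score_grid(curves, target, aggregate="mean_curve")[0].score
        assert mean_curve < np.mean(per_rep)

    def test_single_replicate_modes_coincide(self, small_fit_problem):
        from polfrap import score_grid, simulate_grid

        truth, _, sim, target, _ = small_fit_problem
        grid = ParameterGrid(
            f_prom=(0.45,), f_elong=(0.30,), t_prom=(30.0,), t_elong=(23 * 60.0,),
        )
        curves = simulate_grid(grid, sim)
        assert (
            score_grid(curves, target, aggregate="mean_curve")[0].score
            == score_grid(curves, target, aggregate="per_replicate")[0].score
        )


class TestSelfRecoveryRepetitions:
    def test_recovered_means_within_one_grid_step(self):
        """Across seeded repetitions, fitting a synthetic cohort recovers each
        parameter mean within one grid step of the generating value."""
        from dataclasses import replace

        from polfrap import NoiseSpec, average_curves, generate_cells, preprocess_trace

        truth = KineticModel(f_free=0.25, f_prom=0.45, f_elong=0.30, t_prom=30.0, t_elong=23 * 60)
        grid = ParameterGrid(
            f_prom=(0.1125, 0.45), f_elong=(0.30,), t_prom=(30.0,),
            t_elong=(18 * 60.0, 23 * 60.0, 32 * 60.0), seed_offsets=(0, 1, 2, 3),
        )
        hits = 0
        n_reps = 5
        for rep in range(n_reps):
            sim = SimulationConfig(
                n_particles=5000, dt=0.1, seed=100 + rep,
                acquisition=AcquisitionConfig(recovery_duration=180.0),
            )
            cells = generate_cells(
                truth, NoiseSpec(seed=200 + rep), 6,
                replace(sim, n_particles=40_000), condition_label="0 J",
            )
            target = average_curves([preprocess_trace(t) for t in cells])
            summary = select_best(grid_fit(target, grid, sim), n_best=4)
            ok = (
                abs(summary.means["f_prom"] - truth.f_prom) <= 0.45 - 0.1125
                and 18 * 60.0 <= summary.means["t_elong"] <= 32 * 60.0
            )
            hits += ok
        assert hits >= 0.9 * n_reps


class TestSelectBest:
    def _scored(self, models_scores):
        return [
            ScoredFit(model=m, seed=0, score=s, order=i)
            for i, (m, s) in enumerate(models_scores)
        ]

    def _model(self, te=60.0):
        return KineticModel(f_free=0.25, f_prom=0.45, f_elong=0.30, t_prom=30.0, t_elong=te)

    def test_identical_best_entries_have_zero_sd(self):
        scored = self._scored([(self._model(), 1.0)] * 5 + [(self._model(999.0), 9.0)] * 5)
        summary = select_best(scored, n_best=5)
        assert summary.means["t_elong"] == 60.0
        assert all(v == 0.0 for v in summary.sds.values())

    def test_n_best_equal_to_list_length_uses_all(self):
        scored = self._scored([(self._model(60.0), 1.0), (self._model(120.0), 2.0)])
        summary = select_best(scored, n_best=2)
        assert summary.means["t_elong"] == pytest.approx(90.0)

    def test_ties_at_cutoff_broken_by_enumeration_order(self):
        scored = self._scored(
            [(self._model(60.0), 1.0), (self._model(120.0), 1.0), (self._model(240.0), 1.0)]
        )
        summary = select_best(scored, n_best=2)
        # orders 0 and 1 win the tie
        assert summary.means["t_elong"] == pytest.approx(90.0)

    def test_fewer_entries_than_n_best_rejected(self):
        with pytest.raises(InputError):
            select_best(self._scored([(self._model(), 1.0)]), n_best=2)

    def test_duplicated_grid_points_leave_means_unchanged(self):
        base = [(self._model(60.0), 1.0), (self._model(120.0), 2.0)]
        summary1 = select_best(self._scored(base), n_best=2)
        summary2 = select_best(self._scored(base + base), n_best=4)
        assert summary1.means == summary2.means

    def test_round_trips_through_json(self, tmp_path):
        summary = select_best(
            self._scored([(self._model(60.0), 1.0), (self._model(120.0), 2.0)]),
            n_best=2, condition_label="0 J",
        )
        path = tmp_path / "summary.json"
        summary.to_json(path)
        loaded = FitSummary.from_json(path)
        assert loaded.means == summary.means
        assert loaded.condition_label == "0 J"


class TestCompareConditions:
    def _summary(self, **means):
        base = {"f_free": 0.25, "f_prom": 0.45, "f_elong": 0.30, "t_prom": 30.0, "t_elong": 1380.0}
        base.update(means)
        return FitSummary(means=base, sds={k: 0.0 for k in base}, n_best=1, scores=(0.0,))

    def test_identical_summaries_give_zero_deltas(self):
        a = self._summary()
        deltas = compare_conditions(a, a)
        assert all(v == 0.0 for v in deltas.values())

    def test_t_elong_20_to_25_minutes_is_plus_25_percent(self):
        deltas = compare_conditions(
            self._summary(t_elong=20 * 60.0), self._summary(t_elong=25 * 60.0)
        )
        assert deltas["t_elong"] == pytest.approx(25.0)

    def test_f_prom_040_to_010_is_minus_75_percent(self):
        deltas = compare_conditions(
            self._summary(f_prom=0.40), self._summary(f_prom=0.10)
        )
        assert deltas["f_prom"] == pytest.approx(-75.0)

    def test_zero_denominator_flags_nan(self):
        deltas = compare_conditions(self._summary(f_prom=0.0), self._summary(f_prom=0.1))
        assert np.isnan(deltas["f_prom"])
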