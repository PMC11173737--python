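"""WHAM reconstruction, water-induced decomposition, features, correlations."""

import numpy as np
import pytest

import hydroshape as hs
from hydroshape.errors import (
    ConnectivityError,
    ConvergenceError,
    DegenerateDataError,
    DomainError,
)


def aligned_rmse(profile, truth_fn):
    """RMSE against truth after removing the free additive constant."""
    m = profile.finite_mask
    diff = profile.values[m] - truth_fn(profile.grid[m])
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


class TestWhamSolve:
    def test_uniform_samples_give_flat_profile(self):
        rng = np.random.default_rng(0)
        window = hs.UmbrellaWindow(
            center=5.0, spring_k=1e-9, samples=rng.uniform(0, 10, 200_000)
        )
        profile = hs.wham_solve([window], bin_width=0.1)
        assert np.nanmax(np.abs(profile.values)) < 0.5

    def test_recovers_double_well_truth(self, double_well_truth, small_umbrella_windows):
        profile = hs.wham_solve(small_umbrella_windows, bin_width=0.1)
        # 2000 samples/window: coarse but already well within 1.5 kJ/mol
        assert aligned_rmse(profile, double_well_truth) < 1.5

    def test_rmse_shrinks_with_sampling(self, double_well_truth):
        centers = np.arange(3.0, 13.1, 1.0)
        rmse = {}
        for n in (1000, 10_000):
            windows = hs.generate_umbrella_samples(
                double_well_truth, centers, spring_k=15.0, n_samples=n, seed=13
            )
            rmse[n] = aligned_rmse(hs.wham_solve(windows), double_well_truth)
        assert rmse[10_000] < rmse[1000]

    def test_invariant_under_window_reordering(self, small_umbrella_windows):
        a = hs.wham_solve(small_umbrella_windows)
        b = hs.wham_solve(list(reversed(small_umbrella_windows)))
        assert np.allclose(a.grid, b.grid)
        assert np.allclose(a.values, b.values, atol=1e-4, equal_nan=True)

    def test_duplicating_a_single_window_is_exact(self):
        rng = np.random.default_rng(5)
        w = hs.UmbrellaWindow(center=5.0, spring_k=10.0, samples=rng.normal(5.0, 0.5, 5000))
        a = hs.wham_solve([w])
        b = hs.wham_solve([w, w])
        assert np.allclose(a.values, b.values, atol=1e-9, equal_nan=True)

    def test_duplication_perturbs_only_at_noise_scale(self, small_umbrella_windows):
        # duplicating one of many windows double-weights its finite-sample
        # histogram; the pooled estimate moves by at most the per-window
        # statistical scale
        a = hs.wham_solve(small_umbrella_windows)
        b = hs.wham_solve(list(small_umbrella_windows) + [small_umbrella_windows[0]])
        assert np.nanmax(np.abs(a.values - b.values)) < 0.2

    def test_invariant_under_coordinate_shift(self, small_umbrella_windows):
        shift = 100.0
        shifted = [
            hs.UmbrellaWindow(
                center=w.center + shift, spring_k=w.spring_k,
                samples=w.samples + shift, temperature=w.temperature,
            )
            for w in small_umbrella_windows
        ]
        a = hs.wham_solve(small_umbrella_windows)
        b = hs.wham_solve(shifted)
        assert np.allclose(b.grid - shift, a.grid, atol=1e-9)
        assert np.allclose(a.values, b.values, atol=1e-8, equal_nan=True)

    def test_profile_pinned_to_zero_at_reference(self, small_umbrella_windows):
        profile = hs.wham_solve(small_umbrella_windows)
        m = profile.finite_mask
        ref_idx = np.argmin(np.abs(profile.grid[m] - profile.reference_point))
        assert profile.values[m][ref_idx] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_windows_raise_connectivity_error(self):
        w1 = hs.UmbrellaWindow(center=1.0, spring_k=10.0, samples=np.linspace(0.5, 1.5, 100))
        w2 = hs.UmbrellaWindow(center=8.0, spring_k=10.0, samples=np.linspace(7.5, 8.5, 100))
        with pytest.raises(ConnectivityError, match="gap"):
            hs.wham_solve([w1, w2])

    def test_mixed_temperatures_rejected(self, small_umbrella_windows):
        hot = hs.UmbrellaWindow(
            center=5.0, spring_k=15.0,
            samples=small_umbrella_windows[2].samples, temperature=400.0,
        )
        with pytest.raises(DomainError, match="temperature"):
            hs.wham_solve(list(small_umbrella_windows) + [hot])

    def test_non_convergence_reports_residual(self, small_umbrella_windows):
        with pytest.raises(ConvergenceError) as err:
            hs.wham_solve(small_umbrella_windows, tolerance=1e-12, max_iter=2)
        assert err.value.residual is not None and err.value.residual > 0


class TestWaterInducedDecomposition:
    GRID = np.linspace(2.0, 12.0, 101)

    def _profile(self, values, provenance="total"):
        return hs.PMFProfile(grid=self.GRID, values=np.asarray(values, float),
                             provenance=provenance)

    def test_zero_vacuum_returns_total(self):
        total = self._profile(np.sin(self.GRID)).pinned()
        out = hs.water_induced_pmf(total, self._profile(np.zeros_like(self.GRID), "vacuum"))
        assert np.allclose(out.values, total.values, atol=1e-12)

    def test_total_equals_vacuum_gives_zero(self):
        total = self._profile(np.cos(self.GRID))
        out = hs.water_induced_pmf(total, self._profile(np.cos(self.GRID), "vacuum"))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_recovers_constructed_decomposition(self):
        truth_vac = 5.0 / self.GRID
        truth_wat = -3.0 * np.exp(-((self.GRID - 5) ** 2))
        total = self._profile(truth_vac + truth_wat)
        out = hs.water_induced_pmf(total, self._profile(truth_vac, "vacuum"))
        expected = hs.PMFProfile(grid=self.GRID, values=truth_wat).pinned()
        assert np.allclose(out.values, expected.values, atol=1e-9)
        assert out.provenance == "water_induced"

    def test_decomposition_is_consistent(self):
        # water_induced + vacuum = total after consistent pinning
        vac = self._profile(5.0 / self.GRID, "vacuum")
        total = self._profile(5.0 / self.GRID - np.exp(-((self.GRID - 6) ** 2)))
        wi = hs.water_induced_pmf(total, vac)
        recomposed = hs.PMFProfile(grid=self.GRID, values=wi.values + vac.values).pinned()
        assert np.allclose(recomposed.values, total.pinned().values, atol=1e-9)

    def test_disjoint_grids_rejected(self):
        a = hs.PMFProfile(grid=np.linspace(0, 1, 11), values=np.zeros(11))
        b = hs.PMFProfile(grid=np.linspace(5, 6, 11), values=np.zeros(11))
        with pytest.raises(DomainError, match="overlap"):
            hs.water_induced_pmf(a, b)


class TestFindMinimaBarriers:
    def test_cosine_profile_known_extrema(self):
        grid = np.linspace(0, 10, 201)
        profile = hs.PMFProfile(grid=grid, values=np.cos(2 * np.pi * grid / 5.0))
        feats = hs.find_minima_barriers(profile, prominence_min=0.5)
        assert [pytest.approx(m.position, abs=0.05) for m in feats.minima] == [2.5, 7.5]
        assert len(feats.barriers) == 1
        assert feats.barriers[0].position == pytest.approx(5.0, abs=0.05)
        assert feats.barriers[0].height == pytest.approx(2.0, abs=1e-9)

    def test_monotone_profile_has_no_features(self):
        grid = np.linspace(0, 10, 50)
        feats = hs.find_minima_barriers(hs.PMFProfile(grid=grid, values=grid * 2.0))
        assert feats.minima == [] and feats.barriers == []

    def test_single_parabola_has_one_minimum_at_vertex(self):
        grid = np.linspace(0, 10, 101)
        profile = hs.PMFProfile(grid=grid, values=(grid - 4.0) ** 2)
        feats = hs.find_minima_barriers(profile, prominence_min=0.5)
        assert len(feats.minima) == 1
        assert feats.minima[0].position == pytest.approx(4.0, abs=0.05)

    def test_barrier_heights_non_negative_on_double_well(self, double_well_truth):
        grid = np.linspace(2.5, 12.5, 401)
        profile = hs.PMFProfile(grid=grid, values=double_well_truth(grid))
        feats = hs.find_minima_barriers(profile, prominence_min=0.2)
        assert len(feats.minima) == 2
        assert all(b.height >= 0 for b in feats.barriers)
        for b, left, right in zip(
            feats.barriers, feats.minima[:-1], feats.minima[1:]
        ):
            assert left.position < b.position < right.position

    def test_short_profile_rejected(self):
        with pytest.raises(DomainError):
            hs.find_minima_barriers(
                hs.PMFProfile(grid=np.arange(3.0), values=np.zeros(3))
            )


class TestCorrelation:
    def test_exact_line_has_unit_correlation_magnitude(self):
        n = np.arange(1, 9, dtype=float)
        pairs = np.column_stack([3.0 - 2.0 * n, n])
        res = hs.correlate_energy_transitions(pairs)
        assert abs(res.r_value) == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-2.0, abs=1e-12)

    def test_transition_accounting_recovers_bond_energy(self, ambient):
        # each expelled molecule is worth one tetrahedral bond energy
        counts = np.array([2, 5, 9, 14, 20], dtype=float)
        dg = np.array([hs.hydrophobic_interaction_energy(int(c), ambient) for c in counts])
        res = hs.correlate_energy_transitions(np.column_stack([dg, counts]))
        assert res.slope == pytest.approx(ambient.dg_ddaa, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_counts_rejected(self):
        pairs = [(-1.0, 4), (-2.0, 4), (-3.0, 4)]
        with pytest.raises(DegenerateDataError):
            hs.correlate_energy_transitions(pairs)


class TestSurfaceRanking:
    def _well(self, depth, width=1.0, pos=3.0):
        grid = np.linspace(1.0, 10.0, 181)
        values = depth * np.exp(-((grid - pos) ** 2) / (2 * width**2))
        return hs.PMFProfile(grid=grid, values=values, provenance="water_induced")

    def test_planted_depth_ordering(self):
        profiles = {
            "flat": self._well(-6.0),
            "convex": self._well(-3.0),
            "concave": self._well(-10.0),
        }
        ranking = hs.rank_surface_interactions(profiles)
        assert [lbl for lbl, _ in ranking.by_contact_depth] == ["concave", "flat", "convex"]

    def test_identical_profiles_reported_as_tie(self):
        profiles = {"a": self._well(-5.0), "b": self._well(-5.0)}
        ranking = hs.rank_surface_interactions(profiles)
        assert ranking.depth_ties == [("a", "b")]

    def test_two_profiles_ordered(self):
        ranking = hs.rank_surface_interactions(
            {"x": self._well(-2.0), "y": self._well(-4.0)}
        )
        assert [lbl for lbl, _ in ranking.by_contact_depth] == ["y", "x"]

    def test_profile_without_minimum_excluded_with_warning(self):
        grid = np.linspace(1.0, 10.0, 50)
        flat = hs.PMFProfile(grid=grid, values=grid * 0.0)
        with pytest.warns(UserWarning, match="no detected minimum"):
            ranking = hs.rank_surface_interactions({"flat": flat, "well": self._well(-4.0)})
        assert ranking.excluded == ["flat"]
        assert [lbl for lbl, _ in ranking.by_contact_depth] == ["well"]

    def test_barrier_ordering_descending(self, double_well_truth):
        grid = np.linspace(2.5, 12.5, 401)
        base = double_well_truth(grid)
        profiles = {
            "strong": hs.PMFProfile(grid=grid, values=2.0 * base),
            "weak": hs.PMFProfile(grid=grid, values=0.5 * base),
        }
        ranking = hs.rank_surface_interactions(profiles, prominence_min=0.2)
        assert [lbl for lbl, _ in ranking.by_first_barrier] == ["strong", "weak"]
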