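import numpy as np
import pytest
from scipy import integrate

from afcv import (
    Conformation, FreeEnergySurface, Hill, MeltingCurve, Trajectory,
    cumulative_clusters, daura_cluster, fes_from_hills, fes_time_average,
    folded_fraction,
    kabsch_rmsd, melting_curve_from_surfaces, melting_temperature,
    two_state_fraction, two_state_potential, two_state_surface,
    write_fes, write_melting_curve,
)
from afcv.constants import KB

from helpers import brute_daura, random_conformation, rigid_motion


def random_hills(rng, n, gamma=8.0):
    return [
        Hill(float(t), (float(rng.uniform(-1.5, 1.5)),),
             (float(rng.uniform(0.05, 0.3)),), float(rng.uniform(0.05, 0.5)), gamma)
        for t in np.sort(rng.uniform(0, 100, size=n))
    ]


class TestFESFromHills:
    def test_single_hill_closed_form(self):
        # gamma/(gamma-1) = 8/7: center pinned at 0, far plateau at 4/7
        fes = fes_from_hills([Hill(0.0, (0.0,), (0.1,), 0.5, 8.0)], (-0.4, 0.4, 81))
        x = fes.axes[0]
        center = np.argmin(np.abs(x))
        assert fes.values[center] == pytest.approx(0.0, abs=1e-12)
        assert fes.values[0] == pytest.approx(
            (8 / 7) * 0.5 * (1 - np.exp(-0.5 * (x[0] / 0.1) ** 2)), rel=1e-9
        )

    def test_no_hills_is_flat_zero(self):
        fes = fes_from_hills([], (-1, 1, 11))
        assert np.array_equal(fes.values, np.zeros(11))
        assert fes.visited.all()

    def test_matches_direct_double_loop(self, rng):
        hills = random_hills(rng, 100)
        fes = fes_from_hills(hills, (-2, 2, 97), normalize=False)
        x = fes.axes[0]
        direct = np.zeros_like(x)
        for h in hills:
            for i, s in enumerate(x):
                direct[i] += h.height * np.exp(-((s - h.centers[0]) ** 2)
                                               / (2 * h.widths[0] ** 2))
        assert np.abs(fes.values - (-(8 / 7) * direct)).max() < 1e-10

    def test_mixed_bias_factors_rejected(self, rng):
        hills = random_hills(rng, 3) + random_hills(rng, 2, gamma=10.0)
        with pytest.raises(ValueError, match="mixed"):
            fes_from_hills(hills, (-2, 2, 11))

    def test_plain_hills_use_unscaled_estimator(self):
        fes = fes_from_hills([Hill(0.0, (0.0,), (0.1,), 0.5, None)], (-0.3, 0.3, 61),
                             normalize=False)
        assert fes.values.min() == pytest.approx(-0.5, rel=1e-12)

    def test_linear_in_hills_before_shift(self, rng):
        a, b = random_hills(rng, 10), random_hills(rng, 7)
        grid = (-2, 2, 33)
        fa = fes_from_hills(a, grid, normalize=False).values
        fb = fes_from_hills(b, grid, normalize=False).values
        fab = fes_from_hills(a + b, grid, normalize=False).values
        assert np.allclose(fab, fa + fb, atol=1e-12)

    def test_time_average_equals_mean_of_prefix_estimates(self, rng):
        hills = random_hills(rng, 40)
        grid = (-2, 2, 65)
        got = fes_time_average(hills, grid, fraction=0.5, n_checkpoints=5)
        counts = np.unique(np.linspace(20, 40, 5).astype(int))
        stack = np.mean(
            [fes_from_hills(hills[:k], grid, normalize=False).values for k in counts],
            axis=0,
        )
        vis = fes_from_hills(hills, grid).visited
        expected = np.where(vis, stack - stack[vis].min(), np.nan)
        assert np.allclose(got.values[vis], expected[vis], atol=1e-12)
        assert np.array_equal(got.visited, vis)

    def test_time_average_with_full_fraction_of_one_hill_is_instantaneous(self):
        hills = [Hill(0.0, (0.0,), (0.1,), 0.5, 8.0)]
        a = fes_time_average(hills, (-0.4, 0.4, 41), fraction=1.0)
        b = fes_from_hills(hills, (-0.4, 0.4, 41))
        assert np.allclose(a.values[a.visited], b.values[b.visited], atol=1e-12)

    def test_unvisited_nodes_flagged_beyond_5_sigma(self):
        fes = fes_from_hills([Hill(0.0, (0.0,), (0.1,), 0.5, 8.0)], (-2, 2, 401))
        x = fes.axes[0]
        assert fes.visited[np.abs(x) <= 0.5].all()
        assert not fes.visited[np.abs(x) > 0.5 + 0.02].any()
        assert np.isnan(fes.values[~fes.visited]).all()


class TestFoldedFraction:
    def flat(self, npts=101, lo=0.0, hi=1.0):
        x = np.linspace(lo, hi, npts)
        return FreeEnergySurface((x,), np.zeros(npts), np.ones(npts, bool))

    def test_flat_surface_gives_geometric_fraction(self):
        fes = self.flat(1001)
        frac = folded_fraction(fes, 300.0, threshold=0.7, folded_side="above")
        assert frac == pytest.approx(0.3, abs=2e-3)

    def test_boltzmann_suppression(self):
        x = np.linspace(0, 1, 101)
        vals = np.where(x > 0.5, 0.0, 50.0)
        fes = FreeEnergySurface((x,), vals, np.ones_like(x, bool))
        assert folded_fraction(fes, 300.0, 0.5, "above") == pytest.approx(1.0, abs=1e-8)

    def test_sides_sum_to_one(self, rng):
        x = np.linspace(-1, 1, 257)
        vals = rng.uniform(0, 20, size=x.size)
        fes = FreeEnergySurface((x,), vals, np.ones_like(x, bool))
        above = folded_fraction(fes, 310.0, 0.2, "above")
        below = folded_fraction(fes, 310.0, 0.2, "below")
        assert abs(above + below - 1.0) < 1e-12

    def test_two_gaussian_wells_match_quadrature(self):
        kT = KB * 300.0
        dG = 5.0

        def profile(s):
            return -kT * np.log(np.exp(-((s - 1.0) ** 2) / 0.02)
                                + np.exp(-dG / kT) * np.exp(-((s + 1.0) ** 2) / 0.02))

        x = np.linspace(-2, 2, 8193)
        f = profile(x)
        fes = FreeEnergySurface((x,), f - f.min(), np.ones_like(x, bool))
        got = folded_fraction(fes, 300.0, 0.0, "above")
        num, _ = integrate.quad(lambda s: np.exp(-profile(s) / kT), 0, 2, limit=200)
        den, _ = integrate.quad(lambda s: np.exp(-profile(s) / kT), -2, 2, limit=200)
        assert got == pytest.approx(num / den, abs=1e-6)

    def test_empty_side_rejected(self):
        x = np.linspace(0, 1, 51)
        visited = x < 0.5
        fes = FreeEnergySurface((x,), np.where(visited, 0.0, np.nan), visited)
        with pytest.raises(ValueError, match="no visited"):
            folded_fraction(fes, 300.0, 0.6, "above")


class TestMeltingTemperature:
    def test_exact_hit(self):
        curve = MeltingCurve(np.array([300.0, 310.0]), np.array([0.9, 0.5]))
        est = melting_temperature(curve)
        assert est.temperature == 310.0 and est.crossed

    def test_linear_interpolation(self):
        curve = MeltingCurve(np.array([300.0, 320.0]), np.array([0.75, 0.25]))
        assert melting_temperature(curve).temperature == pytest.approx(310.0)

    def test_already_melted_flags_lowest(self):
        curve = MeltingCurve(np.array([300.0, 320.0]), np.array([0.4, 0.2]))
        with pytest.warns(UserWarning, match="below 0.5"):
            est = melting_temperature(curve)
        assert est.temperature == 300.0 and not est.crossed

    def test_never_melts_flags_highest(self):
        curve = MeltingCurve(np.array([300.0, 320.0]), np.array([0.9, 0.8]))
        with pytest.warns(UserWarning, match="never"):
            est = melting_temperature(curve)
        assert est.temperature == 320.0 and not est.crossed

    def test_multiple_crossings_use_first_with_warning(self):
        curve = MeltingCurve(np.array([300.0, 310.0, 320.0, 330.0]),
                             np.array([0.8, 0.4, 0.6, 0.3]))
        with pytest.warns(UserWarning, match="multiple"):
            est = melting_temperature(curve)
        assert 300.0 < est.temperature < 310.0

    def test_two_state_model_recovers_dh_over_ds(self):
        dH, dS = 200.0, 0.6      # kJ/mol, kJ/mol/K -> Tm = 333.33 K
        temps = np.arange(300.0, 361.0, 5.0)
        curve = MeltingCurve(temps, two_state_fraction(temps, dH, dS))
        assert melting_temperature(curve).temperature == pytest.approx(dH / dS, abs=1.0)

    def test_pipeline_from_synthetic_surfaces(self):
        dH, dS = 200.0, 0.6
        temps = np.arange(300.0, 361.0, 5.0)
        surfaces = [two_state_surface(t, dH, dS) for t in temps]
        curve = melting_curve_from_surfaces(surfaces, threshold=4.75)
        assert melting_temperature(curve).temperature == pytest.approx(dH / dS, abs=1.0)


class TestDauraClustering:
    def test_identical_frames_form_one_cluster(self, rng):
        conf = random_conformation(5, rng)
        frames = [Conformation(rigid_motion(conf.coords, rng)) for _ in range(6)]
        labels, centers = daura_cluster(frames, cutoff=0.1)
        assert set(labels) == {0}
        assert centers == [0]

    def test_two_separated_groups(self, rng):
        a = random_conformation(6, rng, scale=0.3)
        b = Conformation(a.coords + rng.standard_normal((6, 3)) * 2.0)
        frames = [a, a, b, b, a]
        labels, _ = daura_cluster(frames, cutoff=0.1)
        assert labels[0] == labels[1] == labels[4]
        assert labels[2] == labels[3] != labels[0]
        assert len(set(labels)) == 2

    def test_matches_exhaustive_oracle(self, rng):
        frames = [random_conformation(5, rng, scale=0.25) for _ in range(8)]
        n = len(frames)
        rmsd = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(frames[i], frames[j])
        for cutoff in (0.05, 0.15, 0.3, 0.6):
            labels, centers = daura_cluster(frames, cutoff)
            olabels, ocenters = brute_daura(rmsd, cutoff)
            assert np.array_equal(labels, olabels)
            assert centers == ocenters

    def test_trajectory_input_accepted(self, rng):
        frames = [random_conformation(4, rng) for _ in range(3)]
        traj = Trajectory(frames, np.arange(3.0))
        labels, _ = daura_cluster(traj, cutoff=10.0)
        assert len(labels) == 3


class TestCumulativeClusters:
    def test_hand_example(self):
        assert list(cumulative_clusters([0, 0, 1, 0, 2])) == [1, 1, 2, 2, 3]

    def test_single_cluster_all_ones(self):
        assert list(cumulative_clusters([3, 3, 3])) == [1, 1, 1]

    def test_random_sequence_matches_set_scan_and_is_nondecreasing(self, rng):
        seq = rng.integers(0, 7, size=200)
        got = cumulative_clusters(seq)
        seen = set()
        expected = []
        for a in seq:
            seen.add(int(a))
            expected.append(len(seen))
        assert list(got) == expected
        assert (np.diff(got) >= 0).all()
        assert got[-1] == len(set(seq.tolist()))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_clusters([])


def test_text_writers_produce_parseable_files(tmp_path, rng):
    fes = fes_from_hills(random_hills(rng, 5), (-1, 1, 21), temperature=300.0)
    path = write_fes(fes, tmp_path / "fes.dat")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("#") and len(lines) == 22
    curve = MeltingCurve(np.array([300.0, 320.0]), np.array([0.8, 0.3]))
    csv = write_melting_curve(curve, tmp_path / "melt.csv")
    assert csv.read_text().splitlines()[0] == "temperature_K,folded_fraction"
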