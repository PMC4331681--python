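"""FFT correlation vs the direct-sum oracle, ranking, and the dock pipeline."""

import time

import numpy as np
import pytest

from fftdock.config import RunConfig
from fftdock.fft_search import (
    DecoyScore,
    best_per_rotation,
    correlate,
    direct_score,
    dock,
    forward_fft,
    inverse_fft,
    pose_structure,
    top_k_decoys,
)
from fftdock.rotations import apply_rotation
from fftdock.voxelizer import ScoreGrid, determine_grid, voxelize_ligand, voxelize_receptor
from helpers import (
    in_bounds_translations,
    loop_score,
    make_gridspec,
    random_score_grid,
    wrapped_index,
)


class TestForwardInverseFFT:
    def test_delta_gives_flat_spectrum(self):
        g = np.zeros((4, 4, 4), dtype=np.complex64)
        g[0, 0, 0] = 1.0
        np.testing.assert_allclose(forward_fft(g), np.ones((4, 4, 4)), atol=1e-12)

    def test_zero_grid_zero_spectrum(self):
        assert np.all(forward_fft(np.zeros((4, 4, 4), dtype=np.complex64)) == 0)

    def test_roundtrip_identity(self, rng):
        g = rng.normal(size=(4, 4, 4)) + 1j * rng.normal(size=(4, 4, 4))
        back = inverse_fft(forward_fft(g))
        np.testing.assert_allclose(back, g, rtol=1e-9, atol=1e-12)

    def test_parseval(self, rng):
        g = rng.normal(size=(4, 4, 4)) + 1j * rng.normal(size=(4, 4, 4))
        spec = forward_fft(g)
        lhs = np.sum(np.abs(g) ** 2)
        rhs = np.sum(np.abs(spec) ** 2) / 4**3
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            forward_fft(np.zeros((4, 4, 2), dtype=np.complex64))


class TestCorrelate:
    def test_matching_deltas_autocorrelate_to_origin(self):
        g = make_gridspec(edge=2)
        v = np.zeros((4, 4, 4), dtype=np.complex64)
        v[1, 1, 1] = 1.0
        R = ScoreGrid(spec=g, values=v, role="receptor")
        L = ScoreGrid(spec=g, values=v.copy(), role="ligand")
        field = correlate(R, L)
        assert field[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        mask = np.ones_like(field, dtype=bool)
        mask[0, 0, 0] = False
        np.testing.assert_allclose(field[mask], 0.0, atol=1e-9)

    def test_receptor_delta_samples_ligand(self, rng):
        # R a delta at p: field(t) = L(p + t)
        g = make_gridspec(edge=2)
        p = (1, 0, 1)
        rv = np.zeros((4, 4, 4), dtype=np.complex64)
        rv[p] = 1.0
        R = ScoreGrid(spec=g, values=rv, role="receptor")
        L = random_score_grid(g, rng, role="ligand", complex_vals=False)
        field = correlate(R, L)
        for t in in_bounds_translations(2):
            u = tuple(p[i] + t[i] for i in range(3))
            expected = L.values[u].real if all(0 <= c < 4 for c in u) else 0.0
            assert field[wrapped_index(t, 4)] == pytest.approx(expected, abs=1e-6)

    def test_matches_direct_score_on_random_complex_grids(self, rng):
        g = make_gridspec(edge=2)
        for _ in range(10):
            R = random_score_grid(g, rng, "receptor")
            L = random_score_grid(g, rng, "ligand")
            field = correlate(R, L)
            for t in in_bounds_translations(2):
                ds = direct_score(R, L, t)
                fv = field[wrapped_index(t, 4)]
                assert fv == pytest.approx(ds, rel=1e-6, abs=1e-6)

    def test_spec_mismatch_rejected(self, rng):
        a = random_score_grid(make_gridspec(edge=2), rng)
        b = random_score_grid(make_gridspec(edge=3), rng)
        with pytest.raises(ValueError):
            correlate(a, b)

    def test_linearity_in_both_slots(self, rng):
        g = make_gridspec(edge=2)
        R1, R2 = (random_score_grid(g, rng) for _ in range(2))
        L1, L2 = (random_score_grid(g, rng, "ligand") for _ in range(2))
        a, b = 1.7, -0.4

        def combo(x, y, ca, cb, role):
            return ScoreGrid(spec=g, values=(ca * x.values + cb * y.values), role=role)

        np.testing.assert_allclose(
            correlate(R1, combo(L1, L2, a, b, "ligand")),
            a * correlate(R1, L1) + b * correlate(R1, L2),
            atol=1e-5,
        )
        np.testing.assert_allclose(
            correlate(combo(R1, R2, a, b, "receptor"), L1),
            a * correlate(R1, L1) + b * correlate(R2, L1),
            atol=1e-5,
        )


class TestDirectScore:
    def test_two_term_hand_arithmetic(self):
        g = make_gridspec(edge=1)
        rv = np.zeros((2, 2, 2), dtype=np.complex64)
        lv = np.zeros((2, 2, 2), dtype=np.complex64)
        rv[0, 0, 0] = 1.0
        lv[0, 0, 0] = 3.0
        R = ScoreGrid(spec=g, values=rv, role="receptor")
        L = ScoreGrid(spec=g, values=lv, role="ligand")
        assert direct_score(R, L, (0, 0, 0)) == pytest.approx(3.0)

    def test_axis_line_dot_product(self):
        # R = [1, 2] along x, L = [3, 4], t = 0 -> 1*3 + 2*4 = 11
        g = make_gridspec(edge=2)
        rv = np.zeros((4, 4, 4), dtype=np.complex64)
        lv = np.zeros((4, 4, 4), dtype=np.complex64)
        rv[0, 0, 0], rv[1, 0, 0] = 1.0, 2.0
        lv[0, 0, 0], lv[1, 0, 0] = 3.0, 4.0
        R = ScoreGrid(spec=g, values=rv, role="receptor")
        L = ScoreGrid(spec=g, values=lv, role="ligand")
        assert direct_score(R, L, (0, 0, 0)) == pytest.approx(11.0)

    def test_disjoint_supports_score_zero(self):
        g = make_gridspec(edge=2)
        rv = np.zeros((4, 4, 4), dtype=np.complex64)
        lv = np.zeros((4, 4, 4), dtype=np.complex64)
        rv[0, 0, 0] = 5.0
        lv[1, 1, 1] = 7.0
        R = ScoreGrid(spec=g, values=rv, role="receptor")
        L = ScoreGrid(spec=g, values=lv, role="ligand")
        assert direct_score(R, L, (0, 0, 0)) == 0.0

    def test_self_overlap_nonnegative(self, rng):
        g = make_gridspec(edge=2)
        R = random_score_grid(g, rng, complex_vals=False)
        L = ScoreGrid(spec=g, values=R.values.copy(), role="ligand")
        assert direct_score(R, L, (0, 0, 0)) >= 0.0

    def test_matches_pure_python_loop(self, rng):
        g = make_gridspec(edge=2)
        R = random_score_grid(g, rng)
        L = random_score_grid(g, rng, "ligand")
        for t in [(0, 0, 0), (1, -1, 0), (-1, 1, 1)]:
            assert direct_score(R, L, t) == pytest.approx(
                loop_score(R.values, L.values, t), rel=1e-6
            )

    def test_out_of_bounds_translation_rejected(self, rng):
        g = make_gridspec(edge=2)
        R = random_score_grid(g, rng)
        L = random_score_grid(g, rng, "ligand")
        with pytest.raises(ValueError):
            direct_score(R, L, (2, 0, 0))


class TestBestPerRotation:
    def test_unique_max_located(self):
        field = np.zeros((8, 8, 8))
        field[1, 0, 6] = 7.5  # t = (1, 0, -2)
        d = best_per_rotation(field, rotation_index=3)
        assert d == DecoyScore(rotation_index=3, translation=(1, 0, -2), score=7.5)

    def test_constant_field_tie_break(self):
        field = np.ones((8, 8, 8))
        d = best_per_rotation(field)
        assert d.translation == (-3, -3, -3)  # smallest signed (tz, ty, tx)

    def test_wrap_boundary_excluded(self):
        # the maximum sits at index edge (translation ±edge): never reported
        field = np.zeros((4, 4, 4))
        field[2, 0, 0] = 99.0
        field[1, 1, 1] = 1.0
        d = best_per_rotation(field)
        assert d.translation == (1, 1, 1)
        assert d.score == 1.0

    def test_matches_exhaustive_scan(self, rng):
        field = rng.normal(size=(8, 8, 8))
        d = best_per_rotation(field)
        best = None
        for t in in_bounds_translations(4):
            s = field[wrapped_index(t, 8)]
            key = (-s, t[2], t[1], t[0])
            if best is None or key < best[0]:
                best = (key, t, s)
        assert d.translation == best[1]
        assert d.score == pytest.approx(best[2])


class TestDock:
    def test_single_rotation_collapses_to_one_correlation(self, pocket_pair):
        receptor, ligand = pocket_pair
        cfg = RunConfig(pitch=1.0, margin=0, rotation_step=360.0, n_theta_cap=None,
                        w_elec=0.0, w_desolv=0.0, top_k=5)
        res = dock(receptor, ligand, cfg)
        assert len(res.per_rotation_best) == 1

        grid = determine_grid(receptor, ligand, 1.0, 0)
        R = voxelize_receptor(receptor, grid, cfg.score_params)
        L = voxelize_ligand(apply_rotation(ligand, np.eye(3)), grid, cfg.score_params)
        expected = best_per_rotation(correlate(R, L))
        assert res.per_rotation_best[0] == expected

    def test_per_rotation_count_and_pose_count(self, pocket_result):
        res = pocket_result
        assert len(res.per_rotation_best) == res.rotations.n_theta == 24
        assert res.pose_count == 24 * res.grid.fft_size**3

    def test_top_k_is_sorted_submultiset(self, pocket_result):
        res = pocket_result
        scores = [d.score for d in res.top_k]
        assert scores == sorted(scores, reverse=True)
        pool = list(res.per_rotation_best)
        for d in res.top_k:
            assert d in pool
            pool.remove(d)

    def test_deterministic_reruns(self, pocket_pair, shape_only_config):
        receptor, ligand = pocket_pair
        a = dock(receptor, ligand, shape_only_config)
        b = dock(receptor, ligand, shape_only_config)
        assert a.per_rotation_best == b.per_rotation_best
        assert a.top_k == b.top_k
        assert a.config_echo == b.config_echo

    def test_score_field_invariant_under_common_translation(self, pocket_pair,
                                                            shape_only_config):
        receptor, ligand = pocket_pair
        shift = np.array([13.0, -7.0, 5.0])
        rec2 = receptor.with_positions(receptor.positions + shift)
        lig2 = ligand.with_positions(ligand.positions + shift)
        a = dock(receptor, ligand, shape_only_config)
        b = dock(rec2, lig2, shape_only_config)
        assert a.per_rotation_best == b.per_rotation_best

    def test_pocket_recovery_against_brute_force(self, pocket_pair, shape_only_config,
                                                 pocket_result):
        """dock's top-1 equals exhaustive direct-sum enumeration over all
        rotations and all in-bounds translations."""
        receptor, ligand = pocket_pair
        cfg = shape_only_config
        params = cfg.score_params
        grid = determine_grid(receptor, ligand, cfg.pitch, cfg.margin)
        R = voxelize_receptor(receptor, grid, params)
        rots = cfg.rotation_set()
        center = ligand.centroid
        best = None
        for ri, m in enumerate(rots.matrices):
            L = voxelize_ligand(apply_rotation(ligand, m, center=center), grid, params)
            for t in in_bounds_translations(grid.edge):
                s = direct_score(R, L, t)
                key = (-s, ri, t[2], t[1], t[0])
                if best is None or key < best[0]:
                    best = (key, ri, t, s)
        top = pocket_result.top_k[0]
        assert top.rotation_index == best[1]
        assert top.translation == best[2]
        assert top.score == pytest.approx(best[3], rel=1e-6)
        # frozen expected pose: plug seated in the L-shaped notch
        assert (top.rotation_index, top.translation) == (0, (1, 1, -2))
        assert top.score == pytest.approx(18.0, rel=1e-6)

    def test_pose_structure_places_plug_in_notch(self, pocket_pair, pocket_result):
        receptor, ligand = pocket_pair
        top = pocket_result.top_k[0]
        posed = pose_structure(ligand, pocket_result.rotations, pocket_result.grid, top)
        # the seated plug sits within the receptor bounding box inflated by 2 A
        lo = receptor.positions.min(axis=0) - 2.0
        hi = receptor.positions.max(axis=0) + 2.0
        assert np.all(posed.positions >= lo) and np.all(posed.positions <= hi)

    def test_profile_timings_collected(self, pocket_result):
        assert pocket_result.timings is not None
        assert all(v >= 0.0 for v in pocket_result.timings.values())


def test_top_k_tie_break_deterministic():
    decoys = [
        DecoyScore(1, (0, 0, 1), 5.0),
        DecoyScore(0, (0, 0, 1), 5.0),
        DecoyScore(0, (1, 0, 0), 5.0),
        DecoyScore(2, (0, 0, 0), 7.0),
    ]
    ranked = top_k_decoys(decoys, 4)
    assert ranked[0].score == 7.0
    assert ranked[1] == DecoyScore(0, (1, 0, 0), 5.0)  # tz smallest wins
    assert ranked[2] == DecoyScore(0, (0, 0, 1), 5.0)
    assert ranked[3] == DecoyScore(1, (0, 0, 1), 5.0)


def test_fft_scaling_beats_direct_scan():
    """Cost of the all-translation direct sum grows much faster with N than
    the FFT correlation (ratio ordering only, no absolute timings)."""
    rng = np.random.default_rng(0)

    def timed(fn, repeat=3):
        best = float("inf")
        for _ in range(repeat):
            t0 = time.perf_counter()
            fn()
            best = min(best, time.perf_counter() - t0)
        return best

    costs = {}
    for edge in (2, 8):
        g = make_gridspec(edge=edge)
        R = random_score_grid(g, rng)
        L = random_score_grid(g, rng, "ligand")
        ts = in_bounds_translations(edge)
        costs[edge] = (
            timed(lambda: correlate(R, L)),
            timed(lambda: [direct_score(R, L, t) for t in ts], repeat=1),
        )
    fft_ratio = costs[8][0] / max(costs[2][0], 1e-9)
    direct_ratio = costs[8][1] / max(costs[2][1], 1e-9)
    assert direct_ratio > fft_ratio
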