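from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from atacploidy import (
    CnvEvent,
    FragmentSet,
    SimConfig,
    WindowMatrix,
    best_block_delta_bic,
    call_gain_loss,
    detect_cnv_segments,
    make_windows,
    normalize_u,
    simulate_fragments,
    window_u_matrix,
)
from atacploidy.cnv import _bern_ll, _chrom_series

MB = 1_000_000


class TestWindows:
    def test_sixty_mb_chromosome_gives_three_windows(self):
        w = make_windows({"chr1": 60 * MB})
        assert len(w) == 3
        assert w["end"].iloc[-1] == 60 * MB

    def test_short_terminal_remainder_merges_backwards(self):
        w = make_windows({"chr1": 45 * MB})
        assert len(w) == 2
        assert (w["start"].iloc[-1], w["end"].iloc[-1]) == (20 * MB, 45 * MB)

    def test_nonpositive_window_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 60 * MB}, window_size=0)


class TestWindowUMatrix:
    def test_windows_without_points_are_missing(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(100) * 1_000,
                "barcode": "A",
            }
        )
        df["end"] = df["start"] + 500
        fs = FragmentSet(df)
        wm = window_u_matrix(fs, min_points=50, chrom_lengths={"chr1": 60 * MB})
        assert np.isnan(wm.U.loc["A", 1]) and np.isnan(wm.U.loc["A", 2])
        assert np.isfinite(wm.U.loc["A", 0])

    def test_uniform_capture_gives_flat_u_profile(self):
        cfg = SimConfig(
            ploidies=[4],
            s=0.05,
            n_sites=30_000,
            seed=21,
            genome=[("chr1", 60 * MB)],
            fragment_length=200,
        )
        fs = simulate_fragments(cfg)
        wm = window_u_matrix(fs, chrom_lengths={"chr1": 60 * MB})
        row = wm.U.loc[wm.U.index[0]].to_numpy(dtype=float)
        assert np.isfinite(row).all()
        assert row.std() / row.mean() < 0.1


class TestNormalizeU:
    @staticmethod
    def flat_wm(U, windows=None):
        n_cells, n_w = U.shape
        windows = windows if windows is not None else make_windows({"chr1": n_w * 20 * MB})
        idx = [f"c{i}" for i in range(n_cells)]
        return WindowMatrix(
            windows=windows,
            U=pd.DataFrame(U, index=idx),
            n_points=pd.DataFrame(np.full(U.shape, 100.0), index=idx),
        )

    def test_constant_covariate_divides_by_constant(self):
        U = np.full((5, 4), 0.08)
        wm = self.flat_wm(U)
        with pytest.warns(UserWarning, match="intercept-only"):
            normalize_u(wm, None, diploid_cells=["c0", "c1"])
        assert np.allclose(wm.U_prime.to_numpy(), 1.0)

    def test_exact_linearity_gives_constant_u_prime(self):
        acc = np.array([1.0, 2.0, 3.0, 4.0])
        U = np.tile(0.02 * acc, (6, 1))
        wm = self.flat_wm(U)
        normalize_u(wm, acc, diploid_cells=[f"c{i}" for i in range(6)])
        assert np.allclose(wm.U_prime.to_numpy(), 1.0, atol=1e-8)

    def test_huber_fit_resists_outliers(self, rng):
        acc = np.linspace(1, 3, 10)
        clean = np.tile(0.03 * acc + 0.01, (40, 1))
        noisy = clean + rng.normal(0, 0.001, clean.shape)
        corrupt = noisy.copy()
        mask = rng.random(corrupt.shape) < 0.05
        corrupt[mask] *= 10
        wm_clean = self.flat_wm(noisy, make_windows({"chr1": 200 * MB}))
        wm_corrupt = self.flat_wm(corrupt, make_windows({"chr1": 200 * MB}))
        cells = [f"c{i}" for i in range(40)]
        normalize_u(wm_clean, acc, cells)
        normalize_u(wm_corrupt, acc, cells)
        fitted_clean = wm_clean.U.to_numpy()[0] / wm_clean.U_prime.to_numpy()[0]
        fitted_corrupt = wm_corrupt.U.to_numpy()[0] / wm_corrupt.U_prime.to_numpy()[0]
        assert np.all(np.abs(fitted_corrupt / fitted_clean - 1) < 0.05)

    def test_requires_diploid_cells(self):
        wm = self.flat_wm(np.full((3, 4), 0.1))
        with pytest.raises(ValueError, match="diploid"):
            normalize_u(wm, None, diploid_cells=[])


class TestCallGainLoss:
    @staticmethod
    def wm_with_uprime(Up):
        wm = TestNormalizeU.flat_wm(np.asarray(Up, dtype=float))
        wm.U_prime = wm.U.copy()
        return wm

    def test_flat_cell_is_all_neutral(self):
        wm = self.wm_with_uprime(np.full((3, 4), 2.5))
        call_gain_loss(wm)
        assert np.allclose(wm.p_tilde.to_numpy(), 2.0)
        assert (wm.state.to_numpy() == 0).all()

    def test_gain_and_loss_thresholds(self):
        # U'_cell = 1 (median); window with U' = 2 -> p_tilde = 3 (gain);
        # window with U' = 0 -> p_tilde = 1 (loss)
        Up = np.array([[1.0, 1.0, 1.0, 2.0, 0.0]])
        wm = self.wm_with_uprime(Up)
        call_gain_loss(wm)
        assert wm.p_tilde.to_numpy()[0, 3] == pytest.approx(3.0)
        assert wm.p_tilde.to_numpy()[0, 4] == pytest.approx(1.0)
        assert wm.state.to_numpy()[0, 3] == 1 and wm.state.to_numpy()[0, 4] == -1

    def test_p_tilde_nearly_scale_free_at_large_u(self):
        base = np.array([[30.0, 30.0, 30.0, 60.0]])
        wm1 = self.wm_with_uprime(base)
        wm2 = self.wm_with_uprime(3.0 * base)
        call_gain_loss(wm1)
        call_gain_loss(wm2)
        diff = np.abs(wm1.p_tilde.to_numpy() - wm2.p_tilde.to_numpy())
        assert diff.max() < 0.05


def brute_force_best_dbic(B: np.ndarray, windows: pd.DataFrame) -> float:
    """Exhaustive enumeration over all series x all nonempty cell subsets."""
    finite = np.isfinite(B)
    N = int(finite.sum())
    T = float(np.nansum(B))
    ll1 = _bern_ll(T, N)
    best = np.inf
    for _, idx in _chrom_series(windows):
        for r in range(1, B.shape[0] + 1):
            for sub in combinations(range(B.shape[0]), r):
                blk = B[np.array(sub)][:, idx]
                n_in, n1 = blk.size, blk.sum()
                ll2 = _bern_ll(n1, n_in) + _bern_ll(T - n1, N - n_in)
                best = min(best, -2 * (ll2 - ll1) + np.log(N))
    return best


class TestSegmentScan:
    windows20 = make_windows({"chr1": 20 * 20 * MB})

    @staticmethod
    def state_matrix(B):
        idx = [f"c{i}" for i in range(B.shape[0])]
        return WindowMatrix.from_state(pd.DataFrame(B, index=idx),
                                       TestSegmentScan.windows20)

    def test_prefix_scan_matches_exhaustive_enumeration(self, rng):
        w = make_windows({"chr1": 6 * 20 * MB})
        for trial in range(8):
            B = (rng.random((8, 6)) < rng.uniform(0.05, 0.5)).astype(float)
            got = best_block_delta_bic(B, w)
            want = brute_force_best_dbic(B, w)
            assert got == pytest.approx(want, abs=1e-9)

    def test_implanted_block_recovered_with_members(self, rng):
        B = (rng.random((100, 20)) < 0.02).astype(float)
        B[:40, 5:9] = (rng.random((40, 4)) < 0.9).astype(float)
        segs = detect_cnv_segments(self.state_matrix(B))
        gains = [s for s in segs if s.kind == "gain"]
        assert len(gains) == 1
        seg = gains[0]
        assert (seg.window_lo, seg.window_hi) == (5, 8)
        implanted = sum(1 for c in seg.member_cells if int(c[1:]) < 40)
        assert implanted >= 38
        assert seg.delta_bic < 0
        assert seg.start == 5 * 20 * MB and seg.end == 9 * 20 * MB

    def test_null_matrix_yields_no_segments(self, rng):
        B = (rng.random((100, 20)) < 0.02).astype(float)
        assert detect_cnv_segments(self.state_matrix(B)) == []

    def test_single_window_aberration_never_reported(self):
        B = np.zeros((50, 20))
        B[:30, 7] = 1.0  # strong but single-window
        assert detect_cnv_segments(self.state_matrix(B)) == []

    def test_same_kind_segments_are_window_disjoint(self, rng):
        B = (rng.random((80, 20)) < 0.02).astype(float)
        B[:30, 2:5] = (rng.random((30, 3)) < 0.9).astype(float)
        B[40:70, 10:14] = (rng.random((30, 4)) < 0.9).astype(float)
        segs = [s for s in detect_cnv_segments(self.state_matrix(B)) if s.kind == "gain"]
        assert len(segs) == 2
        ranges = sorted((s.window_lo, s.window_hi) for s in segs)
        assert ranges[0][1] < ranges[1][0]
        assert all(s.delta_bic < 0 for s in segs)

    def test_loss_flags_detected_independently(self, rng):
        state = np.zeros((60, 20))
        state[:25, 12:16] = -1.0
        wm = WindowMatrix.from_state(
            pd.DataFrame(state, index=[f"c{i}" for i in range(60)]), self.windows20
        )
        segs = detect_cnv_segments(wm)
        assert [s.kind for s in segs] == ["loss"]
        assert (segs[0].window_lo, segs[0].window_hi) == (12, 15)


def test_cnv_event_end_to_end_sensitivity():
    """Doubling local copy number in 40% of cells flags those cell-windows."""
    n_cells, n_w = 30, 5
    genome = [("chr1", n_w * 20 * MB)]
    cfg = SimConfig(
        ploidies=[2] * n_cells,
        s=0.05,
        n_sites=50_000,
        seed=33,
        genome=genome,
        cnv_spec=[CnvEvent("chr1", 20 * MB, 60 * MB, cell_fraction=0.4, copy_delta=2)],
    )
    fs = simulate_fragments(cfg)
    wm = window_u_matrix(fs, chrom_lengths=dict(genome))
    diploid = [b for i, b in enumerate(sorted(wm.U.index)) if i >= 12]
    with pytest.warns(UserWarning, match="intercept-only"):
        normalize_u(wm, None, diploid_cells=diploid)
    call_gain_loss(wm)
    affected = wm.state.to_numpy()[:12, 1:3]
    unaffected = wm.state.to_numpy()[12:, :]
    assert (affected == 1).mean() >= 0.9
    assert (unaffected == 1).mean() < 0.05
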