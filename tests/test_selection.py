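"""Wavelength selection: PCA loadings, 2D-COS synchronous spectra, RC rule."""

import numpy as np
import pytest
from scipy import stats

import meatspec as ms


class TestPCA:
    def test_rank_one_explains_everything(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6)) + 3.0
        _, _, explained = ms.pca_decompose(X)
        assert explained[0] > 99.999

    def test_explained_variances_valid(self, rng):
        _, _, explained = ms.pca_decompose(rng.normal(size=(15, 8)))
        assert explained.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(explained) <= 1e-9)

    def test_three_factor_spectra_need_three_pcs(self, rng):
        # three independent smooth factors + small noise: >=95 % in 3 PCs
        n, b = 50, 60
        t = np.linspace(0, 1, b)
        P = np.vstack([np.sin(2 * np.pi * k * t) for k in (1, 2, 3)])
        X = rng.normal(size=(n, 3)) @ P + rng.normal(0, 0.05, size=(n, b))
        _, _, explained = ms.pca_decompose(X)
        assert explained[:3].sum() >= 95.0

    def test_loading_signs_deterministic(self, rng):
        X = rng.normal(size=(12, 7))
        _, loadings, _ = ms.pca_decompose(X)
        peaks = np.abs(loadings).argmax(axis=1)
        assert np.all(loadings[np.arange(len(loadings)), peaks] > 0)


class TestLoadingExtrema:
    def test_single_bump_selected_at_apex(self):
        wl = np.linspace(400, 1000, 101)
        loading = np.exp(-0.5 * ((wl - 700) / 30) ** 2)
        ws = ms.pick_loading_extrema(loading[None, :], wl, pcs=(1,))
        assert len(ws) == 1
        assert abs(ws.nm_values[0] - 700) <= 6.0  # one band spacing

    def test_sine_extrema_found(self):
        wl = np.linspace(400, 1000, 201)
        loading = np.sin(2 * np.pi * (wl - 400) / 300.0)  # peaks 475, 775; troughs 625, 925
        ws = ms.pick_loading_extrema(loading[None, :], wl, pcs=(1,))
        expected = [475.0, 625.0, 775.0, 925.0]
        assert len(ws) == 4
        for nm, ref in zip(np.sort(ws.nm_values), expected):
            assert abs(nm - ref) <= 3.0

    def test_flat_loading_warns_and_returns_empty(self):
        wl = np.linspace(400, 1000, 50)
        with pytest.warns(UserWarning, match="no pronounced"):
            ws = ms.pick_loading_extrema(np.zeros((1, 50)), wl, pcs=(1,))
        assert len(ws) == 0

    def test_extrema_merged_across_pcs(self):
        wl = np.linspace(400, 1000, 101)
        l1 = np.exp(-0.5 * ((wl - 500) / 25) ** 2)
        l2 = -np.exp(-0.5 * ((wl - 800) / 25) ** 2)
        ws = ms.pick_loading_extrema(np.vstack([l1, l2]), wl, pcs=(1, 2))
        assert len(ws) == 2


def _brute_force_sync(Y):
    """Independent oracle: Noda's synchronous spectrum by explicit loops."""
    m, b = Y.shape
    mean = Y.mean(axis=0)
    phi = np.zeros((b, b))
    for i in range(b):
        for j in range(b):
            acc = 0.0
            for k in range(m):
                acc += (Y[k, i] - mean[i]) * (Y[k, j] - mean[j])
            phi[i, j] = acc / (m - 1)
    return phi


class Test2DCOS:
    def test_matches_brute_force_oracle(self, rng):
        Y = rng.normal(size=(11, 20))
        sync = ms.sync_2dcos(Y, np.arange(20.0))
        assert np.abs(sync.matrix - _brute_force_sync(Y)).max() < 1e-10

    def test_symmetry_and_nonnegative_diagonal(self, rng):
        sync = ms.sync_2dcos(rng.normal(size=(6, 15)), np.arange(15.0))
        assert np.allclose(sync.matrix, sync.matrix.T, atol=1e-12)
        assert np.all(sync.diagonal >= -1e-15)

    def test_level_independent_spectra_give_zero(self, rng):
        row = rng.normal(size=12)
        sync = ms.sync_2dcos(np.tile(row, (5, 1)), np.arange(12.0))
        assert np.abs(sync.matrix).max() < 1e-14

    def test_invariant_to_level_independent_offset(self, rng):
        Y = rng.normal(size=(7, 10))
        offset = rng.normal(size=10)
        a = ms.sync_2dcos(Y, np.arange(10.0))
        b = ms.sync_2dcos(Y + offset, np.arange(10.0))
        assert np.allclose(a.matrix, b.matrix, atol=1e-12)

    def test_single_varying_band_gives_single_autopeak(self):
        m, b = 11, 30
        levels = np.linspace(0, 100, m)
        Y = np.ones((m, b))
        Y[:, 17] = 1.0 + 0.01 * levels  # only band 17 responds to level
        sync = ms.sync_2dcos(Y, np.arange(float(b)))
        expected_var = np.var(0.01 * levels, ddof=1)
        assert np.isclose(sync.matrix[17, 17], expected_var, atol=1e-12)
        off_diag = sync.diagonal.copy()
        off_diag[17] = 0.0
        assert np.abs(off_diag).max() < 1e-14

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ms.sync_2dcos(np.ones((1, 5)), np.arange(5.0))


class TestAutopeaks:
    def _sync_with_bumps(self, centres, heights, b=60):
        diag = np.zeros(b)
        x = np.arange(b)
        for c, h in zip(centres, heights):
            diag += h * np.exp(-0.5 * ((x - c) / 2.0) ** 2)
        return ms.SyncSpectrum(np.diag(diag), np.linspace(400, 1000, b))

    def test_single_bump(self):
        sync = self._sync_with_bumps([30], [1.0])
        ws = ms.autopeaks(sync, k=1)
        assert ws.band_indices.tolist() == [30]

    def test_top3_of_constructed_truth(self):
        sync = self._sync_with_bumps([10, 25, 40, 52], [0.5, 2.0, 1.5, 1.0])
        ws = ms.autopeaks(sync, k=3)
        assert sorted(ws.band_indices.tolist()) == [25, 40, 52]

    def test_k_larger_than_available_warns(self):
        sync = self._sync_with_bumps([20], [1.0])
        with pytest.warns(UserWarning, match="only 1 exist"):
            ws = ms.autopeaks(sync, k=5)
        assert len(ws) == 1


class TestRCSelect:
    def test_threshold_and_extrema_rule(self):
        coef = np.array([0.0, 6.0, 0.0, -7.0, 0.0])
        wl = np.linspace(400, 800, 5)
        ws = ms.rc_select(coef, wl, threshold=5.0)
        assert ws.band_indices.tolist() == [1, 3]

    def test_all_below_threshold_warns_empty(self):
        coef = np.array([0.0, 2.0, 0.0, -3.0, 0.0])
        with pytest.warns(UserWarning, match="no coefficient extremum"):
            ws = ms.rc_select(coef, np.linspace(400, 800, 5), threshold=5.0)
        assert len(ws) == 0

    def test_monotone_ramp_has_no_extremum(self):
        coef = np.linspace(-10, 10, 9)  # crosses the cut-off with no extremum
        with pytest.warns(UserWarning):
            ws = ms.rc_select(coef, np.linspace(400, 800, 9), threshold=5.0)
        assert len(ws) == 0

    def test_top_k_rule(self):
        coef = np.array([0.0, 1.0, 0.0, -3.0, 0.0, 2.0, 0.0])
        ws = ms.rc_select(coef, np.linspace(400, 1000, 7), n_top=2)
        assert sorted(ws.band_indices.tolist()) == [3, 5]

    def test_accepts_fitted_model(self, rng):
        X = rng.normal(size=(20, 10))
        y = X[:, 4] + rng.normal(0, 0.1, 20)
        model = ms.fit_plsr(X, y, n_lv=2)
        ws = ms.rc_select(model, np.linspace(400, 1000, 10), n_top=3)
        assert len(ws) >= 1


class TestBookkeeping:
    @pytest.mark.parametrize("s,expected", [(10, 96.5), (3, 98.9), (9, 96.8)])
    def test_variable_reduction_percent(self, s, expected):
        ws = ms.WavelengthSet("rc", np.arange(s), np.linspace(400, 900, s))
        assert ws.reduction_percent(284) == expected

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ms.WavelengthSet("rc", [1, 1], [400.0, 400.0])


class TestSelectionOnPhantoms:
    def test_rc_bands_track_endmember_contrast(self):
        """Across seeds, RC-selected bands should sit preferentially where
        the two endmembers differ most.  The models are fitted on SNV
        spectra, so the relevant contrast is the endmember difference in SNV
        space; selection frequency is smoothed over +-3 bands because an
        extremum "near" a contrast band carries the same information."""
        from scipy.ndimage import gaussian_filter1d

        wl = ms.wavelength_grid(120)
        freq = np.zeros(120)
        diffs = np.zeros(120)
        design = ms.DesignSpec(levels=(0., 25., 50., 75., 100.), replicates_per_level=6,
                               calibration_per_level=4)
        for seed in range(4):
            config = ms.PhantomConfig(rows=24, cols=24, bands=120, disk_radius=8, seed=seed)
            em = ms.make_endmembers(wl, seed)
            diffs += np.abs(ms.snv([em.pork])[0] - ms.snv([em.jowl])[0])
            table = ms.extract_spectra(ms.simulate_dataset(design, config, seed))
            model, _ = ms.fit_report(table, "snv", max_lv=6)
            ws = ms.rc_select(model, wl, n_top=8)
            freq[ws.band_indices] += 1
        rho = stats.spearmanr(diffs, gaussian_filter1d(freq, 3)).statistic
        assert rho > 0
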