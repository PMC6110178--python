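"""Chronogram, event detection, spectrum extraction, recalibration, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opticell.msproc import (
    MZ_MIN,
    N_BINS,
    CellEvent,
    SpectrumRecord,
    detect_cell_events,
    extract_cell_spectrum,
    mass_recalibrate,
    normalize_and_bin,
    total_ion_chronogram,
)
from opticell.synthetic import generate_run, generate_spectrum, mz_grid


def flat_scan(level, t, n=200):
    mz = np.linspace(700, 999.9, n)
    return SpectrumRecord(mz=mz, intensity=np.full(n, level), timestamp=t)


class TestChronogram:
    def test_constant_run(self):
        run = [flat_scan(2.0, 0.05 * i) for i in range(10)]
        times, tic = total_ion_chronogram(run)
        assert np.allclose(tic, 400.0)
        assert np.allclose(np.diff(times), 0.05)

    def test_single_scan_sum(self):
        scan = SpectrumRecord(mz=np.array([700.0, 800.0, 900.0]),
                              intensity=np.array([3.0, 4.0, 5.0]))
        _, tic = total_ion_chronogram([scan])
        assert tic[0] == 12.0

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            total_ion_chronogram([])

    def test_matches_generator_envelope(self, euglena):
        """TIC of a noiseless synthetic run equals baseline + the generator's
        Gaussian burst envelope."""
        spec = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        run = generate_run([(2.0, spec)], baseline=300.0, seed=0)
        times, tic = total_ion_chronogram(run)
        sigma = 2 * 0.05
        envelope = np.where(
            np.abs(times - 2.0) <= 6 * sigma,
            np.exp(-0.5 * ((times - 2.0) / sigma) ** 2) * 5e4,
            0.0,
        )
        assert np.allclose(tic, 300.0 + envelope, rtol=1e-4, atol=0.5)


class TestDetectEvents:
    def test_flat_chronogram_no_events(self):
        run = [flat_scan(2.0, 0.05 * i) for i in range(50)]
        assert detect_cell_events(total_ion_chronogram(run)) == []

    def test_single_burst_detected_around_true_time(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        run = generate_run([(2.0, spec)], baseline=1e4 / 5, seed=1, noise_sd=0.02)
        events = detect_cell_events(total_ion_chronogram(run))
        assert len(events) == 1
        assert events[0].t_start < 2.0 < events[0].t_end
        assert events[0].apex_time == pytest.approx(2.0, abs=0.05)

    def test_min_gap_merges_close_bursts(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        run = generate_run([(2.0, spec), (4.5, spec)], baseline=1e4 / 5, seed=1)
        chrono = total_ion_chronogram(run)
        # burst support is +-0.6 s, so the quiet gap between events is ~1.3 s
        assert len(detect_cell_events(chrono, min_gap=1.0)) == 2
        assert len(detect_cell_events(chrono, min_gap=3.0)) == 1

    def test_invalid_k_mad(self):
        run = [flat_scan(2.0, 0.05 * i) for i in range(10)]
        with pytest.raises(ValueError):
            detect_cell_events(total_ion_chronogram(run), k_mad=0.0)


class TestExtractSpectrum:
    def test_single_scan_window_unchanged(self):
        scans = [flat_scan(0.0, 0.0), flat_scan(5.0, 1.0), flat_scan(0.0, 2.0)]
        event = CellEvent(0, 0.9, 1.1, 1.0, 1000.0)
        out = extract_cell_spectrum(scans, event)
        assert np.allclose(out.intensity, 5.0)
        assert out.timestamp == 1.0

    def test_two_identical_scans_sum(self):
        scans = [
            flat_scan(0.0, 0.0),
            flat_scan(3.0, 1.0),
            flat_scan(3.0, 1.05),
            flat_scan(0.0, 2.0),
        ]
        event = CellEvent(0, 0.9, 1.1, 1.0, 1.0)
        out = extract_cell_spectrum(scans, event)
        assert np.allclose(out.intensity, 6.0)

    def test_baseline_subtracted_per_summed_scan(self):
        base = 2.0
        scans = [flat_scan(base, 0.05 * i) for i in range(40)]
        scans[20] = flat_scan(base + 10.0, 1.0)
        scans[21] = flat_scan(base + 10.0, 1.05)
        event = CellEvent(0, 0.99, 1.06, 1.0, 1.0)
        out = extract_cell_spectrum(scans, event)
        assert np.allclose(out.intensity, 20.0)  # burst only, baseline gone

    def test_empty_window_rejected(self):
        scans = [flat_scan(1.0, 0.0)]
        event = CellEvent(0, 5.0, 6.0, 5.5, 1.0)
        with pytest.raises(ValueError, match="no scans"):
            extract_cell_spectrum(scans, event)

    def test_recovers_injected_peak_positions(self, euglena):
        """Top-5 peak centroids of the extracted spectrum match the injected
        profile's strongest ions within 0.05 m/z."""
        from opticell.msproc import _peak_centroids

        spec = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        run = generate_run([(2.0, spec)], baseline=1e4 / 5, seed=1, noise_sd=10.0)
        events = detect_cell_events(total_ion_chronogram(run))
        out = extract_cell_spectrum(run, events[0])
        centroids, heights = _peak_centroids(out)
        top5 = centroids[np.argsort(heights)[-5:]]
        true_top5 = [mz for mz, ab in sorted(euglena.peaks, key=lambda p: p[1])[-5:]]
        for mz_true in true_top5:
            assert np.min(np.abs(top5 - mz_true)) < 0.05


class TestRecalibrate:
    def test_constant_shift_recovered(self, euglena):
        truth = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        locks = [mz for mz, _ in euglena.peaks][:3]
        shifted = SpectrumRecord(mz=truth.mz + 0.02, intensity=truth.intensity)
        corrected, report = mass_recalibrate(shifted, locks, tolerance=0.2)
        assert not report.warning
        from opticell.msproc import _peak_centroids

        centroids, _ = _peak_centroids(corrected)
        for ref in locks:
            assert np.min(np.abs(centroids - ref)) < 1e-3

    def test_linear_drift_slope_recovered(self, euglena):
        """Multiplicative drift of 2e-5: the fitted linear correction must
        recover the inverse slope within 5% (regression oracle)."""
        drift = 2e-5
        truth = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        locks = [mz for mz, _ in euglena.peaks][:4]
        drifted = SpectrumRecord(mz=truth.mz * (1 + drift), intensity=truth.intensity)
        corrected, report = mass_recalibrate(drifted, locks, tolerance=0.2)
        assert report.slope == pytest.approx(1.0 / (1 + drift), abs=0.05 * drift)

    def test_no_match_returns_identity_with_warning(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 0.0, seed=0)
        corrected, report = mass_recalibrate(spec, [850.0], tolerance=0.01)
        assert report.warning
        assert np.array_equal(corrected.mz, spec.mz)


class TestBinning:
    def test_output_length_is_3000(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 50.0, seed=0)
        assert normalize_and_bin(spec).values.shape == (3000,)

    @pytest.mark.parametrize(
        "mz,expected_bin",
        [(700.0, 0), (700.09, 0), (700.1, 1), (999.95, 2999)],
    )
    def test_boundary_arithmetic(self, mz, expected_bin):
        spec = SpectrumRecord(mz=np.array([mz]), intensity=np.array([7.0]))
        binned = normalize_and_bin(spec, normalize=False)
        assert binned.values[expected_bin] == 7.0
        assert binned.values.sum() == 7.0

    def test_mz_1000_excluded(self):
        spec = SpectrumRecord(mz=np.array([999.95, 1000.0]), intensity=np.array([1.0, 5.0]))
        binned = normalize_and_bin(spec, normalize=False)
        assert binned.values.sum() == 1.0

    def test_normalized_sums_to_one(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 50.0, seed=0)
        binned = normalize_and_bin(spec)
        assert binned.normalized
        assert binned.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_spectrum(self):
        spec = SpectrumRecord(mz=mz_grid(), intensity=np.zeros(30000))
        binned = normalize_and_bin(spec)
        assert not binned.normalized
        assert binned.values.sum() == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_binning_conserves_in_range_intensity(self, seed):
        """Pre-normalization binning conserves the total of in-range
        intensities exactly (floating-point sum equality within 1 ulp-scale)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 500)
        mz = np.sort(rng.uniform(695, 1005, n))
        mz = mz[np.diff(mz, prepend=-np.inf) > 0]
        intensity = rng.exponential(100.0, mz.size)
        spec = SpectrumRecord(mz=mz, intensity=intensity)
        binned = normalize_and_bin(spec, normalize=False)
        in_range = intensity[(mz >= 700.0) & (mz < 1000.0)]
        assert binned.values.sum() == pytest.approx(in_range.sum(), rel=1e-12)

    def test_permutation_invariant_and_idempotent(self, euglena):
        spec = generate_spectrum(euglena, 5e4, 20.0, seed=1)
        binned = normalize_and_bin(spec, normalize=False)
        # permuting input channels does not change the result
        rng = np.random.default_rng(0)
        perm = rng.permutation(spec.mz.size)
        order = np.argsort(spec.mz[perm])
        spec2 = SpectrumRecord(mz=spec.mz[perm][order], intensity=spec.intensity[perm][order])
        assert np.allclose(normalize_and_bin(spec2, normalize=False).values, binned.values)
        # re-binning a spectrum already on the bin-centre grid is the identity
        from opticell.msproc import BinnedSpectrum

        centers = BinnedSpectrum.bin_centers()
        rebin = normalize_and_bin(SpectrumRecord(mz=centers, intensity=binned.values), normalize=False)
        assert np.allclose(rebin.values, binned.values)
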