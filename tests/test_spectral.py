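"""Band-power estimator, feature stacking, and occupancy preparation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsfcbf.spectral import (BandSchema, band_powers, extract_features,
                             periodogram_power, prepare_occupancy)
from rsfcbf.volumes import Volume3D, Volume4D


def brute_force_band_powers(series, tr, schema):
    """Independent oracle: direct DFT sums, no library periodogram path."""
    x = np.asarray(series, dtype=float)
    T = x.size
    t = np.arange(T)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)
    out = np.zeros(schema.n_bands)
    for k in range(T // 2 + 1):
        f = k / (T * tr)
        if f == 0:
            continue
        X = np.sum(x * np.exp(-2j * np.pi * k * t / T))
        c = 1.0 if (T % 2 == 0 and k == T // 2) else 2.0
        p = c * abs(X) ** 2 / T
        for b, (lo, hi) in enumerate(schema.edges):
            if lo <= f < hi:
                out[b] += p
    return out


def test_constant_series_has_zero_band_power():
    bp = band_powers(np.full(64, 3.7), tr_seconds=0.5)
    np.testing.assert_allclose(bp, 0.0, atol=1e-20)


def test_pure_tone_concentrates_in_its_bin():
    tr, T = 0.5, 512
    t = np.arange(T) * tr
    f_tone = 31 / (T * tr)  # ~0.121 Hz, on the DFT grid (no leakage)
    series = np.sin(2 * np.pi * f_tone * t)
    bp = band_powers(series, tr)
    assert bp[1] / bp.sum() >= 0.99
    others = np.delete(bp, 1)
    assert others.max() <= 0.01 * bp.sum()


def test_band_powers_match_brute_force_dft():
    rng = np.random.default_rng(42)
    schema = BandSchema()
    tr = 0.5
    for T in (64, 81, 128):
        series = rng.normal(size=T)
        got = band_powers(series, tr, schema)
        want = brute_force_band_powers(series, tr, schema)
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_parseval_identity():
    rng = np.random.default_rng(7)
    x = rng.normal(size=1024)
    _, power = periodogram_power(x)
    from scipy.signal import detrend
    xd = detrend(x, type="linear")
    assert power.sum() == pytest.approx(np.sum(xd ** 2), rel=1e-6)
    assert power.sum() == pytest.approx(xd.var() * xd.size, rel=1e-6)


@given(offset=st.floats(-50, 50), slope=st.floats(-2, 2),
       amp=st.floats(0.5, 4))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_detrending_invariance_and_quadratic_amplitude_scaling(offset, slope, amp):
    rng = np.random.default_rng(3)
    base = rng.normal(size=128)
    t = np.arange(128)
    bp0 = band_powers(base, 0.5)
    bp_shift = band_powers(base + offset + slope * t, 0.5)
    np.testing.assert_allclose(bp_shift, bp0, rtol=1e-8, atol=1e-10)
    bp_amp = band_powers(amp * base, 0.5)
    np.testing.assert_allclose(bp_amp, amp ** 2 * bp0, rtol=1e-8)


def test_schema_validation():
    with pytest.raises(ValueError, match="increasing"):
        BandSchema(midpoints_hz=(0.12, 0.04))
    with pytest.raises(ValueError, match="overlap"):
        BandSchema(midpoints_hz=(0.04, 0.08), bin_width_hz=0.08)
    with pytest.raises(ValueError, match="negative"):
        BandSchema(midpoints_hz=(0.02, 0.12), bin_width_hz=0.08)


def test_nyquist_guard_and_allow_partial():
    series = np.random.default_rng(0).normal(size=128)
    with pytest.raises(ValueError, match="Nyquist"):
        band_powers(series, tr_seconds=2.0)  # Nyquist 0.25 < 0.64
    bp = band_powers(series, tr_seconds=2.0, allow_partial=True)
    # bins fully above 0.25 Hz are zero-filled; bin 4 straddles Nyquist
    assert np.all(bp[4:] == 0.0)
    assert bp[:4].sum() > 0


def test_too_short_series_rejected():
    with pytest.raises(ValueError, match="16 time points"):
        band_powers(np.zeros(8), 0.5)
    # 20 points at tr=0.8: DFT spacing 1/16 Hz ~ 0.0625 < 0.08, all bins hit;
    # 17 points at tr=0.5 leaves the lowest bin empty
    with pytest.raises(ValueError, match="no DFT ordinate"):
        band_powers(np.zeros(17), 0.5)


def _uniform_bold(shape, T, tr, series):
    data = np.broadcast_to(series, shape + (T,)).copy()
    return Volume4D.from_array(data, tr_seconds=tr)


def test_identical_series_give_identical_spectral_rows():
    rng = np.random.default_rng(1)
    series = rng.normal(size=64)
    bold = _uniform_bold((3, 3, 3), 64, 0.5, series)
    mask = Volume3D.from_array(np.ones((3, 3, 3)))
    occ = Volume3D.from_array(np.full((3, 3, 3), 0.5))
    fm = extract_features(bold, mask, occ)
    spectral = fm.rows[:, :56]
    assert np.abs(spectral - spectral[0]).max() < 1e-12 * spectral.max()


def test_single_voxel_replicates_center_for_missing_neighbors():
    rng = np.random.default_rng(2)
    series = rng.normal(size=64)
    bold = _uniform_bold((3, 3, 3), 64, 0.5, series)
    mask_data = np.zeros((3, 3, 3))
    mask_data[1, 1, 1] = 1
    mask = Volume3D.from_array(mask_data)
    occ = Volume3D.from_array(np.full((3, 3, 3), 0.5))
    fm = extract_features(bold, mask, occ)
    assert fm.n_voxels == 1
    center = fm.rows[0, :8]
    for j in range(7):
        np.testing.assert_array_equal(fm.rows[0, 8 * j:8 * (j + 1)], center)
    fm0 = extract_features(bold, mask, occ, neighbor_policy="zero")
    assert np.all(fm0.rows[0, 8:56] == 0)


def test_feature_rows_match_brute_force_neighbor_gathering():
    """3x3x3 phantom with distinct per-voxel sinusoids vs manual assembly."""
    tr, T = 0.5, 256
    t = np.arange(T) * tr
    freqs = np.linspace(0.05, 0.6, 27).reshape(3, 3, 3)
    data = np.sin(2 * np.pi * freqs[..., None] * t)
    bold = Volume4D.from_array(data, tr_seconds=tr)
    mask = Volume3D.from_array(np.ones((3, 3, 3)))
    occ = Volume3D.from_array(np.random.default_rng(0).uniform(0, 1, (3, 3, 3)))
    schema = BandSchema()
    fm = extract_features(bold, mask, occ, schema=schema)

    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for row, (x, y, z) in zip(fm.rows, fm.voxel_index):
        want = [brute_force_band_powers(data[x, y, z], tr, schema)]
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < 3 and 0 <= ny < 3 and 0 <= nz < 3:
                want.append(brute_force_band_powers(data[nx, ny, nz], tr, schema))
            else:
                want.append(want[0])
        np.testing.assert_allclose(row[:56], np.concatenate(want), rtol=1e-9)
        assert row[56] == pytest.approx(occ.data[x, y, z])


def test_extraction_is_deterministic_and_modes_differ_only_in_occupancy():
    rng = np.random.default_rng(5)
    bold = Volume4D.from_array(rng.normal(size=(4, 4, 4, 64)), tr_seconds=0.5)
    mask = Volume3D.from_array(np.ones((4, 4, 4)))
    occ = Volume3D.from_array(rng.uniform(0, 1, (4, 4, 4)))
    fm1 = extract_features(bold, mask, occ, mode="pva_corrected")
    fm2 = extract_features(bold, mask, occ, mode="pva_corrected")
    np.testing.assert_array_equal(fm1.rows, fm2.rows)
    orig = extract_features(bold, mask, occ, mode="original")
    np.testing.assert_array_equal(orig.rows[:, :56], fm1.rows[:, :56])
    assert np.all(orig.rows[:, 56] == 0)
    derived = fm1.as_original()
    np.testing.assert_array_equal(derived.rows, orig.rows)


def test_prepare_occupancy_preserves_constants_and_range():
    occ = Volume3D.from_array(np.full((12, 12, 12), 0.7), voxel_size_mm=(1, 1, 1))
    out = prepare_occupancy(occ, fwhm_mm=5, target_mm=2)
    np.testing.assert_allclose(out.data, 0.7, rtol=1e-12)
    assert out.voxel_size_mm == (2.0, 2.0, 2.0)
    rng = np.random.default_rng(0)
    noisy = Volume3D.from_array(rng.uniform(0, 1, (12, 12, 12)),
                                voxel_size_mm=(1, 1, 1))
    out = prepare_occupancy(noisy)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_prepare_occupancy_conserves_ribbon_mass():
    """Total occupancy volume of a central ribbon survives smoothing and
    resampling within 1% (reflective boundaries, mass away from edges)."""
    data = np.zeros((40, 40, 40))
    data[16:24, 16:24, 16:24] = 0.9
    occ = Volume3D.from_array(data, voxel_size_mm=(1, 1, 1))
    out = prepare_occupancy(occ, fwhm_mm=5, target_mm=2)
    mass_in = data.sum() * 1.0
    mass_out = out.data.sum() * 8.0
    assert mass_out == pytest.approx(mass_in, rel=0.01)


def test_prepare_occupancy_rejects_too_coarse_target():
    occ = Volume3D.from_array(np.full((4, 4, 4), 0.5), voxel_size_mm=(1, 1, 1))
    with pytest.raises(ValueError, match="coarser"):
        prepare_occupancy(occ, target_mm=10)
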