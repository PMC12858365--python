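"""Wave solver, noise rule, time reversal, colored noise."""

import numpy as np
import pytest

from qpactvi.acoustics import (PressureVolume, SensorData, TransducerArray,
                               add_sensor_noise, colored_noise_image,
                               ensemble_noise_sigma, induced_pressure,
                               simulate_acoustics, study1_input, time_reversal)
from qpactvi.grids import GridSpec
from qpactvi.phantom import AcousticMaps


def _uniform_ac(shape, c=1500.0, rho=1000.0):
    return AcousticMaps(c=np.full(shape, c), rho=np.full(shape, rho),
                        alpha0=np.zeros(shape), y=np.ones(shape))


# ------------------------------------------------------- induced pressure


def test_induced_pressure_product_and_linearity():
    rng = np.random.default_rng(0)
    mua, phi = rng.random((6, 6, 6)), rng.random((6, 6, 6))
    assert induced_pressure(np.zeros((4, 4)), np.ones((4, 4))).p0.max() == 0.0
    p1 = induced_pressure(mua, phi, gamma=1.0).p0
    p2 = induced_pressure(mua, phi, gamma=2.0).p0
    np.testing.assert_array_equal(p2, 2.0 * p1)
    np.testing.assert_array_equal(p1, mua * phi)  # elementwise-product oracle
    with pytest.raises(ValueError, match="shape"):
        induced_pressure(np.zeros((3, 3)), np.zeros((4, 4)))


# ------------------------------------------------------------ forward sim


def test_zero_pressure_gives_zero_traces(ring_2d_setup):
    grid, acoustic, array, _, _ = ring_2d_setup
    sd = simulate_acoustics(PressureVolume(np.zeros(grid.shape), grid), acoustic,
                            array, grid)
    assert np.all(sd.records == 0)
    assert sd.dt == array.dt


def test_forward_sim_superposition(ring_2d_setup):
    grid, acoustic, array, _, _ = ring_2d_setup
    rng = np.random.default_rng(1)
    X, Y = grid.meshgrid()
    inside = X**2 + Y**2 < 15**2
    a = rng.random(grid.shape) * inside
    b = rng.random(grid.shape) * inside
    sa = simulate_acoustics(PressureVolume(a, grid), acoustic, array, grid).records
    sb = simulate_acoustics(PressureVolume(b, grid), acoustic, array, grid).records
    sab = simulate_acoustics(PressureVolume(a + b, grid), acoustic, array,
                             grid).records
    np.testing.assert_allclose(sab, sa + sb, atol=1e-10 * np.abs(sab).max())


def test_cfl_violation_rejected(ring_2d_setup):
    grid, acoustic, _, _, _ = ring_2d_setup
    bad = TransducerArray.ring_2d(8, 25.0, (0, 0), sampling_rate=1e6, n_samples=16)
    with pytest.raises(ValueError, match="CFL"):
        simulate_acoustics(PressureVolume(np.zeros(grid.shape), grid), acoustic,
                           bad, grid)


def test_lossless_energy_non_increasing(ring_2d_setup):
    grid, acoustic, array, _, _ = ring_2d_setup
    X, Y = grid.meshgrid()
    p0 = np.exp(-(X**2 + Y**2) / (2 * 1.0**2))
    sd = simulate_acoustics(PressureVolume(p0, grid), acoustic, array, grid,
                            track_energy=True)
    E = np.asarray(sd.meta["energy"])
    assert E.max() <= E[1] * 1.01  # absorbing boundaries only remove energy


def test_attenuation_filter_damps_high_frequencies(ring_2d_setup):
    grid, _, array, _, _ = ring_2d_setup
    X, Y = grid.meshgrid()
    p0 = np.exp(-((X - 3) ** 2 + (Y + 2) ** 2) / (2 * 0.8**2))
    lossy = AcousticMaps(c=np.full(grid.shape, 1500.0),
                         rho=np.full(grid.shape, 1000.0),
                         alpha0=np.full(grid.shape, 5.0),
                         y=np.full(grid.shape, 1.5))
    clean = simulate_acoustics(PressureVolume(p0, grid), _uniform_ac(grid.shape),
                               array, grid, apply_attenuation=False).records
    filt = simulate_acoustics(PressureVolume(p0, grid), lossy, array, grid,
                              apply_attenuation=True).records
    spec_c = np.abs(np.fft.rfft(clean[0, 0]))
    spec_f = np.abs(np.fft.rfft(filt[0, 0]))
    hi = slice(len(spec_c) // 2, None)
    assert spec_f[hi].sum() < 0.5 * spec_c[hi].sum()
    assert np.abs(filt).max() < np.abs(clean).max()


# ------------------------------------------------------------- noise rule


def _fake_sensor(records):
    arr = TransducerArray(np.zeros((1, records.shape[1], 2)), 1e7,
                          records.shape[-1])
    return SensorData(records=records[None] if records.ndim == 2 else records,
                      dt=1e-7, array=arr)


def test_noise_sigma_is_fraction_of_ensemble_mean_max():
    """sigma = fraction x mean over phantoms of max |signal| pooled over
    wavelengths: exact arithmetic on constructed ensembles."""
    m1 = {757.0: _fake_sensor(np.full((2, 8), 3.0)),
          850.0: _fake_sensor(np.full((2, 8), -10.0))}
    m2 = {757.0: _fake_sensor(np.full((2, 8), 6.0)),
          850.0: _fake_sensor(np.full((2, 8), 2.0))}
    assert ensemble_noise_sigma([m1, m2], 0.01) == pytest.approx(0.08)
    assert ensemble_noise_sigma([m1], 0.01) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        ensemble_noise_sigma([m1], -0.5)
    with pytest.raises(ValueError):
        ensemble_noise_sigma([], 0.01)


def test_add_noise_statistics_and_degenerate_fraction():
    sensors = {800.0: _fake_sensor(np.zeros((4, 25_000)))}
    out = add_sensor_noise(sensors, seed=3, sigma=0.2)
    noise = out[800.0].records
    se = 0.2 / np.sqrt(2 * noise.size)
    assert noise.std() == pytest.approx(0.2, abs=3 * se)
    assert abs(noise.mean()) < 3 * 0.2 / np.sqrt(noise.size)
    assert out[800.0].noise_sigma == 0.2
    same = add_sensor_noise(sensors, fraction=0.0, seed=3)
    np.testing.assert_array_equal(same[800.0].records, sensors[800.0].records)
    with pytest.raises(ValueError):
        add_sensor_noise(sensors, fraction=-0.1)


# ---------------------------------------------------------- time reversal


def test_zero_traces_reconstruct_to_zero(ring_2d_setup):
    grid, _, array, c0, rho0 = ring_2d_setup
    sd = SensorData(records=np.zeros((1, array.n_elements, 64)), dt=array.dt,
                    array=array)
    rec = time_reversal(sd, array, c0, rho0, grid)
    assert np.all(rec.volume == 0)
    with pytest.raises(ValueError, match="empty"):
        time_reversal(SensorData(records=np.zeros((1, 0, 0)), dt=array.dt,
                                 array=array), array, c0, rho0, grid)


def test_point_source_localized_within_one_voxel(ring_2d_setup):
    grid, acoustic, array, c0, rho0 = ring_2d_setup
    from scipy import ndimage

    p0 = np.zeros(grid.shape)
    p0[70, 58] = 1.0
    p0 = ndimage.gaussian_filter(p0, 1.0)
    sd = simulate_acoustics(PressureVolume(p0, grid), acoustic, array, grid)
    rec = time_reversal(sd, array, c0, rho0, grid)
    peak = np.unravel_index(np.argmax(rec.volume), grid.shape)
    assert max(abs(peak[0] - 70), abs(peak[1] - 58)) <= 1


def test_duplicate_sensors_collapsed_on_coarse_grid(ring_2d_setup):
    grid, _, array, c0, rho0 = ring_2d_setup
    coarse = GridSpec((32, 32), 2.0, origin=(-31.0, -31.0))
    sd = SensorData(records=np.zeros((1, array.n_elements, 32)), dt=array.dt,
                    array=array)
    rec = time_reversal(sd, array, c0, rho0, coarse)
    assert rec.meta["n_sensors_retained"] <= array.n_elements
    assert rec.meta["n_sensors_collapsed"] > 0
    assert (rec.meta["n_sensors_retained"] + rec.meta["n_sensors_collapsed"]
            == array.n_elements)


def test_mismatched_sos_degrades_reconstruction():
    """Reconstructing with water sound speed through a faster breast-like
    inclusion is strictly worse than using the matched mean speed."""
    grid = GridSpec((96, 96), 0.5, origin=(-23.75, -23.75))
    X, Y = grid.meshgrid()
    disc = X**2 + Y**2 <= 15**2
    acoustic = AcousticMaps(c=np.where(disc, 1560.0, 1480.0),
                            rho=np.where(disc, 1040.0, 1000.0),
                            alpha0=np.zeros(grid.shape), y=np.ones(grid.shape))
    dt = 0.3 * grid.voxel_size * 1e-3 / 1650.0
    array = TransducerArray.ring_2d(96, 20.0, (0, 0), 1.0 / dt, 640)
    p0 = (np.exp(-((X - 4) ** 2 + (Y + 3) ** 2) / 2.0)
          + np.exp(-((X + 6) ** 2 + (Y - 5) ** 2) / (2 * 1.5**2)))
    sd = simulate_acoustics(PressureVolume(p0, grid), acoustic, array, grid)
    r_matched = np.corrcoef(
        time_reversal(sd, array, float(acoustic.c[disc].mean()), 1000.0,
                      grid).volume.ravel(), p0.ravel())[0, 1]
    r_water = np.corrcoef(
        time_reversal(sd, array, 1480.0, 1000.0, grid).volume.ravel(),
        p0.ravel())[0, 1]
    assert r_matched > r_water


# ----------------------------------------------------------- colored noise


def test_colored_noise_properties(ring_2d_setup):
    grid, _, array, c0, _ = ring_2d_setup
    small = GridSpec((64, 64), 1.0, origin=(-31.5, -31.5))
    zero = colored_noise_image(array, small, 0.0, c0, seed=5, n_samples=64)
    assert np.all(zero.volume == 0)
    n1 = colored_noise_image(array, small, 1.0, c0, seed=5, n_samples=96)
    n2 = colored_noise_image(array, small, 2.5, c0, seed=5, n_samples=96)
    np.testing.assert_allclose(n2.volume, 2.5 * n1.volume, rtol=1e-12)
    vals = n1.volume
    assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(vals.size)
    # spatial correlation well above the iid null (lag-1 autocorr ~ 0) in the
    # imaging region interior to the sensor ring
    X, Y = small.meshgrid()
    interior = X**2 + Y**2 < 15**2
    v = vals - vals[interior].mean()
    num = ((v[1:] * v[:-1])[interior[1:] & interior[:-1]].mean()
           + (v[:, 1:] * v[:, :-1])[interior[:, 1:] & interior[:, :-1]].mean())
    assert num / (2 * v[interior].var()) > 0.2
    with pytest.raises(ValueError):
        colored_noise_image(array, small, -1.0, c0, seed=0)


def test_study1_input_additivity():
    rng = np.random.default_rng(2)
    p0 = {wl: rng.random((8, 8, 8)) for wl in (757.0, 800.0, 850.0)}
    noise = {wl: rng.standard_normal((8, 8, 8)) for wl in p0}
    out = study1_input(p0, noise)
    assert set(out) == set(p0)
    for wl in p0:
        np.testing.assert_allclose(out[wl] - p0[wl], noise[wl], atol=1e-12)
    clean = study1_input(p0, {wl: np.zeros((8, 8, 8)) for wl in p0})
    for wl in p0:
        np.testing.assert_array_equal(clean[wl], p0[wl])
    with pytest.raises(ValueError, match="shape"):
        study1_input({800.0: np.zeros((4, 4, 4))}, {800.0: np.zeros((5, 5, 5))})


def test_rotating_arc_geometry():
    arr = TransducerArray.rotating_arc(n_elements=108, radius_mm=85.0,
                                       span_deg=80.0, n_views=480)
    assert arr.positions.shape == (480, 108, 3)
    np.testing.assert_allclose(np.linalg.norm(arr.positions, axis=-1), 85.0,
                               rtol=1e-9)
    assert arr.n_samples == 3720 and arr.dt == pytest.approx(5e-8)
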