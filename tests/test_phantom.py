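import numpy as np
import pytest
from scipy.integrate import quad

from thoraco import PhantomConfig, analytic_chest_volume, breathing_waveform, generate_phantom
from thoraco.phantom import (PhantomConfigError, _section_area_mm2,
                             _volume_from_s)


def test_waveform_quiet_is_sinusoid():
    cfg = PhantomConfig(quiet_duration_s=20.0)
    t = np.linspace(0, 19.9, 500)
    np.testing.assert_allclose(
        breathing_waveform(t, cfg), np.sin(2 * np.pi * cfg.freq_hz * t),
        atol=1e-12)


def test_waveform_continuous_and_hits_extremes():
    cfg = PhantomConfig(quiet_duration_s=20.0)
    t = np.linspace(0, cfg.duration_s, 200001)
    s = breathing_waveform(t, cfg)
    # no jump anywhere (piecewise linear/sinusoidal at this resolution)
    assert np.abs(np.diff(s)).max() < 0.01
    assert s.max() == pytest.approx(cfg.tlc_excursion, abs=1e-3)
    assert s.min() == pytest.approx(-cfg.rv_excursion, abs=1e-3)
    assert s[-1] == pytest.approx(0.0, abs=1e-6)


def test_section_area_matches_polygon_oracle():
    """Oracle: shoelace area of a very dense polygon on the gained ellipse,
    with a genuinely asymmetric left/right gain."""
    cfg = PhantomConfig(asymmetry=0.6)
    a, b, eps, s = 140.0, 108.0, 0.007, 5.0
    theta = np.linspace(0, 2 * np.pi, 2_000_001)
    g = ((1 + cfg.asymmetry) + (1 - cfg.asymmetry) * np.cos(theta)) / 2.0
    u = 1 + eps * s * g
    x = a * np.cos(theta) * u
    y = b * np.sin(theta) * u
    num = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    ana = _section_area_mm2(a, b, eps, s, cfg)
    assert ana == pytest.approx(num, rel=1e-8)


def test_section_area_single_axis_mode():
    cfg = PhantomConfig(scale_axes="a")
    a, b, eps, s = 120.0, 100.0, 0.006, -3.0
    u = 1 + eps * s * 1.0  # asymmetry=1 -> g = 1 everywhere
    assert _section_area_mm2(a, b, eps, s, cfg) == pytest.approx(
        np.pi * (a * u) * b, rel=1e-12)


def test_volume_matches_z_quadrature_oracle():
    cfg = PhantomConfig()
    s = 3.7

    z = cfg.row_heights()
    a = np.array(cfg.a0_mm)
    b = np.array(cfg.b0_mm)
    e = cfg.row_eps()

    def area_at(zq):
        aa = np.interp(zq, z[::-1], a[::-1])
        bb = np.interp(zq, z[::-1], b[::-1])
        ee = np.interp(zq, z[::-1], e[::-1])
        return _section_area_mm2(aa, bb, ee, s, cfg)

    num, _ = quad(area_at, z[-1], z[0], limit=400)
    assert _volume_from_s(cfg, s) == pytest.approx(num * 1e-6, rel=1e-9)


def test_compartment_volumes_sum_to_total():
    cfg = PhantomConfig(quiet_duration_s=12.0)
    _, truth = generate_phantom(cfg)
    total = sum(truth.compartments.values())
    np.testing.assert_allclose(total, truth.volume_l, rtol=1e-12)


def test_ground_truth_capacities_consistent():
    cfg = PhantomConfig(quiet_duration_s=12.0)
    _, truth = generate_phantom(cfg)
    assert truth.vt_l == pytest.approx(truth.frcvt_l - truth.frc_l)
    assert truth.ic_l == pytest.approx(truth.tlc_l - truth.frc_l)
    assert truth.vc_l == pytest.approx(truth.tlc_l - truth.rv_l)
    assert truth.rv_l < truth.frc_l < truth.frcvt_l < truth.tlc_l
    assert truth.rr_bpm == pytest.approx(60.0 * cfg.freq_hz)


def test_default_magnitudes_physiological():
    """The defaults describe a healthy adult: VT ~0.5 L, IC ~2.5 L,
    VC ~3.6 L, chest-wall volume ~22 L."""
    cfg = PhantomConfig(quiet_duration_s=12.0)
    _, truth = generate_phantom(cfg)
    assert 0.3 < truth.vt_l < 0.8
    assert 2.0 < truth.ic_l < 3.5
    assert 3.0 < truth.vc_l < 5.0
    assert 18.0 < truth.frc_l < 26.0


def test_generation_deterministic_per_seed():
    cfg = PhantomConfig(quiet_duration_s=5.0, seed=42)
    t1, _ = generate_phantom(cfg)
    t2, _ = generate_phantom(PhantomConfig(quiet_duration_s=5.0, seed=42))
    np.testing.assert_array_equal(t1.positions, t2.positions)
    t3, _ = generate_phantom(PhantomConfig(quiet_duration_s=5.0, seed=43))
    assert not np.array_equal(t1.positions, t3.positions)


def test_noise_free_markers_on_analytic_surface():
    cfg = PhantomConfig(quiet_duration_s=5.0, jitter_sd_mm=0.0)
    trajs, _ = generate_phantom(cfg)
    layout = cfg.layout
    frame = trajs.frame(17)
    s = breathing_waveform(trajs.times[17], cfg)
    z = cfg.row_heights()
    for i, st in enumerate(layout.stations):
        r = st.row - 1
        u = 1 + cfg.row_eps()[r] * s  # asymmetry=1 -> g=1
        x, y, zz = frame[i]
        assert zz == pytest.approx(z[r], abs=1e-9)
        val = (x / (cfg.a0_mm[r] * u)) ** 2 + (y / (cfg.b0_mm[r] * u)) ** 2
        assert val == pytest.approx(1.0, abs=1e-9)


def test_paradox_flag_flips_row_amplitudes():
    plain = PhantomConfig().row_eps()
    par = PhantomConfig(paradox_flags={"AB"}).row_eps()
    # interior AB rows flip sign; rows untouched by AB are unchanged
    assert par[5] == -plain[5] and par[6] == -plain[6]
    np.testing.assert_allclose(par[:4], plain[:4])


def test_config_validation():
    with pytest.raises(PhantomConfigError):
        PhantomConfig(tlc_excursion=0.5)  # TLC below quiet peaks
    with pytest.raises(PhantomConfigError):
        PhantomConfig(rv_excursion=0.5)
    with pytest.raises(PhantomConfigError):
        PhantomConfig(scale_axes="c")
    with pytest.raises(PhantomConfigError):
        PhantomConfig(eps={"RCp": 0.2, "RCa": 0.005, "AB": 0.007})  # collapses
    with pytest.raises(PhantomConfigError):
        PhantomConfig(a0_mm=(100.0,) * 6)  # one entry per row required


def test_analytic_volume_scalar_and_vector():
    cfg = PhantomConfig()
    t = np.array([0.0, 1.0, 2.0])
    v = analytic_chest_volume(cfg, t)
    assert v.shape == (3,)
    assert analytic_chest_volume(cfg, 1.0) == pytest.approx(v[1])
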