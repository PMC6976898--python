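"""Phantom pipeline: synthetic rod scans and US-based PA normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palight.metrics import DepthProfile
from palight.phantom import (
    RodScan,
    RodSpec,
    compare_model_to_scan,
    default_rods,
    generate_synthetic_scan,
    us_normalize,
)


@pytest.fixture
def profile():
    z = np.linspace(0.25, 35.75, 72)
    return DepthProfile(depth=z, mean_fluence=np.exp(-z / 8.0))


def test_default_rod_layout():
    rods = default_rods()
    assert len(rods.depths) == 11
    np.testing.assert_allclose(np.diff(rods.depths), 2.0)
    spacings = np.abs(np.diff(rods.laterals))
    assert set(np.round(spacings, 6)) == {5.0, 6.0}
    assert rods.diameter == 0.5 and rods.length == 20.0


def test_rod_spec_validation():
    with pytest.raises(ValueError, match="increasing"):
        RodSpec(positions=((0, 4.0), (5, 4.0)))
    with pytest.raises(ValueError):
        RodSpec(positions=((0, 4.0),))


def test_noiseless_scan_is_exact(profile):
    rods = default_rods()
    scan = generate_synthetic_scan(profile, rods, system_factor=np.ones(11),
                                   noise_cv=0.0, seed=0)
    fluence = np.interp(rods.depths, profile.depth, profile.mean_fluence)
    np.testing.assert_allclose(scan.pa, np.tile(fluence[:, None], (1, 4)))
    np.testing.assert_allclose(scan.us, np.ones((11, 4)))

    sf = np.exp(-0.07 * rods.depths)
    scan2 = generate_synthetic_scan(profile, rods, system_factor=sf,
                                    noise_cv=0.0, seed=0)
    np.testing.assert_allclose(scan2.us, np.tile((sf**2)[:, None], (1, 4)))
    np.testing.assert_allclose(scan2.pa, np.tile((fluence * sf)[:, None], (1, 4)))


def test_scan_seeded_determinism(profile):
    rods = default_rods()
    kw = dict(system_factor=np.ones(11), noise_cv=0.05)
    s1 = generate_synthetic_scan(profile, rods, seed=99, **kw)
    s2 = generate_synthetic_scan(profile, rods, seed=99, **kw)
    assert np.array_equal(s1.pa, s2.pa) and np.array_equal(s1.us, s2.us)
    s3 = generate_synthetic_scan(profile, rods, seed=100, **kw)
    assert not np.array_equal(s1.pa, s3.pa)


def test_scan_rejects_rods_outside_profile(profile):
    deep = RodSpec(positions=tuple((0.0, 30.0 + 2 * i) for i in range(11)))
    with pytest.raises(ValueError, match="outside"):
        generate_synthetic_scan(profile, deep, np.ones(11), 0.0, 0)


def test_us_normalize_hand_example():
    """US (4, 1) with PA (8, 1): normalized US (1, 0.25), sqrt (1, 0.5),
    adjusted PA (8, 2)."""
    rods = RodSpec(positions=((0.0, 4.0), (5.0, 6.0)))
    scan = RodScan(rods=rods,
                   pa=np.array([[8.0] * 4, [1.0] * 4]),
                   us=np.array([[4.0] * 4, [1.0] * 4]),
                   theta=40.0, D=7.5)
    adj = us_normalize(scan)
    np.testing.assert_allclose(adj["us_divisor"], [1.0, 0.5])
    np.testing.assert_allclose(adj["adjusted_pa"], [8.0, 2.0])
    np.testing.assert_allclose(adj["adjusted_pa_std"], 0.0)


def test_us_normalize_equal_us_is_identity_on_pa():
    rods = default_rods()
    pa = np.tile(np.linspace(5, 1, 11)[:, None], (1, 4))
    scan = RodScan(rods=rods, pa=pa, us=np.full((11, 4), 3.0),
                   theta=40.0, D=7.5)
    np.testing.assert_allclose(us_normalize(scan)["adjusted_pa"], pa[:, 0])


@settings(deadline=None, max_examples=40)
@given(
    decay=st.floats(0.01, 0.3),
    sf_seed=st.integers(0, 10_000),
)
def test_noiseless_normalization_recovers_fluence_shape(decay, sf_seed):
    """For ANY positive system factor, the square-root US correction cancels
    it exactly on noiseless data: adjusted PA = c * fluence at rod depths."""
    z = np.linspace(0.25, 35.75, 72)
    profile = DepthProfile(depth=z, mean_fluence=np.exp(-decay * z))
    rods = default_rods()
    sf = np.exp(np.random.default_rng(sf_seed).uniform(-2, 2, size=11))
    scan = generate_synthetic_scan(profile, rods, system_factor=sf,
                                   noise_cv=0.0, seed=1)
    adj = us_normalize(scan)["adjusted_pa"].to_numpy()
    fluence = np.interp(rods.depths, z, profile.mean_fluence)
    ratio = adj / fluence
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


def test_reported_std_consistent_with_noise_level(profile):
    """With multiplicative noise of CV c and 4 repeats, the per-rod relative
    std estimates scatter around c (chi-square band for n=4, aggregated)."""
    cv = 0.05
    rods = default_rods()
    rels = []
    for seed in range(30):
        scan = generate_synthetic_scan(profile, rods, np.ones(11), cv, seed)
        adj = us_normalize(scan)
        rels.extend(adj["adjusted_pa_std"] / adj["adjusted_pa"])
    mean_rel = float(np.mean(rels))
    # E[s]/sigma = c4(4) ~ 0.921; the band is generous for the n=330 average
    assert 0.8 * cv < mean_rel < 1.1 * cv


def test_compare_model_noiseless_self_consistency(profile):
    rods = default_rods()
    scan = generate_synthetic_scan(profile, rods,
                                   system_factor=np.exp(-0.05 * rods.depths),
                                   noise_cv=0.0, seed=0)
    comp = compare_model_to_scan(profile, us_normalize(scan))
    assert comp["rms_relative_residual"] < 1e-9
    assert comp["spearman_rho"] == pytest.approx(1.0)


def test_compare_model_flags_wrong_geometry(profile):
    """Data generated from a faster-decaying profile fits its own geometry
    better than a mismatched one."""
    z = profile.depth
    other = DepthProfile(depth=z, mean_fluence=np.exp(-z / 3.0))
    rods = default_rods()
    scan = generate_synthetic_scan(other, rods, np.ones(11),
                                   noise_cv=0.02, seed=5)
    adj = us_normalize(scan)
    matched = compare_model_to_scan(other, adj)
    mismatched = compare_model_to_scan(profile, adj)
    assert matched["rms_relative_residual"] < mismatched["rms_relative_residual"]
    # residual spread consistent with the 2% noise (within a loose factor)
    assert matched["rms_relative_residual"] < 0.05


def test_scan_frame_round_trip(profile):
    rods = default_rods()
    scan = generate_synthetic_scan(profile, rods, np.ones(11), 0.05, seed=3)
    back = RodScan.from_frame(scan.to_frame(), theta=scan.theta, D=scan.D)
    np.testing.assert_allclose(back.pa, scan.pa)
    np.testing.assert_allclose(back.us, scan.us)
    np.testing.assert_allclose(back.rods.depths, scan.rods.depths)
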