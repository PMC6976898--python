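"""Transport engine: analytic oracles, conservation, sampling statistics."""

import math

import numpy as np
import pytest

from palight.mc_engine import (
    PhotonState,
    mirror_average,
    roulette,
    run,
    run_reference,
    sample_hg,
    step_and_tally,
)
from palight.scene import make_source

from conftest import homogeneous_scene


def test_beer_lambert_in_pure_absorber():
    """With no scattering, the per-layer energy flow must follow exp(-mu_a z).

    The continuous-absorption estimator makes this exact (zero variance), so
    the check is at floating-point precision, well inside the 1% bound that
    a collision-based estimator would need 1e6 photons to reach.
    """
    mu_a = 0.1
    pitch = 0.3
    scene = homogeneous_scene(mu_a=mu_a, mu_s=0.0, side=24.0, pitch=pitch)
    src = make_source(D=4.0, theta=0.0, n_photons=1000, seed=1, length=10.0)
    grid = run(scene, src)
    # total tallied fluence * voxel volume per layer = analytic layer integral
    layer_energy = grid.values.sum(axis=(0, 1)) * pitch**3
    z_edges = np.arange(grid.values.shape[2] + 1) * pitch
    analytic = (np.exp(-mu_a * z_edges[:-1]) - np.exp(-mu_a * z_edges[1:])) / mu_a
    np.testing.assert_allclose(layer_energy, analytic, rtol=1e-9)


def test_conservation_closes_with_scattering(small_fibrous_scene):
    src = make_source(D=7.0, theta=45.0, n_photons=20000, seed=11)
    grid = run(small_fibrous_scene, src)
    assert grid.conservation_error() < 1e-6
    assert grid.ledger["absorbed"] > 0
    assert grid.ledger["escaped"] > 0


def test_no_absorber_means_no_absorption():
    scene = homogeneous_scene(mu_a=0.0, mu_s=1.0, g=0.5, side=24.0, pitch=0.6)
    src = make_source(D=4.0, theta=30.0, n_photons=5000, seed=2, length=10.0)
    grid = run(scene, src)
    assert grid.ledger["absorbed"] == 0.0
    # everything escapes (roulette never fires: weight never drops)
    assert grid.ledger["escaped"] == pytest.approx(5000, rel=1e-12)
    assert (grid.values >= 0).all()


def test_absorbed_ledger_equals_mu_a_weighted_tally(small_fibrous_scene):
    """The two energy estimators (ledger vs mu_a * fluence * volume) coincide
    identically under the exponentially weighted track-length tally."""
    src = make_source(D=7.0, theta=45.0, n_photons=5000, seed=5)
    grid = run(small_fibrous_scene, src)
    mu_a = np.array([p.mu_a for p in small_fibrous_scene.palette])
    n_ph = grid.ledger["launched"]
    total = (grid.values * mu_a[small_fibrous_scene.labels]).sum() \
        * grid.voxel_volume * n_ph
    assert total == pytest.approx(grid.ledger["absorbed"], rel=1e-9)


def test_seeded_runs_are_bit_identical(small_fibrous_scene):
    src = make_source(D=7.0, theta=45.0, n_photons=3000, seed=42)
    g1 = run(small_fibrous_scene, src)
    g2 = run(small_fibrous_scene, src)
    assert np.array_equal(g1.values, g2.values)
    assert g1.ledger == g2.ledger
    g3 = run(small_fibrous_scene,
             make_source(D=7.0, theta=45.0, n_photons=3000, seed=43))
    assert not np.array_equal(g1.values, g3.values)


@pytest.mark.parametrize("g", [0.0, 0.7, 0.9])
def test_hg_sample_mean_is_g(g):
    rng = np.random.default_rng(123)
    n = 200_000
    ct = sample_hg(g, rng, size=n)
    se = ct.std(ddof=1) / math.sqrt(n)
    assert abs(ct.mean() - g) < 3 * se + 1e-12
    assert ct.min() >= -1 and ct.max() <= 1


def test_mean_scattering_free_path_matches_mu_s():
    """In a homogeneous medium the hop length between scattering events is
    exponential against the scattering coefficient (absorption is handled
    continuously, not by shortening the hop)."""
    mu_s = 2.0
    scene = homogeneous_scene(mu_a=0.05, mu_s=mu_s, g=0.0,
                              side=400.0, pitch=400.0)
    rng = np.random.default_rng(7)
    state = PhotonState(np.array([200.0, 200.0, 200.0]),
                        np.array([0.0, 0.0, 1.0]), 1.0)
    hops = []
    for _ in range(4000):
        nxt = step_and_tally(state, scene, rng)
        if nxt is None or np.linalg.norm(nxt.position - 200.0) > 150.0:
            state = PhotonState(np.array([200.0, 200.0, 200.0]),
                                np.array([0.0, 0.0, 1.0]), 1.0)
            continue
        hops.append(float(np.linalg.norm(nxt.position - state.position)))
        state = nxt
    hops = np.array(hops)
    se = hops.std(ddof=1) / math.sqrt(len(hops))
    assert hops.mean() == pytest.approx(1.0 / mu_s, abs=4 * se)


def test_step_deposits_energy_consistently():
    """One hop in one voxel: weight loss equals mu_a times the tallied
    fluence contribution (the estimator-consistency identity)."""
    mu_a, mu_s = 0.5, 1.0
    scene = homogeneous_scene(mu_a=mu_a, mu_s=mu_s, g=0.0,
                              side=400.0, pitch=400.0)
    rng = np.random.default_rng(2)
    tally = np.zeros_like(scene.labels, dtype=float)
    state = PhotonState(np.array([200.0, 200.0, 200.0]),
                        np.array([0.0, 0.0, 1.0]), 0.8)
    nxt = step_and_tally(state, scene, rng, tally)
    assert nxt is not None
    deposited = state.weight - nxt.weight
    assert deposited == pytest.approx(mu_a * tally.sum(), rel=1e-12)


def test_roulette_unbiased_and_idempotent_above_threshold():
    rng = np.random.default_rng(0)
    heavy = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.5)
    assert roulette(heavy, rng) is heavy

    w0 = 5e-5
    outcomes = []
    for _ in range(20000):
        light = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), w0)
        survived = roulette(light, rng)
        outcomes.append(0.0 if survived is None else survived.weight)
    outcomes = np.array(outcomes)
    se = outcomes.std(ddof=1) / math.sqrt(len(outcomes))
    assert outcomes.mean() == pytest.approx(w0, abs=3 * se)
    alive = outcomes[outcomes > 0]
    assert np.allclose(alive, w0 / 0.1)


def test_mirror_average_properties(small_fibrous_scene):
    src = make_source(D=7.0, theta=45.0, n_photons=3000, seed=9)
    grid = run(small_fibrous_scene, src)
    m1 = mirror_average(grid)
    # volume integral preserved; idempotent; symmetric fixed point
    assert m1.values.sum() == pytest.approx(grid.values.sum(), rel=1e-12)
    m2 = mirror_average(m1)
    np.testing.assert_allclose(m2.values, m1.values, rtol=1e-12)
    np.testing.assert_allclose(m1.values, m1.values[::-1], rtol=1e-12)


def test_mirror_average_rejects_odd_axis():
    from palight.mc_engine import FluenceGrid

    odd = FluenceGrid(values=np.zeros((3, 4, 4)), pitch=1.0,
                      ledger={"launched": 1.0, "absorbed": 0, "escaped": 1,
                              "roulette_net": 0, "residual": 0})
    with pytest.raises(ValueError, match="even"):
        mirror_average(odd)


def test_reference_engine_agrees_with_kernel():
    """The pure-Python engine and the compiled kernel implement the same
    transport rules; their depth-resolved energy flow must agree within
    Monte Carlo error on a small scattering scene."""
    scene = homogeneous_scene(mu_a=0.05, mu_s=1.0, g=0.7, side=12.0, pitch=0.6)
    src_ref = make_source(D=2.0, theta=30.0, n_photons=400, seed=21,
                          length=6.0, width=1.0)
    src_fast = make_source(D=2.0, theta=30.0, n_photons=200_000, seed=21,
                           length=6.0, width=1.0)
    ref = run_reference(scene, src_ref)
    fast = run(scene, src_fast)
    assert ref.conservation_error() < 1e-9
    prof_ref = ref.values.mean(axis=(0, 1))
    prof_fast = fast.values.mean(axis=(0, 1))
    # few-percent agreement on the first layers, where statistics are dense
    np.testing.assert_allclose(prof_ref[:8], prof_fast[:8], rtol=0.15)
    frac_ref = ref.ledger["absorbed"] / ref.ledger["launched"]
    frac_fast = fast.ledger["absorbed"] / fast.ledger["launched"]
    assert frac_ref == pytest.approx(frac_fast, rel=0.1)
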