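"""Monte-Carlo transport: conservation, scaling laws, physics cross-checks."""

import numpy as np
import pytest

from sfdiml import (
    MCConfig,
    OpticalProperties,
    RadialPathHistogram,
    apply_absorption,
    diffusion_rd,
    mc_forward,
    project_to_frequency,
    run_white_mc,
)

from _oracle import oracle_estimate

PHANTOM = OpticalProperties(0.0117, 1.0827)


def test_zero_photons_gives_empty_histogram():
    hist = run_white_mc(MCConfig(n_photons=0))
    assert hist.launched_weight == 0.0
    assert hist.absorbed_or_lost_weight == 0.0
    assert np.all(hist.weights == 0.0)


@pytest.mark.parametrize("photons,seed", [(2_000, 0), (30_000, 3)])
def test_energy_conservation(photons, seed):
    """Launched weight equals exited plus absorbed/lost to < 1e-9 relative."""
    hist = run_white_mc(MCConfig(n_photons=photons, rng_seed=seed))
    assert hist.conservation_error() < 1e-9


def test_session_histogram_conserves_energy(white_hist):
    assert white_hist.conservation_error() < 1e-9


@pytest.mark.parametrize(
    "kwargs",
    [
        {"anisotropy_g": 1.0},
        {"anisotropy_g": -0.1},
        {"n_inside": 0.9},
        {"n_photons": -1},
        {"min_radius": -1.0},
    ],
)
def test_nonphysical_config_rejected(kwargs):
    with pytest.raises(ValueError):
        MCConfig(**kwargs)


def test_absorption_identity_at_zero_mu_a(white_hist):
    """mu_a=0 at the reference scattering reproduces the raw radial marginal."""
    cfg = white_hist.config
    profile = apply_absorption(
        white_hist, OpticalProperties(0.0, cfg.reference_mu_s_prime)
    )
    marginal = white_hist.weights.sum(axis=1) / white_hist.launched_weight
    np.testing.assert_allclose(
        profile.reflectance * profile.bin_areas, marginal, rtol=1e-12
    )
    assert np.all(profile.reflectance >= 0.0)
    assert 0.0 <= profile.total_reflectance <= 1.0


def test_doubling_absorption_never_increases_reflectance(white_hist):
    rng = np.random.default_rng(7)
    for _ in range(20):
        mu_a = rng.uniform(0.0, 1.0)
        mu_sp = rng.uniform(0.05, 15.0)
        r1 = apply_absorption(white_hist, OpticalProperties(mu_a, mu_sp))
        r2 = apply_absorption(white_hist, OpticalProperties(2 * mu_a, mu_sp))
        assert r2.total_reflectance <= r1.total_reflectance + 1e-15


def test_nonpositive_scattering_rejected(white_hist):
    with pytest.raises(ValueError):
        OpticalProperties(0.1, 0.0)


def test_projection_at_zero_frequency_is_total_reflectance(white_hist):
    profile = apply_absorption(white_hist, PHANTOM)
    assert project_to_frequency(profile, 0.0) == profile.total_reflectance
    with pytest.raises(ValueError):
        project_to_frequency(profile, -0.1)


def test_point_response_is_flat_in_frequency(white_hist):
    """All weight in the innermost bin transforms to ~constant Rd(fx)."""
    from sfdiml.mc_transport import RadialReflectanceProfile

    edges = white_hist.radial_edges
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    refl = np.zeros(areas.size)
    refl[0] = 0.5 / areas[0]
    profile = RadialReflectanceProfile(
        reflectance=refl, radial_edges=edges, total_reflectance=0.5
    )
    for fx in (0.0, 0.1, 0.5, 1.0):
        assert project_to_frequency(profile, fx) == pytest.approx(0.5, rel=1e-3)


def test_rd_nonincreasing_in_frequency(white_hist):
    rng = np.random.default_rng(11)
    fx_grid = np.linspace(0.0, 0.5, 11)
    for _ in range(8):
        props = OpticalProperties(rng.uniform(0, 2), rng.uniform(0.05, 15))
        rd = mc_forward(props, fx_grid, white_hist)
        assert np.all(np.diff(rd) <= 1e-12)


def test_high_frequency_reflectance_below_planar(mc_fwd, rng):
    mu_a = rng.uniform(0.0, 2.0, 300)
    mu_sp = rng.uniform(0.01, 15.0, 300)
    r0, rn = mc_fwd.reflectance_pairs(mu_a, mu_sp)
    assert np.all(rn <= r0)
    assert np.all(r0 <= 1.0) and np.all(rn >= 0.0)


def test_reflectance_surface_monotone_in_mu_a(mc_fwd):
    """Rd decreases strictly with absorption along every mu_s' column."""
    mu_a_axis = np.linspace(0.0, 2.0, 20)
    mu_sp_axis = np.linspace(0.01, 15.0, 20)
    aa, ss = np.meshgrid(mu_a_axis, mu_sp_axis, indexing="ij")
    r0, rn = mc_fwd.reflectance_pairs(aa.ravel(), ss.ravel())
    r0 = r0.reshape(20, 20)
    rn = rn.reshape(20, 20)
    assert np.all(np.diff(r0, axis=0) < 0)
    assert np.all(np.diff(rn, axis=0) < 0)
    # and increases with scattering once absorption is present
    assert np.all(np.diff(r0[1:], axis=1) > 0)


def test_similarity_scaling_identity(white_hist):
    """Scaling (mu_a, mu_s') by c equals scaling fx by c, by construction."""
    for c in (2.0, 0.5):
        for mu_a, mu_sp, fx in [(0.05, 1.2, 0.2), (0.3, 4.0, 0.1)]:
            rd_scaled = mc_forward(
                OpticalProperties(c * mu_a, c * mu_sp), [c * fx], white_hist
            )[0]
            rd_base = mc_forward(OpticalProperties(mu_a, mu_sp), [fx], white_hist)[0]
            assert rd_scaled == pytest.approx(rd_base, rel=1e-9)


def test_total_reflectance_close_to_diffusion_for_phantom(white_hist):
    """Planar diffuse reflectance agrees with the diffusion closed form."""
    rd0 = mc_forward(PHANTOM, [0.0], white_hist)[0]
    assert rd0 == pytest.approx(diffusion_rd(PHANTOM, fx=0.0), rel=0.10)


@pytest.mark.parametrize("props", [(0.01, 1.0), (0.03, 3.0), (0.1, 10.0)])
@pytest.mark.parametrize("fx", [0.0, 0.2])
def test_diffusive_regime_agrees_with_diffusion(white_hist, props, fx):
    """MC and diffusion agree within 15% where mu_s'/mu_a >= 100, fx <= 0.2."""
    p = OpticalProperties(*props)
    rd_mc = mc_forward(p, [fx], white_hist)[0]
    assert rd_mc == pytest.approx(diffusion_rd(p, fx=fx), rel=0.15)


def test_anisotropy_insensitivity_of_planar_reflectance():
    """Under similarity, Rd(fx=0) barely depends on the phase function."""
    rd = {}
    for g in (0.0, 0.9):
        hist = run_white_mc(
            MCConfig(n_photons=150_000, anisotropy_g=g, rng_seed=13)
        )
        rd[g] = mc_forward(PHANTOM, [0.0], hist)[0]
    assert rd[0.9] == pytest.approx(rd[0.0], rel=0.03)


def test_against_explicit_absorption_oracle(white_hist):
    """White-MC rescaling matches a from-scratch MC with in-walk absorption.

    The oracle applies absorption as an albedo weight at every interaction
    and projects to fx by weighting exit events with cos(2*pi*fx*x); the
    package obtains the same quantities from the scattering-only histogram.
    """
    mu_a, mu_sp = 0.1, 1.0
    cfg = white_hist.config
    r0_o, se0, rn_o, sen = oracle_estimate(
        150_000, mu_a, mu_sp, cfg.anisotropy_g, cfg.n_inside, 0.2, seed=21
    )
    rd = mc_forward(OpticalProperties(mu_a, mu_sp), [0.0, 0.2], white_hist)
    # allow 3 sigma of oracle counting error plus the white run's own noise
    tol0 = 3.0 * se0 + 0.01 * r0_o
    toln = 3.0 * sen + 0.01 * rn_o
    assert abs(rd[0] - r0_o) < tol0
    assert abs(rd[1] - rn_o) < toln


def test_histogram_hdf5_round_trip(tmp_path):
    hist = run_white_mc(MCConfig(n_photons=5_000, rng_seed=2))
    path = tmp_path / "hist.h5"
    hist.to_hdf5(path)
    back = RadialPathHistogram.from_hdf5(path)
    np.testing.assert_array_equal(back.weights, hist.weights)
    np.testing.assert_array_equal(back.radial_edges, hist.radial_edges)
    np.testing.assert_array_equal(back.path_edges, hist.path_edges)
    assert back.launched_weight == hist.launched_weight
    assert back.absorbed_or_lost_weight == hist.absorbed_or_lost_weight
    assert back.config == hist.config


def test_white_mc_reproducible_at_fixed_seed():
    a = run_white_mc(MCConfig(n_photons=20_000, rng_seed=9))
    b = run_white_mc(MCConfig(n_photons=20_000, rng_seed=9))
    np.testing.assert_array_equal(a.weights, b.weights)
    assert a.absorbed_or_lost_weight == b.absorbed_or_lost_weight
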