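import warnings

import numpy as np
import pytest
from scipy.special import k0

from dartdose.dl_solver import (
    DLParameters,
    FieldState,
    RadialProfile,
    SeedGeometry,
    chain_energy_constants,
    combine_dose_grids,
    derived_coefficients,
    dose_rate_fields,
    grid_cell_volumes,
    isodose_radius,
    make_grid,
    profile_ratio,
    radial_profile,
    solve_dl,
    solve_rn_steady,
)
from dartdose.errors import ConfigurationError, InvalidInputError, NoCrossingError


def coarse_params(**overrides):
    base = dict(
        pdes_rn=0.5, pdes_pb=0.7, l_pb_mm=0.6,
        duration_days=5.0, beta_mode="local",
    )
    base.update(overrides)
    return DLParameters(**base)


def coarse_solve(p, dt_min=60.0, dr=100.0, lengths=10.0, **kwargs):
    grid = make_grid(p, SeedGeometry(), dr_um=dr, dz_um=dr, domain_lengths=lengths)
    return solve_dl(p, SeedGeometry(), grid, dt_pb_minutes=dt_min, **kwargs)


def test_chain_energy_constants(chain):
    c = chain_energy_constants(chain)
    # Rn-220 + Po-216 alpha energies; Bi-212 branch-weighted alpha energy.
    assert c["alpha_per_rn"] == pytest.approx(13.066, abs=0.01)
    assert c["alpha_per_pb"] == pytest.approx(7.80, abs=0.01)
    assert 0.5 < c["beta_per_pb"] < 1.1


def test_derived_coefficients():
    lam_pb = np.log(2.0) / 38304.0
    d_rn, d_pb, alpha_pb = derived_coefficients(DLParameters(pdes_rn=0.5, pdes_pb=0.7))
    assert alpha_pb == pytest.approx(lam_pb, rel=1e-9)  # leak = 0.5
    assert d_rn == pytest.approx(2.0e-9, rel=1e-2)  # L_Rn = 0.4 mm
    d_rn0, d_pb0, alpha0 = derived_coefficients(
        DLParameters(pdes_rn=0.5, pdes_pb=0.7, leak_prob_pb=0.0)
    )
    assert alpha0 == 0.0
    assert d_pb0 == pytest.approx((0.6e-3) ** 2 * lam_pb, rel=1e-9)
    with pytest.raises(InvalidInputError):
        DLParameters(pdes_rn=0.5, pdes_pb=0.7, leak_prob_pb=1.0)


def test_rn_field_matches_line_source_k0():
    """Mid-plane quasi-static Rn vs the infinite-line K0(r/L) solution."""
    p = DLParameters(pdes_rn=0.5, pdes_pb=0.7)
    n_hat, grid = solve_rn_steady(p)
    r = grid.r_mm
    mid = np.argmin(np.abs(grid.z_mm))
    profile = n_hat[:, mid]
    dr_mm = grid.dr_um * 1e-3
    sel = (r >= r[0] + 2 * dr_mm - 1e-9) & (r <= 5 * p.l_rn_mm + 1e-9)
    reference = k0(r[sel] / p.l_rn_mm)
    ratio = profile[sel] / reference
    assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 0.02


def test_rn_atom_bookkeeping():
    """Total Rn atoms ≈ release rate / λ_Rn (boundary losses < 2 %)."""
    p = DLParameters(pdes_rn=0.5, pdes_pb=0.7)
    n_hat, grid = solve_rn_steady(p)
    total = float((n_hat * grid_cell_volumes(grid)).sum())
    lam_rn = np.log(2.0) / 55.6
    expected = p.pdes_rn * p.a0_bq / lam_rn
    assert total == pytest.approx(expected, rel=0.02)


def test_point_source_limit():
    """A degenerate short seed approaches the spherical exp(−ρ/L)/ρ field."""
    p = DLParameters(pdes_rn=0.5, pdes_pb=0.7)
    seed = SeedGeometry(outer_radius_mm=0.05, length_mm=0.1)
    grid = make_grid(p, seed, dr_um=50.0, dz_um=50.0, domain_lengths=8.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ops_field, _ = solve_rn_steady(p, seed, grid)
    r = grid.r_mm
    mid = np.argmin(np.abs(grid.z_mm))
    sel = (r >= 0.4) & (r <= 1.6)  # several source radii to 4 L
    reference = np.exp(-r[sel] / p.l_rn_mm) / r[sel]
    ratio = ops_field[sel, mid] / reference
    assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 0.05


def test_zero_desorption_zero_dose():
    dose = coarse_solve(coarse_params(pdes_rn=0.0, pdes_pb=0.0))
    assert np.all(dose.dose_total_gy == 0.0)


def test_dose_linear_in_activity_and_channels():
    base = coarse_solve(coarse_params())
    doubled = coarse_solve(coarse_params(a0_bq=2 * 1.11e5))
    assert np.allclose(doubled.dose_total_gy, 2 * base.dose_total_gy, rtol=1e-9)

    rn_unit = coarse_solve(coarse_params(pdes_rn=1.0, pdes_pb=1.0))
    pb_unit = coarse_solve(coarse_params(pdes_rn=0.0, pdes_pb=1.0))
    combo = combine_dose_grids([rn_unit, pb_unit], [0.5, 0.2])
    assert np.allclose(combo.dose_total_gy, base.dose_total_gy, rtol=1e-8, atol=1e-12)


def test_profile_mirror_symmetry():
    dose = coarse_solve(coarse_params())
    up = radial_profile(dose, 1.0)
    down = radial_profile(dose, -1.0)
    assert np.allclose(up.dose_gy, down.dose_gy, rtol=1e-8)


def test_profile_monotone_decreasing_outside_seed():
    dose = coarse_solve(coarse_params())
    prof = radial_profile(dose, 0.0)
    assert np.all(np.diff(prof.dose_gy) <= 1e-12 * prof.dose_gy.max())
    with pytest.raises(InvalidInputError):
        radial_profile(dose, 1e3)


def test_dose_monotone_in_time():
    dose = coarse_solve(coarse_params(), snapshot_every=20)
    previous = None
    for _, snap in dose.snapshots:
        if previous is not None:
            assert np.all(snap >= previous - 1e-12)
        previous = snap


def test_isodose_radius_interpolation_and_errors():
    radii = np.array([0.35, 1.0, 2.0, 3.0])
    prof = RadialProfile(radii_mm=radii, dose_gy=np.array([1e3, 1e2, 10.0, 1.0]),
                         z_plane_mm=0.0)
    # Node-exact level.
    assert isodose_radius(prof, 10.0) == pytest.approx(2.0)
    # Log-linear between nodes: halfway in log space.
    r = isodose_radius(prof, np.sqrt(10.0 * 1.0))
    assert r == pytest.approx(2.5, abs=1e-9)
    with pytest.raises(NoCrossingError):
        isodose_radius(prof, 1e6)
    with pytest.raises(NoCrossingError):
        isodose_radius(prof, 0.1)


def test_profile_ratio_properties():
    radii = np.linspace(0.35, 3.0, 30)
    dose = np.exp(-radii)
    a = RadialProfile(radii_mm=radii, dose_gy=dose, z_plane_mm=0.0)
    unity = profile_ratio(a, a)
    assert np.allclose(unity.dose_gy, 1.0)
    doubled = RadialProfile(radii_mm=radii, dose_gy=2 * dose, z_plane_mm=0.0)
    assert np.allclose(profile_ratio(doubled, a).dose_gy, 2.0)
    with pytest.raises(InvalidInputError):
        profile_ratio(
            a, RadialProfile(radii_mm=radii + 10.0, dose_gy=dose, z_plane_mm=0.0)
        )


def test_lower_desorption_lowers_dose_pointwise():
    rn_unit = coarse_solve(coarse_params(pdes_rn=1.0, pdes_pb=1.0))
    pb_unit = coarse_solve(coarse_params(pdes_rn=0.0, pdes_pb=1.0))
    deep = combine_dose_grids([rn_unit, pb_unit], [0.11, 0.36 - 0.11])
    shallow = combine_dose_grids([rn_unit, pb_unit], [0.50, 0.71 - 0.50])
    ratio = profile_ratio(radial_profile(deep, 0.0), radial_profile(shallow, 0.0))
    finite = np.isfinite(ratio.dose_gy)  # outer Dirichlet node is 0/0
    assert finite.sum() > 0.9 * ratio.dose_gy.size
    assert np.all(ratio.dose_gy[finite] < 1.0)


def test_grid_convergence_of_isodose_radius():
    """Halving dr, dz, and dt moves the 10-Gy radius by < 1 %."""
    p = coarse_params()
    coarse = coarse_solve(p, dt_min=60.0, dr=100.0)
    fine = coarse_solve(p, dt_min=30.0, dr=50.0)
    r_coarse = isodose_radius(radial_profile(coarse, 0.0), 10.0)
    r_fine = isodose_radius(radial_profile(fine, 0.0), 10.0)
    assert abs(r_fine / r_coarse - 1.0) < 0.01


def test_beta_kernel_conserves_energy():
    """Kernel smearing redistributes but conserves the beta energy that the
    local mode deposits (up to outer-boundary leakage)."""
    p_local = coarse_params(beta_mode="local")
    p_kernel = coarse_params(beta_mode="kernel")
    local = coarse_solve(p_local)
    kernel = coarse_solve(p_kernel)
    volumes = grid_cell_volumes(local.grid)
    e_local = float((local.dose_beta_gy * volumes).sum())
    e_kernel = float((kernel.dose_beta_gy * volumes).sum())
    assert e_kernel == pytest.approx(e_local, rel=0.03)
    off = coarse_solve(coarse_params(beta_mode="off"))
    assert np.all(off.dose_beta_gy == 0.0)


def test_dose_rate_fields_zero_and_modes():
    p = coarse_params()
    shape = (4, 5)
    state = FieldState(n_rn=np.zeros(shape), n_pb=np.zeros(shape))
    alpha, beta = dose_rate_fields(state, p)
    assert np.all(alpha == 0.0) and np.all(beta == 0.0)
    state = FieldState(n_rn=np.ones(shape), n_pb=np.ones(shape))
    with pytest.raises(ConfigurationError):
        dose_rate_fields(state, coarse_params(beta_mode="kernel"))  # no grid
    with pytest.raises(InvalidInputError):
        FieldState(n_rn=-np.ones(shape), n_pb=np.zeros(shape))


def test_under_resolved_grid_rejected():
    p = coarse_params(l_pb_mm=0.1)
    grid = make_grid(p, SeedGeometry(), dr_um=100.0, dz_um=100.0)
    with pytest.raises(ConfigurationError):
        solve_dl(p, SeedGeometry(), grid)
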