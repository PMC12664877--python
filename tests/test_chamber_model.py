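import numpy as np
import pytest

from dartdose.chamber_model import (
    ChamberGeometry,
    CorrectionFactors,
    DepositResult,
    LineDeposit,
    emission_inventory,
    k_window,
    min_activity_for_signal,
    sensitivity_study,
    signal_current,
    trace_particles,
)
from dartdose.dl_solver import MEV_TO_J, SeedGeometry
from dartdose.errors import (
    ConfigurationError,
    ExtrapolationError,
    InvalidInputError,
)
from dartdose.recoil_desorption import CascadeResult, SlabSource, SpectrumCounts, simulate_cascade


def make_cascade(pdes_rn, pdes_po, pdes_pb, depth=0.0):
    return CascadeResult(
        p_des={"Rn-220": pdes_rn, "Po-216": pdes_po, "Pb-212": pdes_pb},
        p_des_stderr={"Rn-220": 0.0, "Po-216": 0.0, "Pb-212": 0.0},
        emission_counts=SpectrumCounts(counts={}, histories=0),
        n_histories=0,
        depth_nm=depth,
    )


# ---------------------------------------------------------------- stopping


def test_stopping_tables_physical_anchors(tables):
    """CSDA range of a 5.49 MeV alpha in air is the classic ~4 cm; electron
    collision stopping in air at 1 MeV is ~1.66 MeV·cm²/g."""
    air_alpha = tables[("air", "alpha")]
    range_cm = air_alpha.csda_range(5.49) / 1.196e-3
    assert 3.2 < range_cm < 4.8
    air_e = tables[("air", "electron")]
    assert float(air_e(1.0)) == pytest.approx(1.661, rel=0.05)
    # Alpha stopping decreases with energy over the plateau region.
    energies = np.linspace(2.0, 9.0, 30)
    assert np.all(np.diff(air_alpha(energies)) < 0)


def test_csda_additivity(tables):
    """Splitting a path in two gives the same residual energy (the energy-
    conservation backbone of the ray trace)."""
    table = tables[("mylar", "alpha")]
    e0 = 6.0
    for p1, p2 in [(1e-4, 2e-4), (1e-3, 5e-4), (2e-3, 2e-3)]:
        direct = table.energy_after(e0, p1 + p2)
        chained = table.energy_after(table.energy_after(e0, p1), p2)
        assert float(chained) == pytest.approx(float(direct), rel=1e-3, abs=1e-6)
    assert float(table.energy_after(e0, 0.0)) == pytest.approx(e0, rel=1e-9)
    assert float(table.energy_after(e0, 1e3)) == 0.0


# ---------------------------------------------------------------- inventory


def test_inventory_full_retention_gives_four_alphas(chain):
    """Every decay path Ra→Pb-208 has exactly 4 alpha decays (5 possible
    emitters, branch-split at Bi-212)."""
    inv = emission_inventory(make_cascade(0.0, 0.0, 0.0), chain)
    assert inv.alpha_rate_per_decay == pytest.approx(4.0, abs=1e-6)
    assert inv.beta_rate_per_decay == pytest.approx(2.0, abs=1e-6)


def test_inventory_full_desorption_leaves_only_radium(chain):
    inv = emission_inventory(make_cascade(1.0, 1.0, 1.0), chain)
    assert inv.alpha_rate_per_decay == pytest.approx(1.0, abs=1e-6)
    assert all(l.nuclide == "Ra-224" for l in inv.lines if l.rate_per_decay > 0)


def test_inventory_retention_arithmetic(chain):
    cascade = simulate_cascade(SlabSource(depth_nm=0.0, n_histories=100_000, rng_seed=9))
    inv = emission_inventory(cascade, chain)
    expected = (
        1.0
        + (1.0 - cascade.pdes_rn)
        + (1.0 - cascade.pdes_po)
        + (1.0 - cascade.pdes_pb)
    )
    assert inv.alpha_rate_per_decay == pytest.approx(expected, abs=1e-6)


def test_inventory_missing_progeny_rejected(chain):
    bad = CascadeResult(
        p_des={"Rn-220": 0.5},
        p_des_stderr={"Rn-220": 0.0},
        emission_counts=SpectrumCounts(counts={}, histories=0),
        n_histories=0,
        depth_nm=0.0,
    )
    with pytest.raises(ConfigurationError):
        emission_inventory(bad, chain)


# ---------------------------------------------------------------- transport


def test_trace_deterministic_and_positive(chain, tables):
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    geo = ChamberGeometry()
    a = trace_particles(inv, geo, tables=tables, n_histories=50_000, rng_seed=5)
    b = trace_particles(inv, geo, tables=tables, n_histories=50_000, rng_seed=5)
    assert a.eps_alpha_mev == b.eps_alpha_mev
    assert a.eps_alpha_mev > 0
    assert all(d.mean_mev >= 0 for d in a.per_line.values())


def test_mc_error_shrinks_with_histories(chain, tables):
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    geo = ChamberGeometry()
    small = trace_particles(inv, geo, tables=tables, n_histories=20_000, rng_seed=3)
    large = trace_particles(inv, geo, tables=tables, n_histories=80_000, rng_seed=3)
    assert large.eps_alpha_stderr_mev == pytest.approx(
        small.eps_alpha_stderr_mev / 2.0, rel=0.3
    )


def test_vanishing_cavity_deposit(chain, tables):
    """With a near-vacuum cavity and no window nothing deposits."""
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    geo = ChamberGeometry(window_thickness_um=0.0, air_density_kg_m3=1e-12)
    deposits = trace_particles(inv, geo, tables=tables, n_histories=20_000, rng_seed=1)
    assert deposits.eps_total_mev < 1e-9


def test_window_attenuation_magnitude(tables):
    """Normal-incidence 6 MeV alpha loses ~0.3 MeV in 3 µm of mylar
    (3e-4 cm × 1.40 g/cm³ × S(6 MeV) with S ≈ 700–800 MeV·cm²/g)."""
    table = tables[("mylar", "alpha")]
    path = 3e-4 * 1.40
    loss = 6.0 - float(table.energy_after(6.0, path))
    s_mid = float(table(6.0))
    assert loss == pytest.approx(path * s_mid, rel=0.05)
    assert 0.2 < loss < 0.45


# ---------------------------------------------------------------- signal


def unit_deposit(eps_alpha_mev, eps_beta_mev=0.0):
    return DepositResult(
        per_line={}, eps_alpha_mev=eps_alpha_mev, eps_beta_mev=eps_beta_mev,
        eps_alpha_stderr_mev=0.0, eps_beta_stderr_mev=0.0,
    )


def test_signal_current_arithmetic():
    """An all-alpha energy deposition rate of 2.45e-10 J/s gives
    I = 2.45e-10/34.96 ≈ 7.0 pA, and SNR = 350 at 0.02 pA leakage."""
    a0 = 1.11e5
    eps_mev = 2.45e-10 / a0 / MEV_TO_J
    result = signal_current(unit_deposit(eps_mev), ChamberGeometry(), a0_bq=a0)
    assert result.current_a == pytest.approx(7.0e-12, rel=2e-3)
    assert result.snr == pytest.approx(350.0, rel=2e-3)
    assert result.k_mc_alpha == 1.0


def test_current_linear_in_activity():
    result_1 = signal_current(unit_deposit(0.01), ChamberGeometry(), a0_bq=1.11e5)
    result_2 = signal_current(unit_deposit(0.01), ChamberGeometry(), a0_bq=2.22e5)
    assert result_2.current_a == pytest.approx(2 * result_1.current_a, rel=1e-12)
    with pytest.raises(InvalidInputError):
        signal_current(unit_deposit(0.01), ChamberGeometry(), a0_bq=-1.0)


def test_kmc_weights_sum_to_one():
    result = signal_current(unit_deposit(0.01, 0.002), ChamberGeometry())
    assert result.k_mc_alpha + result.k_mc_beta == pytest.approx(1.0, abs=1e-12)
    assert result.k_mc_beta == pytest.approx(1.0 / 6.0, rel=1e-9)


def test_correction_factor_invariants():
    with pytest.raises(InvalidInputError):
        CorrectionFactors(k_window=0.5)
    defaults = CorrectionFactors()
    assert defaults.k_tp == defaults.k_ion == defaults.k_pol == defaults.k_elec == 1.0


# ---------------------------------------------------------------- k_window


def test_k_window_identity_without_window(chain, tables):
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    geo = ChamberGeometry(window_thickness_um=0.0)
    value, err = k_window(inv, geo, tables=tables, n_histories=20_000, rng_seed=2)
    assert value == 1.0
    assert err == 0.0


def test_k_window_below_one_and_monotone_in_thickness(chain, tables):
    """The window softens the spectrum into a higher-stopping-power region,
    so k_window < 1 and thicker windows push it further down."""
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    thin, err_thin = k_window(
        inv, ChamberGeometry(window_thickness_um=3.0), tables=tables,
        n_histories=150_000, rng_seed=8,
    )
    thick, _ = k_window(
        inv, ChamberGeometry(window_thickness_um=10.0), tables=tables,
        n_histories=150_000, rng_seed=8,
    )
    assert thin < 1.0 - 3 * err_thin
    assert thick < thin


# ---------------------------------------------------------------- sweep


def test_sensitivity_requires_three_points(chain, tables):
    with pytest.raises(InvalidInputError):
        sensitivity_study([make_cascade(0.5, 0.6, 0.7)] * 2, ChamberGeometry(),
                          tables=tables)


def test_signal_decreases_with_desorption(chain, tables):
    cascades = [
        make_cascade(0.1, 0.25, 0.35, depth=14.0),
        make_cascade(0.3, 0.45, 0.55, depth=6.0),
        make_cascade(0.5, 0.64, 0.71, depth=0.0),
    ]
    study = sensitivity_study(
        cascades, ChamberGeometry(), tables=tables,
        n_histories=60_000, rng_seed=6,
    )
    currents = study["table"].sort_values("pdes_rn")["current_pa"].to_numpy()
    assert np.all(np.diff(currents) < 0)
    assert study["slope_a_per_pdes"] < 0
    assert study["r_squared"] > 0.98


def test_min_activity_scaling():
    pdes = [0.1, 0.3, 0.5]
    current = [10e-12, 8e-12, 6e-12]
    a0 = 1.11e5
    base = min_activity_for_signal(1e-12, 0.3, pdes, current, a0)
    assert base == pytest.approx(1e-12 / (8e-12 / a0))
    assert min_activity_for_signal(2e-12, 0.3, pdes, current, a0) == pytest.approx(
        2 * base
    )
    # Threshold equal to the achieved current returns the sweep activity.
    assert min_activity_for_signal(8e-12, 0.3, pdes, current, a0) == pytest.approx(a0)
    with pytest.raises(ExtrapolationError):
        min_activity_for_signal(1e-12, 0.9, pdes, current, a0)
    with pytest.raises(InvalidInputError):
        min_activity_for_signal(-1.0, 0.3, pdes, current, a0)


def test_cavity_radius_must_cover_seed(chain, tables):
    inv = emission_inventory(make_cascade(0.5, 0.64, 0.7), chain)
    geo = ChamberGeometry(cavity_radius_cm=0.3, aperture_radius_cm=0.3)
    with pytest.raises(ConfigurationError):
        trace_particles(inv, geo, SeedGeometry(), tables, n_histories=1_000)
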