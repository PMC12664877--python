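"""Ray-trace/CSDA model of the vacuum-vessel parallel-plate chamber.

The proposed source-strength standard places the DaRT seed in a small
continuously pumped vacuum vessel below a thin (3 µm) mylar window; a
windowless parallel-plate ionization chamber (2 cm diameter, 1 mm air
gap) sits against the window.  Because desorbed progeny are evacuated,
the fluence reaching the cavity comes only from decays inside the seed,
so the signal is proportional to Ra-224 activity times the *retained*
progeny inventory — which is how the measurement becomes sensitive to
the desorption probabilities.

Particles are transported as straight rays: emission points are sampled
uniformly on the seed's side surface with isotropic directions, rays into
the wire body are absorbed (the wire is convex, so a ray with an outward
component never re-enters), the vacuum region is lossless, the window
attenuates by slant-path CSDA loss, and the cavity deposit is the CSDA
loss along the chord through the air volume, capped at the remaining
energy.  Currents follow the absorbed-dose formalism
I = ε̇ / [k_MC,α(W̄/e)_α + k_MC,β(W̄/e)_β] with dose-weighted alpha/beta
fractions k_MC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .decay_chain import ChainDefinition, load_default_chain
from .dl_solver import MEV_TO_J, SeedGeometry
from .errors import (
    ConfigurationError,
    ExtrapolationError,
    InvalidInputError,
)
from .recoil_desorption import CascadeResult

__all__ = [
    "ChamberGeometry",
    "StoppingPowerTable",
    "load_stopping_tables",
    "EmissionInventory",
    "EmissionLine",
    "DepositResult",
    "SignalResult",
    "CorrectionFactors",
    "emission_inventory",
    "trace_particles",
    "signal_current",
    "k_window",
    "sensitivity_study",
    "min_activity_for_signal",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Vessel, window, and air-cavity geometry.

    ``source_window_distance_cm`` is measured from the seed *surface* to
    the window plane.  The aperture defaults to the cavity radius; the
    reference air density is 101.325 kPa at 22 °C (1.196 kg/m³).
    """

    window_thickness_um: float = 3.0
    window_material: str = "mylar"
    window_density_g_cm3: float = 1.40
    source_window_distance_cm: float = 1.0
    aperture_radius_cm: float = 1.0
    cavity_radius_cm: float = 1.0
    cavity_thickness_mm: float = 1.0
    air_density_kg_m3: float = 1.196

    def __post_init__(self) -> None:
        for name in (
            "window_density_g_cm3",
            "source_window_distance_cm",
            "aperture_radius_cm",
            "cavity_radius_cm",
            "cavity_thickness_mm",
            "air_density_kg_m3",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.window_thickness_um < 0:
            raise InvalidInputError("window thickness must be non-negative")

    @property
    def cavity_mass_kg(self) -> float:
        r = self.cavity_radius_cm * 1e-2
        length = self.cavity_thickness_mm * 1e-3
        return self.air_density_kg_m3 * math.pi * r**2 * length


class StoppingPowerTable:
    """Log-log-interpolated mass stopping power with CSDA range inversion.

    Below the tabulated minimum a particle is considered stopped and the
    remaining energy deposits locally.
    """

    def __init__(self, material: str, particle: str,
                 energy_mev: np.ndarray, stopping_mev_cm2_g: np.ndarray):
        energy = np.asarray(energy_mev, dtype=float)
        stopping = np.asarray(stopping_mev_cm2_g, dtype=float)
        if np.any(np.diff(energy) <= 0):
            raise InvalidInputError("energy grid must be strictly increasing")
        if np.any(stopping <= 0):
            raise InvalidInputError("stopping powers must be positive")
        self.material = material
        self.particle = particle
        self.energy_mev = energy
        self.stopping = stopping
        self._log_e = np.log(energy)
        self._log_s = np.log(stopping)
        # CSDA range on a fine log grid; extended to zero energy with the
        # endpoint slope so range(E→0) → 0 smoothly.
        fine = np.geomspace(energy[0], energy[-1], 2048)
        inv_s = 1.0 / self(fine)
        csda = np.concatenate(
            ([fine[0] * inv_s[0]],
             fine[0] * inv_s[0]
             + np.cumsum(0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(fine)))
        )
        self._range_e = fine
        self._range_gcm2 = csda

    def __call__(self, energy_mev) -> np.ndarray:
        e = np.clip(np.asarray(energy_mev, dtype=float),
                    self.energy_mev[0], self.energy_mev[-1])
        return np.exp(np.interp(np.log(e), self._log_e, self._log_s))

    def csda_range(self, energy_mev) -> np.ndarray:
        """Continuous-slowing-down range in g/cm² (0 below the table)."""
        e = np.asarray(energy_mev, dtype=float)
        r = np.interp(e, self._range_e, self._range_gcm2)
        return np.where(e <= self._range_e[0], e / self.stopping[0] * 0.0, r)

    def energy_after(self, energy_mev, path_g_cm2) -> np.ndarray:
        """Residual energy after traversing an areal path, 0 if stopped."""
        e0 = np.asarray(energy_mev, dtype=float)
        r0 = np.interp(e0, self._range_e, self._range_gcm2)
        r1 = r0 - np.asarray(path_g_cm2, dtype=float)
        e1 = np.interp(r1, self._range_gcm2, self._range_e)
        return np.where(r1 <= self._range_gcm2[0], 0.0, e1)


def load_stopping_tables() -> dict[tuple[str, str], StoppingPowerTable]:
    """Load the bundled synthetic stopping-power tables (see
    ``scripts/make_stopping_tables.py`` for their provenance)."""
    path = resources.files("dartdose.data").joinpath("stopping_powers_synthetic.csv")
    with path.open() as fh:
        frame = pd.read_csv(fh, comment="#")
    tables = {}
    for (material, particle), sub in frame.groupby(["material", "particle"]):
        sub = sub.sort_values("energy_mev")
        tables[(material, particle)] = StoppingPowerTable(
            material, particle,
            sub["energy_mev"].to_numpy(),
            sub["mass_stopping_mev_cm2_g"].to_numpy(),
        )
    return tables


@dataclass(frozen=True)
class EmissionLine:
    nuclide: str
    particle: str  # "alpha" | "electron"
    energy_mev: float
    rate_per_decay: float


@dataclass(frozen=True)
class EmissionInventory:
    """In-seed emission rates per Ra-224 decay at chain equilibrium."""

    lines: tuple[EmissionLine, ...]

    def __post_init__(self) -> None:
        if any(line.rate_per_decay < 0 for line in self.lines):
            raise InvalidInputError("emission rates must be non-negative")
        if self.alpha_rate_per_decay > 5.0:
            raise ConfigurationError(
                "alpha emission rate exceeds the chain maximum of 5 per decay"
            )

    @property
    def alpha_rate_per_decay(self) -> float:
        return sum(l.rate_per_decay for l in self.lines if l.particle == "alpha")

    @property
    def beta_rate_per_decay(self) -> float:
        return sum(l.rate_per_decay for l in self.lines if l.particle == "electron")


def emission_inventory(
    cascade: CascadeResult, chain: ChainDefinition | None = None
) -> EmissionInventory:
    """Retained emissions per Ra decay for an equilibrium seed.

    Retention per emitter is 1 − P_des of the mobile ancestor that sets
    whether the emitter is still inside the wall: Rn-220 and Po-216 use
    their own cascade escape fractions; Pb-212 and everything below it
    (Bi-212, Po-212, Tl-208) use P_des(Pb).  Branch fractions weight the
    Bi-212 alpha/beta split; betas are represented by their mean energies.
    """
    if chain is None:
        chain = load_default_chain()
    for needed in ("Rn-220", "Po-216", "Pb-212"):
        if needed not in cascade.p_des:
            raise ConfigurationError(f"cascade result lacks P_des for {needed}")
    retention = {
        "Ra-224": 1.0,
        "Rn-220": 1.0 - cascade.p_des["Rn-220"],
        "Po-216": 1.0 - cascade.p_des["Po-216"],
    }
    pb_ret = 1.0 - cascade.p_des["Pb-212"]
    for name in ("Pb-212", "Bi-212", "Po-212", "Tl-208"):
        retention[name] = pb_ret

    bi = chain["Bi-212"]
    branch = {d: b for _, b, d in bi.decay_modes}
    # Per-Ra-decay occupancy of each emitter at equilibrium.
    occupancy = {
        "Ra-224": 1.0, "Rn-220": 1.0, "Po-216": 1.0,
        "Pb-212": 1.0, "Bi-212": 1.0,
        "Po-212": branch["Po-212"], "Tl-208": branch["Tl-208"],
    }
    lines: list[EmissionLine] = []
    for name, occ in occupancy.items():
        spec = chain[name]
        ret = retention[name]
        for energy, intensity in spec.alpha_lines:
            lines.append(EmissionLine(name, "alpha", energy, occ * intensity * ret))
        if spec.mean_beta_energy_mev > 0:
            beta_fraction = sum(b for m, b, _ in spec.decay_modes if m == "beta")
            lines.append(
                EmissionLine(
                    name, "electron", spec.mean_beta_energy_mev,
                    occ * beta_fraction * ret,
                )
            )
    return EmissionInventory(lines=tuple(lines))


@dataclass(frozen=True)
class LineDeposit:
    """Mean cavity deposit per emitted particle of one line (MeV)."""

    mean_mev: float
    stderr_mev: float
    n_histories: int


@dataclass(frozen=True)
class DepositResult:
    """Cavity energy deposits per Ra decay, split by particle type."""

    per_line: dict[tuple[str, str, float], LineDeposit]
    eps_alpha_mev: float
    eps_beta_mev: float
    eps_alpha_stderr_mev: float
    eps_beta_stderr_mev: float

    @property
    def eps_total_mev(self) -> float:
        return self.eps_alpha_mev + self.eps_beta_mev


@dataclass(frozen=True)
class CorrectionFactors:
    """Monte-Carlo and measurement correction factors of the formalism.

    The measurement-based factors (k_tp, k_ion, k_pol, k_elec) are unity
    placeholders pending a physical instrument; k_scatter is a
    configurable constant (wall/electrode transport is out of scope),
    not a prediction of this model.
    """

    k_window: float = 1.0
    k_scatter: float = 0.985
    k_tp: float = 1.0
    k_ion: float = 1.0
    k_pol: float = 1.0
    k_elec: float = 1.0
    w_over_e_alpha: float = 34.96  # J/C
    w_over_e_beta: float = 33.97  # J/C (ICRU 90)

    def __post_init__(self) -> None:
        for name in ("k_window", "k_scatter"):
            if not (0.9 < getattr(self, name) < 1.1):
                raise InvalidInputError(f"{name} outside the plausible (0.9, 1.1) band")


@dataclass(frozen=True)
class SignalResult:
    """Chamber signal summary for one seed state."""

    dose_to_cavity_per_decay_gy: float
    dose_rate_gy_s: float
    k_mc_alpha: float
    k_mc_beta: float
    current_a: float
    snr: float
    leakage_current_a: float


def _ray_geometry(
    n: int,
    geo: ChamberGeometry,
    seed: SeedGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample emission rays; returns (reaches_cavity, slant_1_over_dz, chord_cm).

    ``slant_1_over_dz`` multiplies areal thicknesses for the window
    crossing; ``chord_cm`` is the geometric path through the cavity.
    """
    if geo.cavity_radius_cm * 1e1 < seed.length_mm / 2.0:
        raise ConfigurationError(
            "cavity radius smaller than the seed half-length breaks the "
            "integral-dose design intent"
        )
    r0 = seed.outer_radius_mm * 0.1  # cm
    half_len = seed.length_mm * 0.05  # cm
    x = rng.uniform(-half_len, half_len, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    y0 = r0 * np.sin(phi)
    z0 = r0 * np.cos(phi)
    # Isotropic directions.
    mu = rng.uniform(-1.0, 1.0, n)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - mu**2)
    dx = sin_t * np.cos(psi)
    dy = sin_t * np.sin(psi)
    dz = mu
    outward = dy * np.sin(phi) + dz * np.cos(phi) > 0.0  # else absorbed in wire
    upward = dz > 1e-12
    ok = outward & upward
    height = geo.source_window_distance_cm + r0  # window plane above the axis
    s_win = np.where(ok, (height - z0) / np.where(upward, dz, 1.0), 0.0)
    xh = x + s_win * dx
    yh = y0 + s_win * dy
    rad2 = xh**2 + yh**2
    ok &= rad2 <= geo.aperture_radius_cm**2
    ok &= rad2 <= geo.cavity_radius_cm**2
    xh = np.where(ok, xh, 0.0)
    yh = np.where(ok, yh, 0.0)
    rad2 = np.where(ok, rad2, 0.0)

    # Chord through the cavity cylinder from the entry point.
    l_cm = geo.cavity_thickness_mm * 0.1
    s_top = l_cm / np.where(ok, dz, 1.0)
    a = dx**2 + dy**2
    b = 2.0 * (xh * dx + yh * dy)
    c = rad2 - geo.cavity_radius_cm**2
    disc = np.maximum(b**2 - 4.0 * a * c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_lat = np.where(a > 1e-15, (-b + np.sqrt(disc)) / (2.0 * a), np.inf)
    chord = np.where(ok, np.minimum(s_top, s_lat), 0.0)
    slant = np.where(ok, 1.0 / np.maximum(dz, 1e-12), 0.0)
    return ok, slant, chord


def _line_deposits(
    energy_mev: float,
    particle: str,
    geo: ChamberGeometry,
    tables: dict[tuple[str, str], StoppingPowerTable],
    ok: np.ndarray,
    slant: np.ndarray,
    chord_cm: np.ndarray,
    window_thickness_um: float,
) -> np.ndarray:
    """Per-history cavity deposits (MeV) for shared ray geometry."""
    kind = "alpha" if particle == "alpha" else "electron"
    win = tables[(geo.window_material, kind)]
    air = tables[("air", kind)]
    window_path = (
        window_thickness_um * 1e-4 * geo.window_density_g_cm3 * slant
    )  # g/cm²
    e_in = np.where(ok, energy_mev, 0.0)
    e_cavity = win.energy_after(e_in, window_path) if window_thickness_um > 0 else e_in
    air_path = chord_cm * geo.air_density_kg_m3 * 1e-3  # g/cm²
    e_exit = air.energy_after(e_cavity, air_path)
    return np.where(ok, e_cavity - e_exit, 0.0)


def trace_particles(
    inv: EmissionInventory,
    geo: ChamberGeometry,
    seed: SeedGeometry | None = None,
    tables: dict[tuple[str, str], StoppingPowerTable] | None = None,
    n_histories: int = 1_000_000,
    rng_seed: int = 0,
) -> DepositResult:
    """Mean cavity deposit per Ra decay via straight-ray CSDA transport.

    Each emission line is traced with ``n_histories`` shared-geometry
    rays; line means are combined with the inventory rates.  Fixed
    ``rng_seed`` gives identical results.
    """
    if n_histories < 1:
        raise InvalidInputError("n_histories must be >= 1")
    if seed is None:
        seed = SeedGeometry()
    if tables is None:
        tables = load_stopping_tables()
    rng = np.random.default_rng(rng_seed)
    ok, slant, chord = _ray_geometry(n_histories, geo, seed, rng)

    per_line: dict[tuple[str, str, float], LineDeposit] = {}
    eps = {"alpha": 0.0, "electron": 0.0}
    var = {"alpha": 0.0, "electron": 0.0}
    for line in inv.lines:
        key = (line.nuclide, line.particle, line.energy_mev)
        if key not in per_line:
            deposits = _line_deposits(
                line.energy_mev, line.particle, geo, tables,
                ok, slant, chord, geo.window_thickness_um,
            )
            per_line[key] = LineDeposit(
                mean_mev=float(deposits.mean()),
                stderr_mev=float(deposits.std(ddof=1) / math.sqrt(n_histories)),
                n_histories=n_histories,
            )
        dep = per_line[key]
        eps[line.particle] += line.rate_per_decay * dep.mean_mev
        var[line.particle] += (line.rate_per_decay * dep.stderr_mev) ** 2
    return DepositResult(
        per_line=per_line,
        eps_alpha_mev=eps["alpha"],
        eps_beta_mev=eps["electron"],
        eps_alpha_stderr_mev=math.sqrt(var["alpha"]),
        eps_beta_stderr_mev=math.sqrt(var["electron"]),
    )


def signal_current(
    deposits: DepositResult,
    geo: ChamberGeometry,
    corrections: CorrectionFactors | None = None,
    a0_bq: float = 1.11e5,
    leakage_current_a: float = 0.02e-12,
) -> SignalResult:
    """Convert per-decay cavity deposits into chamber current and SNR.

    I = ε̇ / [k_MC,α(W̄/e)_α + k_MC,β(W̄/e)_β] with ε̇ the energy
    deposition rate; the dose rate is ε̇ divided by the cavity air mass.
    """
    if corrections is None:
        corrections = CorrectionFactors()
    if a0_bq < 0:
        raise InvalidInputError("activity must be non-negative")
    mass = geo.cavity_mass_kg
    if mass <= 0:
        raise ConfigurationError("cavity air mass is zero")
    eps_j = deposits.eps_total_mev * MEV_TO_J
    if eps_j > 0:
        k_alpha = deposits.eps_alpha_mev / deposits.eps_total_mev
    else:
        k_alpha = 1.0
    k_beta = 1.0 - k_alpha
    w_eff = k_alpha * corrections.w_over_e_alpha + k_beta * corrections.w_over_e_beta
    current = eps_j * a0_bq / w_eff
    return SignalResult(
        dose_to_cavity_per_decay_gy=eps_j / mass,
        dose_rate_gy_s=eps_j * a0_bq / mass,
        k_mc_alpha=k_alpha,
        k_mc_beta=k_beta,
        current_a=current,
        snr=current / leakage_current_a if leakage_current_a > 0 else math.inf,
        leakage_current_a=leakage_current_a,
    )


def k_window(
    inv: EmissionInventory,
    geo: ChamberGeometry,
    seed: SeedGeometry | None = None,
    tables: dict[tuple[str, str], StoppingPowerTable] | None = None,
    n_histories: int = 1_000_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Window correction: cavity dose without / with the mylar window.

    Both arms share the same sampled rays (common random numbers), so the
    returned standard error reflects only the anticorrelated part of the
    MC noise.  The window softens the alpha spectrum, raising the air
    stopping power in the cavity, hence k_window < 1 for any real window.
    """
    if seed is None:
        seed = SeedGeometry()
    if tables is None:
        tables = load_stopping_tables()
    rng = np.random.default_rng(rng_seed)
    ok, slant, chord = _ray_geometry(n_histories, geo, seed, rng)
    total_with = 0.0
    total_without = 0.0
    ratio_terms = []
    for line in inv.lines:
        dep_with = _line_deposits(
            line.energy_mev, line.particle, geo, tables, ok, slant, chord,
            geo.window_thickness_um,
        )
        dep_without = _line_deposits(
            line.energy_mev, line.particle, geo, tables, ok, slant, chord, 0.0
        )
        total_with += line.rate_per_decay * dep_with.mean()
        total_without += line.rate_per_decay * dep_without.mean()
        ratio_terms.append(
            line.rate_per_decay * (dep_without - dep_with)
        )
    if total_with <= 0:
        raise ConfigurationError("no cavity deposit; cannot form k_window")
    value = total_without / total_with
    diff = sum(ratio_terms)
    diff_err = float(diff.std(ddof=1) / math.sqrt(n_histories))
    stderr = diff_err / total_with
    return float(value), stderr


def sensitivity_study(
    cascades: list[CascadeResult],
    geo: ChamberGeometry,
    seed: SeedGeometry | None = None,
    tables: dict[tuple[str, str], StoppingPowerTable] | None = None,
    a0_bq: float = 1.11e5,
    n_histories: int = 1_000_000,
    rng_seed: int = 0,
    chain: ChainDefinition | None = None,
) -> dict:
    """Chamber current across a desorption sweep with an OLS linearity fit.

    Returns slope (A per unit P_des(Rn)), intercept, R², the per-case
    table, and the mean absolute signal change per sweep step.
    """
    if len(cascades) < 3:
        raise InvalidInputError("need at least 3 sweep points for a fit")
    if chain is None:
        chain = load_default_chain()
    rows = []
    for cascade in cascades:
        inv = emission_inventory(cascade, chain)
        deposits = trace_particles(
            inv, geo, seed, tables, n_histories=n_histories, rng_seed=rng_seed
        )
        signal = signal_current(deposits, geo, a0_bq=a0_bq)
        rows.append(
            {
                "depth_nm": cascade.depth_nm,
                "pdes_rn": cascade.pdes_rn,
                "pdes_pb": cascade.pdes_pb,
                "dose_per_decay_gy": signal.dose_to_cavity_per_decay_gy,
                "kmc_alpha": signal.k_mc_alpha,
                "kmc_beta": signal.k_mc_beta,
                "current_pa": signal.current_a * 1e12,
                "snr": signal.snr,
            }
        )
    table = pd.DataFrame(rows).sort_values("depth_nm").reset_index(drop=True)
    x = table["pdes_rn"].to_numpy()
    y = table["current_pa"].to_numpy() * 1e-12
    if np.ptp(x) == 0.0:  # degenerate sweep: no desorption variation
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    predicted = slope * x + intercept
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    increments = np.abs(np.diff(table["current_pa"].to_numpy()))
    return {
        "table": table,
        "slope_a_per_pdes": float(slope),
        "intercept_a": float(intercept),
        "r_squared": r_squared,
        "mean_step_increment_pa": float(increments.mean()) if increments.size else 0.0,
    }


def min_activity_for_signal(
    threshold_a: float,
    pdes_rn_target: float,
    sweep_pdes_rn,
    sweep_current_a,
    a0_bq: float,
) -> float:
    """Smallest Ra-224 activity (Bq) keeping the current above threshold
    at a given Rn desorption probability, interpolated over the sweep."""
    if threshold_a <= 0:
        raise InvalidInputError("threshold must be positive")
    pdes = np.asarray(sweep_pdes_rn, dtype=float)
    current = np.asarray(sweep_current_a, dtype=float)
    order = np.argsort(pdes)
    pdes, current = pdes[order], current[order]
    if not (pdes[0] <= pdes_rn_target <= pdes[-1]):
        raise ExtrapolationError(
            f"P_des(Rn) target {pdes_rn_target} outside the sweep "
            f"[{pdes[0]:.3f}, {pdes[-1]:.3f}]"
        )
    current_per_bq = np.interp(pdes_rn_target, pdes, current) / a0_bq
    return threshold_a / current_per_bq
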