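"""Finite-difference diffusion-leakage (DL) dose model in (r, z).

The DL model describes the macroscopic alpha dose around a DaRT seed: the
seed surface releases Rn-220 (and, via recoil pathways, Pb-212) into
tissue, where the two mobile species diffuse, decay, and — for Pb-212 —
are cleared by the vasculature.  The governing equations, with Po-216 and
Bi-212 taken in local secular equilibrium with Rn-220 and Pb-212,

    ∂n_Rn/∂t = D_Rn ∇² n_Rn − λ_Rn n_Rn
    ∂n_Pb/∂t = D_Pb ∇² n_Pb − (λ_Pb + α_Pb) n_Pb + λ_Rn n_Rn

are solved on a uniform axisymmetric grid surrounding an infinite rigid
cylinder of the seed radius.  Sources enter as surface fluxes over the
seed's side wall, paced by the decaying Ra-224 activity and scaled by the
desorption probabilities: the Rn flux carries pdes_rn per Ra decay and
the *direct* Pb flux carries (pdes_pb − pdes_rn), since the gamma-based
Pb desorption probability counts Pb leaving the seed through every
pathway and Rn already in tissue is handled by the Rn field.

Numerics: second-order 5-point axisymmetric Laplacian; the Rn field is
quasi-static (80 s mean life versus 15 min macro steps) and solved once
per case, scaling as exp(−λ_Ra t); Pb is advanced by backward Euler with
a factorized sparse operator reused across steps.  Cumulative alpha dose
uses local deposition (alpha range ≪ the mm profile scale); beta dose
optionally smears the Pb-212-chain mean beta energy with a normalized
single-exponential point kernel, implemented as a screened-Poisson solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .decay_chain import CURIE_UCI_TO_BQ, ChainDefinition, load_default_chain
from .errors import (
    ConfigurationError,
    InvalidInputError,
    NoCrossingError,
    SolverError,
)

__all__ = [
    "SeedGeometry",
    "DLParameters",
    "Grid2D",
    "FieldState",
    "DoseGrid",
    "RadialProfile",
    "chain_energy_constants",
    "derived_coefficients",
    "make_grid",
    "solve_rn_steady",
    "solve_dl",
    "dose_rate_fields",
    "radial_profile",
    "isodose_radius",
    "profile_ratio",
    "combine_dose_grids",
]

MEV_TO_J = 1.602176634e-13


@dataclass(frozen=True)
class SeedGeometry:
    """DaRT seed wire: 0.7 mm outer diameter, 1.0 cm length."""

    outer_radius_mm: float = 0.35
    length_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.outer_radius_mm <= 0 or self.length_mm <= 0:
            raise InvalidInputError("seed dimensions must be positive")


@dataclass(frozen=True)
class DLParameters:
    """Physical parameters of one DL case.

    ``l_rn_mm``/``l_pb_mm`` are diffusion lengths; ``leak_prob_pb`` is the
    fraction of tissue Pb-212 removed by vascular clearance rather than
    decaying in place; ``pdes_rn``/``pdes_pb`` come from the recoil
    cascade; ``beta_mode`` selects how beta energy is deposited
    ("off", "local", or "kernel").
    """

    pdes_rn: float
    pdes_pb: float
    l_rn_mm: float = 0.4
    l_pb_mm: float = 0.6
    leak_prob_pb: float = 0.5
    a0_bq: float = 3.0 * CURIE_UCI_TO_BQ
    duration_days: float = 30.0
    tissue_density_kg_m3: float = 1000.0
    beta_mode: str = "kernel"
    beta_kernel_length_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.l_rn_mm <= 0 or self.l_pb_mm <= 0:
            raise InvalidInputError("diffusion lengths must be positive")
        if not (0.0 <= self.leak_prob_pb < 1.0):
            raise InvalidInputError("leak_prob_pb must lie in [0, 1)")
        if self.duration_days <= 0:
            raise InvalidInputError("duration must be positive")
        if self.a0_bq < 0:
            raise InvalidInputError("activity must be non-negative")
        if self.beta_mode not in ("off", "local", "kernel"):
            raise ConfigurationError(f"unknown beta_mode {self.beta_mode!r}")


@dataclass(frozen=True)
class Grid2D:
    """Uniform axisymmetric node grid: r in [seed radius, r_max],
    z in [−z_max, z_max], with the seed surface on the first r line."""

    dr_um: float
    dz_um: float
    r0_mm: float
    r_max_mm: float
    z_max_mm: float

    def __post_init__(self) -> None:
        for name in ("dr_um", "dz_um", "r_max_mm", "z_max_mm"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.r_max_mm <= self.r0_mm:
            raise InvalidInputError("r_max must exceed the seed radius")

    @property
    def r_mm(self) -> np.ndarray:
        n = int(round((self.r_max_mm - self.r0_mm) / (self.dr_um * 1e-3))) + 1
        return self.r0_mm + np.arange(n) * self.dr_um * 1e-3

    @property
    def z_mm(self) -> np.ndarray:
        n = int(round(self.z_max_mm / (self.dz_um * 1e-3)))
        return np.arange(-n, n + 1) * self.dz_um * 1e-3

    @property
    def shape(self) -> tuple[int, int]:
        return self.r_mm.size, self.z_mm.size


@dataclass(frozen=True)
class FieldState:
    """Instantaneous Rn-220 and Pb-212 number densities (atoms/m³)."""

    n_rn: np.ndarray
    n_pb: np.ndarray
    grid: Grid2D | None = None

    def __post_init__(self) -> None:
        if np.any(self.n_rn < 0) or np.any(self.n_pb < 0):
            raise InvalidInputError("number densities must be non-negative")


@dataclass(frozen=True)
class DoseGrid:
    """Cumulative alpha and beta dose (Gy) plus provenance metadata."""

    grid: Grid2D
    dose_alpha_gy: np.ndarray
    dose_beta_gy: np.ndarray
    params: DLParameters
    seed: SeedGeometry
    dt_pb_minutes: float
    snapshots: tuple[tuple[float, np.ndarray], ...] = field(default=(), repr=False)

    @property
    def dose_total_gy(self) -> np.ndarray:
        return self.dose_alpha_gy + self.dose_beta_gy


@dataclass(frozen=True)
class RadialProfile:
    """Dose versus radius at a fixed axial plane."""

    radii_mm: np.ndarray
    dose_gy: np.ndarray
    z_plane_mm: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii_mm) <= 0):
            raise InvalidInputError("radii must be strictly increasing")


def chain_energy_constants(chain: ChainDefinition | None = None) -> dict[str, float]:
    """Per-decay energy bookkeeping (MeV) for the local-equilibrium sub-chains.

    ``alpha_per_rn``: Rn-220 + Po-216 mean alpha energy released per Rn
    decay in tissue; ``alpha_per_pb``: Bi-212-branch-weighted alpha energy
    per Pb-212 decay; ``beta_per_pb``: mean beta energy per Pb-212 decay
    including Bi-212 and Tl-208 at their branch weights.
    """
    if chain is None:
        chain = load_default_chain()

    def mean_alpha(name: str) -> float:
        return sum(e * i for e, i in chain[name].alpha_lines)

    bi = chain["Bi-212"]
    branch_beta = dict(
        (d, b) for _, b, d in bi.decay_modes
    )  # {"Po-212": 0.6406, "Tl-208": 0.3594}
    alpha_per_pb = mean_alpha("Bi-212") + branch_beta["Po-212"] * mean_alpha("Po-212")
    beta_per_pb = (
        chain["Pb-212"].mean_beta_energy_mev
        + branch_beta["Po-212"] * bi.mean_beta_energy_mev
        + branch_beta["Tl-208"] * chain["Tl-208"].mean_beta_energy_mev
    )
    return {
        "alpha_per_rn": mean_alpha("Rn-220") + mean_alpha("Po-216"),
        "alpha_per_pb": alpha_per_pb,
        "beta_per_pb": beta_per_pb,
        "lambda_rn": chain["Rn-220"].decay_constant,
        "lambda_pb": chain["Pb-212"].decay_constant,
        "lambda_ra": chain["Ra-224"].decay_constant,
    }


def derived_coefficients(p: DLParameters, chain: ChainDefinition | None = None) -> tuple[float, float, float]:
    """(D_Rn, D_Pb, α_Pb) in SI units.

    The leakage probability relates clearance to decay through
    leak = α/(α + λ), hence α_Pb = λ_Pb·leak/(1 − leak); diffusion
    lengths are defined against each species' total removal rate,
    D = L²·(removal).
    """
    consts = chain_energy_constants(chain)
    if p.leak_prob_pb >= 1.0:
        raise InvalidInputError("leak probability of 1 gives infinite clearance")
    alpha_pb = consts["lambda_pb"] * p.leak_prob_pb / (1.0 - p.leak_prob_pb)
    d_rn = (p.l_rn_mm * 1e-3) ** 2 * consts["lambda_rn"]
    d_pb = (p.l_pb_mm * 1e-3) ** 2 * (consts["lambda_pb"] + alpha_pb)
    return d_rn, d_pb, alpha_pb


def make_grid(
    p: DLParameters,
    seed: SeedGeometry | None = None,
    dr_um: float = 50.0,
    dz_um: float = 50.0,
    domain_lengths: float = 15.0,
) -> Grid2D:
    """Build a grid whose outer boundaries sit ``domain_lengths`` diffusion
    lengths beyond the seed, snapped outward to whole grid cells."""
    if seed is None:
        seed = SeedGeometry()
    l_max = max(p.l_rn_mm, p.l_pb_mm)
    r_extent = domain_lengths * l_max
    z_extent = seed.length_mm / 2.0 + domain_lengths * l_max
    dr_mm, dz_mm = dr_um * 1e-3, dz_um * 1e-3
    r_max = seed.outer_radius_mm + np.ceil(r_extent / dr_mm) * dr_mm
    z_max = np.ceil(z_extent / dz_mm) * dz_mm
    return Grid2D(
        dr_um=dr_um,
        dz_um=dz_um,
        r0_mm=seed.outer_radius_mm,
        r_max_mm=float(r_max),
        z_max_mm=float(z_max),
    )


def _check_resolution(grid: Grid2D, p: DLParameters) -> None:
    l_min_um = min(p.l_rn_mm, p.l_pb_mm) * 1e3
    h = max(grid.dr_um, grid.dz_um)
    if h > l_min_um / 2.0 + 1e-9:
        raise ConfigurationError(
            f"grid spacing {h} µm under-resolves the {l_min_um} µm diffusion "
            "length (need h ≤ L/2)"
        )
    if h > l_min_um / 4.0 + 1e-9:
        warnings.warn(
            f"grid spacing {h} µm is coarser than L/4 for the shortest "
            f"diffusion length ({l_min_um} µm); short-range dose structure "
            "is smoothed",
            stacklevel=3,
        )


def _axisymmetric_operator(grid: Grid2D) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Discrete Laplacian L (1/m²) with Neumann inner wall, Dirichlet outer
    boundaries, plus the inner-wall flux pattern vector.

    Returns ``(laplacian, flux_pattern)`` where adding
    ``flux_density · flux_pattern`` to the right-hand side of
    ``D·L n − removal·n + rhs = 0`` imposes an inward diffusive flux
    density (atoms/m²/s) on the marked inner-wall nodes.
    """
    r = grid.r_mm * 1e-3
    z = grid.z_mm * 1e-3
    nr, nz = r.size, z.size
    dr = grid.dr_um * 1e-6
    dz = grid.dz_um * 1e-6

    def node(i: int, j: int) -> int:
        return i * nz + j

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    inv_dr2, inv_dz2 = 1.0 / dr**2, 1.0 / dz**2
    for i in range(nr):
        dirichlet_r = i == nr - 1
        for j in range(nz):
            k = node(i, j)
            if dirichlet_r or j == 0 or j == nz - 1:
                # Outer boundaries: n = 0 handled by leaving the row empty
                # (operator row zero; removal term pins the value).
                continue
            # z second difference
            rows += [k, k, k]
            cols += [node(i, j - 1), k, node(i, j + 1)]
            vals += [inv_dz2, -2.0 * inv_dz2, inv_dz2]
            if i == 0:
                # Ghost-eliminated Neumann wall: n_{-1} = n_1 (+ flux RHS).
                rows += [k, k]
                cols += [k, node(1, j)]
                vals += [-2.0 * inv_dr2, 2.0 * inv_dr2]
            else:
                coef_m = inv_dr2 - 1.0 / (2.0 * r[i] * dr)
                coef_p = inv_dr2 + 1.0 / (2.0 * r[i] * dr)
                rows += [k, k, k]
                cols += [node(i - 1, j), k, node(i + 1, j)]
                vals += [coef_m, -2.0 * inv_dr2, coef_p]
    lap = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(nr * nz, nr * nz)
    )

    flux_pattern = np.zeros(nr * nz)
    for j in range(1, nz - 1):
        flux_pattern[node(0, j)] = 2.0 / dr - 1.0 / r[0]
    return lap, flux_pattern


def _surface_band_weights(grid: Grid2D, seed: SeedGeometry) -> np.ndarray:
    """Trapezoid weights over inner-wall nodes covering |z| ≤ seed length/2."""
    z = grid.z_mm
    half = seed.length_mm / 2.0
    w = np.zeros(z.size)
    inside = np.abs(z) <= half + 1e-9
    w[inside] = 1.0
    edge = np.isclose(np.abs(z), half, atol=1e-9)
    w[edge & inside] = 0.5
    if w.sum() == 0:
        raise ConfigurationError("seed band does not intersect the grid")
    return w


class _DLOperators:
    """Factorized sparse operators shared across a solve."""

    def __init__(self, grid: Grid2D, seed: SeedGeometry, p: DLParameters,
                 chain: ChainDefinition | None = None):
        self.grid, self.seed, self.p = grid, seed, p
        self.consts = chain_energy_constants(chain)
        self.d_rn, self.d_pb, self.alpha_pb = derived_coefficients(p, chain)
        self.lap, self.flux_pattern = _axisymmetric_operator(grid)
        band = _surface_band_weights(grid, seed)
        dz = grid.dz_um * 1e-6
        r0 = grid.r0_mm * 1e-3
        length = band.sum() * dz  # discrete band length = seed length
        area = 2.0 * np.pi * r0 * length
        nr, nz = grid.shape
        pattern = np.zeros(nr * nz)
        pattern[:nz] = band / area  # per-node flux density for unit atoms/s
        self.unit_release_rhs = pattern * self.flux_pattern

    def helmholtz(self, diffusion: float, removal: float) -> sparse.csc_matrix:
        n = self.lap.shape[0]
        return (removal * sparse.identity(n, format="csr") - diffusion * self.lap).tocsc()


def _checked_solve(lu, matrix, rhs, what: str) -> np.ndarray:
    x = lu.solve(rhs)
    norm = np.linalg.norm(rhs)
    if norm > 0:
        residual = np.linalg.norm(matrix @ x - rhs) / norm
        if not np.isfinite(residual) or residual > 1e-8:
            raise SolverError(f"{what}: relative residual {residual:.3e}")
    return x


def solve_rn_steady(
    p: DLParameters,
    seed: SeedGeometry | None = None,
    grid: Grid2D | None = None,
    chain: ChainDefinition | None = None,
) -> tuple[np.ndarray, Grid2D]:
    """Quasi-static Rn-220 field (atoms/m³) for the t = 0 release rate.

    Solves D_Rn ∇² n = λ_Rn n with the seed-surface flux carrying
    pdes_rn·A0 atoms/s; the time-dependent field is this shape times
    exp(−λ_Ra t).
    """
    if seed is None:
        seed = SeedGeometry()
    if grid is None:
        grid = make_grid(p, seed)
    _check_resolution(grid, p)
    ops = _DLOperators(grid, seed, p, chain)
    a_rn = ops.helmholtz(ops.d_rn, ops.consts["lambda_rn"])
    rhs = p.pdes_rn * p.a0_bq * ops.unit_release_rhs
    lu = splu(a_rn)
    n_hat = _checked_solve(lu, a_rn, rhs, "Rn Helmholtz solve")
    return n_hat.reshape(grid.shape), grid


def solve_dl(
    p: DLParameters,
    seed: SeedGeometry | None = None,
    grid: Grid2D | None = None,
    dt_pb_minutes: float = 15.0,
    snapshot_every: int | None = None,
    chain: ChainDefinition | None = None,
) -> DoseGrid:
    """Advance the coupled DL system and accumulate the 30-day dose map.

    The Rn field is quasi-static and scales as exp(−λ_Ra t), so its decay
    fluence integrates analytically; Pb-212 is stepped by backward Euler
    with trapezoid accumulation of its decay fluence.  ``snapshot_every``
    stores the cumulative total-dose array every that many Pb steps (used
    for monotonicity checks).
    """
    if seed is None:
        seed = SeedGeometry()
    if grid is None:
        grid = make_grid(p, seed)
    if dt_pb_minutes <= 0:
        raise InvalidInputError("dt must be positive")
    _check_resolution(grid, p)

    ops = _DLOperators(grid, seed, p, chain)
    c = ops.consts
    lam_ra, lam_rn, lam_pb = c["lambda_ra"], c["lambda_rn"], c["lambda_pb"]
    rho = p.tissue_density_kg_m3
    n_nodes = ops.lap.shape[0]

    # --- Rn channel (quasi-static) ---
    if p.pdes_rn > 0:
        a_rn = ops.helmholtz(ops.d_rn, lam_rn)
        rhs_rn = p.pdes_rn * p.a0_bq * ops.unit_release_rhs
        n_rn_hat = _checked_solve(splu(a_rn), a_rn, rhs_rn, "Rn Helmholtz solve")
    else:
        n_rn_hat = np.zeros(n_nodes)

    # --- Pb transient (backward Euler) ---
    dt = dt_pb_minutes * 60.0
    total_time = p.duration_days * 86400.0
    n_steps = int(round(total_time / dt))
    removal_pb = lam_pb + ops.alpha_pb
    a_step = ops.helmholtz(ops.d_pb, removal_pb + 1.0 / dt)
    lu = splu(a_step)
    source0 = (
        lam_rn * n_rn_hat
        + (p.pdes_pb - p.pdes_rn) * p.a0_bq * ops.unit_release_rhs
    )

    n_pb = np.zeros(n_nodes)
    pb_fluence = np.zeros(n_nodes)  # ∫ λ_Pb n_Pb dt (decays/m³)
    snapshots: list[tuple[float, np.ndarray]] = []

    def dose_arrays(pb_fl: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        rn_fl = lam_rn * n_rn_hat * (1.0 - np.exp(-lam_ra * t)) / lam_ra
        alpha = (
            (rn_fl * c["alpha_per_rn"] + pb_fl * c["alpha_per_pb"])
            * MEV_TO_J
            / rho
        )
        if p.beta_mode == "off":
            beta = np.zeros_like(alpha)
        elif p.beta_mode == "local":
            beta = pb_fl * c["beta_per_pb"] * MEV_TO_J / rho
        else:  # kernel
            ell = p.beta_kernel_length_mm * 1e-3
            a_kernel = ops.helmholtz(1.0, 1.0 / ell**2)
            u = _checked_solve(splu(a_kernel), a_kernel, pb_fl, "beta kernel solve")
            beta = (u / ell**2) * c["beta_per_pb"] * MEV_TO_J / rho
        return alpha, beta

    for k in range(1, n_steps + 1):
        t = k * dt
        rhs = n_pb / dt + source0 * np.exp(-lam_ra * t)
        n_new = lu.solve(rhs)
        pb_fluence += 0.5 * dt * lam_pb * (n_pb + n_new)
        n_pb = n_new
        if snapshot_every and (k % snapshot_every == 0 or k == n_steps):
            alpha, beta = dose_arrays(pb_fluence, t)
            snapshots.append((t, (alpha + beta).reshape(grid.shape)))

    residual = np.linalg.norm(a_step @ n_pb - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if not np.isfinite(residual) or residual > 1e-6:
        raise SolverError(f"Pb backward-Euler solve: relative residual {residual:.3e}")

    alpha, beta = dose_arrays(pb_fluence, total_time)
    return DoseGrid(
        grid=grid,
        dose_alpha_gy=alpha.reshape(grid.shape),
        dose_beta_gy=beta.reshape(grid.shape),
        params=p,
        seed=seed,
        dt_pb_minutes=dt_pb_minutes,
        snapshots=tuple(snapshots),
    )


def dose_rate_fields(
    state: FieldState,
    p: DLParameters,
    chain: ChainDefinition | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous alpha and beta dose rates (Gy/s) from field densities."""
    c = chain_energy_constants(chain)
    rho = p.tissue_density_kg_m3
    alpha = (
        (c["lambda_rn"] * state.n_rn * c["alpha_per_rn"]
         + c["lambda_pb"] * state.n_pb * c["alpha_per_pb"])
        * MEV_TO_J
        / rho
    )
    beta_source = c["lambda_pb"] * state.n_pb * c["beta_per_pb"] * MEV_TO_J / rho
    if p.beta_mode == "off":
        beta = np.zeros_like(alpha)
    elif p.beta_mode == "local":
        beta = beta_source
    elif p.beta_mode == "kernel":
        if state.grid is None:
            raise ConfigurationError("kernel beta mode needs a grid-bearing FieldState")
        lap, _ = _axisymmetric_operator(state.grid)
        ell = p.beta_kernel_length_mm * 1e-3
        n = lap.shape[0]
        a_kernel = ((1.0 / ell**2) * sparse.identity(n, format="csr") - lap).tocsc()
        rhs = (c["lambda_pb"] * state.n_pb).ravel()
        u = _checked_solve(splu(a_kernel), a_kernel, rhs, "beta kernel solve")
        beta = (u / ell**2).reshape(state.n_pb.shape) * c["beta_per_pb"] * MEV_TO_J / rho
    else:
        raise ConfigurationError(f"unknown beta_mode {p.beta_mode!r}")
    return alpha, beta


def radial_profile(dose: DoseGrid, z_plane_mm: float = 0.0) -> RadialProfile:
    """Total-dose radial profile at an axial plane, by linear interpolation."""
    z = dose.grid.z_mm
    if not (z[0] <= z_plane_mm <= z[-1]):
        raise InvalidInputError("z plane outside the grid")
    total = dose.dose_total_gy
    j = int(np.searchsorted(z, z_plane_mm))
    if np.isclose(z_plane_mm, z[min(j, z.size - 1)]):
        values = total[:, min(j, z.size - 1)]
    elif j > 0 and np.isclose(z_plane_mm, z[j - 1]):
        values = total[:, j - 1]
    else:
        frac = (z_plane_mm - z[j - 1]) / (z[j] - z[j - 1])
        values = (1.0 - frac) * total[:, j - 1] + frac * total[:, j]
    return RadialProfile(
        radii_mm=dose.grid.r_mm.copy(), dose_gy=values.copy(), z_plane_mm=z_plane_mm
    )


def isodose_radius(profile: RadialProfile, level_gy: float) -> float:
    """Outermost radius at which the profile crosses ``level_gy``.

    Interpolates log-linearly between the bracketing nodes (dose falls
    near-exponentially in the diffusion-dominated exterior).
    """
    if level_gy <= 0:
        raise InvalidInputError("isodose level must be positive")
    d = profile.dose_gy
    r = profile.radii_mm
    if level_gy > d.max():
        raise NoCrossingError(f"level {level_gy} Gy above profile maximum {d.max():.3g}")
    exact = np.isclose(d, level_gy, rtol=1e-12, atol=0.0)
    for i in range(d.size - 2, -1, -1):
        if exact[i] and d[i + 1] < level_gy:
            return float(r[i])
        if d[i] > level_gy >= d[i + 1] and d[i + 1] > 0:
            log_hi, log_lo = np.log(d[i]), np.log(d[i + 1])
            frac = (np.log(level_gy) - log_hi) / (log_lo - log_hi)
            return float(r[i] + frac * (r[i + 1] - r[i]))
        if d[i] > level_gy and d[i + 1] == 0.0:
            return float(r[i])
    raise NoCrossingError(f"level {level_gy} Gy below the profile everywhere")


def profile_ratio(a: RadialProfile, b: RadialProfile) -> RadialProfile:
    """Pointwise a/b on a's radii, with zero denominators masked as NaN."""
    lo = max(a.radii_mm[0], b.radii_mm[0])
    hi = min(a.radii_mm[-1], b.radii_mm[-1])
    if lo >= hi:
        raise InvalidInputError("profiles have disjoint radial supports")
    mask = (a.radii_mm >= lo) & (a.radii_mm <= hi)
    radii = a.radii_mm[mask]
    b_interp = np.interp(radii, b.radii_mm, b.dose_gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b_interp > 0, a.dose_gy[mask] / b_interp, np.nan)
    return RadialProfile(radii_mm=radii, dose_gy=ratio, z_plane_mm=a.z_plane_mm)


def grid_cell_volumes(grid: Grid2D) -> np.ndarray:
    """Trapezoid-rule node volumes (m³) for integrating fields over the
    axisymmetric domain; boundary nodes carry half cells."""
    r = grid.r_mm * 1e-3
    z = grid.z_mm * 1e-3
    dr = grid.dr_um * 1e-6
    dz = grid.dz_um * 1e-6
    wr = np.ones(r.size)
    wr[0] = wr[-1] = 0.5
    wz = np.ones(z.size)
    wz[0] = wz[-1] = 0.5
    return 2.0 * np.pi * r[:, None] * dr * dz * wr[:, None] * wz[None, :]


def combine_dose_grids(grids: list[DoseGrid], weights: list[float]) -> DoseGrid:
    """Weighted superposition of dose maps on a shared grid.

    The DL system is linear in its source channels, so any desorption pair
    is an exact combination of unit-channel solves; the result keeps the
    first map's metadata with desorption fields left to the caller.
    """
    if len(grids) != len(weights) or not grids:
        raise InvalidInputError("need matching, non-empty grids and weights")
    base = grids[0]
    for g in grids[1:]:
        if g.grid != base.grid:
            raise ConfigurationError("dose grids live on different meshes")
    alpha = sum(w * g.dose_alpha_gy for g, w in zip(grids, weights))
    beta = sum(w * g.dose_beta_gy for g, w in zip(grids, weights))
    return replace(base, dose_alpha_gy=alpha, dose_beta_gy=beta, snapshots=())
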