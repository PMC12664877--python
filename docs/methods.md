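# Methods

`dartdose` models the chain of physics that links how a DaRT (diffusing
alpha-emitters radiation therapy) seed is manufactured — specifically, how
deep below the steel surface its ²²⁴Ra sits — to the tumour dose it
delivers and to the signal of a proposed absorbed-dose-based
source-strength standard.  This note records the models, their
assumptions, the defaults, and the numerical choices, in the order the
pipeline runs them.

## 1. Decay chain and Bateman kinetics (`decay_chain`)

The ²²⁴Ra chain (Ra-224 →α Rn-220 →α Po-216 →α Pb-212 →β Bi-212 →
{α Tl-208 →β, β Po-212 →α} Pb-208) is shipped as a structured YAML
resource with DDEP-based half-lives, branching fractions, emission lines
and mean beta energies; the header records the values used.  Four line
intensities are load-bearing for the desorption estimators and are fixed
at Ra-224 α 5.6855 MeV: 94.73 %, Rn-220 α 6.2881 MeV: 99.88 %, Ra-224 γ
0.2410 MeV: 4.12 %, Pb-212 γ 0.2386 MeV: 43.6 %.

Activities come from the matrix exponential of the branched rate matrix
rather than the classical Bateman product formula; this handles the
Bi-212 branch without special cases and conserves total nuclei to machine
precision.  A `collapse_fast_intermediates` helper removes sub-minute
nuclides analytically; doing so shifts Pb-212 ingrowth by the ~80 s
Rn-220 + Po-216 mean delay, i.e. a relative error ≈ 80 s/t (2 % at one
hour, below 0.1 % beyond a day).

**Equilibration time.** `equilibrium_time(chain, tol)` returns the first
time the Pb-212/Ra-224 activity ratio is within `tol` of its
transient-equilibrium asymptote λ_Pb/(λ_Pb − λ_Ra) = 1.139.  The closed
form is t ≈ ln(1/tol)/(λ_Pb − λ_Ra): a 1 % criterion gives 3.4 d, 0.1 %
gives 5.0 d, and the often-quoted "about six days after separation"
corresponds to a ≈ 0.03 % criterion.  The package defaults to the 1 %
criterion and reports the number it actually computes; we deliberately do
not pick a tolerance to match a quoted round number.

## 2. Recoil-escape Monte Carlo (`recoil_desorption`)

Each alpha decay imparts E_rec = E_α·m_α/m_daughter (~100–130 keV) to the
daughter.  Atoms are tracked in a planar semi-infinite slab — the 0.35 mm
wire radius exceeds the nm recoil ranges by >10⁴, so curvature is
irrelevant — through the three recoil steps Ra→Rn→Po→Pb.  Flights are
straight lines with isotropic direction; an atom whose flight crosses the
surface escapes to vacuum together with all its descendants (escapees are
pumped away and cannot decay back onto the seed).  Emissions are scored
only while the emitter is inside the wall, matching the definition of the
count-based estimators P_des(Rn) = 1 − A^α_Rn/A^α_Ra and
P_des(Pb) = 1 − A^γ_Pb/A^γ_Ra with A = C/I.  The overlapping 0.240/0.239
MeV gamma peaks are separated by emitter identity, which a simulation can
do and a real spectrometer cannot.

**Range model.** Full ion transport in steel is replaced by a power-law
range–energy relation R(E) = s·(E/103.4 keV)^1.0 with per-flight Gaussian
straggling σ/R = 0.2 (truncated at zero).  The exponent is 1.0 because
recoil energies only span 100–130 keV, where ranges vary slowly.  The
scale s is calibrated **once**, by bisection, so that the Rn-220 escape
probability at a 14 nm delta layer equals 0.11; this gives s = 18.33 nm
(consistent with the analytic inversion (1 − d/R)/2 = 0.11 → R ≈ 18 nm).
Everything else — the surface values, all Pb-212 and Po-216 escape
probabilities, the shape of the depth dependence — is then a prediction,
not a fit.

**Depth semantics.** "Distribution depth" defaults to a delta layer at
exactly d nm; a `uniform` mode (uniform in [0, d]) is available because
the manufacturing literature is ambiguous about the profile.  At d = 0
the delta layer gives exactly the half-space escape probability 0.5 for
Rn-220, used as an analytic anchor in the tests.

Defaults: 10⁶ histories per depth (binomial σ ≈ 5×10⁻⁴), depth sweep
0–14 nm in 2 nm steps.

## 3. Diffusion-leakage dose model (`dl_solver`)

Tissue dose is driven by the two mobile species.  With Po-216 and Bi-212
in local secular equilibrium with their parents, the fields obey

    ∂n_Rn/∂t = D_Rn ∇²n_Rn − λ_Rn n_Rn
    ∂n_Pb/∂t = D_Pb ∇²n_Pb − (λ_Pb + α_Pb) n_Pb + λ_Rn n_Rn

in axisymmetric (r, z) around an infinite rigid cylinder of the seed
radius.  The leakage probability relates vascular clearance to decay,
leak = α_Pb/(α_Pb + λ_Pb), so α_Pb = λ_Pb·leak/(1 − leak); diffusion
lengths are defined against total removal, D = L²·(removal).

**Sources.** The side wall injects Rn at pdes_rn·A_Ra(t) atoms/s and Pb
directly at (pdes_pb − pdes_rn)·A_Ra(t), both uniform over the band
|z| ≤ 5 mm, with A_Ra(t) = A₀e^(−λ_Ra t).  The direct-Pb weight is
(pdes_pb − pdes_rn) because the gamma-based Pb desorption probability
counts Pb that left the seed through *any* pathway, and Pb produced by Rn
already in tissue is generated by the λ_Rn n_Rn coupling term.  End caps
and the wall outside the band are no-flux; outer boundaries are Dirichlet
zero at ≥ 15 diffusion lengths.

**Numerics.** Second-order 5-point axisymmetric Laplacian (ghost-node
Neumann wall); the Rn field is quasi-static (80 s mean life vs 15 min
macro steps) and solved once, scaling as e^(−λ_Ra t), so its decay
fluence integrates analytically; Pb-212 advances by backward Euler with
one factorized sparse operator reused across all steps and trapezoidal
accumulation of its decay fluence.  Defaults dr = dz = 50 µm, dt = 15
min.  The solver refuses grids coarser than L/2 for the shortest
diffusion length and warns between L/4 and L/2; the low-diffusion
scenario (L_Pb = 0.1 mm) therefore runs at dr = L_Pb/2 by design, which
smooths sub-0.1 mm Pb structure but leaves the 10-Gy radius
grid-converged to < 1 % (tested by halving dr, dz, dt).

**Dose.** Alpha dose deposits locally (alpha range ≪ mm scales):
13.066 MeV per tissue Rn decay (Rn-220 + Po-216 lines) and 7.80 MeV per
tissue Pb decay (Bi-212 branch-weighted mean of the 6.05 and 8.785 MeV
alphas), to water at 1000 kg/m³.  Beta dose (≈ 0.80 MeV per Pb decay from
Pb/Bi/Tl mean energies) supports three modes: `off`, `local`, and the
default `kernel`, a normalized single-exponential point kernel
k(x) = e^(−x/ℓ)/(4πℓ²x) implemented as one screened-Poisson solve of the
time-integrated beta source (ℓ = 0.3 mm, an effective attenuation length
for the chain's ~0.1–0.8 MeV mean-energy betas).  The kernel conserves
the emitted beta energy up to outer-boundary leakage (tested at 3 %);
gamma dose is neglected (long mean free path, < 1 % of local dose).

The PDE system is linear in its two source channels, so the study
pipeline solves two unit-channel problems per diffusion scenario and
superposes them for every depth; the identity with a direct solve is
itself a test.  A 30-day solve at default resolution takes ~20–60 s on
one core.

**Validation oracles.** The mid-plane quasi-static Rn field matches the
infinite-line K₀(r/L) solution to < 2 %; a degenerate short-seed
configuration matches the spherical e^(−ρ/L)/ρ field to 5 % (the residual
reflects the thin rigid wire column the solver always keeps, which a true
point source does not have); steady-state Rn atom bookkeeping closes to
2 %.

## 4. Chamber signal model (`chamber_model`)

Geometry: the seed sits in a pumped vacuum vessel 1 cm below a 3 µm mylar
(PET, 1.40 g/cm³) window; behind it a parallel-plate chamber with a 1 cm
radius, 1 mm thick air cavity at 1.196 kg/m³ (101.325 kPa, 22 °C).  The
aperture radius is not specified by the design and defaults to the cavity
radius.  The sub-100 nm aluminization of the window is ignored against
3 µm of PET.

The per-decay emission inventory at chain equilibrium retains each
emitter at 1 − P_des of its governing mobile ancestor (Rn-220 and Po-216
by their own escape fractions; Pb-212 and everything below by
P_des(Pb)).  At zero desorption the chain yields exactly 4 alphas per
Ra-224 decay (five possible alpha emitters, branch-split at Bi-212); a
fully desorbing surface source retains ≈ 2.15.

Transport is straight-ray CSDA: uniform emission over the side surface,
isotropic directions, inward rays absorbed by the (convex) wire, vacuum
lossless, slant-path window loss and cavity chord deposit from log-log
interpolated stopping-power tables with range inversion.  Delta rays are
not tracked separately; all energy on an alpha's chord is booked as alpha
dose.  Betas use branch mean energies and the electron table — adequate
because their share of cavity dose is bounded (< 1 %), not resolved.
Particles that fall below the table minimum deposit the remainder
locally.

**Stopping powers** are a *synthetic* resource
(`stopping_powers_synthetic.csv`, generated by
`scripts/make_stopping_tables.py`): Bethe theory with an effective-charge
factor for alphas (√E extension below 0.9 MeV) and the Moller/ICRU
collision formula for electrons, for air and PET.  Electron values match
standard compilations to < 1 % in the relevant range; alpha values are
accurate to ~5–8 % on the 4–9 MeV plateau, which propagates linearly into
the absolute current scale but largely cancels in the k_window ratio.

**Signal.** I = ε̇/[k_MC,α(W̄/e)_α + k_MC,β(W̄/e)_β] with
(W̄/e)_α = 34.96 J/C, (W̄/e)_β = 33.97 J/C and dose-weighted k_MC
fractions; SNR is defined against a 0.02 pA leakage current.  k_window is
the ratio of cavity dose without/with the window, computed with common
random numbers across both arms; it is < 1 because the window softens the
spectrum into a higher-stopping-power region.  k_scatter (0.985) is a
configurable constant, *not* predicted — it would require the
wall/electrode transport this model deliberately omits.  The
measurement-based factors k_tp, k_ion, k_pol, k_elec are unity
placeholders pending a physical instrument.

## 5. Study pipeline (`study_pipeline`)

`run_full_study` chains sweep → DL → chamber with all RNG streams spawned
from one master seed (re-runs are byte-identical), logs per-stage wall
time, and writes tidy CSVs plus a JSON manifest.  Default study
conditions: 3 µCi at insertion, full chain equilibrium at t = 0, 30-day
treatment, Pb-212 leakage probability 0.5, L_Rn = 0.4 mm, L_Pb = 0.1 mm
(low) and 0.6 mm (high), depth sweep 0–14 nm in 2 nm steps (the 0–1 nm /
0.2 nm fine sweep is available through the same config fields).

## What the defaults do and do not show

The synthetic study emulates an idealized seed: uniform plating, a sharp
delta-layer depth, no polymer coating, homogeneous tissue, a single
clearance constant, and a perfectly aligned chamber.  Passing tests show
internal consistency against analytic oracles and reproduction of the
study conditions' headline numbers; they do not validate the range-law
calibration against real ion-transport data, the beta kernel against
measured dose-point kernels, or the absolute current against a physical
chamber.  Known limitations worth keeping in mind: the alpha
stopping-power scale (±~8 %) bounds the absolute current accuracy; the
low-diffusion Pb field is resolved at L/2; and k_scatter is carried, not
derived.
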