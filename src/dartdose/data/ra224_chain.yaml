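# Ra-224 decay chain nuclide data.
#
# Values follow the Decay Data Evaluation Project (DDEP / LNHB) recommended
# evaluations as rounded below (half-lives in seconds, energies in MeV,
# intensities per decay of the emitting nuclide, masses in u).  Alpha and
# gamma lines with intensities below ~1e-3 are omitted; the retained alpha
# lines of each nuclide are normalised so that alpha-branch intensities sum
# to the alpha branching fraction.  Mean beta energies are the
# intensity-weighted mean kinetic energies of the beta branch.
#
# Key printed intensities used by the count-based desorption estimators:
#   Ra-224 alpha 5.6855 MeV : 94.73 %
#   Rn-220 alpha 6.2881 MeV : 99.88 %
#   Ra-224 gamma 0.2410 MeV :  4.12 %
#   Pb-212 gamma 0.2386 MeV : 43.6 %
nuclides:
  - name: Ra-224
    half_life_s: 313718.4        # 3.631 d
    atomic_mass_u: 224.020212
    decay_modes:
      - [alpha, 1.0, Rn-220]
    alpha_lines:
      - [5.6855, 0.9473]
      - [5.4486, 0.0527]
    gamma_lines:
      - [0.24099, 0.0412]
    mean_beta_energy_mev: 0.0

  - name: Rn-220
    half_life_s: 55.6
    atomic_mass_u: 220.011394
    decay_modes:
      - [alpha, 1.0, Po-216]
    alpha_lines:
      - [6.2881, 0.9988]
      - [5.7470, 0.0012]
    gamma_lines:
      - [0.54973, 0.00114]
    mean_beta_energy_mev: 0.0

  - name: Po-216
    half_life_s: 0.145
    atomic_mass_u: 216.001915
    decay_modes:
      - [alpha, 1.0, Pb-212]
    alpha_lines:
      - [6.7783, 1.0]
    gamma_lines: []
    mean_beta_energy_mev: 0.0

  - name: Pb-212
    half_life_s: 38304.0         # 10.64 h
    atomic_mass_u: 211.991898
    decay_modes:
      - [beta, 1.0, Bi-212]
    alpha_lines: []
    gamma_lines:
      - [0.23863, 0.436]
      - [0.30009, 0.0318]
    mean_beta_energy_mev: 0.102

  - name: Bi-212
    half_life_s: 3633.0          # 60.55 min
    atomic_mass_u: 211.991286
    decay_modes:
      - [beta, 0.6406, Po-212]
      - [alpha, 0.3594, Tl-208]
    alpha_lines:
      - [6.0509, 0.2513]
      - [6.0898, 0.0975]
      - [5.7680, 0.0106]
    gamma_lines:
      - [0.72733, 0.0667]
    mean_beta_energy_mev: 0.770

  - name: Po-212
    half_life_s: 2.99e-07
    atomic_mass_u: 211.988868
    decay_modes:
      - [alpha, 1.0, Pb-208]
    alpha_lines:
      - [8.7849, 1.0]
    gamma_lines: []
    mean_beta_energy_mev: 0.0

  - name: Tl-208
    half_life_s: 183.18          # 3.053 min
    atomic_mass_u: 207.982019
    decay_modes:
      - [beta, 1.0, Pb-208]
    alpha_lines: []
    gamma_lines:
      - [2.61451, 0.9975]
      - [0.58319, 0.850]
      - [0.51077, 0.226]
    mean_beta_energy_mev: 0.557

  - name: Pb-208
    half_life_s: null            # stable
    atomic_mass_u: 207.976652
    decay_modes: []
    alpha_lines: []
    gamma_lines: []
    mean_beta_energy_mev: 0.0
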