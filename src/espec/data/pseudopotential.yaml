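# Electron-water pseudopotential parameters (versioned).
#
# Functional form per site (eV, A units):
#   V(r) = -q * e2 * erf(A*r)/r + sum_j B_j * exp(-C_j * r^2)
# i.e. an erf-screened Coulomb tail that matches the water model's SPC
# partial charges beyond the screening length 1/A, plus Gaussian core
# repulsion keeping the potential finite and smooth atop the nuclei.
#
# The O site carries, besides its core repulsion, a broad attractive
# Gaussian standing in for the molecular polarization attraction that
# stabilizes the solvent cavity.
#
# The constants below are this package's own calibration of that smooth
# screened-Coulomb + Gaussian family, chosen against physical targets for
# the hydrated electron: a bound cavity state with s->p gaps of 1-2 eV and
# a ground-state radius of gyration near 2-2.5 A.  They are a package
# default, not a literature transcription; swap in an alternative file to
# use a different parameterization (all solver contracts and tests are
# parameter-agnostic).
version: 2
sites:
  O:
    q: -0.82          # elementary charges (SPC oxygen)
    A: 2.50           # 1/A, inverse screening length
    B: [30.0, -1.8]   # eV, core repulsion + polarization-like attraction
    C: [2.00, 0.25]   # 1/A^2, matching Gaussian widths
  H:
    q: 0.41           # elementary charges (SPC hydrogen)
    A: 3.00
    B: [12.0]
    C: [3.50]
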