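"""Ensemble absorption spectra, sub-band Gaussian fits, moments and tests.

In the slow-modulation limit the absorption spectrum is the ensemble
distribution of instantaneous vertical transition energies, each transition
deposited with its oscillator strength.  The spectrum is assembled as an
oscillator-strength density on a fine energy grid (so its raw integral
equals the mean summed oscillator strength per configuration), split into
per-transition sub-bands; each sub-band is fitted with a Gaussian and the
total modeled as the sum of the fitted Gaussians.  Moments (integral, mean
energy, standard deviation) are always computed from the raw transitions,
never from the binned density, with seeded bootstrap confidence intervals
over configurations.  Classical-vs-quantized ensembles are compared with a
one-sided unpaired Student t test on the mean and an F test on the
variance, plus per-sub-band deltas and the p-state splitting <E3 - E1>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core_io import ExcitationTable

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


# ---------------------------------------------------------------------------
# Spectrum assembly
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Oscillator-strength density (per eV) on a uniform energy grid."""

    energies: np.ndarray
    density: np.ndarray
    subbands: dict[int, np.ndarray]
    bin_width: float
    normalization: str = "raw"

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)

    def normalized_to_unit_maximum(self) -> "Spectrum":
        m = self.density.max()
        return Spectrum(self.energies, self.density / m,
                        {k: v / m for k, v in self.subbands.items()},
                        self.bin_width, normalization="unit-maximum")


def assemble_spectrum(table: ExcitationTable,
                      e_min: float | None = None,
                      e_max: float | None = None,
                      bin_width: float = 0.005,
                      smoothing_ev: float = 0.010) -> Spectrum:
    """Deposit each transition's f at its energy, averaged over configurations.

    ``bin_width`` defaults to 5 meV; ``smoothing_ev`` applies an optional
    Gaussian kernel (10 meV default, 0 disables) so the sub-bands are smooth
    enough for least-squares fitting.  Sub-band densities are kept per
    transition index and sum exactly to the total.
    """
    if len(table.df) == 0:
        raise ValueError("empty excitation table")
    dE = table.energies()
    nc = table.n_configs
    lo = dE.min() if e_min is None else e_min
    hi = dE.max() if e_max is None else e_max
    pad = max(4.0 * smoothing_ev, 0.1)
    edges = np.arange(lo - pad, hi + pad + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if dE.min() < edges[0] or dE.max() > edges[-1]:
        import warnings
        warnings.warn("energy grid does not cover all transitions; clipping")
    subbands: dict[int, np.ndarray] = {}
    for k in sorted(table.df["k"].unique()):
        sel = table.df["k"] == k
        h, _ = np.histogram(table.df.loc[sel, "dE_eV"], bins=edges,
                            weights=table.df.loc[sel, "f"])
        d = h / (nc * bin_width)  # oscillator strength per eV per configuration
        if smoothing_ev > 0:
            d = _gaussian_smooth(d, smoothing_ev / bin_width)
        subbands[int(k)] = d
    total = np.sum(list(subbands.values()), axis=0)
    return Spectrum(centers, total, subbands, bin_width)


def _gaussian_smooth(y: np.ndarray, sigma_bins: float) -> np.ndarray:
    m = int(np.ceil(6 * sigma_bins)) | 1
    x = np.arange(m) - m // 2
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    k /= k.sum()
    return np.convolve(y, k, mode="same")


# ---------------------------------------------------------------------------
# Gaussian sub-band fits
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    k: int
    amplitude: float
    center: float
    sigma: float
    residual: float

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    def __call__(self, e: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((e - self.center) / self.sigma) ** 2)


@dataclass
class SubbandFitReport:
    fits: list[GaussianFit]
    max_position: float     # maximum of the fitted total (eV)
    half_width: float       # numeric FWHM of the fitted total (eV)
    skipped: list[int]


def _gauss(e, a, mu, sigma):
    return a * np.exp(-0.5 * ((e - mu) / sigma) ** 2)


def fit_subbands(spectrum: Spectrum,
                 min_mass: float = 1e-6) -> SubbandFitReport:
    """Least-squares Gaussian per sub-band (moment-based initial guesses).

    Near-empty sub-bands (integrated strength below ``min_mass``) are
    skipped with a warning.  The fitted total is the sum of the per-band
    Gaussians; its maximum position and full width at half maximum are
    measured numerically since a Gaussian mixture has no closed form.
    """
    e = spectrum.energies
    fits: list[GaussianFit] = []
    skipped: list[int] = []
    for k, d in sorted(spectrum.subbands.items()):
        mass = d.sum() * spectrum.bin_width
        if mass < min_mass:
            import warnings
            warnings.warn(f"sub-band {k} nearly empty; skipped")
            skipped.append(k)
            continue
        mu0 = float((e * d).sum() / d.sum())
        sig0 = float(np.sqrt(((e - mu0) ** 2 * d).sum() / d.sum()))
        sig0 = max(sig0, spectrum.bin_width)
        a0 = mass / (sig0 * np.sqrt(2 * np.pi))
        try:
            popt, _ = optimize.curve_fit(
                _gauss, e, d, p0=[a0, mu0, sig0],
                bounds=([0.0, e[0], spectrum.bin_width / 10],
                        [np.inf, e[-1], e[-1] - e[0]]), maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"Gaussian fit failed for sub-band {k}") from exc
        resid = float(np.sqrt(np.mean((d - _gauss(e, *popt)) ** 2)))
        fits.append(GaussianFit(k, float(popt[0]), float(popt[1]),
                                abs(float(popt[2])), resid))
    if not fits:
        raise ValueError("no sub-band could be fitted")
    total = np.sum([f(e) for f in fits], axis=0)
    # refine maximum / numeric FWHM on a finer grid of the fitted model
    ef = np.linspace(e[0], e[-1], 20 * len(e))
    tf = np.sum([f(ef) for f in fits], axis=0)
    imax = int(np.argmax(tf))
    half = tf[imax] / 2.0
    above = tf >= half
    idx = np.flatnonzero(above)
    lo = _cross(ef, tf, idx[0] - 1, idx[0], half) if idx[0] > 0 else ef[0]
    hi = (_cross(ef, tf, idx[-1], idx[-1] + 1, half)
          if idx[-1] < len(ef) - 1 else ef[-1])
    return SubbandFitReport(fits=fits, max_position=float(ef[imax]),
                            half_width=float(hi - lo), skipped=skipped)


def _cross(x, y, i, j, level):
    """Linear interpolation of the level crossing between samples i and j."""
    if y[j] == y[i]:
        return x[i]
    t = (level - y[i]) / (y[j] - y[i])
    return x[i] + t * (x[j] - x[i])


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

@dataclass
class MomentReport:
    """f-weighted spectral moments with 95% bootstrap confidence intervals.

    ``m0`` is the mean summed oscillator strength per configuration (the
    spectrum integral), ``m1`` the mean transition energy (eV) and ``sd``
    the square root of the second central moment (eV).  CIs are percentile
    bootstrap over configurations (seeded).
    """

    m0: float
    m1: float
    sd: float
    m0_ci: tuple[float, float]
    m1_ci: tuple[float, float]
    sd_ci: tuple[float, float]
    degenerate: bool = False


def _weighted_moments(dE: np.ndarray, f: np.ndarray,
                      n_configs: int) -> tuple[float, float, float]:
    m0 = f.sum() / n_configs
    m1 = float(np.average(dE, weights=f))
    var = float(np.average((dE - m1) ** 2, weights=f))
    return float(m0), m1, float(np.sqrt(max(var, 0.0)))


def spectral_moments(table: ExcitationTable, k: int | None = None,
                     n_boot: int = 1000, seed: int = 0) -> MomentReport:
    """Moments over all transitions (or sub-band ``k`` only) of all
    configurations, computed from the raw transition list."""
    df = table.df if k is None else table.df[table.df["k"] == k]
    if len(df) == 0:
        raise ValueError("no transitions selected")
    configs = df["config"].to_numpy()
    uniq = np.unique(configs)
    dE = df["dE_eV"].to_numpy()
    f = df["f"].to_numpy()
    m0, m1, sd = _weighted_moments(dE, f, len(uniq))
    if len(uniq) < 2:
        return MomentReport(m0, m1, sd, (m0, m0), (m1, m1), (sd, sd),
                            degenerate=True)
    rng = np.random.default_rng(seed)
    groups = {c: i for i, c in enumerate(uniq)}
    gidx = np.array([groups[c] for c in configs])
    order = np.argsort(gidx, kind="stable")
    gsorted = gidx[order]
    starts = np.searchsorted(gsorted, np.arange(len(uniq)))
    ends = np.append(starts[1:], len(gsorted))
    dEs, fs = dE[order], f[order]
    boot = np.empty((n_boot, 3))
    for b in range(n_boot):
        pick = rng.integers(0, len(uniq), size=len(uniq))
        idx = np.concatenate([np.arange(starts[p], ends[p]) for p in pick])
        boot[b] = _weighted_moments(dEs[idx], fs[idx], len(uniq))
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return MomentReport(m0, m1, sd,
                        (float(lo[0]), float(hi[0])),
                        (float(lo[1]), float(hi[1])),
                        (float(lo[2]), float(hi[2])))


# ---------------------------------------------------------------------------
# Classical vs quantized comparison
# ---------------------------------------------------------------------------

@dataclass
class SubbandDelta:
    k: int
    center_shift: float   # quantized - classical, eV
    width_ratio: float    # quantized / classical


@dataclass
class ComparisonReport:
    mean_shift: float            # quantized - classical mean energy, eV
    t_statistic: float
    t_pvalue: float              # one-sided, H1: means differ in observed direction
    sd_ratio: float              # quantized / classical
    f_statistic: float
    f_pvalue: float              # one-sided, H1: quantized variance larger
    subband_deltas: list[SubbandDelta]
    splitting_classical: float   # <E3 - E1>, eV
    splitting_quantized: float
    splitting_shift_ci: tuple[float, float]


def _f_weighted_sample(table: ExcitationTable) -> tuple[np.ndarray, np.ndarray]:
    return table.energies(), table.strengths()


def compare_spectra(classical: ExcitationTable, quantized: ExcitationTable,
                    n_boot: int = 1000, seed: int = 0) -> ComparisonReport:
    """Statistical comparison of two transition ensembles over the same K.

    Uses the unpaired Student t test (pooled variance, one-sided in the
    observed direction of the shift) on the transition energies and an F
    test of equal variances (one-sided toward larger quantized variance).
    """
    if classical.K != quantized.K:
        raise ValueError("tables have mismatched numbers of transitions")
    e_cl, e_q = classical.energies(), quantized.energies()
    t_stat, p_two = stats.ttest_ind(e_q, e_cl, equal_var=True)
    shift = float(e_q.mean() - e_cl.mean())
    # one-sided p in the observed direction; identical samples give 0.5
    p_one = p_two / 2.0 if shift != 0 else 0.5
    v_cl, v_q = e_cl.var(ddof=1), e_q.var(ddof=1)
    F = float(v_q / v_cl)
    f_p = float(stats.f.sf(F, len(e_q) - 1, len(e_cl) - 1))
    deltas = []
    for k in range(1, classical.K + 1):
        c_k, q_k = classical.energies(k), quantized.energies(k)
        if len(c_k) == 0 or len(q_k) == 0:
            continue
        deltas.append(SubbandDelta(
            k, float(q_k.mean() - c_k.mean()),
            float(q_k.std(ddof=1) / c_k.std(ddof=1))
            if len(c_k) > 1 and c_k.std(ddof=1) > 0 else np.nan))
    if classical.K >= 3:
        sp_cl = p_state_splitting(classical)
        sp_q = p_state_splitting(quantized)
        ci = _splitting_shift_ci(classical, quantized, n_boot, seed)
    else:
        sp_cl = sp_q = float("nan")
        ci = (float("nan"), float("nan"))
    return ComparisonReport(shift, float(t_stat), float(p_one),
                            float(np.sqrt(F)), F, f_p, deltas,
                            sp_cl, sp_q, ci)


def p_state_splitting(table: ExcitationTable) -> float:
    """<E3 - E1>: mean spread of the three lowest excited (p-like) states."""
    if table.K < 3:
        raise ValueError("need at least three transitions for the splitting")
    e1, e3 = table.energies(1), table.energies(3)
    return float(np.mean(e3 - e1))


def _splitting_shift_ci(classical, quantized, n_boot, seed):
    d_cl = classical.energies(3) - classical.energies(1)
    d_q = quantized.energies(3) - quantized.energies(1)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = (np.mean(rng.choice(d_q, len(d_q)))
                   - np.mean(rng.choice(d_cl, len(d_cl))))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return (float(lo), float(hi))
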