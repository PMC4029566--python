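"""Backbone ``15N`` relaxation analysis and reduced spectral density mapping.

Relaxation rate constants are obtained by non-linear least squares of a
two-parameter mono-exponential decay, with standard deviations from the
curvature (inverse-Hessian) matrix and t-based 95% confidence intervals.
The steady-state heteronuclear NOE is the ratio of the peak volumes in the
saturated and non-saturated spectra.  R1, R2 and NOE are then inverted into
the spectral density at three frequencies — J(0), J(wN) and J(0.87*wH) — via
the standard reduced mapping, where all high-frequency dipolar terms are
collapsed onto a single effective frequency 0.87*wH.

Amide hydrogen/deuterium exchange is fitted with the same decay model,
v = v0 * exp(-k t), for peaks with at least three time points; residues that
vanish faster are classified undetectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

# physical constants (SI)
MU0 = 4e-7 * math.pi
HBAR = 1.054571817e-34
GAMMA_H = 2.6752218744e8      # rad s^-1 T^-1
GAMMA_N = -2.7126180436e7     # rad s^-1 T^-1 (15N, negative)

#: delay grids used for the relaxation experiments (s)
R2_DELAYS_S = (0.010, 0.030, 0.050, 0.090, 0.130, 0.170, 0.210)
R1_DELAYS_S = (0.010, 0.080, 0.150, 0.300, 0.500, 0.750, 1.000)


@dataclass(frozen=True)
class FieldParams:
    """Static-field parameters and interaction constants for 15N relaxation.

    Defaults: 18.8 T (800.13 MHz proton), N-H bond length 1.02 A, axially
    symmetric 15N CSA of -160 ppm, high-frequency spectral density evaluated
    at 0.87*wH.
    """

    b0: float
    r_nh: float = 1.02e-10
    csa: float = -160e-6
    high_freq_factor: float = 0.87

    @classmethod
    def from_proton_mhz(cls, proton_mhz: float = 800.13, **kw) -> "FieldParams":
        b0 = 2 * math.pi * proton_mhz * 1e6 / GAMMA_H
        return cls(b0=b0, **kw)

    @property
    def omega_h(self) -> float:
        return GAMMA_H * self.b0

    @property
    def omega_n(self) -> float:
        return abs(GAMMA_N) * self.b0

    @property
    def omega_high(self) -> float:
        return self.high_freq_factor * self.omega_h

    @property
    def gamma_ratio(self) -> float:
        """gamma_N / gamma_H (negative for 15N)."""
        return GAMMA_N / GAMMA_H

    @property
    def d2(self) -> float:
        """Squared dipolar coupling constant, (rad/s)^2."""
        d = MU0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4 * math.pi * self.r_nh ** 3)
        return d * d

    @property
    def c2(self) -> float:
        """Squared CSA interaction constant, (rad/s)^2."""
        c = self.omega_n * self.csa / math.sqrt(3.0)
        return c * c


# --- exponential decay fitting ----------------------------------------------

@dataclass(frozen=True)
class RelaxationSeries:
    residue: int
    delays_s: tuple[float, ...]
    intensities: tuple[float, ...]
    experiment: Literal["R1", "R2"] = "R2"

    def __post_init__(self) -> None:
        if len(self.delays_s) != len(self.intensities):
            raise ValueError("delays and intensities differ in length")
        if len(set(self.delays_s)) < 3:
            raise ValueError("need at least 3 distinct delay values")
        if not all(math.isfinite(v) for v in self.intensities):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class RateFit:
    residue: int
    rate: float | None
    amplitude: float | None
    sd: float | None
    ci95: tuple[float, float] | None
    success: bool
    message: str = ""


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, int]:
    """Fit y = A * exp(-k t); returns (A, k, sd_A, sd_k, dof)."""
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 1e-6))
    else:
        p0 = (float(y[0]), 1.0)

    def model(t, a, k):
        return a * np.exp(-k * t)

    def jac(t, a, k):
        e = np.exp(-k * t)
        return np.column_stack([e, -a * t * e])

    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, jac=jac, maxfev=10000)
    dof = len(t) - 2
    perr = np.sqrt(np.diag(pcov))
    return popt[0], popt[1], perr[0], perr[1], dof


def fit_rate(series: RelaxationSeries) -> RateFit:
    """Mono-exponential decay fit I(t) = I0 * exp(-R t).

    The standard deviation of R comes from the curvature matrix of the least
    squares problem; the 95% confidence interval uses the t distribution with
    n - 2 degrees of freedom.  Constant or non-decaying data are flagged as
    fit failures rather than returning a rate.
    """
    t = np.asarray(series.delays_s, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    if np.ptp(y) == 0:
        return RateFit(series.residue, None, None, None, None, False,
                       "constant intensities")
    try:
        a, k, _, sd_k, dof = _fit_exponential(t, y)
    except Exception as exc:  # convergence failure
        return RateFit(series.residue, None, None, None, None, False, str(exc))
    if k <= 0 or not math.isfinite(k):
        return RateFit(series.residue, None, None, None, None, False,
                       "non-decaying series")
    tq = stats.t.ppf(0.975, dof) if dof > 0 else math.nan
    ci = (k - tq * sd_k, k + tq * sd_k)
    return RateFit(series.residue, k, a, sd_k, ci, True)


# --- heteronuclear NOE -------------------------------------------------------

@dataclass(frozen=True)
class HetNOEPair:
    residue: int
    vol_saturated: float
    vol_unsaturated: float


def het_noe(pair: HetNOEPair) -> float:
    """NOE = saturated / unsaturated peak volume."""
    if pair.vol_unsaturated == 0:
        raise ValueError("unsaturated peak volume must be non-zero")
    return pair.vol_saturated / pair.vol_unsaturated


# --- reduced spectral density mapping ----------------------------------------

@dataclass(frozen=True)
class SpectralDensityTriple:
    residue: int
    j0: float
    jn: float
    jh: float
    r_ex: float | None = None
    flagged: bool = False


def relaxation_from_j(j0: float, jn: float, jh: float, field: FieldParams,
                      r_ex: float = 0.0) -> tuple[float, float, float]:
    """Forward reduced-form relations: (J(0), J(wN), J(0.87wH)) -> (R1, R2, NOE).

    This is the exact algebraic inverse of :func:`map_spectral_density`.
    """
    d2, c2 = field.d2, field.c2
    r1 = d2 / 4 * (3 * jn + 7 * jh) + c2 * jn
    r2 = (d2 / 8 * (4 * j0 + 3 * jn + 13 * jh)
          + c2 / 6 * (4 * j0 + 3 * jn) + r_ex)
    sigma = d2 / 4 * 5 * jh
    noe = 1.0 + (1.0 / field.gamma_ratio) * sigma / r1
    return r1, r2, noe


def map_spectral_density(r1: float, r2: float, noe: float, field: FieldParams,
                         residue: int = 0,
                         neg_tol: float = 0.0) -> SpectralDensityTriple:
    """Invert R1, R2 and NOE into J(0), J(wN) and J(0.87wH).

    NOE = 1 forces a zero cross-relaxation rate and hence J(0.87wH) = 0.
    A resulting J below ``-neg_tol`` flags the triple (noise or an exchange
    inconsistency) without discarding it.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("relaxation rates must be positive")
    d2, c2 = field.d2, field.c2
    sigma = (noe - 1.0) * r1 * field.gamma_ratio
    jh = 4 * sigma / (5 * d2)
    jn = (r1 - 7 * d2 / 4 * jh) / (3 * d2 / 4 + c2)
    j0 = (r2 - (3 * d2 / 8 + c2 / 2) * jn - 13 * d2 / 8 * jh) / (d2 / 2 + 2 * c2 / 3)
    flagged = min(j0, jn, jh) < -neg_tol
    return SpectralDensityTriple(residue, j0, jn, jh, flagged=flagged)


def estimate_rex(triples: Sequence[SpectralDensityTriple], field: FieldParams,
                 trim: float = 0.10) -> list[SpectralDensityTriple]:
    """Heuristic per-residue exchange contribution from the J(0) excess.

    The baseline J(0) is the ``trim``-trimmed mean over residues; the excess
    is converted to rate units through the coefficient of J(0) in R2.  This
    is a labelled heuristic, not a model-free exchange fit.
    """
    if not triples:
        return []
    j0s = np.array([tr.j0 for tr in triples])
    baseline = stats.trim_mean(j0s, trim)
    coeff = field.d2 / 2 + 2 * field.c2 / 3
    return [SpectralDensityTriple(tr.residue, tr.j0, tr.jn, tr.jh,
                                  r_ex=(tr.j0 - baseline) * coeff,
                                  flagged=tr.flagged)
            for tr in triples]


def lorentzian_j(omega: float, tau_c: float) -> float:
    """Single-Lorentzian spectral density (s/rad), isotropic rigid tumbling."""
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def lipari_szabo_j(omega: float, s2: float, tau_m: float, tau_e: float) -> float:
    """Two-timescale model-free spectral density (s/rad).

    s2 is the squared order parameter, tau_m the global tumbling time and
    tau_e the internal correlation time (tau_e < tau_m).
    """
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("order parameter S^2 must lie in [0, 1]")
    if tau_e >= tau_m:
        raise ValueError("internal time must be shorter than tumbling time")
    tau = tau_m * tau_e / (tau_m + tau_e)
    return 0.4 * (s2 * tau_m / (1 + (omega * tau_m) ** 2)
                  + (1 - s2) * tau / (1 + (omega * tau) ** 2))


# --- hydrogen/deuterium exchange ---------------------------------------------

@dataclass(frozen=True)
class HDXSeries:
    residue: int
    times_h: tuple[float, ...]
    integrals: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.integrals):
            raise ValueError("times and integrals differ in length")


@dataclass(frozen=True)
class HalfLife:
    residue: int
    half_life_h: float | None
    k_per_h: float | None
    sd_k: float | None
    detectable: bool
    message: str = ""


def fit_hdx_halflife(series: HDXSeries, min_points: int = 3) -> HalfLife:
    """Exponential decay fit v = v0 * exp(-k t); half-life = ln 2 / k.

    Peaks with fewer than ``min_points`` time points exchange too fast to be
    fitted and are classified undetectable.
    """
    if len(series.times_h) < min_points:
        return HalfLife(series.residue, None, None, None, False,
                        f"only {len(series.times_h)} points; exchange too fast")
    t = np.asarray(series.times_h, dtype=float)
    v = np.asarray(series.integrals, dtype=float)
    if np.ptp(v) == 0:
        return HalfLife(series.residue, None, None, None, False,
                        "constant integrals")
    try:
        _, k, _, sd_k, _ = _fit_exponential(t, v)
    except Exception as exc:
        return HalfLife(series.residue, None, None, None, False, str(exc))
    if k <= 0:
        return HalfLife(series.residue, None, None, None, False,
                        "non-decaying integrals")
    return HalfLife(series.residue, math.log(2.0) / k, k, sd_k, True)


def classify_slow_exchangers(halflives: Iterable[HalfLife],
                             threshold_h: float = 2.5) -> set[int]:
    """Residues whose amide half-life strictly exceeds ``threshold_h`` hours.

    These are the H-bond-candidate amides; undetectable residues are excluded.
    """
    return {hl.residue for hl in halflives
            if hl.detectable and hl.half_life_h is not None
            and hl.half_life_h > threshold_h}
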