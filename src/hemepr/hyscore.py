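"""Proton HYSCORE analysis: nuclear frequencies, correlation ridges,
point-dipole distances, and the 2D time-to-frequency processing chain.

For an S = 1/2, I = 1/2 pair the nuclear transition frequencies of the two
electron-spin manifolds at orientation theta (angle between the hyperfine
symmetry axis and the field) are

    A(theta) = aiso + T (3 cos^2 theta - 1)
    B(theta) = 3 T sin(theta) cos(theta)
    nu_{alpha,beta} = sqrt( (nu_I -/+ A/2)^2 + (B/2)^2 )

with nu_I the nuclear Larmor frequency.  Sweeping theta traces the
correlation ridge observed in the (+,+) quadrant of a HYSCORE spectrum.  The
axial dipolar coupling T maps to an electron-nucleus distance through the
point-dipole approximation

    T = (mu0 / 4 pi h) * g_e beta_e g_n beta_n / r^3 .

Raw 4-pulse HYSCORE time traces are turned into magnitude spectra by
polynomial baseline correction along both time axes, separable Hamming
apodization, zero filling, 2D Fourier transformation and the absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ConfigurationError, FormatError

__all__ = [
    "HyperfineCoupling",
    "NuclearFrequencies",
    "HyscoreMap",
    "NUCLEAR_G_FACTORS",
    "larmor_frequency",
    "nuclear_frequencies",
    "ridge_curve",
    "ridge_apex_shift",
    "orientation_weights",
    "blind_spot_weight",
    "point_dipole_distance",
    "dipolar_from_distance",
    "dipolar_prefactor_MHz_A3",
    "process_hyscore",
]

#: Nuclear g-factors of the supported nuclei.  Proton-only by design: the
#: printed dataset quantifies only the 1H couplings.  Extend by assignment.
NUCLEAR_G_FACTORS: dict[str, float] = {
    "1H": constants.physical_constants["proton g factor"][0],
}

_G_E = abs(constants.physical_constants["electron g factor"][0])
_MU_B = constants.physical_constants["Bohr magneton"][0]
_MU_N = constants.physical_constants["nuclear magneton"][0]


@dataclass(frozen=True)
class HyperfineCoupling:
    """Axial hyperfine interaction: isotropic part ``aiso_MHz`` (signed),
    dipolar magnitude ``T_MHz`` (>= 0) and the polar angle ``beta_deg`` of the
    electron-nucleus vector in the g frame (0-90 degrees)."""

    aiso_MHz: float
    T_MHz: float
    beta_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.T_MHz < 0:
            raise ConfigurationError("T_MHz is a magnitude; track sign on aiso")
        if not 0.0 <= self.beta_deg <= 90.0:
            raise ConfigurationError("beta_deg must lie in [0, 90]")


@dataclass(frozen=True)
class NuclearFrequencies:
    """Nuclear transition frequencies (MHz) in the alpha and beta electron-spin
    manifolds, evaluated at orientation ``theta_rad``."""

    nu_alpha_MHz: float
    nu_beta_MHz: float
    theta_rad: float


@dataclass(frozen=True)
class HyscoreMap:
    """2D HYSCORE data on time (ns) or frequency (MHz) axes."""

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    domain: str  # "time" or "frequency"
    field_mT: float | None = None
    mw_freq_GHz: float | None = None
    tau_ns: float | None = None

    def __post_init__(self) -> None:
        a1 = np.asarray(self.axis1, dtype=float)
        a2 = np.asarray(self.axis2, dtype=float)
        v = np.asarray(self.values)
        if self.domain not in ("time", "frequency"):
            raise ConfigurationError(f"unknown domain {self.domain!r}")
        if v.shape != (a1.size, a2.size):
            raise ConfigurationError(
                f"values shape {v.shape} does not match axes ({a1.size}, {a2.size})"
            )
        if self.domain == "frequency" and (np.iscomplexobj(v) or np.any(v < 0)):
            raise ConfigurationError("frequency-domain values must be a magnitude")
        object.__setattr__(self, "axis1", a1)
        object.__setattr__(self, "axis2", a2)
        object.__setattr__(self, "values", v)


def larmor_frequency(field_mT: float, nucleus: str = "1H") -> float:
    """Nuclear Larmor frequency nu_I = g_n * mu_N * B / h in MHz."""
    try:
        gn = NUCLEAR_G_FACTORS[nucleus]
    except KeyError:
        raise ConfigurationError(
            f"unknown nucleus {nucleus!r}; supported: {sorted(NUCLEAR_G_FACTORS)}"
        ) from None
    return abs(gn) * _MU_N * field_mT * 1e-3 / constants.h * 1e-6


def nuclear_frequencies(
    hfc: HyperfineCoupling, nu_I_MHz: float, theta_rad: float
) -> NuclearFrequencies:
    """Evaluate both manifold frequencies at orientation ``theta_rad``."""
    if not nu_I_MHz > 0:
        raise ConfigurationError("nu_I_MHz must be > 0")
    a = hfc.aiso_MHz + hfc.T_MHz * (3.0 * np.cos(theta_rad) ** 2 - 1.0)
    b = 3.0 * hfc.T_MHz * np.sin(theta_rad) * np.cos(theta_rad)
    nu_alpha = np.sqrt((nu_I_MHz - a / 2.0) ** 2 + (b / 2.0) ** 2)
    nu_beta = np.sqrt((nu_I_MHz + a / 2.0) ** 2 + (b / 2.0) ** 2)
    return NuclearFrequencies(float(nu_alpha), float(nu_beta), float(theta_rad))


def ridge_curve(
    hfc: HyperfineCoupling,
    nu_I_MHz: float,
    n_theta: int = 181,
    mirror: bool = True,
) -> np.ndarray:
    """Correlation ridge as (nu_alpha, nu_beta) pairs over theta in [0, pi/2].

    With ``mirror`` the (nu_beta, nu_alpha) branch is appended, as both appear
    symmetrically about the diagonal of a HYSCORE spectrum.  Returns an
    (N, 2) array suitable for overlay on a frequency-domain map.
    """
    if n_theta < 2:
        raise ConfigurationError("n_theta must be >= 2")
    theta = np.linspace(0.0, np.pi / 2.0, n_theta)
    pairs = np.array(
        [
            (nf.nu_alpha_MHz, nf.nu_beta_MHz)
            for nf in (nuclear_frequencies(hfc, nu_I_MHz, t) for t in theta)
        ]
    )
    if mirror:
        pairs = np.vstack([pairs, pairs[:, ::-1]])
    return pairs


def ridge_apex_shift(hfc: HyperfineCoupling, nu_I_MHz: float, n_theta: int = 4001) -> float:
    """Apex elevation of the ridge above the proton antidiagonal (MHz).

    Measured as the maximum shift of the half-sum frequency,
    max over theta of (nu_alpha + nu_beta)/2 - nu_I.  For a weak axial
    coupling this approaches 9 T^2 / (32 nu_I), the standard curvature
    measure used to read the dipolar coupling T off a proton ridge.
    """
    pairs = ridge_curve(hfc, nu_I_MHz, n_theta=n_theta, mirror=False)
    return float(np.max(pairs.sum(axis=1)) / 2.0 - nu_I_MHz)


def orientation_weights(
    theta_rad: np.ndarray, beta_deg: float, width_deg: float = 15.0
) -> np.ndarray:
    """Gaussian orientation-selection weights centered on the coupling's beta
    angle, for ridge overlays at a field position that excites orientations
    near a principal axis (e.g. the gz extremity)."""
    beta = np.deg2rad(beta_deg)
    width = np.deg2rad(width_deg)
    return np.exp(-0.5 * ((np.asarray(theta_rad) - beta) / width) ** 2)


def blind_spot_weight(
    nu_alpha_MHz: np.ndarray, nu_beta_MHz: np.ndarray, tau_ns: float
) -> np.ndarray:
    """4-pulse HYSCORE blind-spot suppression sin^2(pi nu_a tau) sin^2(pi nu_b tau)."""
    tau_us = tau_ns * 1e-3
    return (
        np.sin(np.pi * np.asarray(nu_alpha_MHz) * tau_us) ** 2
        * np.sin(np.pi * np.asarray(nu_beta_MHz) * tau_us) ** 2
    )


def dipolar_prefactor_MHz_A3(nucleus: str = "1H") -> float:
    """(mu0/4 pi h) g_e beta_e g_n beta_n in MHz * Angstrom^3 (~79.07 for 1H)."""
    try:
        gn = abs(NUCLEAR_G_FACTORS[nucleus])
    except KeyError:
        raise ConfigurationError(
            f"unknown nucleus {nucleus!r}; supported: {sorted(NUCLEAR_G_FACTORS)}"
        ) from None
    pref_Hz_m3 = constants.mu_0 / (4.0 * np.pi) * _G_E * _MU_B * gn * _MU_N / constants.h
    return pref_Hz_m3 * 1e-6 * 1e30  # Hz m^3 -> MHz A^3


def point_dipole_distance(T_MHz: float, nucleus: str = "1H") -> float:
    """Electron-nucleus distance r (Angstrom) from the dipolar coupling T."""
    if not T_MHz > 0:
        raise ConfigurationError("T_MHz must be > 0")
    return float((dipolar_prefactor_MHz_A3(nucleus) / T_MHz) ** (1.0 / 3.0))


def dipolar_from_distance(r_angstrom: float, nucleus: str = "1H") -> float:
    """Dipolar coupling T (MHz) at electron-nucleus distance r (Angstrom)."""
    if not r_angstrom > 0:
        raise ConfigurationError("r must be > 0")
    return float(dipolar_prefactor_MHz_A3(nucleus) / r_angstrom**3)


def _hamming(n: int) -> np.ndarray:
    # 0.54 - 0.46 cos(2 pi k/(N-1)); the symmetric dialect
    if n == 1:
        return np.ones(1)
    k = np.arange(n)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (n - 1))


def _baseline_2d(values: np.ndarray, t1: np.ndarray, t2: np.ndarray, order: int) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    # rows (along axis2) then columns (along axis1)
    w2 = np.ptp(t2) / 2.0 or 1.0
    x2 = (t2 - t2.mean()) / w2
    coeffs = np.polynomial.polynomial.polyfit(x2, out.T, order)
    out -= np.polynomial.polynomial.polyval(x2, coeffs)
    w1 = np.ptp(t1) / 2.0 or 1.0
    x1 = (t1 - t1.mean()) / w1
    coeffs = np.polynomial.polynomial.polyfit(x1, out, order)
    out -= np.polynomial.polynomial.polyval(x1, coeffs).T
    return out


def _next_pow2(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


def _process_complex(
    raw: HyscoreMap,
    baseline_order: int = 3,
    window: str = "hamming",
    zerofill_factor: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline, apodize, zero-fill and 2D-FFT a time-domain map.

    Returns (f1_MHz, f2_MHz, complex spectrum), fftshifted on both axes.
    This pre-magnitude stage is linear in the input values.
    """
    if raw.domain != "time":
        raise ConfigurationError("process_hyscore expects a time-domain map")
    t1, t2 = raw.axis1, raw.axis2
    for t, name in ((t1, "axis1"), (t2, "axis2")):
        d = np.diff(t)
        if d.size == 0 or not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise FormatError(f"{name} dwell time is not uniform")
    n1, n2 = t1.size, t2.size
    if baseline_order >= min(n1, n2):
        raise ConfigurationError(
            f"baseline_order {baseline_order} must be < number of points {min(n1, n2)}"
        )
    if zerofill_factor < 1:
        raise ConfigurationError("zerofill_factor must be >= 1")
    if window not in ("hamming", "none"):
        raise ConfigurationError(f"unsupported window {window!r}")

    if np.iscomplexobj(raw.values):
        vals = _baseline_2d(raw.values.real, t1, t2, baseline_order).astype(complex)
        vals += 1j * _baseline_2d(raw.values.imag, t1, t2, baseline_order)
    else:
        vals = _baseline_2d(raw.values, t1, t2, baseline_order)
    if window == "hamming":
        vals = vals * _hamming(n1)[:, None] * _hamming(n2)[None, :]

    m1 = zerofill_factor * _next_pow2(n1)
    m2 = zerofill_factor * _next_pow2(n2)
    spec = np.fft.fft2(vals, s=(m1, m2))
    dwell1_us = (t1[1] - t1[0]) * 1e-3
    dwell2_us = (t2[1] - t2[0]) * 1e-3
    f1 = np.fft.fftshift(np.fft.fftfreq(m1, d=dwell1_us))
    f2 = np.fft.fftshift(np.fft.fftfreq(m2, d=dwell2_us))
    return f1, f2, np.fft.fftshift(spec)


def process_hyscore(
    raw: HyscoreMap,
    baseline_order: int = 3,
    window: str = "hamming",
    zerofill_factor: int = 2,
    full: bool = False,
) -> HyscoreMap:
    """Standard HYSCORE processing: per-row and per-column polynomial baseline
    subtraction (default third order), separable Hamming apodization,
    zero filling to ``zerofill_factor`` times the next power of two, 2D
    Fourier transformation and the absolute-value spectrum.

    By default only the (+,+) frequency quadrant is returned — the quadrant
    carrying the weak-coupling proton correlation ridges; ``full=True`` keeps
    all quadrants (axes centered on zero).
    """
    f1, f2, spec = _process_complex(raw, baseline_order, window, zerofill_factor)
    mag = np.abs(spec)
    if not full:
        i1 = f1 >= 0
        i2 = f2 >= 0
        f1, f2, mag = f1[i1], f2[i2], mag[np.ix_(i1, i2)]
    return HyscoreMap(
        axis1=f1, axis2=f2, values=mag, domain="frequency",
        field_mT=raw.field_mT, mw_freq_GHz=raw.mw_freq_GHz, tau_ns=raw.tau_ns,
    )
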