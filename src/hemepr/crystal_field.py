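"""Griffith–Taylor one-hole analysis of low-spin ferric heme g-tensors.

A low-spin d5 ion (S = 1/2) with the single hole in the t2g set has a Kramers
ground doublet that is an admixture of the three t2g orbitals,

    |+> = a|dyz,+> - i b|dxz,+> - c|dxy,->

with real mixing coefficients a, b, c.  The principal g-values follow from the
coefficients,

    gz = 2[(a+b)^2 - c^2],  gy = 2[(a+c)^2 - b^2],  gx = 2[a^2 - (b+c)^2],

and conversely, with D = sqrt(8(gz + gy - gx)),

    a = (gz+gy)/D,  b = (gz-gx)/D,  c = (gy-gx)/D.

The rhombic (V) and axial (Delta) splittings of the t2g orbitals, in units of
the spin-orbit coupling constant xi, follow Taylor's expressions

    V/xi     = gx/(gz+gy) + gy/(gz-gx)
    Delta/xi = gx/(gz+gy) + gz/(gy-gx) - (V/xi)/2.

The normalization m^2 = a^2 + b^2 + c^2 gauges the validity of the pure-t2g
picture: m^2 < 1 hints at covalent delocalization onto the ligands, m^2 > 1 at
admixture of excited states with orbital character.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateGError,
    InvalidCoefficientsError,
    InvalidGTensorError,
)

__all__ = [
    "GTensor",
    "OrbitalCoefficients",
    "CrystalFieldParams",
    "coefficients_from_g",
    "g_from_coefficients",
    "crystal_field_ratios",
    "propagate_uncertainties",
    "analyze_table",
    "rounded_report",
    "read_gtensor_table",
    "reference_gtensors",
    "normalization_flag",
    "XI_FREE_IRON_CM1",
    "REPORT_COLUMNS",
]

#: Free-ion spin-orbit coupling constant of Fe(III), cm^-1 (conventional value).
XI_FREE_IRON_CM1 = 400.0

#: Advisory threshold on |m^2 - 1| beyond which a normalization flag is raised.
M2_FLAG_THRESHOLD = 0.02


@dataclass(frozen=True)
class GTensor:
    """Principal g-values of an S = 1/2 center, canonically ordered gz >= gy >= gx.

    Inputs are reordered on construction (with a warning) so that the
    largest principal value is gz; the one-hole formalism assumes this axis
    convention.  Uncertainties are optional 1-sigma values; ``None`` means
    "not determined", which is distinct from an explicit 0.
    """

    gz: float
    gy: float
    gx: float
    sigma_gz: float | None = None
    sigma_gy: float | None = None
    sigma_gx: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        g = (float(self.gz), float(self.gy), float(self.gx))
        if any(v <= 0 or not np.isfinite(v) for v in g):
            raise InvalidGTensorError(f"g-values must be strictly positive, got {g}")
        sig = (self.sigma_gz, self.sigma_gy, self.sigma_gx)
        for s in sig:
            if s is not None and (s < 0 or not np.isfinite(s)):
                raise InvalidGTensorError(f"uncertainties must be >= 0, got {sig}")
        if not (g[0] >= g[1] >= g[2]):
            order = sorted(range(3), key=lambda i: g[i], reverse=True)
            warnings.warn(
                f"g-values {g} reordered to the canonical gz >= gy >= gx convention",
                stacklevel=3,
            )
            gs = [g[i] for i in order]
            ss = [sig[i] for i in order]
            object.__setattr__(self, "gz", gs[0])
            object.__setattr__(self, "gy", gs[1])
            object.__setattr__(self, "gx", gs[2])
            object.__setattr__(self, "sigma_gz", ss[0])
            object.__setattr__(self, "sigma_gy", ss[1])
            object.__setattr__(self, "sigma_gx", ss[2])

    @property
    def values(self) -> np.ndarray:
        """Principal values as an array (gz, gy, gx)."""
        return np.array([self.gz, self.gy, self.gx])

    @property
    def sigmas(self) -> np.ndarray | None:
        """1-sigma uncertainties (gz, gy, gx), or None if any is unset."""
        s = (self.sigma_gz, self.sigma_gy, self.sigma_gx)
        if any(v is None for v in s):
            return None
        return np.array(s, dtype=float)


@dataclass(frozen=True)
class OrbitalCoefficients:
    """Mixing coefficients (a, b, c) of the Kramers ground doublet.

    ``m_squared`` is always recomputed from the coefficients; it is not an
    independent degree of freedom.
    """

    a: float
    b: float
    c: float

    @property
    def m_squared(self) -> float:
        return self.a**2 + self.b**2 + self.c**2


@dataclass(frozen=True)
class CrystalFieldParams:
    """Crystal-field splittings of the t2g orbitals in units of xi.

    ``v_abs`` / ``delta_abs`` (cm^-1) are populated only when an absolute
    spin-orbit constant xi was supplied.
    """

    v_over_xi: float
    delta_over_xi: float
    rhombicity: float
    sigma_v: float | None = None
    sigma_delta: float | None = None
    sigma_rhombicity: float | None = None
    v_abs: float | None = None
    delta_abs: float | None = None


def coefficients_from_g(g: GTensor) -> OrbitalCoefficients:
    """Invert the g-values to the orbital mixing coefficients.

    Uses a = (gz+gy)/D, b = (gz-gx)/D, c = (gy-gx)/D with
    D = sqrt(8(gz+gy-gx)).

    Raises
    ------
    InvalidGTensorError
        If gz + gy - gx <= 0, where D is undefined.
    """
    gz, gy, gx = g.gz, g.gy, g.gx
    arg = gz + gy - gx
    if arg <= 0:
        raise InvalidGTensorError(
            f"gz + gy - gx = {arg:.6g} must be > 0 for the one-hole inversion"
        )
    d = np.sqrt(8.0 * arg)
    return OrbitalCoefficients(a=(gz + gy) / d, b=(gz - gx) / d, c=(gy - gx) / d)


def g_from_coefficients(coeffs: OrbitalCoefficients) -> GTensor:
    """Forward map from mixing coefficients to principal g-values."""
    a, b, c = coeffs.a, coeffs.b, coeffs.c
    if a + b + c <= 0:
        raise InvalidCoefficientsError(
            f"a + b + c = {a + b + c:.6g} must be > 0 to define a g-tensor"
        )
    gz = 2.0 * ((a + b) ** 2 - c**2)
    gy = 2.0 * ((a + c) ** 2 - b**2)
    gx = 2.0 * (a**2 - (b + c) ** 2)
    return GTensor(gz=gz, gy=gy, gx=gx, sigma_gz=0.0, sigma_gy=0.0, sigma_gx=0.0)


def _ratios(gz: float, gy: float, gx: float) -> tuple[float, float, float]:
    v = gx / (gz + gy) + gy / (gz - gx)
    delta = gx / (gz + gy) + gz / (gy - gx) - v / 2.0
    return v, delta, v / delta


def crystal_field_ratios(g: GTensor, xi: float | None = None) -> CrystalFieldParams:
    """Taylor crystal-field ratios V/xi, Delta/xi and the rhombicity V/Delta.

    Parameters
    ----------
    g
        Canonically ordered g-tensor with gz > gx and gy > gx strictly.
    xi
        Optional spin-orbit coupling constant in cm^-1 (free Fe(III):
        ~400 cm^-1).  When given, absolute V and Delta are also returned.

    Raises
    ------
    DegenerateGError
        If gz = gx or gy = gx, naming the vanishing denominator.
    """
    if g.gz <= g.gx:
        raise DegenerateGError("gz - gx vanishes: rhombic analysis undefined")
    if g.gy <= g.gx:
        raise DegenerateGError("gy - gx vanishes: rhombic analysis undefined")
    v, delta, rho = _ratios(g.gz, g.gy, g.gx)
    v_abs = delta_abs = None
    if xi is not None:
        if xi <= 0:
            raise ConfigurationError(f"xi must be positive, got {xi}")
        v_abs, delta_abs = v * xi, delta * xi
    return CrystalFieldParams(
        v_over_xi=v,
        delta_over_xi=delta,
        rhombicity=rho,
        v_abs=v_abs,
        delta_abs=delta_abs,
    )


def _jacobian(gz: float, gy: float, gx: float) -> np.ndarray:
    """Analytic partials of (V/xi, Delta/xi, V/Delta) w.r.t. (gz, gy, gx)."""
    s = gz + gy  # gx numerator denominator
    dzx = gz - gx
    dyx = gy - gx
    v, delta, _ = _ratios(gz, gy, gx)

    dv = np.array(
        [
            -gx / s**2 - gy / dzx**2,
            -gx / s**2 + 1.0 / dzx,
            1.0 / s + gy / dzx**2,
        ]
    )
    ddelta = (
        np.array(
            [
                -gx / s**2 + 1.0 / dyx,
                -gx / s**2 - gz / dyx**2,
                1.0 / s + gz / dyx**2,
            ]
        )
        - dv / 2.0
    )
    drho = (dv * delta - v * ddelta) / delta**2
    return np.vstack([dv, ddelta, drho])


def propagate_uncertainties(
    g: GTensor,
    method: str = "linear_sum",
    n_draws: int = 10_000,
    seed: int | None = None,
    xi: float | None = None,
) -> CrystalFieldParams:
    """Propagate g-value uncertainties onto the crystal-field ratios.

    ``linear_sum`` is the conservative worst-case rule sum_i |df/dg_i| sigma_i
    (this reproduces the printed +-0.06 on V/xi for the resting-state enzyme);
    ``quadrature`` is the root-sum-square, always <= linear_sum;
    ``monte_carlo`` draws independent Gaussian g-values and reports the sample
    standard deviation (requires an explicit seed for reproducibility).
    """
    sig = g.sigmas
    if sig is None:
        raise ConfigurationError(
            f"all three sigma fields must be set on {g.label or 'the g-tensor'}"
        )
    central = crystal_field_ratios(g, xi=xi)
    jac = _jacobian(g.gz, g.gy, g.gx)

    if method == "linear_sum":
        out = np.abs(jac) @ sig
    elif method == "quadrature":
        out = np.sqrt((jac**2) @ (sig**2))
    elif method == "monte_carlo":
        if seed is None:
            raise ConfigurationError("monte_carlo propagation requires a seed")
        if n_draws < 1000:
            raise ConfigurationError(f"n_draws must be >= 1000, got {n_draws}")
        rng = np.random.default_rng(seed)
        draws = g.values[None, :] + rng.standard_normal((n_draws, 3)) * sig[None, :]
        vals = np.array([_ratios(*row) for row in draws])
        out = vals.std(axis=0, ddof=1)
    else:
        raise ConfigurationError(
            f"unknown method {method!r}; choose linear_sum, quadrature or monte_carlo"
        )
    return CrystalFieldParams(
        v_over_xi=central.v_over_xi,
        delta_over_xi=central.delta_over_xi,
        rhombicity=central.rhombicity,
        sigma_v=float(out[0]),
        sigma_delta=float(out[1]),
        sigma_rhombicity=float(out[2]),
        v_abs=central.v_abs,
        delta_abs=central.delta_abs,
    )


def normalization_flag(m_squared: float) -> str:
    """Advisory interpretation of the normalization parameter m^2.

    Returns an empty string while |m^2 - 1| <= 0.02; otherwise a short note:
    m^2 below one suggests covalent spin delocalization onto the ligands,
    above one suggests admixture of excited states with orbital character.
    """
    if m_squared < 1.0 - M2_FLAG_THRESHOLD:
        return "m2<1: possible covalent delocalization"
    if m_squared > 1.0 + M2_FLAG_THRESHOLD:
        return "m2>1: possible excited-state admixture"
    return ""


REPORT_COLUMNS = [
    "label", "gz", "gy", "gx", "a", "b", "c", "m2",
    "V_xi", "dV_xi", "Delta_xi", "dDelta_xi", "V_Delta", "dV_Delta",
]


def analyze_table(
    rows: Sequence[GTensor],
    xi: float | None = None,
    method: str = "linear_sum",
    n_draws: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Batch crystal-field analysis: one report record per input g-tensor.

    Rows that fail (degenerate g-values, missing sigmas...) are kept in place
    with NaN numerics and the error message in the ``error`` column; the batch
    continues.  Row order is the input order.
    """
    if len(rows) == 0:
        raise ConfigurationError("analyze_table requires at least one g-tensor row")
    records = []
    for row in rows:
        rec: dict = {c: np.nan for c in REPORT_COLUMNS}
        rec.update(label=row.label, gz=row.gz, gy=row.gy, gx=row.gx,
                   flag="", error="")
        try:
            coeffs = coefficients_from_g(row)
            rec.update(a=coeffs.a, b=coeffs.b, c=coeffs.c, m2=coeffs.m_squared,
                       flag=normalization_flag(coeffs.m_squared))
            if row.sigmas is not None:
                cf = propagate_uncertainties(row, method=method,
                                             n_draws=n_draws, seed=seed, xi=xi)
            else:
                cf = crystal_field_ratios(row, xi=xi)
            rec.update(
                V_xi=cf.v_over_xi, dV_xi=cf.sigma_v,
                Delta_xi=cf.delta_over_xi, dDelta_xi=cf.sigma_delta,
                V_Delta=cf.rhombicity, dV_Delta=cf.sigma_rhombicity,
            )
            if cf.v_abs is not None:
                rec.update(V_cm1=cf.v_abs, Delta_cm1=cf.delta_abs)
        except (InvalidGTensorError, DegenerateGError, ConfigurationError) as exc:
            rec["error"] = str(exc)
        records.append(rec)
    cols = REPORT_COLUMNS + [c for c in ("V_cm1", "Delta_cm1") if any(
        c in r for r in records)] + ["flag", "error"]
    return pd.DataFrame.from_records(records, columns=cols)


def rounded_report(df: pd.DataFrame) -> pd.DataFrame:
    """Report rounded to publication precision.

    Coefficients and m^2 to 3 decimals, crystal-field ratios and their
    uncertainties to 2, matching how such tables are conventionally printed;
    raw doubles stay available in the unrounded frame.
    """
    out = df.copy()
    for c in ("a", "b", "c", "m2"):
        if c in out:
            out[c] = out[c].round(3)
    for c in ("V_xi", "dV_xi", "Delta_xi", "dDelta_xi", "V_Delta", "dV_Delta"):
        if c in out:
            out[c] = out[c].round(2)
    return out


def read_gtensor_table(path) -> list[GTensor]:
    """Read g-tensors from CSV/TSV with columns label,gz,gy,gx[,sgz,sgy,sgx].

    Extra columns (line-broadening parameters etc.) are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"label", "gz", "gy", "gx"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"g-tensor table lacks columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        kwargs = {}
        for src, dst in (("sgz", "sigma_gz"), ("sgy", "sigma_gy"), ("sgx", "sigma_gx")):
            if src in df.columns and pd.notna(r[src]):
                kwargs[dst] = float(r[src])
        rows.append(GTensor(gz=float(r["gz"]), gy=float(r["gy"]), gx=float(r["gx"]),
                            label=str(r["label"]), **kwargs))
    return rows


def reference_gtensors() -> list[GTensor]:
    """The packaged reference table of g-tensors for CYP116B5hd, its histidine
    and imidazole adducts, and the benchmark enzyme CYPBM3hd."""
    with resources.files("hemepr.data").joinpath("gtensors.csv").open("r") as fh:
        return read_gtensor_table(fh)
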