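"""Reader/writer for the Bruker BES3T format (.DSC descriptor + .DTA binary)
and plain ASCII spectra.

The supported BES3T subset covers the layouts produced by an Elexsys-series
spectrometer for 1D field-swept CW spectra and 2D pulse data: real (IKKF
REAL) or complex (IKKF CPLX) values, float64 ('D') or int32 ('I') storage,
big- or little-endian byte order (BSEQ), and linear (XTYP/YTYP IDX) axes
reconstructed from MIN/WID/PTS.  Nonlinear companion axis files (.XGF/.YGF)
are detected and rejected explicitly.  Field axes in Gauss are normalized to
mT on read.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["EPRDataset", "read_bes3t", "write_bes3t", "read_ascii", "write_ascii"]

_FORMATS = {"D": ("f8", 8), "I": ("i4", 4)}
_BYTE_ORDERS = {"BIG": ">", "LIT": "<"}


@dataclass
class EPRDataset:
    """In-memory EPR dataset: 1 or 2 monotone axes with units, a real or
    complex value array of matching shape, and the raw descriptor key map."""

    axes: list[np.ndarray]
    units: list[str]
    values: np.ndarray
    params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.values = np.asarray(self.values)
        if len(self.axes) not in (1, 2) or len(self.units) != len(self.axes):
            raise FormatError("EPRDataset needs 1 or 2 axes with matching units")
        shape = tuple(a.size for a in self.axes)
        if self.values.shape != (shape if len(shape) > 1 else (shape[0],)):
            raise FormatError(
                f"values shape {self.values.shape} does not match axes {shape}"
            )
        for a in self.axes:
            if a.size > 1 and not (np.all(np.diff(a) > 0) or np.all(np.diff(a) < 0)):
                raise FormatError("axes must be monotone")

    @property
    def ndim(self) -> int:
        return len(self.axes)


def _parse_dsc(text: str) -> dict[str, str]:
    params: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "*", ";", ".DVC")):
            continue
        parts = line.split(None, 1)
        if len(parts) == 2:
            params[parts[0]] = parts[1].strip().strip("'\"")
        elif len(parts) == 1:
            params[parts[0]] = ""
    return params


def _axis_from_params(params: dict[str, str], prefix: str) -> tuple[np.ndarray, str]:
    for key in (f"{prefix}PTS", f"{prefix}MIN", f"{prefix}WID"):
        if key not in params:
            raise FormatError(f"descriptor lacks required key {key}")
    npts = int(params[f"{prefix}PTS"])
    vmin = float(params[f"{prefix}MIN"])
    vwid = float(params[f"{prefix}WID"])
    axis = vmin + vwid * np.arange(npts) / (npts - 1 if npts > 1 else 1)
    unit = params.get(f"{prefix}UNI", "")
    if unit in ("G", "Gauss"):
        axis = axis / 10.0  # Gauss -> mT, the package-wide field unit
        unit = "mT"
    return axis, unit


def read_bes3t(dsc_path: str | os.PathLike) -> EPRDataset:
    """Read a BES3T .DSC/.DTA pair, given the path of either file.

    Raises
    ------
    FormatError
        On a missing .DTA companion, an unsupported format code, a nonlinear
        axis, or a point-count/file-size mismatch (never silent truncation).
    """
    dsc_path = os.fspath(dsc_path)
    stem, ext = os.path.splitext(dsc_path)
    if ext.lower() == ".dta":
        dsc_path = stem + (".DSC" if ext == ".DTA" else ".dsc")
    stem = os.path.splitext(dsc_path)[0]
    dta_path = None
    for cand in (stem + ".DTA", stem + ".dta"):
        if os.path.exists(cand):
            dta_path = cand
            break
    if not os.path.exists(dsc_path):
        raise FormatError(f"descriptor file not found: {dsc_path}")
    if dta_path is None:
        raise FormatError(f"no .DTA data file alongside {dsc_path}")
    for ext2 in (".XGF", ".YGF"):
        if os.path.exists(stem + ext2):
            raise FormatError(f"nonlinear companion axis file {stem + ext2} unsupported")

    with open(dsc_path, "r", encoding="latin-1") as fh:
        params = _parse_dsc(fh.read())

    for prefix in "XY":
        typ = params.get(f"{prefix}TYP", "IDX" if prefix == "X" else "NODATA")
        if typ == "IGD":
            raise FormatError(f"{prefix}TYP IGD (nonlinear axis) unsupported")

    ikkf = params.get("IKKF", "REAL")
    if ikkf not in ("REAL", "CPLX"):
        raise FormatError(f"unsupported IKKF {ikkf!r}")
    irfmt = params.get("IRFMT", "D")
    if irfmt not in _FORMATS:
        raise FormatError(f"unsupported IRFMT code {irfmt!r}")
    if ikkf == "CPLX":
        iifmt = params.get("IIFMT", irfmt)
        if iifmt != irfmt:
            raise FormatError(f"mixed IRFMT/IIFMT ({irfmt}/{iifmt}) unsupported")
    bseq = params.get("BSEQ", "BIG")
    if bseq not in _BYTE_ORDERS:
        raise FormatError(f"unsupported BSEQ {bseq!r}")

    axes, units = [], []
    x_axis, x_unit = _axis_from_params(params, "X")
    axes.append(x_axis)
    units.append(x_unit)
    two_d = params.get("YTYP", "NODATA") not in ("NODATA", "") and "YPTS" in params
    if two_d:
        y_axis, y_unit = _axis_from_params(params, "Y")
        axes.insert(0, y_axis)  # rows = Y (slow axis), columns = X
        units.insert(0, y_unit)

    dtype_char, itemsize = _FORMATS[irfmt]
    dtype = np.dtype(_BYTE_ORDERS[bseq] + dtype_char)
    raw = np.fromfile(dta_path, dtype=dtype)
    n_expected = int(np.prod([a.size for a in axes]))
    n_per_point = 2 if ikkf == "CPLX" else 1
    if raw.size != n_expected * n_per_point:
        raise FormatError(
            f"{dta_path}: decoded {raw.size} values, descriptor promises "
            f"{n_expected * n_per_point}"
        )
    if ikkf == "CPLX":
        values = raw.astype(np.float64)[0::2] + 1j * raw.astype(np.float64)[1::2]
    else:
        values = raw.astype(np.float64)
    if two_d:
        values = values.reshape(axes[0].size, axes[1].size)
    return EPRDataset(axes=axes, units=units, values=values, params=params)


def write_bes3t(ds: EPRDataset, path: str | os.PathLike, byte_order: str = "BIG") -> tuple[str, str]:
    """Write a minimal conformant .DSC/.DTA pair; returns the two paths.

    Values are stored as float64 so that write -> read is bit exact.  Field
    axes in mT are emitted in Gauss (the native descriptor unit).
    """
    if byte_order not in _BYTE_ORDERS:
        raise FormatError(f"byte_order must be BIG or LIT, got {byte_order!r}")
    stem = os.path.splitext(os.fspath(path))[0]
    dsc_path, dta_path = stem + ".DSC", stem + ".DTA"

    cplx = np.iscomplexobj(ds.values)
    lines = [
        "#DESC	1.2 * DESCRIPTOR INFORMATION ***********************",
        "DSRC	EXP",
        f"BSEQ	{byte_order}",
        f"IKKF	{'CPLX' if cplx else 'REAL'}",
        "IRFMT	D",
    ]
    if cplx:
        lines.append("IIFMT	D")

    def axis_lines(prefix: str, axis: np.ndarray, unit: str) -> list[str]:
        if unit == "mT":
            axis, unit = axis * 10.0, "G"
        return [
            f"{prefix}TYP	IDX",
            f"{prefix}PTS	{axis.size}",
            f"{prefix}MIN	{float(axis[0])!r}",
            f"{prefix}WID	{float(axis[-1] - axis[0])!r}",
            f"{prefix}UNI	'{unit}'",
        ]

    if ds.ndim == 1:
        lines += axis_lines("X", ds.axes[0], ds.units[0])
        lines.append("YTYP	NODATA")
        flat = ds.values
    else:
        lines += axis_lines("X", ds.axes[1], ds.units[1])
        lines += axis_lines("Y", ds.axes[0], ds.units[0])
        flat = ds.values.reshape(-1)
    for key in ("MWFQ", "TITL"):
        if key in ds.params:
            lines.append(f"{key}	{ds.params[key]}")

    with open(dsc_path, "w", encoding="latin-1") as fh:
        fh.write("\n".join(lines) + "\n")

    dtype = np.dtype(_BYTE_ORDERS[byte_order] + "f8")
    if cplx:
        inter = np.empty(flat.size * 2, dtype=np.float64)
        inter[0::2] = np.asarray(flat).real
        inter[1::2] = np.asarray(flat).imag
        inter.astype(dtype).tofile(dta_path)
    else:
        np.asarray(flat, dtype=np.float64).astype(dtype).tofile(dta_path)
    return dsc_path, dta_path


def read_ascii(path: str | os.PathLike) -> EPRDataset:
    """Read a two-column (1D) or header+matrix (2D) ASCII spectrum.

    Lines starting with ``#`` are comments, except the axis headers written
    by :func:`write_ascii` (``# axis1: ...`` / ``# axis2: ...``) which carry
    the coordinate vectors of a 2D map.  Ragged rows raise with the offending
    line number.
    """
    header_axes: dict[str, np.ndarray] = {}
    rows: list[list[float]] = []
    width = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            m = re.match(r"#\s*(axis[12])\s*(?:\[(\S*)\])?\s*:\s*(.*)$", s)
            if m:
                header_axes[m.group(1)] = np.array(
                    [float(v) for v in m.group(3).split()]
                )
                header_axes[m.group(1) + "_unit"] = m.group(2) or ""
                continue
            if s.startswith(("#", "%", ";")):
                continue
            try:
                vals = [float(v) for v in s.replace(",", " ").split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row: {s!r}") from exc
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(vals)} fields, expected {width})"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.array(rows)

    if "axis1" in header_axes and "axis2" in header_axes:
        a1, a2 = header_axes["axis1"], header_axes["axis2"]
        if data.shape != (a1.size, a2.size):
            raise FormatError(
                f"{path}: matrix shape {data.shape} does not match header axes "
                f"({a1.size}, {a2.size})"
            )
        return EPRDataset(
            axes=[a1, a2],
            units=[str(header_axes.get("axis1_unit", "")),
                   str(header_axes.get("axis2_unit", ""))],
            values=data,
        )
    if data.shape[1] == 2:
        return EPRDataset(axes=[data[:, 0]], units=[""], values=data[:, 1])
    if data.shape[1] == 1:
        raise FormatError(f"{path}: single-column file; need (axis, value) pairs")
    # headerless matrix: index axes
    return EPRDataset(
        axes=[np.arange(data.shape[0], dtype=float),
              np.arange(data.shape[1], dtype=float)],
        units=["index", "index"],
        values=data,
    )


def write_ascii(ds: EPRDataset, path: str | os.PathLike) -> str:
    """Write a dataset as plain text: two columns for 1D, axis headers plus a
    matrix for 2D.  Complex values are not representable; take a magnitude
    first."""
    if np.iscomplexobj(ds.values):
        raise FormatError("ASCII export supports real values only")
    path = os.fspath(path)
    with open(path, "w") as fh:
        if ds.ndim == 1:
            for x, y in zip(ds.axes[0], ds.values):
                fh.write(f"{float(x)!r}\t{float(y)!r}\n")
        else:
            for i, axis in enumerate(ds.axes, start=1):
                unit = ds.units[i - 1]
                fh.write(f"# axis{i}[{unit}]: "
                         + " ".join(repr(float(v)) for v in axis) + "\n")
            for row in ds.values:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    return path
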