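"""Seeded generators for every input the pipeline consumes.

Emulates the statistical structure of frozen-solution X-band EPR data on a
ferric heme protein: first-derivative powder CW spectra of rhombic S = 1/2
g-tensors with Gaussian g-strain plus additive white noise and an optional
linear baseline drift, and 2D HYSCORE time traces built from exponentially
decaying cosines at correlated nuclear frequencies.  Everything is
reproducible from an integer seed, and fixture suites are written both as
BES3T pairs and ASCII twins.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np

from . import bruker_io
from .errors import ConfigurationError, NyquistError
from .hyscore import HyscoreMap, blind_spot_weight
from .powder_sim import ExperimentCW, SpinSystem, Spectrum1D, simulate_cw

__all__ = [
    "CWSynthConfig",
    "HyscoreSynthConfig",
    "make_cw",
    "make_hyscore_trace",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class CWSynthConfig:
    """Recipe for a noisy synthetic CW spectrum.

    ``noise_rms`` is relative to the maximum absolute intensity of the clean
    spectrum; ``baseline_slope`` adds a linear drift in the same relative
    units per mT (frozen-solution backgrounds drift slowly and roughly
    linearly across an X-band sweep).
    """

    system: SpinSystem
    experiment: ExperimentCW
    seed: int
    noise_rms: float = 0.01
    baseline_slope: float = 0.0
    n_orientations: int = 800

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is required")
        if self.noise_rms < 0:
            raise ConfigurationError("noise_rms must be >= 0")


@dataclass(frozen=True)
class HyscoreSynthConfig:
    """Recipe for a 2D HYSCORE time trace.

    ``peaks`` are (nu1_MHz, nu2_MHz, amplitude) triples of correlated nuclear
    frequencies.  Dwell times follow the acquisition practice of stepping t1
    and t2 in 16 ns or 24 ns increments; tau is typically 208 or 250 ns.
    """

    peaks: tuple[tuple[float, float, float], ...]
    seed: int
    dwell_ns: float = 16.0
    n_points: int = 128
    decay_ns: float = 600.0
    tau_ns: float = 208.0
    dc_offset: float = 0.0
    noise_rms: float = 0.01
    phase_rad: float = 0.0
    apply_blind_spots: bool = False
    field_mT: float | None = None
    mw_freq_GHz: float | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is required")
        if self.noise_rms < 0:
            raise ConfigurationError("noise_rms must be >= 0")
        if self.dwell_ns <= 0 or self.n_points < 8:
            raise ConfigurationError("need dwell_ns > 0 and n_points >= 8")


def make_cw(config: CWSynthConfig) -> Spectrum1D:
    """Simulate a CW spectrum and add baseline drift plus white noise."""
    clean = simulate_cw(config.system, config.experiment,
                        n_orientations=config.n_orientations)
    scale = float(np.max(np.abs(clean.intensity)))
    y = clean.intensity.copy()
    if config.baseline_slope:
        b = clean.field_mT
        y = y + config.baseline_slope * scale * (b - b[0])
    if config.noise_rms:
        rng = np.random.default_rng(config.seed)
        y = y + rng.standard_normal(y.size) * config.noise_rms * scale
    return Spectrum1D(clean.field_mT, y, experiment=config.experiment,
                      provenance=f"make_cw(seed={config.seed})")


def make_hyscore_trace(config: HyscoreSynthConfig) -> HyscoreMap:
    """Sum of decaying 2D cosines at the configured frequency pairs.

    Each pair contributes A cos(2 pi nu1 t1 + phi) cos(2 pi nu2 t2 + phi)
    exp(-(t1 + t2)/decay); a DC offset and white noise are added on top.
    Frequencies at or above the Nyquist limit of the dwell time are refused.
    """
    if len(config.peaks) == 0 and config.dc_offset == 0 and config.noise_rms == 0:
        raise ConfigurationError("nothing to generate: no peaks, DC or noise")
    nyquist = 1e3 / (2.0 * config.dwell_ns)  # MHz
    for nu1, nu2, _ in config.peaks:
        if nu1 >= nyquist or nu2 >= nyquist:
            raise NyquistError(
                f"frequency pair ({nu1}, {nu2}) MHz exceeds the Nyquist limit "
                f"{nyquist:.2f} MHz of a {config.dwell_ns:g} ns dwell"
            )
    t = np.arange(config.n_points) * config.dwell_ns
    t1, t2 = t[:, None], t[None, :]
    vals = np.full((config.n_points, config.n_points), float(config.dc_offset))
    for nu1, nu2, amp in config.peaks:
        if config.apply_blind_spots:
            amp = amp * float(blind_spot_weight(nu1, nu2, config.tau_ns))
        vals += (
            amp
            * np.cos(2e-3 * np.pi * nu1 * t1 + config.phase_rad)
            * np.cos(2e-3 * np.pi * nu2 * t2 + config.phase_rad)
            * np.exp(-(t1 + t2) / config.decay_ns)
        )
    if config.noise_rms:
        rng = np.random.default_rng(config.seed)
        ref = max(float(np.max(np.abs(vals))), 1.0e-30)
        vals = vals + rng.standard_normal(vals.shape) * config.noise_rms * ref
    return HyscoreMap(
        axis1=t, axis2=t, values=vals, domain="time",
        field_mT=config.field_mT, mw_freq_GHz=config.mw_freq_GHz,
        tau_ns=config.tau_ns,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# Reference conditions for the fixture suite: the resting-state enzyme's
# simulation parameters and the proton HYSCORE frequencies at the gz field.
_FIXTURE_G = (2.44, 2.25, 1.92)
_FIXTURE_STRAIN = (0.040, 0.0080, 0.010)
_FIXTURE_LW_MT = 2.0
_FIXTURE_MW_GHZ = 9.68
_FIXTURE_HYSCORE_PEAKS = ((7.43, 16.73, 1.0),)
_FIXTURE_FIELD_MT = 283.8


def make_fixture_suite(outdir: str | os.PathLike, seed: int) -> dict:
    """Write a deterministic fixture suite and return its manifest.

    Contents: the reference CW spectrum as big- and little-endian BES3T pairs
    plus an ASCII twin, a 2D HYSCORE time trace as BES3T plus ASCII twin, and
    the reference g-tensor table as CSV.  The manifest (also written as
    ``manifest.json``) maps file names to SHA-256 checksums; regenerating with
    the same seed reproduces the checksums exactly.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    from .crystal_field import GTensor  # local import avoids cycle at module load

    sys_ = SpinSystem(
        g=GTensor(*_FIXTURE_G), gstrain=_FIXTURE_STRAIN, lw_mT=_FIXTURE_LW_MT
    )
    exp = ExperimentCW(mw_freq_GHz=_FIXTURE_MW_GHZ, field_min_mT=200.0,
                       field_max_mT=420.0, n_points=1024)
    cw = make_cw(CWSynthConfig(system=sys_, experiment=exp, seed=seed,
                               noise_rms=0.01, baseline_slope=0.02))
    cw_ds = bruker_io.EPRDataset(
        axes=[cw.field_mT], units=["mT"], values=cw.intensity,
        params={"MWFQ": repr(_FIXTURE_MW_GHZ * 1e9)},
    )
    files = []
    files += bruker_io.write_bes3t(cw_ds, os.path.join(outdir, "cw_resting_big"), "BIG")
    files += bruker_io.write_bes3t(cw_ds, os.path.join(outdir, "cw_resting_lit"), "LIT")
    files.append(bruker_io.write_ascii(cw_ds, os.path.join(outdir, "cw_resting.txt")))

    hy = make_hyscore_trace(
        HyscoreSynthConfig(peaks=_FIXTURE_HYSCORE_PEAKS, seed=seed + 1,
                           dwell_ns=16.0, n_points=128, tau_ns=250.0,
                           noise_rms=0.01, field_mT=_FIXTURE_FIELD_MT,
                           mw_freq_GHz=_FIXTURE_MW_GHZ)
    )
    hy_ds = bruker_io.EPRDataset(
        axes=[hy.axis1, hy.axis2], units=["ns", "ns"], values=hy.values,
        params={"MWFQ": repr(_FIXTURE_MW_GHZ * 1e9)},
    )
    files += bruker_io.write_bes3t(hy_ds, os.path.join(outdir, "hyscore_proton"), "BIG")
    files.append(bruker_io.write_ascii(hy_ds, os.path.join(outdir, "hyscore_proton.txt")))

    from importlib import resources

    gtable_path = os.path.join(outdir, "gtensors.csv")
    with resources.files("hemepr.data").joinpath("gtensors.csv").open("r") as src:
        with open(gtable_path, "w") as dst:
            dst.write(src.read())
    files.append(gtable_path)

    manifest = {
        "seed": seed,
        "files": {os.path.basename(p): _sha256(p) for p in sorted(files)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
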