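"""Impedance spectrum container, CSV dialect, and sample metadata.

A spectrum is one frequency sweep of complex impedance measured on a single
tissue sample: frequency in Hz, real part ``z_re_ohm`` and imaginary part
``z_im_ohm`` in ohms.  Capacitive (tissue-like) response has a negative
imaginary part; Nyquist plots conventionally display ``-Im(Z)``.

The on-disk dialect is deliberately plain: one spectrum per UTF-8 CSV file,
comma separator, dot decimal, mandatory header ``f_hz,z_re_ohm,z_im_ohm``,
with sample metadata stored as ``# key: value`` comment lines above the
header so a file is self-describing and diffs cleanly.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    InsufficientDataError,
    SpectrumFormatError,
    SpectrumValidationError,
)

logger = logging.getLogger(__name__)

#: Measurement band of the LCR bridge, Hz.
FREQ_MIN_HZ = 80.0
FREQ_MAX_HZ = 1.0e6

#: Default sample geometry: a 10 x 10 x 10 mm sapwood cube with electrodes
#: on opposite faces -> cross-sectional area 1e-4 m^2, length 1e-2 m.
DEFAULT_CROSS_AREA_M2 = 1.0e-4
DEFAULT_LENGTH_M = 1.0e-2

MIN_POINTS = 8

SPECTRUM_COLUMNS = ("f_hz", "z_re_ohm", "z_im_ohm")

SPECIES_CODES = ("Pi", "Po")


def moisture_content(m_conditioned: float, m_oven_dry: float) -> float:
    """Moisture content in percent of oven-dry mass.

    MC = 100 * (M_conditioned - M_oven_dry) / M_oven_dry, the gravimetric
    wood-science definition (values above 100% mean more water than dry
    matter, as in fully saturated sapwood).

    Parameters
    ----------
    m_conditioned : float
        Mass of the conditioned (moist) sample, g.
    m_oven_dry : float
        Oven-dry mass of the same sample, g. Must be positive.

    Returns
    -------
    float
        Moisture content in percent.
    """
    if m_oven_dry <= 0:
        raise ValueError(f"oven-dry mass must be positive, got {m_oven_dry!r}")
    if m_conditioned < 0:
        raise ValueError(f"conditioned mass must be >= 0, got {m_conditioned!r}")
    return 100.0 * (m_conditioned - m_oven_dry) / m_oven_dry


@dataclass(frozen=True)
class SampleMeta:
    """Identity, treatment and geometry of one measured sample.

    ``temperature`` is the freezing-exposure temperature in deg C (<= 0 for
    frozen samples); ``cross_area`` (m^2) and ``length`` (m) are the
    electrode geometry used to convert lumped resistances (ohm) to specific
    resistances (ohm * m).
    """

    sample_id: str
    species: str = "Pi"
    moisture_content: float = 100.0
    cooling_rate: float = 2.0
    duration: float = 0.5
    temperature: float = -10.0
    cross_area: float = DEFAULT_CROSS_AREA_M2
    length: float = DEFAULT_LENGTH_M
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.species not in SPECIES_CODES:
            raise ValueError(
                f"species must be one of {SPECIES_CODES}, got {self.species!r}"
            )
        if self.cross_area <= 0 or self.length <= 0:
            raise ValueError("cross_area and length must be positive")
        if self.moisture_content < 0:
            raise ValueError("moisture_content must be >= 0")
        if self.cooling_rate <= 0:
            raise ValueError("cooling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One sample's validated frequency sweep.

    Frequencies are strictly increasing within the measurement band; the
    three arrays have equal length >= 8; all values are finite and the real
    part is strictly positive.  Construction sorts by frequency, so the
    stored order never depends on the order on disk.
    """

    frequencies: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        zr = np.asarray(self.z_real, dtype=float)
        zi = np.asarray(self.z_imag, dtype=float)
        if not (f.ndim == zr.ndim == zi.ndim == 1):
            raise SpectrumValidationError("spectrum arrays must be 1-D")
        if not (len(f) == len(zr) == len(zi)):
            raise SpectrumValidationError(
                f"array lengths differ: f={len(f)}, z_real={len(zr)}, z_imag={len(zi)}"
            )
        if len(f) < MIN_POINTS:
            raise InsufficientDataError(
                f"spectrum has {len(f)} points; at least {MIN_POINTS} required"
            )
        order = np.argsort(f, kind="stable")
        f, zr, zi = f[order], zr[order], zi[order]
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(zr)) and np.all(np.isfinite(zi))):
            raise SpectrumValidationError("spectrum contains non-finite values")
        if np.any(np.diff(f) <= 0):
            raise SpectrumValidationError("frequencies contain duplicates")
        # small relative slack so a grid endpoint written at reduced precision
        # still validates
        if f[0] < FREQ_MIN_HZ * (1 - 1e-9) or f[-1] > FREQ_MAX_HZ * (1 + 1e-9):
            raise SpectrumValidationError(
                f"frequencies [{f[0]:g}, {f[-1]:g}] Hz outside the measurement "
                f"band [{FREQ_MIN_HZ:g}, {FREQ_MAX_HZ:g}] Hz"
            )
        bad = np.nonzero(zr <= 0)[0]
        if bad.size:
            raise SpectrumValidationError(
                f"z_real must be positive; first offending point index {bad[0]} "
                f"(f={f[bad[0]]:g} Hz, z_real={zr[bad[0]]:g})"
            )
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z_real", zr)
        object.__setattr__(self, "z_imag", zi)
        for a in (self.frequencies, self.z_real, self.z_imag):
            a.setflags(write=False)

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def z(self) -> np.ndarray:
        """Complex impedance, ohms."""
        return self.z_real + 1j * self.z_imag

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency, rad/s (2 * pi * f)."""
        return 2.0 * math.pi * self.frequencies


_META_FLOAT_FIELDS = (
    "moisture_content",
    "cooling_rate",
    "duration",
    "temperature",
    "cross_area",
    "length",
)


def _meta_to_comments(meta: SampleMeta) -> list[str]:
    lines = [f"# sample_id: {meta.sample_id}", f"# species: {meta.species}"]
    for name in _META_FLOAT_FIELDS:
        lines.append(f"# {name}: {getattr(meta, name)!r}")
    lines.append(f"# replicate: {meta.replicate}")
    return lines


def _meta_from_comments(comments: dict[str, str]) -> SampleMeta | None:
    if "sample_id" not in comments:
        return None
    kwargs: dict = {"sample_id": comments["sample_id"]}
    if "species" in comments:
        kwargs["species"] = comments["species"]
    for name in _META_FLOAT_FIELDS:
        if name in comments:
            kwargs[name] = float(comments[name])
    if "replicate" in comments:
        kwargs["replicate"] = int(comments["replicate"])
    return SampleMeta(**kwargs)


def write_spectrum(spectrum: ImpedanceSpectrum, path: str | Path) -> Path:
    """Write one spectrum to CSV at full float precision.

    Metadata, when present, goes into ``# key: value`` comment lines so
    :func:`read_spectrum` round-trips the file exactly.
    """
    path = Path(path)
    buf = io.StringIO()
    if spectrum.meta is not None:
        for line in _meta_to_comments(spectrum.meta):
            buf.write(line + "\n")
    buf.write(",".join(SPECTRUM_COLUMNS) + "\n")
    for f, zr, zi in zip(spectrum.frequencies, spectrum.z_real, spectrum.z_imag):
        buf.write(f"{float(f)!r},{float(zr)!r},{float(zi)!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_spectrum(path: str | Path, meta: SampleMeta | None = None) -> ImpedanceSpectrum:
    """Read and validate a spectrum CSV.

    The file must contain the columns ``f_hz``, ``z_re_ohm`` and
    ``z_im_ohm``; rows may appear in any order (the returned spectrum is
    sorted by ascending frequency).  ``# key: value`` comment lines are
    parsed into :class:`SampleMeta` unless ``meta`` is supplied explicitly.

    An input whose imaginary part is uniformly non-negative but shows a
    clear arc is accepted with a logged sign flip: some instruments report
    capacitive reactance with the opposite sign convention.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"spectrum file not found: {path}")
    comments: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    comments[key.strip()] = value.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = parts
            else:
                rows.append(parts)
    if header is None:
        raise SpectrumFormatError(f"{path}: empty file")
    missing = [c for c in SPECTRUM_COLUMNS if c not in header]
    if missing:
        raise SpectrumFormatError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in SPECTRUM_COLUMNS}
    if len(rows) < MIN_POINTS:
        raise InsufficientDataError(
            f"{path}: {len(rows)} data rows; at least {MIN_POINTS} required"
        )
    try:
        f = np.array([float(r[idx["f_hz"]]) for r in rows])
        zr = np.array([float(r[idx["z_re_ohm"]]) for r in rows])
        zi = np.array([float(r[idx["z_im_ohm"]]) for r in rows])
    except (ValueError, IndexError) as exc:
        raise SpectrumFormatError(f"{path}: malformed numeric row ({exc})") from exc

    bad = np.nonzero(~np.isfinite(zr) | (zr <= 0))[0]
    if bad.size:
        raise SpectrumValidationError(
            f"{path}: z_re_ohm must be finite and positive; "
            f"offending data row {bad[0] + 1} (value {zr[bad[0]]!r})"
        )

    if np.all(zi >= 0) and np.any(zi > 0):
        interior_peak = 0 < int(np.argmax(zi)) < len(zi) - 1
        if interior_peak:
            logger.warning(
                "%s: imaginary part uniformly non-negative with a clear arc; "
                "flipping sign to the capacitive convention (Im(Z) <= 0)",
                path,
            )
            zi = -zi

    if meta is None:
        meta = _meta_from_comments(comments)
    return ImpedanceSpectrum(frequencies=f, z_real=zr, z_imag=zi, meta=meta)


def with_meta(spectrum: ImpedanceSpectrum, meta: SampleMeta) -> ImpedanceSpectrum:
    """Return a copy of ``spectrum`` carrying ``meta``."""
    return replace(spectrum, meta=meta)
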