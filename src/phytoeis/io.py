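"""Reading and writing impedance spectra as delimited text files.

Two CSV dialects are supported: ``freq_real_imag`` (frequency in Hz plus
the real and imaginary parts of Z in ohm) and ``freq_mag_phasedeg``
(frequency plus |Z| in ohm and phase in degrees, capacitive negative).
Dialect auto-detection keys off the header tokens.  Writing uses 15
significant digits so a write/read round trip is lossless well beyond 12
significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import FrequencyGrid, ImpedanceSpectrum, ValidationError

__all__ = ["SpectrumFileDialect", "read_spectrum", "write_spectrum"]

_REAL_IMAG_COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")
_MAG_PHASE_COLUMNS = ("frequency_hz", "z_mag_ohm", "z_phase_deg")


@dataclass(frozen=True)
class SpectrumFileDialect:
    """Column convention of a spectrum file."""

    columns: str = "freq_real_imag"
    delimiter: str = ","
    header: bool = True

    def __post_init__(self) -> None:
        if self.columns not in ("freq_real_imag", "freq_mag_phasedeg"):
            raise ValidationError(f"unknown column convention {self.columns!r}")

    @property
    def column_names(self) -> tuple[str, str, str]:
        return _REAL_IMAG_COLUMNS if self.columns == "freq_real_imag" else _MAG_PHASE_COLUMNS


def _detect_dialect(path: Path) -> SpectrumFileDialect:
    with open(path) as fh:
        first = fh.readline()
    delimiter = ";" if first.count(";") > first.count(",") else ","
    tokens = [t.strip().lower() for t in first.split(delimiter)]
    joined = " ".join(tokens)
    has_header = not any(_is_number(t) for t in tokens)
    if "real" in joined or "imag" in joined:
        columns = "freq_real_imag"
    elif "mag" in joined or "phase" in joined:
        columns = "freq_mag_phasedeg"
    elif not has_header:
        columns = "freq_real_imag"
    else:
        raise ValidationError(
            f"cannot auto-detect spectrum dialect from header {first.strip()!r}"
        )
    return SpectrumFileDialect(columns=columns, delimiter=delimiter, header=has_header)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_spectrum(
    path: str | Path, dialect: SpectrumFileDialect | str = "auto"
) -> ImpedanceSpectrum:
    """Read a spectrum file, validating frequencies on the way in.

    Rows must have strictly positive, duplicate-free frequencies; the
    spectrum is returned sorted ascending in frequency.  Parse failures and
    invalid rows are reported with their (1-based, header included) line
    number.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    frame = pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=0 if dialect.header else None,
        comment="#",
    )
    if frame.shape[1] < 3:
        raise ValidationError(f"{path}: expected 3 columns, found {frame.shape[1]}")
    frame = frame.iloc[:, :3]
    frame.columns = dialect.column_names
    offset = 2 if dialect.header else 1
    for i, row in enumerate(frame.itertuples(index=False)):
        vals = [row[0], row[1], row[2]]
        if any(pd.isna(v) or not np.isfinite(v) for v in vals):
            raise ValidationError(f"{path}: unparseable or non-finite row at line {i + offset}")
        if vals[0] <= 0:
            raise ValidationError(f"{path}: non-positive frequency at line {i + offset}")
    freqs = frame.iloc[:, 0].to_numpy(float)
    if np.unique(freqs).size != freqs.size:
        raise ValidationError(f"{path}: duplicate frequencies")
    order = np.argsort(freqs)
    frame = frame.iloc[order]
    freqs = freqs[order]
    if dialect.columns == "freq_real_imag":
        z = frame["z_real_ohm"].to_numpy(float) + 1j * frame["z_imag_ohm"].to_numpy(float)
    else:
        mag = frame["z_mag_ohm"].to_numpy(float)
        phase = np.radians(frame["z_phase_deg"].to_numpy(float))
        z = mag * np.exp(1j * phase)
    return ImpedanceSpectrum(FrequencyGrid(freqs), z)


def write_spectrum(
    spectrum: ImpedanceSpectrum,
    path: str | Path,
    dialect: SpectrumFileDialect | None = None,
) -> None:
    """Write a spectrum in the given dialect (default: freq_real_imag CSV)."""
    dialect = dialect or SpectrumFileDialect()
    names = dialect.column_names
    if dialect.columns == "freq_real_imag":
        cols = [spectrum.frequencies, spectrum.values.real, spectrum.values.imag]
    else:
        cols = [spectrum.frequencies, spectrum.magnitude, spectrum.phase_deg]
    frame = pd.DataFrame(dict(zip(names, cols)))
    frame.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        header=dialect.header,
        float_format="%.15g",
    )
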