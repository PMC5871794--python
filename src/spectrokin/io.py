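"""CSV and JSON I/O for the analysis stages.

All tables are UTF-8, comma-separated, dot-decimal CSV with ``#``-prefixed
``key: value`` metadata header lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bands import Spectrum
from .dielectric import LossSpectrum
from .kinetics import KineticsTrace


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        v = float(raw)
        return int(v) if v.is_integer() and "." not in raw and "e" not in raw.lower() else v
    except ValueError:
        return raw


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV with ``# key: value`` metadata headers."""
    path = Path(path)
    metadata: dict = {}
    n_header = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, raw = body.split(":", 1)
                metadata[key.strip()] = _parse_value(raw)
    df = pd.read_csv(path, skiprows=n_header)
    return df, metadata


def write_table(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


# -- typed wrappers ---------------------------------------------------------

def write_loss_spectrum(path, s: LossSpectrum) -> None:
    df = pd.DataFrame({"frequency_hz": s.frequency, "eps_imag": s.loss})
    write_table(path, df, {"temperature_K": s.temperature})


def read_loss_spectrum(path) -> LossSpectrum:
    df, meta = read_table(path)
    return LossSpectrum(temperature=float(meta["temperature_K"]),
                        frequency=df["frequency_hz"].to_numpy(),
                        loss=df["eps_imag"].to_numpy())


def write_spectrum(path, s: Spectrum) -> None:
    df = pd.DataFrame({"wavenumber_cm1": s.wavenumber,
                       "intensity": s.intensity})
    write_table(path, df, s.metadata)


def read_spectrum(path) -> Spectrum:
    df, meta = read_table(path)
    return Spectrum(wavenumber=df["wavenumber_cm1"].to_numpy(),
                    intensity=df["intensity"].to_numpy(), metadata=meta)


def write_trace(path, tr: KineticsTrace) -> None:
    df = pd.DataFrame({"time_s": tr.time,
                       "integral_intensity": tr.intensity})
    write_table(path, df, {"temperature_K": tr.temperature})


def read_trace(path) -> KineticsTrace:
    df, meta = read_table(path)
    return KineticsTrace(temperature=float(meta["temperature_K"]),
                         time=df["time_s"].to_numpy(),
                         intensity=df["integral_intensity"].to_numpy())


def read_mode_table(path):
    """Computed-mode CSV: columns ``frequency_cm1, raman_activity``."""
    from .raman import ComputedMode
    df, _ = read_table(path)
    return [ComputedMode(frequency=float(r.frequency_cm1),
                         activity=float(r.raman_activity))
            for r in df.itertuples()]


def write_relaxation_map(path, relax_map: pd.DataFrame) -> None:
    write_table(path, relax_map[["temperature_K", "process", "tau_s"]])


def read_directory(directory, reader):
    """Apply ``reader`` to every ``*.csv`` in a directory, sorted by name."""
    files = sorted(Path(directory).glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no CSV files in {directory}")
    return [reader(p) for p in files]
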