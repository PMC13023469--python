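"""Readers and writers for spectrum, parameter and report files.

Spectrum CSV dialect: UTF-8, ``#``-prefixed ``key=value`` metadata
lines, then a ``frequency_hz,z_abs_ohm`` header and one row per
frequency.  Floats are serialised with shortest round-trip precision so
write-then-read is lossless.

Parameter files are flat JSON or YAML maps with the canonical key names
(Rendo ... Cperi_epi) in SI units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import (
    PARAM_NAMES,
    CircuitParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
)
from .geometry import SampleGeometry

__all__ = [
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_parameters",
    "write_parameters",
    "write_fit_report",
    "format_parameter_table",
]


class SpectrumFormatError(ValueError):
    """A spectrum or parameter file violates the expected dialect."""


_META_KEYS = ("sample_id", "group", "length_mm", "area_mm2", "seed")


def write_spectrum(spectrum: ImpedanceSpectrum, path: "str | Path") -> Path:
    """Write a spectrum CSV with metadata header lines."""
    path = Path(path)
    lines: list[str] = []
    if spectrum.sample_id is not None:
        lines.append(f"# sample_id={spectrum.sample_id}")
    if spectrum.group is not None:
        lines.append(f"# group={spectrum.group}")
    if spectrum.geometry is not None:
        lines.append(f"# length_mm={spectrum.geometry.length_mm!r}")
        lines.append(f"# area_mm2={spectrum.geometry.area_mm2!r}")
    if spectrum.seed is not None:
        lines.append(f"# seed={spectrum.seed}")
    lines.append("frequency_hz,z_abs_ohm")
    for f, z in zip(spectrum.grid.frequencies, spectrum.z_abs):
        lines.append(f"{float(f)!r},{float(z)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_spectrum(path: "str | Path") -> ImpedanceSpectrum:
    """Read a spectrum CSV, validating every data row.

    Raises :class:`SpectrumFormatError` naming the offending line on
    malformed or non-positive entries.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    freqs: list[float] = []
    zabs: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["frequency_hz", "z_abs_ohm"]:
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'frequency_hz,z_abs_ohm', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                f, z = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from None
            if z <= 0:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: |Z| must be > 0, got {z}"
                )
            freqs.append(f)
            zabs.append(z)
    if not header_seen or not freqs:
        raise SpectrumFormatError(f"{path}: no spectrum data found")
    geometry = None
    if "length_mm" in meta and "area_mm2" in meta:
        geometry = SampleGeometry(length_mm=float(meta["length_mm"]),
                                  area_mm2=float(meta["area_mm2"]))
    seed = int(meta["seed"]) if "seed" in meta else None
    return ImpedanceSpectrum(
        grid=FrequencyGrid(np.asarray(freqs), spacing="explicit"),
        z_abs=np.asarray(zabs),
        sample_id=meta.get("sample_id"),
        group=meta.get("group"),
        geometry=geometry,
        seed=seed,
    )


def write_parameters(params: CircuitParameters, path: "str | Path") -> Path:
    """Write a parameter set as flat JSON (default) or YAML by suffix."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    return path


def read_parameters(path: "str | Path") -> CircuitParameters:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise SpectrumFormatError(f"{path}: expected a flat key->value map")
    return CircuitParameters.from_dict(data)


def write_fit_report(results, path: "str | Path") -> Path:
    """Write one CSV row per fit: scheme, parameters, metrics, convergence."""
    rows = []
    for res in results:
        row = {"scheme": res.scheme.name}
        row.update(res.params.to_dict())
        row.update(res.metrics.to_dict())
        row["converged"] = res.converged
        rows.append(row)
    frame = pd.DataFrame(rows)
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def format_parameter_table(results) -> str:
    """Render fitted parameter sets as a fixed-width text table.

    One row per circuit parameter, one column per fit (labelled by its
    scheme), mirroring the layout in which such parameter sets are
    conventionally reported.
    """
    results = list(results)
    header = ["Parameter"] + [r.scheme.name for r in results]
    units = {"R": "(Ohm)", "C": "(F)"}
    lines = ["\t".join(header)]
    for name in PARAM_NAMES:
        unit = units[name[0]]
        cells = [f"{name} {unit}"]
        for r in results:
            cells.append(f"{r.params.to_dict()[name]:.3e}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
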