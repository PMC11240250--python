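"""Spectrum file formats: two-column CSV with a JSON sidecar, and JCAMP-DX.

CSV is the primary interchange format (``ppm,intensity`` with a ``.meta.json``
sidecar carrying nucleus, scan count and free-form metadata).  A minimal
JCAMP-DX 4.24 writer/reader (AFFN ``(X++(Y..Y))`` tables, no compression) is
provided for interoperability with spectrometer software; it covers only the
records this package writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import Spectrum


def write_csv_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )
    sidecar = {
        "nucleus": spectrum.nucleus,
        "n_scans": spectrum.n_scans,
        "metadata": spectrum.metadata,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_csv_spectrum(path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    nucleus, n_scans, metadata = "1H", 1, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        nucleus = sidecar.get("nucleus", nucleus)
        n_scans = int(sidecar.get("n_scans", n_scans))
        metadata = sidecar.get("metadata", {})
    return Spectrum(
        ppm=df["ppm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        nucleus=nucleus,
        n_scans=n_scans,
        metadata=metadata,
    )


def write_jcampdx(spectrum: Spectrum, path, title: str = "phipchip spectrum") -> None:
    """Write an evenly spaced spectrum as JCAMP-DX 4.24 with an AFFN XYDATA table."""
    ppm = spectrum.ppm
    steps = np.diff(ppm)
    if len(ppm) < 2 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("JCAMP-DX export requires an evenly spaced ppm axis")
    y = spectrum.intensity
    yfactor = float(np.max(np.abs(y))) / 1e6 if np.any(y) else 1.0
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        f"##.OBSERVE NUCLEUS=^{spectrum.nucleus}",
        f"##NSCANS={spectrum.n_scans}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={ppm[0]:.10g}",
        f"##LASTX={ppm[-1]:.10g}",
        f"##NPOINTS={len(ppm)}",
        f"##XFACTOR={1.0:.10g}",
        f"##YFACTOR={yfactor:.10g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    scaled = np.round(y / yfactor).astype(int)
    per_line = 6
    for i in range(0, len(ppm), per_line):
        chunk = scaled[i : i + per_line]
        lines.append(f"{ppm[i]:.8g} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path) -> Spectrum:
    """Read the subset of JCAMP-DX produced by :func:`write_jcampdx`."""
    text = Path(path).read_text()
    header: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                break
            header[key] = value.strip()
            continue
        if in_table:
            parts = line.split()
            ys.extend(float(v) for v in parts[1:])  # first token is the X check value
    npoints = int(header["NPOINTS"])
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} ordinates, parsed {len(ys)}")
    first_x = float(header["FIRSTX"])
    last_x = float(header["LASTX"])
    yfactor = float(header.get("YFACTOR", 1.0))
    ppm = np.linspace(first_x, last_x, npoints)
    nucleus = header.get(".OBSERVE NUCLEUS", "^1H").lstrip("^")
    return Spectrum(
        ppm=ppm,
        intensity=np.asarray(ys) * yfactor,
        nucleus=nucleus,
        n_scans=int(header.get("NSCANS", 1)),
        metadata={"title": header.get("TITLE", "")},
    )
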