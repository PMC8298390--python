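"""Plain-text I/O: spectra CSV with ``# key=value`` header metadata,
component tables, trajectory CSV and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_fit import ComponentSet, Spectrum


def write_spectrum_csv(spec: Spectrum, path) -> None:
    path = Path(path)
    lines = []
    if spec.tape_speed_mm_s is not None:
        lines.append(f"# tape_speed_mm_s={spec.tape_speed_mm_s}")
    lines.append(f"# replicates={spec.replicates}")
    lines.append(f"# speed_corrected={int(spec.speed_corrected)}")
    body = pd.DataFrame({"wavelength_nm": spec.wavelengths_nm,
                         "intensity": spec.intensities})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        body.to_csv(fh, index=False)


def read_spectrum_csv(path) -> Spectrum:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)
    speed = meta.get("tape_speed_mm_s")
    return Spectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(),
        tape_speed_mm_s=float(speed) if speed is not None else None,
        replicates=int(meta.get("replicates", 1)),
        speed_corrected=bool(int(meta.get("speed_corrected", 0))),
    )


def write_components_csv(comps: ComponentSet, path) -> None:
    df = pd.DataFrame({"wavelength_nm": comps.wavelengths_nm,
                       **{n: y for n, y in comps.components.items()}})
    df.to_csv(path, index=False)


def read_components_csv(path, peaks_nm: dict | None = None) -> ComponentSet:
    df = pd.read_csv(path)
    wl = df.pop("wavelength_nm").to_numpy()
    comps = {name: df[name].to_numpy() for name in df.columns}
    return ComponentSet(wl, comps, peaks_nm or {})


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
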