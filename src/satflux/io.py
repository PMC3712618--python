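"""Plain-text I/O: TSV spectra/FIDs with JSON sidecars, expression tables, GMT.

Spectra and FIDs travel as two/four-column TSV files with a JSON sidecar
(``<name>.json``) holding the acquisition descriptors
(spectrometer_freq_mhz, sweep_width_hz, n_points, reference_ppm) and, for
spectra, the processing log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import ExpressionMatrix
from .errors import ValidationError
from .fitting import SpectralFit
from .processing import FID, Spectrum

__all__ = [
    "save_fid",
    "load_fid",
    "save_spectrum",
    "load_spectrum",
    "save_fit_json",
    "save_expression_tsv",
    "load_expression_tsv",
    "save_gmt",
    "load_gmt",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_fid(fid: FID, path: str | Path) -> Path:
    """Write a FID as a two-column (real/imag) TSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"real": fid.points.real, "imag": fid.points.imag}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    meta = {
        "kind": "fid",
        "spectrometer_freq_mhz": fid.spectrometer_freq_mhz,
        "sweep_width_hz": fid.sweep_width_hz,
        "n_points": fid.n_points,
        "reference_ppm": 0.0,
        "processing_log": fid.processing_log,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_fid(path: str | Path) -> FID:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "fid":
        raise ValidationError(f"{path}: sidecar does not describe a FID")
    df = pd.read_csv(path, sep="\t")
    points = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    fid = FID(
        points,
        dwell_time=1.0 / meta["sweep_width_hz"],
        spectrometer_freq_mhz=meta["spectrometer_freq_mhz"],
    )
    fid.processing_log = meta.get("processing_log", [])
    return fid


def save_spectrum(spec: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as ppm/real/imag TSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"ppm": spec.ppm_axis, "real": spec.values.real, "imag": spec.values.imag}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {
        "kind": "spectrum",
        "spectrometer_freq_mhz": spec.spectrometer_freq_mhz,
        "n_points": int(spec.values.size),
        "reference_ppm": 0.0,
        "processing_log": spec.processing_log,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "spectrum":
        raise ValidationError(f"{path}: sidecar does not describe a spectrum")
    df = pd.read_csv(path, sep="\t")
    return Spectrum(
        df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
        df["ppm"].to_numpy(),
        meta["spectrometer_freq_mhz"],
        meta.get("processing_log", []),
    )


def save_fit_json(fit: SpectralFit, path: str | Path) -> Path:
    """Serialize fitted peak parameters, uncertainties and fit diagnostics."""
    path = Path(path)
    payload = {
        "peaks": [
            {
                "label": p.label,
                "center_ppm": p.center_ppm,
                "amplitude": p.amplitude,
                "fwhm_hz": p.fwhm_hz,
                "gauss_fraction": p.gauss_fraction,
                "area": p.area,
                "stderr": p.stderr,
            }
            for p in fit.peaks
        ],
        "residual_rms": fit.residual_rms,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "message": fit.message,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def save_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Probe sets/genes as rows, samples as columns; a leading '#groups' row
    records the group label of each sample."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.values.columns) + "\n")
        fh.write("#groups\t" + "\t".join(matrix.groups) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False, float_format="%.8g")
    return path


def load_expression_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        groups_row = fh.readline().rstrip("\n").split("\t")
        if groups_row[0] != "#groups":
            raise ValidationError(f"{path}: second line must be the '#groups' row")
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    df.columns = header[1:]
    df.index.name = "id"
    groups = pd.Series(groups_row[1:], index=header[1:])
    return ExpressionMatrix(values=df, groups=groups)


def save_gmt(categories: dict[str, list[str]], path: str | Path) -> Path:
    """Write category -> genes as GMT (name, description, members)."""
    path = Path(path)
    with open(path, "w") as fh:
        for cat in sorted(categories):
            fh.write("\t".join([cat, "na", *categories[cat]]) + "\n")
    return path


def load_gmt(path: str | Path) -> dict[str, list[str]]:
    categories: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: GMT lines need name, description, genes")
        categories[fields[0]] = fields[2:]
    return categories


def dataclass_to_jsonable(obj):
    """Recursively convert dataclasses / numpy types for json.dumps."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: dataclass_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
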