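"""Readers and writers: peak lists, chains, trajectories, configs, manifests.

Peak lists use a Sparky-flavoured TSV with an explicit header::

    assignment  w1_ppm  w2_ppm  height  chea_total_M  chey_total_M  temperature_K

where ``w1`` is the indirect (13C) and ``w2`` the direct (1H) dimension.
Every artifact gets a JSON sidecar (``<file>.json``) recording the
producing command, seed and package version.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .titration import ObservedTitration, PosteriorChain

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "write_chain",
    "read_chain",
    "write_trajectory",
    "write_spectrum",
    "read_spectrum",
    "load_config",
    "write_manifest",
    "read_manifest",
]

PEAK_COLUMNS = [
    "assignment",
    "w1_ppm",
    "w2_ppm",
    "height",
    "chea_total_M",
    "chey_total_M",
    "temperature_K",
]


class PeaklistSchemaError(ValueError):
    pass


def write_peaklist(observed: ObservedTitration, path, metadata: dict | None = None,
                   assignment: str = "I5CD1-HD1", force: bool = False) -> Path:
    """Write titration peak positions as a Sparky-style TSV plus sidecar."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    frame = observed.frame
    out = pd.DataFrame(
        {
            "assignment": assignment,
            "w1_ppm": frame["shift_c_ppm"].round(6),
            "w2_ppm": frame["shift_h_ppm"].round(6),
            "height": 1.0,
            "chea_total_M": frame["chea_total_M"],
            "chey_total_M": frame["chey_total_M"],
            "temperature_K": frame["temperature_K"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")
    write_manifest(path.with_suffix(path.suffix + ".json"), metadata or {})
    return path


def read_peaklist(path) -> ObservedTitration:
    """Read a peak-list TSV into an :class:`ObservedTitration`.

    Missing concentration metadata is a schema error; malformed rows are
    reported with their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEAK_COLUMNS if c not in table.columns and c not in ("assignment", "height")]
    if missing:
        raise PeaklistSchemaError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in table.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = {
                "temperature_K": float(row["temperature_K"]),
                "chea_total_M": float(row["chea_total_M"]),
                "chey_total_M": float(row["chey_total_M"]),
                "shift_c_ppm": float(row["w1_ppm"]),
                "shift_h_ppm": float(row["w2_ppm"]),
            }
        except (TypeError, ValueError) as exc:
            raise PeaklistSchemaError(f"{path} line {line_no}: malformed row ({exc})") from None
        if rec["chea_total_M"] <= 0 or rec["chey_total_M"] < 0:
            raise PeaklistSchemaError(
                f"{path} line {line_no}: non-positive concentration"
            )
        records.append(rec)
    try:
        return ObservedTitration(pd.DataFrame(records))
    except ValueError as exc:
        raise PeaklistSchemaError(f"{path}: {exc}") from None


def write_chain(chain: PosteriorChain, path, metadata: dict | None = None,
                force: bool = False) -> Path:
    """Write an MCMC chain as TSV (step, parameters, logP, accepted)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    chain.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = dict(metadata or {})
    meta.update({"burn_in": chain.burn_in, "seed": chain.seed})
    write_manifest(path.with_suffix(path.suffix + ".json"), meta)
    return path


def read_chain(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectory(trajectory, path, metadata: dict | None = None,
                     force: bool = False) -> Path:
    """Write a signaling trajectory as TSV (t, T0..T4, Ap, Yp, MYp, Bp)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    trajectory.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_manifest(path.with_suffix(path.suffix + ".json"), metadata or {})
    return path


def write_spectrum(spectrum, path, metadata: dict | None = None,
                   force: bool = False) -> Path:
    """Write a processed 2D spectrum as a plain-text matrix plus sidecar.

    The matrix holds the real intensities (rows = indirect/13C); the JSON
    sidecar carries both frequency axes, the spectrometer field and the
    carriers, so the file pair is self-describing.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    np.savetxt(path, spectrum.data, fmt="%.8e", delimiter="\t")
    acq = spectrum.acquisition
    write_manifest(
        path.with_suffix(path.suffix + ".json"),
        {
            **(metadata or {}),
            "hz_direct": spectrum.hz_direct,
            "hz_indirect": spectrum.hz_indirect,
            "h_frequency_mhz": spectrum.spins.h_frequency_mhz,
            "carrier_h_ppm": acq.carrier_h_ppm,
            "carrier_c_ppm": acq.carrier_c_ppm,
            "sw_direct": acq.sw_direct,
            "sw_indirect": acq.sw_indirect,
        },
    )
    return path


def read_spectrum(path):
    """Read a spectrum written by :func:`write_spectrum`.

    Returns ``(matrix, sidecar)`` — the intensity matrix and the parsed
    axis metadata.
    """
    path = Path(path)
    matrix = np.loadtxt(path, delimiter="\t")
    sidecar = read_manifest(path.with_suffix(path.suffix + ".json"))
    return matrix, sidecar


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def write_manifest(path, metadata: dict) -> Path:
    """Write a JSON sidecar with provenance (command, seed, version)."""
    from . import __version__

    meta = {
        "package": "cheadyn",
        "version": __version__,
        "argv": sys.argv,
        **metadata,
    }
    path = Path(path)
    path.write_text(json.dumps(_jsonable(meta), indent=2) + "\n")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
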