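"""Reading and writing recordings and connectivity matrices.

Recordings travel either as EDF (read via :mod:`mne`, which is an
optional dependency) or as the package's own documented container: a
``.npy`` array of shape (channels, samples) plus a JSON sidecar of the
same stem carrying ``labels``, ``fs`` and seed provenance. Matrices are
written as labeled CSV and as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, ThresholdedMatrix
from .types import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_matrix_json",
    "matrix_filename",
]


def read_recording(path: str | Path) -> Recording:
    """Read a recording from EDF or from the .npy + JSON sidecar container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix == ".npy":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar for {path.name}: {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        data = np.load(path)
        return Recording(tuple(meta["labels"]), float(meta["fs"]), data)
    raise ValueError(f"unsupported recording format {path.suffix!r} ({path.name})")


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(tuple(raw.ch_names), float(raw.info["sfreq"]), raw.get_data())


def write_recording(rec: Recording, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a recording as .npy + JSON sidecar."""
    path = Path(path).with_suffix(".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, rec.data)
    meta = {"labels": list(rec.labels), "fs": rec.fs}
    if provenance:
        meta.update(provenance)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def matrix_filename(
    subject: int, session: str, phase: str, band: str, metric: str, ext: str = "csv"
) -> str:
    """Canonical file name: sub-NN_ses-S_phase-P_band-B_metric-M.ext"""
    return f"sub-{subject:02d}_ses-{session}_phase-{phase}_band-{band}_metric-{metric}.{ext}"


def write_matrix_csv(m: ConnectivityMatrix | ThresholdedMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(m.values, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, float_format="%.10g")
    return path


def read_matrix_csv(path: str | Path, metric: str = "", band: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(tuple(df.columns), df.to_numpy(), metric=metric, band=band)


def write_matrix_json(m: ConnectivityMatrix | ThresholdedMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "labels": list(m.labels),
        "metric": m.metric,
        "band": m.band,
        "values": np.asarray(m.values).tolist(),
    }
    if isinstance(m, ThresholdedMatrix):
        payload["mask"] = m.mask.astype(int).tolist()
        payload["proportion"] = m.proportion
    path.write_text(json.dumps(payload))
    return path
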