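"""Readers and writers for recordings, coupling matrices and reports.

Recordings travel as a ``channels x samples x epochs`` block in one of:

* a delimited text matrix (``.tsv``) of shape channels x (samples * epochs),
  epochs concatenated along the row;
* a numpy array container (``.npy``) with the full 3-D block;
* an EDF file (read-only, via :mod:`mne`), channels x total samples.

Each data file is accompanied by a small JSON sidecar (same stem, ``.json``)
holding the sampling rate, the pre-stimulus sample count, the epoch
structure, and the subject id / group label, so synthetic cohorts are
indistinguishable from real inputs to the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AveragedRecording, EpochedRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_averaged",
    "write_coupling_matrix",
    "read_coupling_matrix",
    "write_metrics_table",
    "read_metrics_table",
    "write_comparison_report",
    "write_outlier_report",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(rec: EpochedRecording, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a recording plus its JSON sidecar; returns the data path."""
    path = Path(path).with_suffix(f".{fmt}")
    c, s, e = rec.data.shape
    if fmt == "tsv":
        flat = rec.data.transpose(0, 2, 1).reshape(c, e * s)
        np.savetxt(path, flat, delimiter="\t")
    elif fmt == "npy":
        np.save(path, rec.data)
    else:
        raise ValueError("fmt must be 'tsv' or 'npy'")
    sidecar = {
        "fs": rec.fs,
        "prestim_samples": rec.prestim_samples,
        "n_epochs": e,
        "epoch_len": s,
        "subject_id": rec.subject_id,
        "group": rec.group,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: {sc}")
    return json.loads(sc.read_text())


def load_recording(path: str | Path) -> EpochedRecording:
    """Read a recording (``.tsv``/``.npy``/``.edf``) and its sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    meta = _load_sidecar(path)
    if path.suffix == ".npy":
        data = np.load(path)
    elif path.suffix == ".edf":
        import mne  # deferred: heavy import, EDF path only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        flat = raw.get_data()
        c = flat.shape[0]
        e, s = meta["n_epochs"], meta["epoch_len"]
        data = flat[:, : e * s].reshape(c, e, s).transpose(0, 2, 1)
        meta.setdefault("fs", float(raw.info["sfreq"]))
    else:
        flat = np.loadtxt(path, delimiter="\t", ndmin=2)
        c = flat.shape[0]
        e, s = meta["n_epochs"], meta["epoch_len"]
        data = flat.reshape(c, e, s).transpose(0, 2, 1)
    return EpochedRecording(
        data=data,
        fs=float(meta["fs"]),
        prestim_samples=int(meta.get("prestim_samples", 0)),
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "")),
    )


def save_averaged(rec: AveragedRecording, path: str | Path) -> Path:
    """Write a filtered averaged recording as a channels x samples matrix."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t")
    return path


def _labels(n: int, labels=None) -> list[str]:
    return list(labels) if labels is not None else [f"ch{i:03d}" for i in range(n)]


def write_coupling_matrix(mat: np.ndarray, path: str | Path, labels=None) -> Path:
    """Square delimited matrix with a header row of channel labels."""
    path = Path(path)
    df = pd.DataFrame(mat, columns=_labels(mat.shape[0], labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_coupling_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns)


def write_metrics_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_comparison_report(results, path: str | Path, labels=("A", "B")) -> Path:
    """Per-metric group comparison as JSON (means, SDs, test, exact p)."""
    path = Path(path)
    payload = {
        "groups": list(labels),
        "metrics": {
            r.metric: {
                "mean_a": r.mean_a,
                "sd_a": r.sd_a,
                "n_a": r.n_a,
                "mean_b": r.mean_b,
                "sd_b": r.sd_b,
                "n_b": r.n_b,
                "normal_a": r.normal_a,
                "normal_b": r.normal_b,
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p_value,
                "significant": r.significant,
            }
            for r in results
        },
        "alpha": results[0].alpha if results else 0.05,
        "note": "p-values are per-metric; no multiple-testing correction applied",
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_outlier_report(reports, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps({r.metric: asdict(r) for r in reports}, indent=1)
    )
    return path
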