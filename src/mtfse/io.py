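"""File formats: RR CSV, minute-annotation JSON, feature CSV, TFSI exports.

RR CSV convention: header ``time_s,rr_ms``, one row per beat; the first beat
has an empty ``rr_ms`` field because no interval ends at it. The annotation
sidecar of record ``X.csv`` is ``X.ann.json`` and holds
``{"record_class": "A"|"C", "labels": ["apnea"|"normal", ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MinuteAnnotations, RRSeries
from .spectrum import TFSI

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_annotations_json",
    "write_annotations_json",
    "annotation_sidecar_path",
    "read_features_csv",
    "write_features_csv",
    "export_tfsi_csv",
    "export_tfsi_png",
    "read_wfdb_record",
]


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    times = rr.beat_times
    rr_col = [""] + [f"{v:.6f}" for v in rr.rr_intervals]
    with open(path, "w") as fh:
        fh.write("time_s,rr_ms\n")
        for t, v in zip(times, rr_col):
            fh.write(f"{t:.9f},{v}\n")


def read_rr_csv(path: str | Path, record_id: str | None = None) -> RRSeries:
    df = pd.read_csv(path)
    if not {"time_s", "rr_ms"}.issubset(df.columns):
        raise ValueError(f"{path}: RR CSV needs columns time_s,rr_ms")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two beats")
    # intervals are reconstructed from beat times; stored rr_ms is a
    # consistency cross-check only (tolerates CSV rounding)
    rr = np.diff(times) * 1000.0
    stored = df["rr_ms"].to_numpy(dtype=float)[1:]
    valid = np.isfinite(stored)
    if np.any(np.abs(stored[valid] - rr[valid]) > 1.0):
        raise ValueError(f"{path}: rr_ms column disagrees with time_s spacing")
    if record_id is None:
        record_id = Path(path).stem
    return RRSeries(times, rr, record_id=record_id)


def annotation_sidecar_path(rr_csv_path: str | Path) -> Path:
    p = Path(rr_csv_path)
    return p.with_name(p.stem + ".ann.json")


def write_annotations_json(
    ann: MinuteAnnotations, record_class: str, path: str | Path, **extra
) -> None:
    payload = {"record_class": record_class, "labels": list(ann.labels), **extra}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations_json(path: str | Path) -> tuple[MinuteAnnotations, str]:
    data = json.loads(Path(path).read_text())
    return MinuteAnnotations(tuple(data["labels"])), data["record_class"]


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False, na_rep="")


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_tfsi_csv(tfsi: TFSI, path: str | Path) -> None:
    """Power matrix as CSV (rows = time) plus a JSON sidecar with the axes."""
    path = Path(path)
    np.savetxt(path, tfsi.power, delimiter=",")
    sidecar = {
        "time_axis_s": tfsi.time_axis.tolist(),
        "freq_axis_hz": tfsi.freq_axis.tolist(),
        "window_length_s": tfsi.window_length_s,
        "hop_s": tfsi.hop_s,
    }
    path.with_suffix(path.suffix + ".axes.json").write_text(json.dumps(sidecar))


def export_tfsi_png(tfsi: TFSI, path: str | Path) -> None:
    """Heat-map of the TFSI (time on x, frequency on y) for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(
        tfsi.time_axis, tfsi.freq_axis, tfsi.power.T, shading="nearest"
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(mesh, ax=ax, label="PSD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_wfdb_record(
    record_name: str, annotator: str = "apn", pn_dir: str | None = None
) -> tuple[RRSeries, MinuteAnnotations]:
    """Read a PhysioNet-style record with per-minute apnea annotations.

    Requires the optional ``wfdb`` package plus an installed QRS detector path
    (``wfdb.processing.xqrs_detect``); beat detection itself is delegated to
    that established detector. Raises ImportError with guidance when ``wfdb``
    is not installed.
    """
    try:
        import wfdb
        from wfdb import processing as wfdb_processing
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); RR CSV input does not"
        ) from exc

    record = wfdb.rdrecord(record_name, pn_dir=pn_dir)
    sig = record.p_signal[:, 0]
    fs = record.fs
    beat_samples = wfdb_processing.xqrs_detect(sig=sig, fs=fs, verbose=False)
    beat_times = np.asarray(beat_samples, dtype=float) / fs
    rr = np.diff(beat_times) * 1000.0
    series = RRSeries(beat_times, rr, record_id=Path(record_name).name)

    ann = wfdb.rdann(record_name, annotator, pn_dir=pn_dir)
    labels = tuple("apnea" if s == "A" else "normal" for s in ann.symbol)
    return series, MinuteAnnotations(labels)
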