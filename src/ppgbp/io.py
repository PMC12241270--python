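"""Delimited-text readers/writers for signals, manifests and predictions."""

from __future__ import annotations

import json
import os
from typing import Dict, List

import numpy as np
import pandas as pd

from ppgbp.preprocess import InputError
from ppgbp.simulate import SignalRecord


def read_signal_file(
    path: str,
    sampling_rate: float | None = None,
    sbp_ref: float = float("nan"),
    dbp_ref: float = float("nan"),
    record_id: str | None = None,
    subject_id: str | None = None,
) -> SignalRecord:
    """Read a (time_s, value) CSV; sampling rate inferred from time stamps
    unless given.  Malformed rows raise with the 1-based line number."""
    if os.path.getsize(path) == 0:
        raise InputError(f"{path}: empty file")
    times: List[float] = []
    values: List[float] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() == "":
            raise InputError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.strip().split(",")
            if len(cells) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                times.append(float(cells[0]))
                values.append(float(cells[1]))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-numeric cell") from exc
    if len(values) < 2:
        raise InputError(f"{path}: fewer than 2 samples")
    if sampling_rate is None:
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise InputError(f"{path}: non-increasing time stamps")
        sampling_rate = 1.0 / dt
    stem = os.path.splitext(os.path.basename(path))[0]
    if np.isnan(sbp_ref):  # labels unknown: placeholder pair satisfying SBP > DBP
        sbp_ref, dbp_ref = 120.0, 80.0
    return SignalRecord(
        record_id=record_id or stem,
        subject_id=subject_id or stem,
        samples=np.asarray(values),
        sampling_rate=float(sampling_rate),
        sbp_ref=sbp_ref,
        dbp_ref=dbp_ref,
    )


def read_dataset(in_dir: str) -> List[SignalRecord]:
    """Load all records listed in a simulator manifest directory."""
    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest["records"]:
        records.append(
            read_signal_file(
                os.path.join(in_dir, f"{entry['record_id']}.csv"),
                sampling_rate=entry["sampling_rate"],
                sbp_ref=entry["sbp"],
                dbp_ref=entry["dbp"],
                record_id=entry["record_id"],
                subject_id=entry["subject_id"],
            )
        )
    return records


def write_predictions(path: str, pooled: Dict[str, np.ndarray]) -> None:
    """Long-format CSV: window_id, target, estimate, reference."""
    rows = []
    for i, wid in enumerate(pooled["window_ids"]):
        for j, target in enumerate(("sbp", "dbp")):
            rows.append(
                {
                    "window_id": wid,
                    "target": target,
                    "estimate": pooled["estimates"][i, j],
                    "reference": pooled["references"][i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_predictions(path: str) -> Dict[str, np.ndarray]:
    """Inverse of :func:`write_predictions`."""
    df = pd.read_csv(path)
    required = {"window_id", "target", "estimate", "reference"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {required - set(df.columns)}")
    wide_est = df.pivot(index="window_id", columns="target", values="estimate")
    wide_ref = df.pivot(index="window_id", columns="target", values="reference")
    ids = wide_est.index.to_numpy()
    return {
        "window_ids": ids,
        "estimates": wide_est[["sbp", "dbp"]].to_numpy(),
        "references": wide_ref[["sbp", "dbp"]].to_numpy(),
    }


__all__ = ["read_signal_file", "read_dataset", "write_predictions", "read_predictions"]
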