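"""Synthetic PPG generator with a planted, documented morphology–BP link.

Each beat is the sum of two Gaussians — a systolic peak at 0.30 T and a
dicrotic/diastolic component at 0.65 T for beat period T — which is the
simplest shape exhibiting the systolic upstroke and diastolic hump that
carry blood-pressure information in real pulses.  The statistical link is:

* diastolic/systolic amplitude ratio
  ``A_d/A_s = clip(0.8 - link_strength * 0.004 * (SBP - 120), 0.1, 0.95)``
  (higher systolic pressure -> relatively smaller diastolic component), and
* systolic width ``sigma_s = 0.10 T * (1 + link_strength * 0.005 * (DBP - 80))``
  (higher diastolic pressure -> broader systolic peak).

SBP and DBP are drawn uniformly from their ranges and redrawn until the
pulse pressure SBP - DBP is at least 20 mmHg.  Baseline wander is a slow
sinusoid; measurement noise is white Gaussian.  These are artifact choices
for testing the estimation pipeline, not claims about physiology.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from ppgbp.config import ConfigurationError, SimConfig

MIN_PULSE_PRESSURE = 20.0  # mmHg; physiologic lower bound enforced by rejection
_SYS_POS = 0.30  # systolic peak position, fraction of beat period
_DIA_POS = 0.65  # diastolic component position
_DIA_WIDTH = 0.16  # diastolic Gaussian width, fraction of beat period


@dataclass
class SignalRecord:
    """One subject's PPG trace with reference blood pressures."""

    record_id: str
    subject_id: str
    samples: np.ndarray
    sampling_rate: float
    sbp_ref: float
    dbp_ref: float
    truth_params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.record_id}: non-finite samples")
        if not self.sbp_ref > self.dbp_ref:
            raise ValueError(
                f"{self.record_id}: SBP {self.sbp_ref} must exceed DBP {self.dbp_ref}"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


def _record_rng(seed: int, record_index: int) -> np.random.Generator:
    # A SeedSequence keyed on (seed, index) gives independent, reproducible
    # streams without consuming draws from a shared generator.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(record_index)]))


def draw_bp(rng: np.random.Generator, config: SimConfig) -> Tuple[float, float]:
    """Uniform SBP/DBP with rejection until SBP - DBP >= 20 mmHg."""
    lo_s, hi_s = config.sbp_range
    lo_d, hi_d = config.dbp_range
    if lo_s - hi_d < MIN_PULSE_PRESSURE and hi_s - lo_d < MIN_PULSE_PRESSURE:
        raise ConfigurationError(
            "sbp_range/dbp_range cannot produce pulse pressure >= 20 mmHg"
        )
    while True:
        sbp = rng.uniform(lo_s, hi_s)
        dbp = rng.uniform(lo_d, hi_d)
        if sbp - dbp >= MIN_PULSE_PRESSURE:
            return float(sbp), float(dbp)


def beat_morphology(
    sbp: float, dbp: float, period: float, link_strength: float
) -> Dict[str, float]:
    """Morphology parameters implied by the planted link (before noise)."""
    ratio_raw = 0.8 - link_strength * 0.004 * (sbp - 120.0)
    ratio = float(np.clip(ratio_raw, 0.1, 0.95))
    sigma_s = 0.10 * period * (1.0 + link_strength * 0.005 * (dbp - 80.0))
    return {
        "amp_sys": 1.0,
        "amp_dia": ratio,
        "amp_ratio": ratio,
        "amp_ratio_unclipped": float(ratio_raw),
        "sigma_s": float(sigma_s),
        "sigma_d": _DIA_WIDTH * period,
        "period": float(period),
    }


def _pulse_train(t: np.ndarray, morph: Dict[str, float]) -> np.ndarray:
    tau = np.mod(t, morph["period"])
    sys_peak = morph["amp_sys"] * np.exp(
        -((tau - _SYS_POS * morph["period"]) ** 2) / (2.0 * morph["sigma_s"] ** 2)
    )
    dia_peak = morph["amp_dia"] * np.exp(
        -((tau - _DIA_POS * morph["period"]) ** 2) / (2.0 * morph["sigma_d"] ** 2)
    )
    return sys_peak + dia_peak


def simulate_record(config: SimConfig, record_index: int) -> SignalRecord:
    """Generate one record; deterministic given (config.seed, record_index)."""
    config.validate()
    if record_index < 0 or record_index >= config.n_records:
        raise ValueError(f"record_index {record_index} outside [0, {config.n_records})")
    rng = _record_rng(config.seed, record_index)

    hr = rng.uniform(*config.heart_rate_range)
    sbp, dbp = draw_bp(rng, config)
    period = 60.0 / hr
    morph = beat_morphology(sbp, dbp, period, config.link_strength)

    n = int(round(config.record_duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    ppg = _pulse_train(t, morph)
    if config.wander_amplitude > 0:
        ppg = ppg + config.wander_amplitude * np.sin(2 * np.pi * config.wander_freq * t)
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, size=n)

    truth = dict(morph)
    truth.update({"heart_rate": float(hr), "sbp": sbp, "dbp": dbp})
    return SignalRecord(
        record_id=f"rec_{record_index:04d}",
        subject_id=f"subj_{record_index:04d}",
        samples=ppg,
        sampling_rate=config.sampling_rate,
        sbp_ref=sbp,
        dbp_ref=dbp,
        truth_params=truth,
    )


def simulate_dataset(config: SimConfig) -> Tuple[List[SignalRecord], Dict]:
    """Generate all records plus a manifest of ids, labels, seed and config."""
    config.validate()
    if config.n_records < 1:
        raise ConfigurationError("n_records must be >= 1")
    records = [simulate_record(config, i) for i in range(config.n_records)]
    manifest = {
        "seed": config.seed,
        "n_records": config.n_records,
        "sampling_rate": config.sampling_rate,
        "records": [
            {
                "record_id": r.record_id,
                "subject_id": r.subject_id,
                "sbp": r.sbp_ref,
                "dbp": r.dbp_ref,
                "sampling_rate": r.sampling_rate,
            }
            for r in records
        ],
    }
    return records, manifest


def write_dataset(records: List[SignalRecord], manifest: Dict, out_dir: str) -> None:
    """One CSV (time_s, ppg) per record plus manifest.json."""
    os.makedirs(out_dir, exist_ok=True)
    for rec in records:
        t = np.arange(len(rec.samples)) / rec.sampling_rate
        path = os.path.join(out_dir, f"{rec.record_id}.csv")
        np.savetxt(
            path,
            np.column_stack([t, rec.samples]),
            delimiter=",",
            header="time_s,ppg",
            comments="",
            fmt="%.9g",
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


__all__ = [
    "SignalRecord",
    "simulate_record",
    "simulate_dataset",
    "write_dataset",
    "draw_bp",
    "beat_morphology",
    "MIN_PULSE_PRESSURE",
]
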