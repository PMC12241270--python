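"""Deterministic rasterization of signal windows into fixed-size images.

A plotting library would make the pixels depend on its version, DPI and
font stack; instead each trace is drawn with a pure-NumPy polyline
rasterizer, so the mapping samples -> pixels is a bit-exact function of the
samples and the :class:`~ppgbp.config.RenderSpec`.  Amplitude is min–max
normalized per window (images are therefore invariant to sensor gain and
offset), time maps linearly to columns, and there are no axes or text —
only the trace on a plain background.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from ppgbp.config import RenderSpec
from ppgbp.preprocess import InputError, SegmentWindow

MODALITIES = ("ppg", "vppg", "appg")


@dataclass
class ModalityImageTriplet:
    """Rendered PPG/vPPG/aPPG images for one window, labels carried through."""

    ppg_img: np.ndarray
    vppg_img: np.ndarray
    appg_img: np.ndarray
    window_id: str
    sbp_label: float
    dbp_label: float

    @property
    def images(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.ppg_img, self.vppg_img, self.appg_img


def _polyline_mask(rows: np.ndarray, cols: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean mask of the polyline through (rows[i], cols[i]), 1-px pen."""
    dr = np.diff(rows)
    dc = np.diff(cols)
    # Enough interpolation points per segment that consecutive points land on
    # the same or an 8-adjacent pixel.
    steps = np.maximum(np.ceil(np.maximum(np.abs(dr), np.abs(dc))).astype(int), 1)
    seg = np.repeat(np.arange(len(dr)), steps)
    offsets = np.concatenate([[0], np.cumsum(steps)])
    within = np.arange(offsets[-1]) - offsets[seg]
    t = (within + 1) / steps[seg]
    rr = rows[seg] + t * dr[seg]
    cc = cols[seg] + t * dc[seg]
    rr = np.concatenate([[rows[0]], rr])
    cc = np.concatenate([[cols[0]], cc])
    mask = np.zeros((height, width), dtype=bool)
    ri = np.clip(np.rint(rr).astype(int), 0, height - 1)
    ci = np.clip(np.rint(cc).astype(int), 0, width - 1)
    mask[ri, ci] = True
    return mask


def render_window(samples: Sequence[float], spec: RenderSpec) -> np.ndarray:
    """Rasterize one trace to a (height, width, channels) uint8 image.

    Min–max normalization maps the amplitude range onto
    ``[margin, height - 1 - margin]`` with larger values nearer the top row;
    a constant trace maps to the vertical center.  Sample i maps to column
    ``i * (width - 1) / (n - 1)``.
    """
    spec.validate()
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise InputError("need at least 2 samples to render")
    if not np.all(np.isfinite(x)):
        raise InputError("cannot render non-finite samples")

    lo, hi = float(np.min(x)), float(np.max(x))
    top = spec.margin
    bottom = spec.height - 1 - spec.margin
    if hi > lo:
        # high amplitude -> small row index (top of image)
        rows = bottom - (x - lo) / (hi - lo) * (bottom - top)
    else:
        rows = np.full_like(x, (top + bottom) / 2.0)
    cols = np.arange(len(x)) * (spec.width - 1) / (len(x) - 1)

    mask = _polyline_mask(rows, cols, spec.height, spec.width)
    if spec.line_thickness > 1:
        footprint = np.ones((spec.line_thickness, spec.line_thickness), dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=footprint)

    img = np.full((spec.height, spec.width), spec.background_value, dtype=np.uint8)
    img[mask] = spec.line_value
    return np.repeat(img[:, :, None], spec.channels, axis=2)


def render_triplet(window: SegmentWindow, spec: RenderSpec) -> ModalityImageTriplet:
    """One image per modality (same spec), labels copied through."""
    return ModalityImageTriplet(
        ppg_img=render_window(window.ppg, spec),
        vppg_img=render_window(window.vppg, spec),
        appg_img=render_window(window.appg, spec),
        window_id=window.window_id,
        sbp_label=window.sbp_label,
        dbp_label=window.dbp_label,
    )


def line_fraction(img: np.ndarray, spec: RenderSpec) -> float:
    """Fraction of pixels occupied by the trace (first channel)."""
    return float(np.mean(img[:, :, 0] == spec.line_value))


def write_triplets(
    triplets: List[ModalityImageTriplet], out_dir: str
) -> Dict[str, Dict]:
    """PNG files named ``<window>_<modality>.png`` plus a JSON label index."""
    os.makedirs(out_dir, exist_ok=True)
    index: Dict[str, Dict] = {}
    for trip in triplets:
        entry = {"sbp": trip.sbp_label, "dbp": trip.dbp_label, "files": {}}
        for modality, img in zip(MODALITIES, trip.images):
            name = f"{trip.window_id}_{modality}.png"
            Image.fromarray(img).save(os.path.join(out_dir, name))
            entry["files"][modality] = name
        index[trip.window_id] = entry
    with open(os.path.join(out_dir, "index.json"), "w") as fh:
        json.dump(index, fh, indent=2)
    return index


def read_triplets(in_dir: str) -> List[ModalityImageTriplet]:
    """Reload triplets written by :func:`write_triplets`."""
    with open(os.path.join(in_dir, "index.json")) as fh:
        index = json.load(fh)
    triplets = []
    for window_id, entry in sorted(index.items()):
        imgs = {
            m: np.asarray(Image.open(os.path.join(in_dir, entry["files"][m])))
            for m in MODALITIES
        }
        triplets.append(
            ModalityImageTriplet(
                ppg_img=imgs["ppg"],
                vppg_img=imgs["vppg"],
                appg_img=imgs["appg"],
                window_id=window_id,
                sbp_label=entry["sbp"],
                dbp_label=entry["dbp"],
            )
        )
    return triplets


__all__ = [
    "MODALITIES",
    "ModalityImageTriplet",
    "render_window",
    "render_triplet",
    "line_fraction",
    "write_triplets",
    "read_triplets",
]
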