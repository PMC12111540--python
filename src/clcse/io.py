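"""Image reading/writing and report serialization for the command line."""

from __future__ import annotations

import csv
import json
import os

import numpy as np
import imageio.v3 as iio

from .seof import SeofCurve

# ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray_image(path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale grid.

    Multi-channel inputs are collapsed with the BT.601 luminance weights and
    rounded; 16-bit inputs are linearly rescaled to [0, 255].
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as e:
        raise ValueError(f"unreadable image format: {path} ({e})") from e
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = np.floor(arr.astype(np.float64) @ _LUMA + 0.5)
    if arr.dtype == np.uint16 or (arr.ndim == 2 and arr.max(initial=0) > 255):
        arr = np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5)
    return arr.astype(np.int64)


def write_gray_image(path, pixels) -> None:
    """Write an integer grid in [0, 255] as an 8-bit image."""
    arr = np.asarray(pixels)
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    iio.imwrite(path, arr.astype(np.uint8))


def labels_to_gray(labels, n_classes: int | None = None) -> np.ndarray:
    """Map class indices to evenly spaced gray levels for visual inspection."""
    lab = np.asarray(labels, dtype=np.int64)
    k = int(lab.max()) + 1 if n_classes is None else int(n_classes)
    if k <= 1:
        return np.zeros(lab.shape, dtype=np.int64)
    return np.floor(lab * (255.0 / (k - 1)) + 0.5).astype(np.int64)


def labels_from_image(pixels) -> np.ndarray:
    """Recover class indices from a gray-coded label image.

    The distinct gray values present are ranked ascending and replaced by
    their rank, inverting ``labels_to_gray`` for any class count.
    """
    arr = np.asarray(pixels, dtype=np.int64)
    _, inverse = np.unique(arr, return_inverse=True)
    return inverse.reshape(arr.shape).astype(np.int64)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


def write_seof_csv(path, curve: SeofCurve) -> None:
    """Dump a SEOF curve as a two-column CSV (threshold, entropy bits)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "entropy_bits"])
        for t, s in zip(curve.t_values, curve.entropy_values):
            writer.writerow([int(t), f"{float(s):.10g}"])


def read_config(path) -> dict:
    """Parse a plain key=value defaults file (k_max, matching policy, ...).

    Blank lines and ``#`` comments are ignored; integer-looking values are
    converted.
    """
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key=value): {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            try:
                out[key] = int(value)
            except ValueError:
                out[key] = value
    return out
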