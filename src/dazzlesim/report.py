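"""Bit-stable report writers (CSV and JSON) and grayscale image I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

_FLOAT_FMT = "%.6g"


def _format_value(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (float, np.floating)):
        return float(_FLOAT_FMT % v)
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, np.ndarray):
        return [_format_value(x) for x in v.tolist()]
    if isinstance(v, dict):
        return {str(k): _format_value(x) for k, x in sorted(v.items())}
    if isinstance(v, (list, tuple)):
        return [_format_value(x) for x in v]
    return v


def write_report(report: pd.DataFrame, path, fmt: str = "csv") -> Path:
    """Write a report deterministically: sorted JSON keys, %.6g floats,
    LF line endings, UTF-8.  Same report in -> byte-identical file out."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        text = report.to_csv(index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        path.write_text(text, encoding="utf-8", newline="\n")
    elif fmt == "json":
        records = [
            {k: _format_value(v) for k, v in sorted(row.items())}
            for row in report.to_dict(orient="records")
        ]
        path.write_text(
            json.dumps(records, indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
            newline="\n",
        )
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
    return path


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a float array in [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I"):
            im = im.convert("L")
        arr = np.asarray(im, dtype=float)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def write_image(image: np.ndarray, path, bit_depth: int = 16) -> Path:
    """Write a [0, 1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    path = Path(path)
    if bit_depth == 8:
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(path)
    elif bit_depth == 16:
        Image.fromarray((img * 65535).round().astype(np.uint16)).save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    return path
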