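"""TIFF / JSON / CSV plumbing shared by the CLI stages."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import DataError
from .simcore import MovieStack


def write_movie_tiff(movie: MovieStack, path: str | Path) -> Path:
    """Write a (T, Y, X) float32 multipage TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_rate_hz": movie.frame_rate_hz,
                "pixel_size_um": movie.pixel_size_um,
                "t0_s": movie.t0_s,
                "axes": "TYX",
            }
        )
    )
    return path


def read_movie_tiff(path: str | Path) -> MovieStack:
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise DataError(f"cannot read movie TIFF {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise DataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return MovieStack(
        frames=np.asarray(frames, dtype=np.float32),
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta["pixel_size_um"],
        t0_s=meta.get("t0_s", 0.0),
    )


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")
    return path


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float32)
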