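"""Reading ultrasound cine recordings and frame concatenation.

Two input dialects are supported:

* **Sidecar dialect** (primary, fully text-based): a run directory containing
  a ``recording.yaml`` metadata file and one ASCII PGM (``P2``) file per
  frame.  Frames contribute strictly ordered time columns; an optional
  integer ``frame_overlap`` declares how many leading columns of each frame
  after the first duplicate the tail of its predecessor and are dropped
  (the earlier frame's columns are kept).
* **DICOM** multi-frame grayscale, if :mod:`pydicom` is installed.  Time and
  value calibrations are taken from the ultrasound region calibration
  sequence (``PhysicalDeltaX``/``PhysicalDeltaY``).

Coordinate convention: row 0 is the top of the image (shallowest depth /
highest velocity above baseline), column 0 the earliest time; indices are
0-based and row/column ranges half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import CalibrationError, ParseError, ShapeError

__all__ = [
    "UltrasoundRecording",
    "read_recording",
    "write_recording",
    "concatenate_frames",
    "read_pgm",
    "write_pgm",
]

_SIDECAR_NAME = "recording.yaml"


@dataclass
class UltrasoundRecording:
    """One acquisition run: concatenated pixels plus calibration metadata.

    Parameters
    ----------
    pixels
        2-D grayscale matrix, rows = depth (M-mode) or velocity (Doppler)
        axis, columns = time.
    modality
        ``"mmode"`` or ``"doppler"``.
    time_cal
        Milliseconds per pixel column.
    value_cal
        cm per pixel row (M-mode) or m/s per pixel row (Doppler).
    ecg_band
        Half-open row range ``(start, stop)`` containing the ECG strip.
    baseline_row
        Row index of zero velocity; required iff ``modality == "doppler"``.
    run_id
        Acquisition run label.
    """

    pixels: np.ndarray
    modality: str
    time_cal: float
    value_cal: float
    ecg_band: tuple[int, int]
    baseline_row: int | None = None
    run_id: int | str = 1

    def __post_init__(self) -> None:
        self.pixels = to_grayscale(np.asarray(self.pixels))
        if self.modality not in ("mmode", "doppler"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ShapeError(f"pixel matrix must be 2-D with >=2 rows/columns, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel values must be finite and non-negative")
        if not (self.time_cal > 0):
            raise CalibrationError(f"time_cal must be positive, got {self.time_cal}")
        if not (self.value_cal > 0):
            raise CalibrationError(f"value_cal must be positive, got {self.value_cal}")
        if (self.baseline_row is None) == (self.modality == "doppler"):
            raise CalibrationError("baseline_row must be present iff modality is doppler")
        b0, b1 = self.ecg_band
        if not (0 <= b0 < b1 <= self.pixels.shape[0]):
            raise CalibrationError(f"ecg_band {self.ecg_band} outside image with {self.pixels.shape[0]} rows")
        self.ecg_band = (int(b0), int(b1))

    @property
    def n_columns(self) -> int:
        return self.pixels.shape[1]

    def summary(self) -> str:
        """One-line JSON summary, suitable for JSON-lines logging."""
        return json.dumps(
            {
                "run_id": self.run_id,
                "modality": self.modality,
                "shape": list(self.pixels.shape),
                "time_cal_ms": self.time_cal,
                "value_cal": self.value_cal,
                "baseline_row": self.baseline_row,
                "ecg_band": list(self.ecg_band),
            },
            sort_keys=True,
        )


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel image to luma; pass 2-D input through."""
    if pixels.ndim == 3:
        weights = np.array([0.299, 0.587, 0.114])[: pixels.shape[2]]
        weights = weights / weights.sum()
        return pixels.astype(float) @ weights
    return pixels


def concatenate_frames(frames: Sequence[np.ndarray], overlap: int = 0) -> np.ndarray:
    """Concatenate cine frames column-wise into one continuous image.

    Each frame after the first may repeat the last ``overlap`` columns of its
    predecessor; those duplicated leading columns are dropped so the earlier
    frame's columns are kept.
    """
    if len(frames) == 0:
        raise ShapeError("need at least one frame")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    arrs = [to_grayscale(np.asarray(f)) for f in frames]
    height = arrs[0].shape[0]
    for i, a in enumerate(arrs):
        if a.ndim != 2:
            raise ShapeError(f"frame {i} is not 2-D")
        if a.shape[0] != height:
            raise ShapeError(f"frame {i} has {a.shape[0]} rows, expected {height}")
    pieces = [arrs[0]]
    for a in arrs[1:]:
        if overlap >= a.shape[1]:
            raise ShapeError(f"overlap {overlap} >= frame width {a.shape[1]}")
        pieces.append(a[:, overlap:])
    return np.concatenate(pieces, axis=1)


# --------------------------------------------------------------------------
# ASCII PGM (portable graymap, "P2") — plain-text frame storage
# --------------------------------------------------------------------------

def write_pgm(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D uint8 image as ASCII PGM (``P2``)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ShapeError("PGM image must be 2-D")
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    h, w = img.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n255\n")
        for row in img:
            fh.write(" ".join(map(str, row.tolist())) + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    """Read an ASCII PGM (``P2``) image."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise ParseError(f"{path}: not an ASCII PGM (P2) file")
    try:
        w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
        data = np.array(tokens[4 : 4 + w * h], dtype=float).reshape(h, w)
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed PGM data") from exc
    if maxval <= 0:
        raise ParseError(f"{path}: invalid maxval {maxval}")
    return data


# --------------------------------------------------------------------------
# Sidecar dialect I/O
# --------------------------------------------------------------------------

_REQUIRED_KEYS = ("modality", "time_cal_ms", "value_cal", "ecg_band", "frames")


def read_recording(path: str | Path, modality: str) -> UltrasoundRecording:
    """Read one acquisition run and concatenate its frames.

    ``path`` is either a run directory containing ``recording.yaml`` (sidecar
    dialect) or a DICOM file (requires :mod:`pydicom`).
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path, modality)
    sidecar = path / _SIDECAR_NAME if path.is_dir() else path
    if not sidecar.exists():
        raise ParseError(f"no {_SIDECAR_NAME} found under {path}")
    try:
        meta = yaml.safe_load(sidecar.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{sidecar}: invalid YAML: {exc}") from exc
    if not isinstance(meta, dict):
        raise ParseError(f"{sidecar}: expected a mapping")
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise CalibrationError(f"{sidecar}: missing calibration field {key!r}")
    if meta["modality"] != modality:
        raise ParseError(f"{sidecar}: recording is {meta['modality']!r}, expected {modality!r}")
    if modality == "doppler" and meta.get("baseline_row") is None:
        raise CalibrationError(f"{sidecar}: missing calibration field 'baseline_row'")
    base = sidecar.parent
    frames = [read_pgm(base / name) for name in meta["frames"]]
    pixels = concatenate_frames(frames, overlap=int(meta.get("frame_overlap", 0)))
    return UltrasoundRecording(
        pixels=pixels,
        modality=modality,
        time_cal=float(meta["time_cal_ms"]),
        value_cal=float(meta["value_cal"]),
        ecg_band=tuple(meta["ecg_band"]),
        baseline_row=None if modality == "mmode" else int(meta["baseline_row"]),
        run_id=meta.get("run_id", 1),
    )


def write_recording(
    rec: UltrasoundRecording,
    directory: str | Path,
    frame_width: int = 256,
    frame_overlap: int = 0,
) -> Path:
    """Write a recording in the sidecar dialect, splitting it into frames.

    The split is the inverse of :func:`concatenate_frames`: each frame after
    the first re-emits the last ``frame_overlap`` columns of its predecessor.
    Returns the run directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels = rec.pixels
    n = pixels.shape[1]
    if frame_width <= frame_overlap:
        raise ValueError("frame_width must exceed frame_overlap")
    names: list[str] = []
    start = 0  # first column of new content in the next frame
    idx = 0
    while start < n:
        new_width = frame_width if idx == 0 else frame_width - frame_overlap
        hi = min(n, start + new_width)
        lo = start if idx == 0 else start - frame_overlap
        frame = pixels[:, lo:hi]  # frames after the first repeat the overlap
        name = f"frame_{idx:03d}.pgm"
        write_pgm(directory / name, frame)
        names.append(name)
        start = hi
        idx += 1
    meta = {
        "modality": rec.modality,
        "run_id": rec.run_id,
        "time_cal_ms": float(rec.time_cal),
        "value_cal": float(rec.value_cal),
        "ecg_band": [int(rec.ecg_band[0]), int(rec.ecg_band[1])],
        "frame_overlap": int(frame_overlap),
        "frames": names,
    }
    if rec.baseline_row is not None:
        meta["baseline_row"] = int(rec.baseline_row)
    (directory / _SIDECAR_NAME).write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


def _read_dicom(path: Path, modality: str) -> UltrasoundRecording:
    """Minimal multi-frame grayscale DICOM reader (optional pydicom route)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - pydicom not installed
        raise ParseError("reading DICOM requires the optional pydicom dependency") from exc
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse DICOM file {path}: {exc}") from exc
    frames = [arr[i] for i in range(arr.shape[0])] if arr.ndim >= 3 else [arr]
    pixels = concatenate_frames(frames)
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if not regions:
        raise CalibrationError(f"{path}: missing calibration field 'SequenceOfUltrasoundRegions'")
    region = regions[0]
    for tag in ("PhysicalDeltaX", "PhysicalDeltaY"):
        if getattr(region, tag, None) is None:
            raise CalibrationError(f"{path}: missing calibration field {tag!r}")
    time_cal = float(region.PhysicalDeltaX) * 1000.0  # seconds/px -> ms/px
    value_cal = abs(float(region.PhysicalDeltaY))
    baseline = None
    if modality == "doppler":
        baseline = getattr(region, "ReferencePixelY0", None)
        if baseline is None:
            raise CalibrationError(f"{path}: missing calibration field 'ReferencePixelY0'")
    band = getattr(ds, "ecg_band", None) or (pixels.shape[0] - 40, pixels.shape[0])
    return UltrasoundRecording(
        pixels=pixels,
        modality=modality,
        time_cal=time_cal,
        value_cal=value_cal,
        ecg_band=tuple(band),
        baseline_row=None if baseline is None else int(baseline),
    )
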