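"""Dense-map containers and their on-disk formats.

The package works in *inverse-depth space*: stereo disparity and monocular
network output both live there, each up to an unknown affine (scale/shift)
transform.  Three thin containers travel together through the rest of the
code:

* :class:`InverseDepthMap` — per-pixel inverse depth / disparity, arbitrary
  scale.  Invalid pixels are non-finite (NaN) in memory.
* :class:`ConfidenceMap` — per-pixel reliability ``q`` in [0, 1] attached to
  a supervisory disparity estimate; ``q = 0`` marks unmatched / occluded
  pixels (for a rectified stereo pair, typically a band along the left
  image border that has no counterpart in the right image).
* :class:`ValidityMask` — boolean per-pixel flags; the pixel population
  ``M`` over which losses and metrics average.

On disk, maps travel as grayscale PFM (exact float32 round-trip) or 16-bit
grayscale PNG with a caller-declared scale factor (quantised; integer 0 is
the invalid sentinel).  Internal convention everywhere: row-major,
origin top-left, 0-based; PFM's bottom-up row order is normalised on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DimensionError, FormatError, UnsupportedFormatError

__all__ = [
    "InverseDepthMap",
    "ConfidenceMap",
    "ValidityMask",
    "SupervisionFrame",
    "read_pfm",
    "write_pfm",
    "read_png16",
    "write_png16",
    "build_validity_mask",
]


@dataclass
class InverseDepthMap:
    """A 2-D field of inverse-depth (disparity) values.

    Values carry an arbitrary affine ambiguity; non-finite entries mark
    pixels with no estimate.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError(
                f"inverse-depth map must be 2-D, got shape {self.values.shape}"
            )
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise DimensionError(
                f"map must be at least 2x2, got {self.values.shape}"
            )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ConfidenceMap:
    """Per-pixel supervisory confidence ``q`` in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError(
                f"confidence map must be 2-D, got shape {self.values.shape}"
            )
        if not np.all((self.values >= 0.0) & (self.values <= 1.0)):
            bad = self.values[~((self.values >= 0.0) & (self.values <= 1.0))]
            raise ValueError(
                f"confidence values must lie in [0, 1]; offending values "
                f"include {bad.flat[:3]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ValidityMask:
    """Boolean pixel flags; ``count_valid`` is the population ``M``."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise DimensionError(
                f"validity mask must be 2-D, got shape {self.flags.shape}"
            )

    @property
    def count_valid(self) -> int:
        return int(self.flags.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape


@dataclass
class SupervisionFrame:
    """One self-supervisory signal: disparity + confidence + validity.

    Invariant: the mask is False wherever confidence is 0 or disparity is
    non-finite (enforced at construction by re-deriving the mask
    conjunction).
    """

    disparity: InverseDepthMap
    confidence: ConfidenceMap
    mask: ValidityMask = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.disparity.shape != self.confidence.shape:
            raise DimensionError(
                f"disparity {self.disparity.shape} and confidence "
                f"{self.confidence.shape} shapes differ"
            )
        derived = build_validity_mask(self.disparity, self.confidence)
        if self.mask is None:
            self.mask = derived
        else:
            if self.mask.shape != self.disparity.shape:
                raise DimensionError("mask shape differs from maps")
            # never allow a mask that claims validity where it cannot hold
            self.mask = ValidityMask(self.mask.flags & derived.flags)

    @property
    def shape(self) -> tuple[int, int]:
        return self.disparity.shape


# ----------------------------------------------------------------------
# PFM: the Portable Float Map.  Header is three ASCII lines — "Pf" (gray)
# or "PF" (colour), "<width> <height>", and a scale whose sign encodes
# endianness (negative = little-endian) — followed by raw float32 rows
# stored bottom-up.


def read_pfm(path: str | Path) -> InverseDepthMap:
    """Read a grayscale PFM file into an :class:`InverseDepthMap`.

    The bottom-up row order and the header's endianness are normalised;
    the absolute value of the scale field is ignored (values are returned
    as stored), matching common disparity-map usage.
    """
    data = Path(path).read_bytes()

    def next_token(pos: int) -> tuple[bytes, int]:
        while pos < len(data) and data[pos : pos + 1].isspace():
            pos += 1
        start = pos
        while pos < len(data) and not data[pos : pos + 1].isspace():
            pos += 1
        if start == pos:
            raise FormatError(f"{path}: truncated PFM header")
        return data[start:pos], pos

    magic, pos = next_token(0)
    if magic == b"PF":
        raise UnsupportedFormatError(
            f"{path}: colour PFM ('PF') is not supported; expected grayscale 'Pf'"
        )
    if magic != b"Pf":
        raise FormatError(
            f"{path}: not a PFM file (magic line {magic!r}, expected 'Pf')"
        )
    wtok, pos = next_token(pos)
    htok, pos = next_token(pos)
    stok, pos = next_token(pos)
    try:
        width, height = int(wtok), int(htok)
        scale = float(stok)
    except ValueError as exc:
        raise FormatError(
            f"{path}: malformed PFM dimension/scale line "
            f"({wtok!r} {htok!r} {stok!r})"
        ) from exc
    if width <= 0 or height <= 0:
        raise FormatError(f"{path}: non-positive PFM dimensions {width}x{height}")
    if scale == 0.0:
        raise FormatError(f"{path}: PFM scale field must be non-zero")
    # exactly one whitespace byte separates header from data
    pos += 1
    expected = width * height * 4
    raw = data[pos : pos + expected]
    if len(raw) != expected:
        raise FormatError(
            f"{path}: PFM data block has {len(raw)} bytes, expected {expected}"
        )
    endian = "<" if scale < 0 else ">"
    values = np.frombuffer(raw, dtype=np.dtype(endian + "f4")).reshape(height, width)
    # PFM stores rows bottom-up; flip to top-left origin
    return InverseDepthMap(values[::-1].astype(np.float64))


def write_pfm(
    m: InverseDepthMap,
    path: str | Path,
    *,
    invalid_sentinel: float | None = None,
) -> None:
    """Write a grayscale little-endian PFM file.

    Non-finite pixels are stored as ``invalid_sentinel`` when one is given;
    otherwise they are written verbatim (PFM floats carry NaN fine, and
    :func:`read_pfm` round-trips them bit-for-bit).
    """
    values = m.values.astype(np.float32)
    if invalid_sentinel is not None:
        values = np.where(np.isfinite(values), values, np.float32(invalid_sentinel))
    header = f"Pf\n{m.width} {m.height}\n-1.0\n".encode("ascii")
    body = values[::-1].astype("<f4").tobytes()
    Path(path).write_bytes(header + body)


# ----------------------------------------------------------------------
# 16-bit PNG with a declared scale factor (value = integer / scale_factor;
# integer 0 is the invalid sentinel, decoded to NaN).


def read_png16(path: str | Path, scale_factor: float) -> InverseDepthMap:
    """Read a 16-bit single-channel PNG; stored integer 0 decodes to NaN."""
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    with Image.open(path) as img:
        if img.mode not in ("I", "I;16", "I;16B", "I;16L"):
            raise UnsupportedFormatError(
                f"{path}: expected 16-bit single-channel PNG, got mode {img.mode!r}"
            )
        raw = np.asarray(img, dtype=np.int64)
    if raw.ndim != 2:
        raise UnsupportedFormatError(f"{path}: multi-channel PNG not supported")
    if raw.max(initial=0) > 65535 or raw.min(initial=0) < 0:
        raise FormatError(f"{path}: sample values outside the 16-bit range")
    values = raw.astype(np.float64) / float(scale_factor)
    values[raw == 0] = np.nan
    return InverseDepthMap(values)


def write_png16(m: InverseDepthMap, path: str | Path, scale_factor: float) -> None:
    """Quantise ``values * scale_factor`` to uint16; NaN/inf store as 0.

    Finite values are clipped into [1, 65535] so that no valid pixel
    collides with the invalid sentinel.
    """
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    scaled = np.rint(m.values * float(scale_factor))
    finite = np.isfinite(m.values)
    out = np.where(finite, np.clip(scaled, 1, 65535), 0.0).astype(np.uint16)
    Image.fromarray(out).save(Path(path), format="PNG")


def build_validity_mask(
    disparity: InverseDepthMap, confidence: ConfidenceMap
) -> ValidityMask:
    """Pixels usable as supervision: finite disparity AND confidence > 0.

    Confidence 0 marks pixels the stereo matcher declared unmatched (e.g.
    the left-border occlusion band), which carry no disparity estimate and
    are excluded from every loss and metric population.
    """
    if disparity.shape != confidence.shape:
        raise DimensionError(
            f"disparity {disparity.shape} vs confidence {confidence.shape}"
        )
    flags = np.isfinite(disparity.values) & (confidence.values > 0.0)
    return ValidityMask(flags)
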