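"""Core containers shared across the pipeline.

A :class:`FieldImage` is one imaging field: five aligned 2-D channels
(nucleus stain, mitochondria, acetylated alpha-tubulin, whole-cell mask,
phase contrast) plus pixel-size metadata and provenance.  A
:class:`LabelMask` is an integer-labelled segmentation (0 = background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import tifffile

#: Canonical channel order for a five-channel field.
CHANNEL_NAMES = ("nucleus", "mito", "aat", "cellmask", "phase")


@dataclass
class FieldImage:
    """One multichannel imaging field.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D float array, all the same shape.
        Names follow :data:`CHANNEL_NAMES`.
    pixel_size
        Physical edge length of one pixel (micrometres per pixel).
    provenance
        Free-form metadata (run, plate, well, field, seed, ...).
    """

    channels: Mapping[str, np.ndarray]
    pixel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if ch.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def to_tiff(self, path) -> None:
        """Write channels as a multipage TIFF with channel-name tags."""
        stack = np.stack([np.asarray(self.channels[n], dtype=np.float32)
                          for n in CHANNEL_NAMES if n in self.channels])
        names = [n for n in CHANNEL_NAMES if n in self.channels]
        tifffile.imwrite(
            path, stack,
            metadata={"axes": "CYX", "channel_names": names,
                      "pixel_size": self.pixel_size, **self.provenance},
        )

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 1.0) -> "FieldImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        names = meta.get("channel_names", list(CHANNEL_NAMES[: stack.shape[0]]))
        channels = {n: stack[i].astype(float) for i, n in enumerate(names)}
        return cls(channels=channels,
                   pixel_size=float(meta.get("pixel_size", pixel_size)))


@dataclass
class LabelMask:
    """Integer-labelled objects on a 2-D grid; 0 is background.

    Labels are positive, consecutive integers; objects are 4-connected
    components.  Coordinates are 0-based (row, col).
    """

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def relabeled(self) -> "LabelMask":
        """Return a copy with labels renumbered to 1..n, preserving order."""
        ids = self.label_ids
        out = np.zeros_like(self.labels)
        for new, old in enumerate(ids, start=1):
            out[self.labels == old] = new
        return LabelMask(out, self.pixel_size)

    def to_tiff(self, path) -> None:
        if self.labels.max() > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for 16-bit TIFF")
        tifffile.imwrite(path, self.labels.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 1.0) -> "LabelMask":
        return cls(tifffile.imread(path).astype(np.int32), pixel_size)
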