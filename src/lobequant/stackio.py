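"""Image-stack container and file I/O.

Conventions used throughout the package, stated once here:

* pixel arrays are 4-axis, ordered ``(plane, channel, row, column)``;
* coordinates are 0-based, ``(row, column)``, origin at the top-left pixel;
* channels are identified by name ("DAPI" for the nuclear stain, "RFP"
  for the cytoplasmic reporter), with configurable aliases, never by
  acquisition index;
* on disk a stack is a multi-page TIFF (page order plane-major, then
  channel) plus a JSON sidecar carrying channel names and labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "FormatError",
    "read_stack",
    "write_stack",
    "write_quantification_table",
    "read_quantification_table",
    "DEFAULT_CHANNEL_ALIASES",
]

#: Case-insensitive aliases accepted for the two canonical channel names.
DEFAULT_CHANNEL_ALIASES: Mapping[str, tuple[str, ...]] = {
    "DAPI": ("dapi", "dna", "nuclear", "nuclei", "hoechst"),
    "RFP": ("rfp", "mrfp", "reporter", "red"),
}


class FormatError(ValueError):
    """Raised when an on-disk file is inconsistent with the stack layout."""


@dataclass
class ImageStack:
    """A per-lobe multi-plane, multi-channel image.

    Parameters
    ----------
    pixels
        Nonnegative intensity array of shape ``(n_planes, n_channels,
        height, width)``.
    channel_names
        One name per channel axis entry.
    lobe_id, group_label
        Sample identifiers carried through the pipeline.
    """

    pixels: np.ndarray
    channel_names: list[str]
    lobe_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_names = list(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be (plane, channel, row, column); got ndim={self.pixels.ndim}"
            )
        if not self.channel_names:
            raise ValueError("channel_names must be nonempty")
        if self.pixels.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.pixels.shape[1]} channel planes but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels contain NaN or infinity")
        if (self.pixels < 0).any():
            raise ValueError("pixels must be nonnegative intensities")

    # -- shape helpers -------------------------------------------------
    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    # -- channel access ------------------------------------------------
    def channel_index(
        self,
        name: str,
        aliases: Mapping[str, Sequence[str]] = DEFAULT_CHANNEL_ALIASES,
    ) -> int:
        """Resolve a canonical channel name to its axis index.

        Matching is case-insensitive and consults ``aliases`` so that
        stacks whose metadata says e.g. ``"mRFP"`` still resolve.
        """
        wanted = {name.lower()}
        wanted.update(a.lower() for a in aliases.get(name, ()))
        for i, ch in enumerate(self.channel_names):
            if ch.lower() in wanted:
                return i
        raise KeyError(
            f"stack {self.lobe_id!r} has no channel {name!r} "
            f"(channels: {self.channel_names})"
        )

    def channel(self, name: str, **kwargs) -> np.ndarray:
        """All planes of one channel, shape ``(n_planes, height, width)``."""
        return self.pixels[:, self.channel_index(name, **kwargs)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF plus JSON sidecar.

    Page order is plane-major then channel (plane 0/channel 0, plane 0/
    channel 1, plane 1/channel 0, ...). Integer input is stored as
    uint16 (the package's on-disk default); floating-point input is
    stored as float32.
    """
    stack.validate()
    path = Path(path)
    pix = stack.pixels
    if np.issubdtype(pix.dtype, np.integer):
        if pix.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("integer pixels exceed the uint16 range")
        data = pix.astype(np.uint16)
    else:
        data = pix.astype(np.float32)
    pages = data.reshape(-1, *stack.frame_shape)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "channel_names": stack.channel_names,
        "lobe_id": stack.lobe_id,
        "group_label": stack.group_label,
        "n_planes": stack.n_planes,
        "n_channels": stack.n_channels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into canonical (plane, channel, row, column) order.

    ``channel_map`` maps channel index to name; when omitted, the JSON
    sidecar written by :func:`write_stack` supplies names and layout.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D pages, got shape {pages.shape}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if channel_map is not None:
        indices = sorted(channel_map)
        if indices != list(range(len(indices))):
            raise FormatError(f"channel_map indices must be 0..C-1, got {indices}")
        names = [channel_map[i] for i in indices]
    elif "channel_names" in meta:
        names = list(meta["channel_names"])
    else:
        raise FormatError(f"{path}: no channel_map given and no sidecar metadata found")

    n_channels = len(names)
    if pages.shape[0] % n_channels != 0:
        raise FormatError(
            f"{path}: {pages.shape[0]} pages are not divisible by "
            f"{n_channels} channels"
        )
    n_planes = pages.shape[0] // n_channels
    if "n_planes" in meta and meta["n_planes"] != n_planes:
        raise FormatError(
            f"{path}: sidecar says {meta['n_planes']} planes, file implies {n_planes}"
        )
    pixels = pages.reshape(n_planes, n_channels, *pages.shape[1:])
    return ImageStack(
        pixels=pixels,
        channel_names=names,
        lobe_id=str(meta.get("lobe_id", path.stem)),
        group_label=str(meta.get("group_label", "")),
    )


# ---------------------------------------------------------------------
# per-lobe quantification tables


def write_quantification_table(records: Sequence, path: str | Path) -> Path:
    """Write per-lobe quantifications as CSV.

    Columns: lobe_id, group_label, n_cells, n_positive, percent_positive.
    A lobe with no detected cells has an empty percent_positive field
    (missing, not zero). Percentages are printed with at least four
    significant digits.
    """
    if not records:
        raise ValueError("no quantification records to write")
    path = Path(path)
    df = pd.DataFrame(
        {
            "lobe_id": [r.lobe_id for r in records],
            "group_label": [r.group_label for r in records],
            "n_cells": [r.n_cells for r in records],
            "n_positive": [r.n_positive for r in records],
            "percent_positive": [
                np.nan if r.percent_positive is None else r.percent_positive
                for r in records
            ],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_quantification_table(path: str | Path):
    """Read a CSV written by :func:`write_quantification_table`."""
    from .shells import LobeQuantification

    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        # counts are exact; the printed percentage is not, so rebuild it
        out.append(
            LobeQuantification.from_counts(
                lobe_id=str(row.lobe_id),
                group_label=str(row.group_label),
                n_cells=int(row.n_cells),
                n_positive=int(row.n_positive),
            )
        )
    return out
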