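"""Annular-shell reporter quantification and positive/negative calling.

Each detected cell's cytoplasmic reporter signal is sampled in an
annular shell centred on its nuclear peak. The shell is offset from the
centre by an empty gap of one nuclear diameter, so it reads cytoplasmic
reporter without ever sampling the nucleus itself. Cells are then
called reporter-positive when their shell statistic reaches 75% of the
maximal shell statistic in the lobe — a relative rule, so the calls are
invariant to overall intensity rescaling of the reporter channel.

Background handling: shell statistics sit on top of a camera/stain
background common to all cells. A purely relative 75% rule applied to
raw values would call every cell positive in a lobe with no reporter
signal at all (all shell means then sit within noise of the background,
hence above 75% of their own maximum). By default the mean of the
max-projected reporter frame is therefore subtracted from each shell
value (clipped at zero) before thresholding; set
``background_correction="none"`` for the literal raw-value rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import DetectedCell, DetectionParams, detect_nuclei
from .stackio import ImageStack

__all__ = [
    "ShellParams",
    "LobeQuantification",
    "shell_mask",
    "full_shell_size",
    "shell_statistic",
    "classify_cells",
    "quantify_lobe",
    "quantify_lobe_detailed",
]

logger = logging.getLogger(__name__)

_STATISTICS = ("mean", "median", "max")
_SCOPES = ("lobe", "image_pixel_max")
_CORRECTIONS = ("global_mean", "none")


@dataclass(frozen=True)
class ShellParams:
    """Geometry and thresholding of the reporter shell.

    ``gap`` is the empty annulus between the nuclear peak and the
    sampling shell, default one nuclear diameter; the shell spans radii
    ``[gap, gap + shell_width)``. ``threshold_fraction`` is the
    relative positivity cut (default 0.75). ``threshold_scope`` chooses
    the reference maximum: the per-lobe maximum of the cells' shell
    statistics (default) or the image pixel maximum.
    """

    gap: float = 12.0
    shell_width: float = 6.0
    threshold_fraction: float = 0.75
    shell_statistic: str = "mean"
    threshold_scope: str = "lobe"
    background_correction: str = "global_mean"
    #: cells whose shell loses more than this fraction of its pixels to
    #: the image border are excluded from the threshold-defining maximum
    #: (but still classified).
    border_clip_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be nonnegative")
        if self.shell_width < 1:
            raise ValueError("shell_width must be >= 1")
        if not 0.0 <= self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in [0, 1]")
        if self.shell_statistic not in _STATISTICS:
            raise ValueError(f"shell_statistic must be one of {_STATISTICS}")
        if self.threshold_scope not in _SCOPES:
            raise ValueError(f"threshold_scope must be one of {_SCOPES}")
        if self.background_correction not in _CORRECTIONS:
            raise ValueError(f"background_correction must be one of {_CORRECTIONS}")


@dataclass
class LobeQuantification:
    """Per-lobe aggregate: the paper-style "N cells" and "% positive"."""

    lobe_id: str
    group_label: str
    n_cells: int
    n_positive: int
    percent_positive: float | None  # None when n_cells == 0 (missing, not 0)

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_cells:
            raise ValueError("need 0 <= n_positive <= n_cells")
        if self.n_cells > 0:
            expected = 100.0 * self.n_positive / self.n_cells
            if self.percent_positive is None or not math.isclose(
                self.percent_positive, expected, abs_tol=1e-9
            ):
                raise ValueError("percent_positive inconsistent with counts")
        elif self.percent_positive is not None:
            raise ValueError("percent_positive must be missing when n_cells == 0")

    @classmethod
    def from_counts(
        cls, lobe_id: str, group_label: str, n_cells: int, n_positive: int
    ) -> "LobeQuantification":
        pct = 100.0 * n_positive / n_cells if n_cells > 0 else None
        return cls(lobe_id, group_label, n_cells, n_positive, pct)


def shell_mask(
    centre: tuple[int, int],
    inner_radius: float,
    outer_radius: float,
    image_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """In-bounds pixels with ``inner_radius <= dist(p, centre) < outer_radius``.

    Euclidean distance between pixel centres, half-open interval.
    Pixels outside the image are silently excluded; near a corner the
    mask may be empty. Returns (rows, cols) index arrays.
    """
    if inner_radius >= outer_radius:
        raise ValueError(
            f"inner_radius ({inner_radius}) must be < outer_radius ({outer_radius})"
        )
    r, c = centre
    ext = int(np.ceil(outer_radius))
    r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, image_shape[0])
    c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, image_shape[1])
    if r1 <= r0 or c1 <= c0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    d = np.sqrt(rr**2 + cc**2)
    sel = (d >= inner_radius) & (d < outer_radius)
    rows, cols = np.nonzero(sel)
    return rows + r0, cols + c0


def full_shell_size(inner_radius: float, outer_radius: float) -> int:
    """Pixel count of the unclipped annulus (used to flag border cells)."""
    ext = int(np.ceil(outer_radius))
    rr = np.arange(-ext, ext + 1)[:, None]
    cc = np.arange(-ext, ext + 1)[None, :]
    d = np.sqrt(rr**2 + cc**2)
    return int(((d >= inner_radius) & (d < outer_radius)).sum())


def shell_statistic(
    reporter_plane: np.ndarray,
    mask: tuple[np.ndarray, np.ndarray],
    statistic: str = "mean",
) -> float:
    """Summary of the reporter intensity over the masked shell pixels.

    ``reporter_plane`` is normally the maximum-intensity projection of
    the reporter channel. An empty mask returns 0 with a warning.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    rows, cols = mask
    if len(rows) == 0:
        logger.warning("empty shell mask; returning 0")
        return 0.0
    vals = np.asarray(reporter_plane)[rows, cols]
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "median":
        return float(np.median(vals))
    return float(vals.max())


def classify_cells(
    cells: Sequence[DetectedCell],
    stack: ImageStack,
    params: ShellParams,
    nuclear_diameter: float | None = None,
) -> list[DetectedCell]:
    """Call each detected cell reporter-positive or -negative (in place).

    Shell values are computed on the maximum-intensity projection of
    the reporter channel, the per-lobe threshold is
    ``threshold_fraction x`` the reference maximum, and a cell is
    positive when its (background-corrected) shell value reaches the
    threshold. Border-clipped shells are excluded from the
    threshold-defining maximum but still classified. If every shell
    value is zero, every cell is negative.
    """
    del nuclear_diameter  # geometry is fully specified by params.gap
    projection = stack.channel("RFP").max(axis=0)
    inner = params.gap
    outer = params.gap + params.shell_width
    full_size = full_shell_size(inner, outer)
    background = (
        float(projection.mean())
        if params.background_correction == "global_mean"
        else 0.0
    )

    cells = list(cells)
    for cell in cells:
        mask = shell_mask(cell.centre, inner, outer, projection.shape)
        cell.border_clipped = len(mask[0]) < params.border_clip_fraction * full_size
        raw = shell_statistic(projection, mask, params.shell_statistic)
        cell.shell_value = max(raw - background, 0.0)

    if not cells:
        return cells

    if params.threshold_scope == "image_pixel_max":
        reference = max(float(projection.max()) - background, 0.0)
    else:
        eligible = [c.shell_value for c in cells if not c.border_clipped]
        if not eligible:  # every shell clipped: fall back to all cells
            eligible = [c.shell_value for c in cells]
        reference = max(eligible)

    if reference <= 0.0:
        for cell in cells:
            cell.is_positive = False
        return cells

    threshold = params.threshold_fraction * reference
    for cell in cells:
        cell.is_positive = cell.shell_value >= threshold
    return cells


def quantify_lobe_detailed(
    stack: ImageStack,
    det: DetectionParams,
    shell: ShellParams,
) -> tuple[LobeQuantification, list[DetectedCell]]:
    """Detect, classify, and aggregate one lobe; also return the cells."""
    cells = detect_nuclei(stack, det)
    cells = classify_cells(cells, stack, shell)
    n_cells = len(cells)
    n_positive = sum(bool(c.is_positive) for c in cells)
    quant = LobeQuantification.from_counts(
        stack.lobe_id, stack.group_label, n_cells, n_positive
    )
    return quant, cells


def quantify_lobe(
    stack: ImageStack,
    det: DetectionParams,
    shell: ShellParams,
) -> LobeQuantification:
    """Per-lobe "N cells" and "% positive" (missing when no cells)."""
    quant, _ = quantify_lobe_detailed(stack, det, shell)
    return quant
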