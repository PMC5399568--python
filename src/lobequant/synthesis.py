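"""Synthetic two-channel confocal-like lobes with known ground truth.

The generator emulates the statistical structure of primary-lobe
confocal acquisitions: a nuclear-stain channel ("DAPI") holding round,
roughly uniform-diameter nuclei at non-overlapping positions across 2-3
z-planes, and a cytoplasmic-reporter channel ("RFP") in which only
reporter-positive cells carry an annular ring around — never over —
their nucleus. Additive background and zero-mean Gaussian noise
(clipped at zero) stand in for camera offset and shot noise. Every
image comes with its answer key, so detection, classification and the
group statistics can all be validated against ground truth.

Geometry defaults mirror the measurement geometry: the ring starts one
nuclear diameter from the nucleus centre, exactly where the measurement
shell samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .stackio import ImageStack

__all__ = [
    "SynthesisParams",
    "GroundTruthCell",
    "GroundTruth",
    "PlacementError",
    "generate_lobe_image",
    "generate_cohort",
    "CohortLobe",
    "derive_seed",
    "write_ground_truth_csv",
]

#: Per-nucleus cap on rejection-sampling attempts before declaring the
#: requested density infeasible.
MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Requested nucleus density cannot be placed without overlap."""


@dataclass(frozen=True)
class SynthesisParams:
    """Parameters of one synthetic lobe.

    All sizes are in pixels, all intensities in arbitrary units on the
    scale of a 16-bit acquisition. Defaults define the reference study
    conditions used throughout the test-bed: 512x512 frames, 3 planes,
    100 nuclei of diameter 12 px, ring and shell both spanning radii
    12-18 px from the nucleus centre, nuclear peak 1000 over background
    100 with noise sd 200 (peak signal-to-noise ~ 5).
    """

    image_height: int = 512
    image_width: int = 512
    n_planes: int = 3
    n_nuclei: int = 100
    nuclear_diameter: float = 12.0
    #: minimum centre-to-centre distance; the default keeps every cell's
    #: sampling shell disjoint from every neighbour's reporter ring
    #: (2 * (ring_inner_offset + ring_width)).
    min_centre_separation: float = 36.0
    positive_fraction: float = 0.5
    ring_inner_offset: float = 12.0
    ring_width: float = 6.0
    nuclear_peak_intensity: float = 1000.0
    reporter_ring_intensity: float = 800.0
    background_level: float = 100.0
    noise_sd: float = 200.0
    seed: int = 0
    #: multiplicative attenuation applied to odd-numbered planes of the
    #: nuclear channel (1.0 = identical nuclei on every plane).
    plane_attenuation: float = 1.0

    def validate(self) -> None:
        if self.n_planes not in (2, 3):
            raise ValueError(f"n_planes must be 2 or 3, got {self.n_planes}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        if self.min_centre_separation < self.nuclear_diameter:
            raise ValueError(
                "min_centre_separation must be >= nuclear_diameter "
                "(nuclei must not overlap)"
            )
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        for name in (
            "nuclear_diameter",
            "ring_inner_offset",
            "ring_width",
            "nuclear_peak_intensity",
            "reporter_ring_intensity",
            "background_level",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.plane_attenuation <= 1.0:
            raise ValueError("plane_attenuation must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruthCell:
    """One true nucleus: ``x`` is the column, ``y`` the row (0-based)."""

    x: int
    y: int
    is_positive: bool


@dataclass
class GroundTruth:
    """Answer key for one synthetic lobe."""

    cells: list[GroundTruthCell]
    params: SynthesisParams

    @property
    def n_positive(self) -> int:
        return sum(c.is_positive for c in self.cells)

    def centres_rc(self) -> np.ndarray:
        """True centres as an ``(n, 2)`` array of (row, column)."""
        return np.array([(c.y, c.x) for c in self.cells], dtype=float).reshape(-1, 2)

    def positive_mask(self) -> np.ndarray:
        return np.array([c.is_positive for c in self.cells], dtype=bool)


def _place_centres(params: SynthesisParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping integer centres (row, col).

    The margin keeps every reporter ring fully inside the frame.
    """
    margin = int(np.ceil(params.ring_inner_offset + params.ring_width))
    lo_r, hi_r = margin, params.image_height - 1 - margin
    lo_c, hi_c = margin, params.image_width - 1 - margin
    if params.n_nuclei > 0 and (hi_r < lo_r or hi_c < lo_c):
        raise PlacementError("image too small for the ring margin")
    centres = np.empty((params.n_nuclei, 2), dtype=float)
    min_sq = params.min_centre_separation**2
    for i in range(params.n_nuclei):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            r = rng.integers(lo_r, hi_r + 1)
            c = rng.integers(lo_c, hi_c + 1)
            if i == 0:
                centres[0] = (r, c)
                break
            d2 = np.sum((centres[:i] - (r, c)) ** 2, axis=1)
            if d2.min() >= min_sq:
                centres[i] = (r, c)
                break
        else:
            raise PlacementError(
                f"density infeasible: could not place nucleus {i + 1}/"
                f"{params.n_nuclei} after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return centres


def _render_nuclei(params: SynthesisParams, centres: np.ndarray) -> np.ndarray:
    """One noiseless nuclear frame: an isotropic Gaussian blob per nucleus.

    Gaussian profiles (sd = diameter / 4) give each nucleus a unique
    interior maximum, matching the peak-based detection principle; hard
    discs would create plateau maxima with ill-defined peak locations.
    """
    frame = np.zeros((params.image_height, params.image_width))
    s = params.nuclear_diameter / 4.0
    ext = int(np.ceil(4 * s))
    for r, c in centres:
        r, c = int(r), int(c)
        r0, r1 = max(r - ext, 0), min(r + ext + 1, params.image_height)
        c0, c1 = max(c - ext, 0), min(c + ext + 1, params.image_width)
        rr = np.arange(r0, r1)[:, None] - r
        cc = np.arange(c0, c1)[None, :] - c
        frame[r0:r1, c0:c1] += params.nuclear_peak_intensity * np.exp(
            -(rr**2 + cc**2) / (2 * s * s)
        )
    return frame


def annulus_mask_bounds(
    centre_rc: tuple[int, int],
    inner: float,
    outer: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """In-bounds pixel coordinates with ``inner <= dist < outer`` (Euclidean).

    Shared by the generator's ring rendering and by analytic masks in
    tests, so the two agree pixel-for-pixel by construction of the
    convention, not by coincidence.
    """
    r, c = centre_rc
    ext = int(np.ceil(outer))
    r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, shape[0])
    c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, shape[1])
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    d = np.sqrt(rr**2 + cc**2)
    sel = (d >= inner) & (d < outer)
    rows, cols = np.nonzero(sel)
    return rows + r0, cols + c0


def _render_rings(params: SynthesisParams, centres: np.ndarray, positive: np.ndarray) -> np.ndarray:
    frame = np.zeros((params.image_height, params.image_width))
    inner = params.ring_inner_offset
    outer = params.ring_inner_offset + params.ring_width
    for (r, c), pos in zip(centres, positive):
        if not pos:
            continue
        rows, cols = annulus_mask_bounds((int(r), int(c)), inner, outer, frame.shape)
        frame[rows, cols] += params.reporter_ring_intensity
    return frame


def generate_lobe_image(
    params: SynthesisParams,
    lobe_id: str = "synthetic",
    group_label: str = "",
) -> tuple[ImageStack, GroundTruth]:
    """Generate one synthetic lobe and its answer key.

    The first ``round(positive_fraction * n_nuclei)`` nuclei in
    placement order are reporter-positive, giving exact per-lobe count
    control. Fixed ``params.seed`` gives bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    centres = _place_centres(params, rng)

    n_pos = int(round(params.positive_fraction * params.n_nuclei))
    positive = np.zeros(params.n_nuclei, dtype=bool)
    positive[:n_pos] = True

    nuclear = _render_nuclei(params, centres)
    rings = _render_rings(params, centres, positive)

    shape = (params.n_planes, 2, params.image_height, params.image_width)
    pixels = np.empty(shape)
    for p in range(params.n_planes):
        att = params.plane_attenuation if p % 2 == 1 else 1.0
        pixels[p, 0] = att * nuclear
        pixels[p, 1] = rings
    pixels += params.background_level
    if params.noise_sd > 0:
        pixels += rng.normal(0.0, params.noise_sd, size=shape)
    np.clip(pixels, 0.0, None, out=pixels)

    stack = ImageStack(
        pixels=pixels,
        channel_names=["DAPI", "RFP"],
        lobe_id=lobe_id,
        group_label=group_label,
    )
    cells = [
        GroundTruthCell(x=int(c), y=int(r), is_positive=bool(p))
        for (r, c), p in zip(centres, positive)
    ]
    return stack, GroundTruth(cells=cells, params=params)


# ---------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortLobe:
    label: str
    stack: ImageStack
    ground_truth: GroundTruth


def derive_seed(master_seed: int, label: str, index: int) -> int:
    """Per-lobe seed from (master seed, group label, lobe index).

    Hash-based so it is stable under reordering of groups, and kept
    below 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_cohort(
    group_specs: Sequence[tuple[str, SynthesisParams, int]],
    seed: int,
) -> list[CohortLobe]:
    """Generate ``n_lobes`` independent lobes per group.

    Each lobe's seed is derived from the master seed, its group label
    and its index, so lobes are statistically independent within and
    across groups and the whole cohort is reproducible from one seed.
    """
    if not group_specs:
        raise ValueError("group_specs must be nonempty")
    lobes: list[CohortLobe] = []
    for label, params, n_lobes in group_specs:
        if n_lobes < 1:
            raise ValueError(f"group {label!r}: n_lobes must be >= 1")
        for i in range(n_lobes):
            p = replace(params, seed=derive_seed(seed, label, i))
            lobe_id = f"{label}_{i:03d}"
            stack, truth = generate_lobe_image(p, lobe_id=lobe_id, group_label=label)
            lobes.append(CohortLobe(label=label, stack=stack, ground_truth=truth))
    return lobes


def write_ground_truth_csv(
    lobes: Sequence[tuple[str, GroundTruth]],
    path,
) -> None:
    """Answer keys as CSV: lobe_id, cell_id, x, y, is_positive."""
    rows = []
    for lobe_id, truth in lobes:
        for cell_id, cell in enumerate(truth.cells):
            rows.append((lobe_id, cell_id, cell.x, cell.y, cell.is_positive))
    pd.DataFrame(
        rows, columns=["lobe_id", "cell_id", "x", "y", "is_positive"]
    ).to_csv(path, index=False)
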