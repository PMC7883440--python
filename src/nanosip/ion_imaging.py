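"""Ion-image stack processing: drift correction, accumulation, ratio maps, HSI.

Mirrors the standard OpenMIMS chain applied to NanoSIMS acquisitions: the
per-plane count images are registered to the first plane by integer-pixel
cross-correlation on a high-count reference species, summed ("stacked"), and
converted to isotope-ratio maps with Poisson counting uncertainty.  Ratio maps
are rendered as hue-saturation-intensity images in which hue encodes the ratio
(blue at natural abundance through red at the display ceiling) and intensity
encodes ion counts.

Only integer-pixel registration is performed: the counts stay exact integers
and their Poisson statistics are preserved (no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb

SPECIES = ("12C12C", "13C12C", "12C14N", "12C15N", "31P")

#: Default registration channel: 12C14N- is the highest-count species in
#: organic tissue and is the map the original ROIs were drawn on.
DEFAULT_REFERENCE_SPECIES = "12C14N"

#: Default minimum accumulated denominator counts for a ratio pixel to be
#: considered defined (caps the relative counting error at ~22%).
DEFAULT_MIN_DENOMINATOR_COUNTS = 20


def translate(arr: np.ndarray, dx: int, dy: int, fill=0) -> np.ndarray:
    """Shift a 2-D array's content by ``+dx`` columns and ``+dy`` rows.

    Exposed pixels are set to ``fill``.  Inverse of ``translate(.., -dx, -dy)``
    up to the filled border.
    """
    out = np.full_like(arr, fill)
    h, w = arr.shape
    dx, dy = int(dx), int(dy)
    if abs(dx) >= w or abs(dy) >= h:
        return out
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


@dataclass
class IonImageStack:
    """Raw per-plane, per-species count rasters from one acquisition.

    ``counts`` is indexed ``(plane, species, y, x)`` and holds nonnegative
    integers; ``species_order`` names the species axis.
    """

    counts: np.ndarray
    species_order: list[str]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be (plane, species, y, x)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.species_order)) != len(self.species_order):
            raise ValueError("duplicate species in species_order")
        if len(self.species_order) != self.counts.shape[1]:
            raise ValueError("species_order length must match species axis")

    @property
    def n_planes(self) -> int:
        return self.counts.shape[0]

    def species_index(self, name: str) -> int:
        try:
            return self.species_order.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in stack {self.species_order}")


@dataclass
class AccumulatedCounts:
    """Drift-corrected, plane-summed counts.

    ``valid_mask`` marks pixels covered by every aligned plane; outside it the
    counts are still the sum over whichever planes covered the pixel.
    """

    counts: np.ndarray  # (species, y, x) integers
    species_order: list[str]
    shifts_applied: list[tuple[int, int]]
    valid_mask: np.ndarray
    pixel_size_um: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def species_index(self, name: str) -> int:
        try:
            return self.species_order.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in {self.species_order}")


@dataclass
class RatioMap:
    """Per-pixel isotope count ratio with counting-statistics standard error."""

    ratio: np.ndarray
    sigma: np.ndarray
    numerator_species: str
    denominator_species: str
    mask: np.ndarray


def estimate_drift(
    stack: IonImageStack,
    reference_species: str = DEFAULT_REFERENCE_SPECIES,
) -> list[tuple[int, int]]:
    """Estimate the per-plane (dx, dy) stage drift against plane 0.

    The shift of plane ``k`` maximises the circular cross-correlation of plane
    ``k`` with plane 0 on the reference species; ties (within float precision)
    are broken toward smaller ``|dx|+|dy|``, then lexicographically on
    ``(dx, dy)``.  Plane 0 is the reference and gets shift ``(0, 0)``.
    """
    ref = stack.species_index(reference_species)
    planes = stack.counts[:, ref].astype(float)
    h, w = planes.shape[1:]
    if not np.any(planes[0]):
        raise ValueError("reference species is all zero on plane 0")

    f0 = np.fft.rfft2(planes[0])
    # signed shift value for each FFT index
    dys = np.where(np.arange(h) <= h // 2, np.arange(h), np.arange(h) - h)
    dxs = np.where(np.arange(w) <= w // 2, np.arange(w), np.arange(w) - w)
    penalty = np.abs(dys)[:, None] + np.abs(dxs)[None, :]

    shifts: list[tuple[int, int]] = [(0, 0)]
    for k in range(1, stack.n_planes):
        if not np.any(planes[k]):
            raise ValueError(f"reference species is all zero on plane {k}")
        corr = np.fft.irfft2(np.fft.rfft2(planes[k]) * np.conj(f0), s=(h, w))
        # corr[dy, dx] = sum plane_k(y, x) * plane_0(y - dy, x - dx):
        # peaks at the shift that moved plane 0's content into plane k.
        tied = corr >= corr.max() - 1e-6 * max(corr.max(), 1.0)
        cand = np.argwhere(tied)
        order = np.lexsort(
            (dys[cand[:, 0]], dxs[cand[:, 1]], penalty[cand[:, 0], cand[:, 1]])
        )
        best = cand[order[0]]
        shifts.append((int(dxs[best[1]]), int(dys[best[0]])))
    return shifts


def align_and_accumulate(
    stack: IonImageStack, shifts: Sequence[tuple[int, int]]
) -> AccumulatedCounts:
    """Undo the per-plane shifts and sum counts per species.

    Each plane is translated by the negative of its shift; ``valid_mask``
    marks pixels covered by all planes after alignment.
    """
    if len(shifts) != stack.n_planes:
        raise ValueError("one shift per plane is required")
    h, w = stack.counts.shape[2:]
    for dx, dy in shifts:
        if abs(int(dx)) >= w or abs(int(dy)) >= h:
            raise ValueError(f"shift ({dx}, {dy}) exceeds the image size")

    acc = np.zeros(stack.counts.shape[1:], dtype=np.int64)
    valid = np.ones((h, w), dtype=bool)
    ones = np.ones((h, w), dtype=np.int64)
    for k, (dx, dy) in enumerate(shifts):
        for s in range(stack.counts.shape[1]):
            acc[s] += translate(stack.counts[k, s].astype(np.int64), -dx, -dy)
        valid &= translate(ones, -dx, -dy).astype(bool)
    return AccumulatedCounts(
        counts=acc,
        species_order=list(stack.species_order),
        shifts_applied=[(int(dx), int(dy)) for dx, dy in shifts],
        valid_mask=valid,
        pixel_size_um=stack.pixel_size_um,
        metadata=dict(stack.metadata),
    )


def compute_ratio_map(
    acc: AccumulatedCounts,
    numerator: str,
    denominator: str,
    min_denominator_counts: int = DEFAULT_MIN_DENOMINATOR_COUNTS,
) -> RatioMap:
    """Per-pixel ``N_num / N_den`` with Poisson counting standard error.

    ``sigma = ratio * sqrt(1/N_num + 1/N_den)``; where the numerator count is
    zero the one-count upper bound ``sigma = 1/N_den`` is used.  Pixels whose
    denominator counts fall below ``min_denominator_counts`` are masked out.
    """
    if numerator == denominator:
        raise ValueError("numerator and denominator must differ")
    if min_denominator_counts < 1:
        raise ValueError("min_denominator_counts must be >= 1")
    num = acc.counts[acc.species_index(numerator)].astype(float)
    den = acc.counts[acc.species_index(denominator)].astype(float)
    mask = den >= min_denominator_counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        sigma = np.where(
            num > 0,
            ratio * np.sqrt(np.where(num > 0, 1.0 / np.maximum(num, 1), 0.0)
                            + 1.0 / np.maximum(den, 1)),
            1.0 / np.maximum(den, 1),
        )
    ratio[~mask] = 0.0
    sigma[~mask] = np.inf
    return RatioMap(
        ratio=ratio,
        sigma=sigma,
        numerator_species=numerator,
        denominator_species=denominator,
        mask=mask,
    )


def render_hsi(
    rm: RatioMap,
    scale_lo: float,
    scale_hi: float,
    acc: AccumulatedCounts,
    intensity_max: float | None = None,
) -> np.ndarray:
    """Render a ratio map as an RGB hue-saturation-intensity image.

    Hue runs linearly from blue (240 deg) at ``ratio <= scale_lo`` to red
    (0 deg) at ``ratio >= scale_hi``; intensity scales linearly with the
    denominator-species counts (zero counts render black), saturating at
    ``intensity_max`` (default: the maximum denominator count).
    """
    if not (np.isfinite(scale_lo) and np.isfinite(scale_hi)):
        raise ValueError("scale bounds must be finite")
    if not scale_lo < scale_hi:
        raise ValueError("scale_lo must be < scale_hi")
    den = acc.counts[acc.species_index(rm.denominator_species)].astype(float)
    if intensity_max is None:
        intensity_max = float(den.max()) if den.max() > 0 else 1.0
    frac = np.clip((rm.ratio - scale_lo) / (scale_hi - scale_lo), 0.0, 1.0)
    hue = (240.0 * (1.0 - frac)) / 360.0
    sat = np.ones_like(hue)
    val = np.clip(den / intensity_max, 0.0, 1.0)
    return hsv_to_rgb(np.dstack([hue, sat, val]))
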