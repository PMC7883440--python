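"""Synthetic sponge-tissue scenes and simulated NanoSIMS / bulk-IRMS data.

The generator emulates the study system end to end so every downstream stage
is testable with known ground truth:

* **Tissue scenes** — choanocyte chambers (rings of flagellated filter cells),
  mesohyl cells, optional spherulous cells, and ~1 um microbial symbionts
  scattered through the mesohyl matrix at either high (HMA) or low (LMA)
  density.  Each pixel carries a true 13C and 15N atom fraction; enriched
  choanocytes additionally contain 1-2 um intracellular hotspots.
* **Acquisitions** — per-plane, per-pixel ion counts are independent Poisson
  draws from an isotopologue rate model for the five recorded secondary-ion
  species (12C12C-, 13C12C-, 12C14N-, 12C15N-, 31P-), with integer-pixel
  stage drift between planes and a multiplicative instrument
  mass-fractionation bias on each minor/major ratio.
* **Bulk pulse-chase tables** — per-individual delta13C/delta15N values that
  rise linearly over a 3-h pulse and decay geometrically through the chase,
  with unlabelled controls at every time point.

All randomness flows from the spec seeds; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import F_NAT_C, F_NAT_N
from .ion_imaging import SPECIES, IonImageStack, translate

CATEGORIES = (
    "choanocyte",
    "mesohyl_cell",
    "microbe",
    "spherulous_cell",
    "mesohyl_matrix",
    "background",
)

#: Microbial symbiont densities (cells per um^2 of mesohyl) for the two
#: sponge archetypes; HMA sponges carry orders of magnitude more symbionts.
MICROBE_DENSITY_HMA = 0.25
MICROBE_DENSITY_LMA = 0.02

# Nominal cell diameters in um, loosely matching electron micrographs of
# encrusting sponge tissue.
_CELL_DIAMETER_UM = {
    "choanocyte": 3.5,
    "mesohyl_cell": 4.5,
    "spherulous_cell": 5.5,
    "microbe": 1.0,
}

#: Relative C, N, P surface densities per category (matrix is dilute organic
#: material; microbes are P-rich relative to host cytoplasm).
DEFAULT_DENSITY_SCALE = {
    "choanocyte": (1.0, 1.0, 1.0),
    "mesohyl_cell": (1.0, 1.0, 1.0),
    "spherulous_cell": (1.0, 0.8, 0.5),
    "microbe": (1.0, 1.2, 2.5),
    "mesohyl_matrix": (0.35, 0.30, 0.15),
    "background": (0.35, 0.30, 0.15),
}


def natural_atom_fractions() -> tuple[float, float]:
    """(f_C, f_N) at natural abundance (VPDB / atmospheric N2)."""
    return (F_NAT_C, F_NAT_N)


@dataclass
class HotspotSpec:
    """Intracellular enrichment hotspots inside choanocytes.

    Hotspot pixels multiply the cell's *excess* atom fraction over natural
    abundance by ``multiplier`` (capped at 1), producing the 1-2 um
    high-intensity features seen in enriched filter cells.
    """

    count_per_cell: int = 2
    diameter_um: tuple[float, float] = (1.0, 2.0)
    multiplier: float = 4.0


@dataclass
class SceneSpec:
    """Parameters of a synthetic tissue scene."""

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.05
    n_choanocyte_chambers: int = 1
    choanocytes_per_chamber: int = 8
    n_mesohyl_cells: int = 4
    n_spherulous_cells: int = 0
    microbe_density_per_um2: float = MICROBE_DENSITY_LMA
    hotspot_spec: HotspotSpec = field(default_factory=HotspotSpec)
    category_atom_fractions: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    background_atom_fractions: tuple[float, float] = (F_NAT_C, F_NAT_N)
    elemental_density_scale: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_SCALE)
    )
    seed: int = 0

    def validate(self) -> None:
        for cat, (fc, fn) in self.category_atom_fractions.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if not (0 <= fc <= 1 and 0 <= fn <= 1):
                raise ValueError(f"atom fractions for {cat!r} outside [0, 1]")
        fc, fn = self.background_atom_fractions
        if not (0 <= fc <= 1 and 0 <= fn <= 1):
            raise ValueError("background atom fractions outside [0, 1]")
        if self.microbe_density_per_um2 < 0:
            raise ValueError("microbe density must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class GroundTruthScene:
    """Per-pixel truth for a simulated scene.

    ``label_map`` holds 0 for background/matrix and a positive cell id
    elsewhere; ``category_of_cell`` maps every nonzero id to its category.
    """

    label_map: np.ndarray
    category_of_cell: dict[int, str]
    f_c_map: np.ndarray
    f_n_map: np.ndarray
    density_maps: dict[str, np.ndarray]  # keys "C", "N", "P"
    pixel_size_um: float

    def cells_of(self, category: str) -> list[int]:
        return [i for i, c in self.category_of_cell.items() if c == category]


@dataclass
class AcquisitionSpec:
    """Parameters of a simulated NanoSIMS acquisition.

    ``yields`` gives the expected counts per pixel per plane at unit elemental
    density for each detected ion family: ``"C2"`` (both C2- isotopologues),
    ``"CN"`` (both CN- isotopologues) and ``"P"``.  ``bias_c`` / ``bias_n``
    multiply the minor/major expected-count ratio (instrument mass
    fractionation).  ``drift_per_plane_px`` is either an explicit list of
    integer (dx, dy) shifts or a random-walk sigma in pixels.
    """

    n_planes: int = 6
    yields: dict[str, float] = field(
        default_factory=lambda: {"C2": 120.0, "CN": 250.0, "P": 40.0}
    )
    drift_per_plane_px: list[tuple[int, int]] | float = 0.0
    bias_c: float = 1.0
    bias_n: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if any(v < 0 for v in self.yields.values()):
            raise ValueError("yields must be nonnegative")
        if self.bias_c <= 0 or self.bias_n <= 0:
            raise ValueError("biases must be positive")

    def resolve_shifts(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Explicit per-plane (dx, dy) drift, plane 0 fixed at (0, 0)."""
        if isinstance(self.drift_per_plane_px, (int, float)):
            sigma = float(self.drift_per_plane_px)
            if sigma == 0:
                return [(0, 0)] * self.n_planes
            steps = rng.normal(0.0, sigma, size=(self.n_planes, 2))
            steps[0] = 0.0
            walk = np.rint(np.cumsum(steps, axis=0)).astype(int)
            return [(int(dx), int(dy)) for dx, dy in walk]
        shifts = [(int(dx), int(dy)) for dx, dy in self.drift_per_plane_px]
        if len(shifts) != self.n_planes:
            raise ValueError("need one drift vector per plane")
        if shifts[0] != (0, 0):
            raise ValueError("plane 0 drift must be (0, 0)")
        return shifts


@dataclass
class BulkSeriesSpec:
    """Design of a synthetic bulk pulse-chase series for one species/food."""

    species_label: str = "H. caerulea"
    treatment: str = "DOM"
    n_per_timepoint: int = 3
    timepoints_h: tuple[float, ...] = (0.25, 0.5, 1.0, 3.0, 24.0, 48.0)
    pulse_end_h: float = 3.0
    true_slope_c: float = 100.0  # Δδ13C per hour during the pulse
    true_slope_n: float = 120.0  # Δδ15N per hour during the pulse
    chase_decay: float = 0.02  # fractional Δδ decline per hour after pulse
    noise_sd: float = 15.0  # ‰, gaussian, both isotopes
    control_delta: tuple[float, float] = (-18.0, 5.0)  # (δ13C, δ15N) baseline
    pct_c: float = 32.0
    pct_n: float = 7.5
    dry_weight_g: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_timepoint < 1:
            raise ValueError("n_per_timepoint must be >= 1")
        if not (min(self.timepoints_h) <= self.pulse_end_h <= max(self.timepoints_h)):
            raise ValueError("pulse_end_h must lie within the sampled range")

    def true_delta_excess(self, t: float, isotope: str) -> float:
        """Noise-free Δδ (‰) at time ``t`` for ``isotope`` in {"C", "N"}."""
        slope = self.true_slope_c if isotope == "C" else self.true_slope_n
        if t <= self.pulse_end_h:
            return slope * t
        peak = slope * self.pulse_end_h
        return peak * (1.0 - self.chase_decay) ** (t - self.pulse_end_h)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

_MAX_PLACEMENT_TRIES = 200


def _disk_pixels(cy, cx, radius_px, shape):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def _place_disk(rng, occupied, radius_px, shape, margin_px=1.0):
    """Find a free disk centre: rejection sampling, then exhaustive fallback."""
    h, w = shape
    r = radius_px + margin_px
    if 2 * r >= min(h, w):
        raise RuntimeError(
            f"a feature of radius {radius_px:.1f} px cannot fit in a "
            f"{h}x{w} px field; enlarge the field or coarsen the pixels"
        )
    for _ in range(_MAX_PLACEMENT_TRIES):
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        footprint = _disk_pixels(cy, cx, r, shape)
        if not np.any(occupied & footprint):
            return cy, cx
    # crowded field: enumerate feasible centres via the distance transform
    # of the free region (field border treated as occupied)
    free = np.pad(~occupied, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(free)[1:-1, 1:-1]
    cand = np.argwhere(dist > r + 1)
    if len(cand) == 0:
        raise RuntimeError(
            f"no room left for a feature of radius {radius_px:.1f} px; "
            "reduce cell counts or enlarge the field"
        )
    cy, cx = cand[rng.integers(len(cand))]
    return float(cy), float(cx)


def build_scene(spec: SceneSpec) -> GroundTruthScene:
    """Construct a ground-truth tissue scene from a spec.

    Choanocyte chambers are laid out as rings of touching cells; mesohyl and
    spherulous cells are scattered without overlap; microbes are placed in the
    remaining matrix at the configured surface density.  Hotspot pixels occur
    only inside choanocytes.  Deterministic for a fixed seed.
    """
    spec.validate()
    h, w = spec.image_size_px
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um

    label = np.zeros((h, w), dtype=np.uint16)
    category_of_cell: dict[int, str] = {}
    f_c = np.full((h, w), spec.background_atom_fractions[0], dtype=np.float64)
    f_n = np.full((h, w), spec.background_atom_fractions[1], dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    next_id = 1

    def cat_fractions(cat):
        return spec.category_atom_fractions.get(cat, spec.background_atom_fractions)

    def paint(mask, cat):
        nonlocal next_id
        label[mask] = next_id
        occupied[mask] = True
        fc, fn = cat_fractions(cat)
        f_c[mask] = fc
        f_n[mask] = fn
        category_of_cell[next_id] = cat
        next_id += 1
        return next_id - 1

    choano_r = _CELL_DIAMETER_UM["choanocyte"] / 2 / px
    hot_cells: list[int] = []
    for _ in range(spec.n_choanocyte_chambers):
        n = spec.choanocytes_per_chamber
        if n <= 0:
            continue
        # ring radius so adjacent cells just clear each other
        ring_r = choano_r * 1.15 / np.sin(np.pi / n) if n > 1 else 0.0
        cy, cx = _place_disk(rng, occupied, ring_r + choano_r, (h, w))
        phase = rng.uniform(0, 2 * np.pi)
        for j in range(n):
            ang = phase + 2 * np.pi * j / n
            mask = _disk_pixels(
                cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang), choano_r, (h, w)
            )
            hot_cells.append(paint(mask, "choanocyte"))

    for cat, count in (
        ("mesohyl_cell", spec.n_mesohyl_cells),
        ("spherulous_cell", spec.n_spherulous_cells),
    ):
        r = _CELL_DIAMETER_UM[cat] / 2 / px
        for _ in range(count):
            cy, cx = _place_disk(rng, occupied, r, (h, w))
            paint(_disk_pixels(cy, cx, r, (h, w)), cat)

    # microbes in the remaining matrix
    area_um2 = h * w * px * px
    n_microbes = int(round(spec.microbe_density_per_um2 * area_um2))
    r = _CELL_DIAMETER_UM["microbe"] / 2 / px
    for _ in range(n_microbes):
        cy, cx = _place_disk(rng, occupied, r, (h, w), margin_px=0.5)
        paint(_disk_pixels(cy, cx, r, (h, w)), "microbe")

    # intracellular hotspots: multiply the excess over natural abundance
    hs = spec.hotspot_spec
    if hs.count_per_cell > 0:
        fc_cell, fn_cell = cat_fractions("choanocyte")
        fc_hot = min(F_NAT_C + hs.multiplier * (fc_cell - F_NAT_C), 1.0)
        fn_hot = min(F_NAT_N + hs.multiplier * (fn_cell - F_NAT_N), 1.0)
        for cid in hot_cells:
            ys, xs = np.nonzero(label == cid)
            for _ in range(hs.count_per_cell):
                d_um = rng.uniform(*hs.diameter_um)
                i = rng.integers(len(ys))
                mask = _disk_pixels(ys[i], xs[i], d_um / 2 / px, (h, w))
                mask &= label == cid  # hotspots stay inside the cell
                f_c[mask] = fc_hot
                f_n[mask] = fn_hot

    # elemental density rasters
    dens = {e: np.empty((h, w)) for e in "CNP"}
    bg = spec.elemental_density_scale.get(
        "background", DEFAULT_DENSITY_SCALE["background"]
    )
    for i, e in enumerate("CNP"):
        dens[e].fill(bg[i])
    for cid, cat in category_of_cell.items():
        scale = spec.elemental_density_scale.get(cat, (1.0, 1.0, 1.0))
        mask = label == cid
        for i, e in enumerate("CNP"):
            dens[e][mask] = scale[i]

    return GroundTruthScene(
        label_map=label,
        category_of_cell=category_of_cell,
        f_c_map=f_c,
        f_n_map=f_n,
        density_maps=dens,
        pixel_size_um=px,
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def plane_rates(
    scene: GroundTruthScene,
    acq: AcquisitionSpec,
    shift: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Expected counts per pixel, per species, for one plane at one drift.

    The isotopologue model: with carbon atom fraction f and relative carbon
    density D_C, the C2- rates are ``y_C2 D_C (1-f)^2`` for 12C12C- and
    ``y_C2 D_C 2 f (1-f) bias_c`` for 13C12C- (13C13C- is not recorded);
    the CN- rates are ``y_CN D_N (1-f_N)`` and ``y_CN D_N f_N bias_n``;
    31P- is ``y_P D_P``.
    """
    bg = scene.density_maps  # aliases
    fill_fc, fill_fn = F_NAT_C, F_NAT_N
    dx, dy = shift
    f_c = translate(scene.f_c_map, dx, dy, fill=fill_fc)
    f_n = translate(scene.f_n_map, dx, dy, fill=fill_fn)
    bg_d = DEFAULT_DENSITY_SCALE["background"]
    d_c = translate(bg["C"], dx, dy, fill=bg_d[0])
    d_n = translate(bg["N"], dx, dy, fill=bg_d[1])
    d_p = translate(bg["P"], dx, dy, fill=bg_d[2])

    y_c2 = acq.yields.get("C2", 0.0)
    y_cn = acq.yields.get("CN", 0.0)
    y_p = acq.yields.get("P", 0.0)
    lam = np.empty((len(SPECIES),) + scene.label_map.shape)
    lam[0] = y_c2 * d_c * (1.0 - f_c) ** 2
    lam[1] = y_c2 * d_c * 2.0 * f_c * (1.0 - f_c) * acq.bias_c
    lam[2] = y_cn * d_n * (1.0 - f_n)
    lam[3] = y_cn * d_n * f_n * acq.bias_n
    lam[4] = y_p * d_p
    return lam


def simulate_acquisition(
    scene: GroundTruthScene, acq: AcquisitionSpec
) -> IonImageStack:
    """Simulate a multi-plane NanoSIMS acquisition of a scene.

    Per pixel, per plane, counts are independent Poisson draws from the
    isotopologue rate model; plane k's field of view is the scene shifted by
    the k-th drift vector, with exposed edges filled at background
    composition.  Deterministic for fixed scene + spec seeds.
    """
    acq.validate()
    rng = np.random.default_rng(acq.seed)
    shifts = acq.resolve_shifts(rng)
    h, w = scene.label_map.shape
    counts = np.empty((acq.n_planes, len(SPECIES), h, w), dtype=np.int64)
    for k, shift in enumerate(shifts):
        counts[k] = rng.poisson(plane_rates(scene, acq, shift))
    return IonImageStack(
        counts=counts,
        species_order=list(SPECIES),
        pixel_size_um=scene.pixel_size_um,
        metadata={
            "simulated": True,
            "applied_drift_px": [list(s) for s in shifts],
            "seed": int(acq.seed),
        },
    )


# ---------------------------------------------------------------------------
# Bulk pulse-chase series
# ---------------------------------------------------------------------------


def simulate_bulk_series(spec: BulkSeriesSpec) -> pd.DataFrame:
    """Simulate a bulk-tissue pulse-chase sample table.

    Returns one row per individual with columns matching the bulk-sample
    schema: labelled individuals at every time point plus unlabelled controls
    (treatment ``"control"``) at every time point.  Pulse-phase Δδ means
    follow ``true_slope * t``; chase-phase means decay geometrically.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    i = 0
    for t in spec.timepoints_h:
        for group in (spec.treatment, "control"):
            for _ in range(spec.n_per_timepoint):
                if group == "control":
                    ddc = ddn = 0.0
                else:
                    ddc = spec.true_delta_excess(t, "C")
                    ddn = spec.true_delta_excess(t, "N")
                noise = rng.normal(0.0, spec.noise_sd, size=2) if spec.noise_sd else (0.0, 0.0)
                rows.append(
                    {
                        "sample_id": f"{spec.species_label}-{group}-t{t:g}-{i:03d}",
                        "species_label": spec.species_label,
                        "treatment": group,
                        "timepoint_h": float(t),
                        "delta_c_permil": spec.control_delta[0] + ddc + noise[0],
                        "delta_n_permil": spec.control_delta[1] + ddn + noise[1],
                        "pct_c": spec.pct_c,
                        "pct_n": spec.pct_n,
                        "dry_weight_g": spec.dry_weight_g,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def control_scene_spec(spec: SceneSpec) -> SceneSpec:
    """The unlabelled-control counterpart of a scene spec.

    Same geometry and seed, all categories at natural abundance (so control
    ROI statistics are measured on matched tissue).
    """
    return replace(spec, category_atom_fractions={}, seed=spec.seed)
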