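"""Per-ROI isotope quantification, enrichment calls, and category summaries.

Each region of interest (a manually drawn or simulated cell mask) is reduced
to a ratio-of-sums over its pixels — the minimum-variance ratio estimator for
Poisson counts and robust at low per-pixel counts — then converted to
calibrated 13C and 15N Atom% with the matching session correction factor.

Enrichment is called against unlabelled-control statistics per ROI category:
an ROI is enriched when its Atom% strictly exceeds the control mean plus
three control standard deviations for that category and isotope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import SessionCalibration, atom_fraction
from .ion_imaging import AccumulatedCounts

ROI_CATEGORIES = (
    "choanocyte",
    "mesohyl_cell",
    "microbe",
    "spherulous_cell",
    "mesohyl_matrix",
)

#: Categories reported in headline summaries; spherulous cells and bare
#: matrix are measured but kept out of the main plots (low enrichment).
HEADLINE_CATEGORIES = ("choanocyte", "mesohyl_cell", "microbe")

#: Number of control standard deviations above the control mean an ROI's
#: Atom% must exceed to be called enriched.
ENRICHMENT_SD_MULTIPLIER = 3.0


@dataclass
class Roi:
    """One region of interest on an accumulated ion image."""

    id: int
    category: str
    pixels: tuple[np.ndarray, np.ndarray]  # (ys, xs) index arrays
    sample_id: str = ""
    timepoint_h: float = float("nan")
    treatment: str = ""

    def __post_init__(self) -> None:
        ys, xs = self.pixels
        ys = np.asarray(ys, dtype=np.intp)
        xs = np.asarray(xs, dtype=np.intp)
        if ys.size == 0:
            raise ValueError(f"ROI {self.id} has no pixels")
        if ys.size != xs.size:
            raise ValueError("pixel index arrays must have equal length")
        if self.category not in ROI_CATEGORIES:
            raise ValueError(f"unknown ROI category {self.category!r}")
        self.pixels = (ys, xs)

    @property
    def n_pixels(self) -> int:
        return self.pixels[0].size


@dataclass
class RoiMeasurement:
    """Summed counts, ratio-of-sums and calibrated Atom% for one ROI."""

    roi_id: int
    category: str
    counts: dict[str, int]
    r_c: float
    r_n: float
    atom_pct_c: float
    atom_pct_n: float
    valid_c: bool
    valid_n: bool
    sample_id: str = ""
    timepoint_h: float = float("nan")
    treatment: str = ""
    enriched_c: bool | None = None
    enriched_n: bool | None = None

    def atom_pct(self, isotope: str) -> float:
        return self.atom_pct_c if isotope == "13C" else self.atom_pct_n

    def is_valid(self, isotope: str) -> bool:
        return self.valid_c if isotope == "13C" else self.valid_n


@dataclass
class ControlStats:
    """Natural-abundance Atom% statistics for one category and isotope."""

    category: str
    isotope: str
    mean_atom_pct: float
    sd_atom_pct: float
    n_controls: int

    @property
    def threshold_atom_pct(self) -> float:
        return self.mean_atom_pct + ENRICHMENT_SD_MULTIPLIER * self.sd_atom_pct


def rois_from_scene(scene, sample_id="", timepoint_h=float("nan"), treatment=""):
    """Build ROIs directly from a simulated scene's ground-truth labels."""
    rois = []
    for cid, cat in scene.category_of_cell.items():
        ys, xs = np.nonzero(scene.label_map == cid)
        rois.append(
            Roi(
                id=int(cid),
                category=cat,
                pixels=(ys, xs),
                sample_id=sample_id,
                timepoint_h=timepoint_h,
                treatment=treatment,
            )
        )
    return rois


def measure_rois(
    acc: AccumulatedCounts,
    rois: list[Roi],
    calib_c: SessionCalibration,
    calib_n: SessionCalibration,
) -> list[RoiMeasurement]:
    """Quantify each ROI on an accumulated stack.

    The per-ROI ratio is the ratio of summed counts, ``Σ(13C12C)/Σ(12C12C)``
    and ``Σ(12C15N)/Σ(12C14N)``, converted to Atom% with the matching session
    correction factor.  An ROI whose denominator counts sum to zero is
    flagged invalid for that isotope (never silently dropped).
    """
    h, w = acc.counts.shape[1:]
    idx = {s: acc.species_index(s) for s in acc.species_order}
    out = []
    for roi in rois:
        ys, xs = roi.pixels
        if ys.max() >= h or xs.max() >= w or ys.min() < 0 or xs.min() < 0:
            raise ValueError(f"ROI {roi.id} has pixels outside the image")
        sums = {s: int(acc.counts[i, ys, xs].sum()) for s, i in idx.items()}
        s_c2, s_c2m = sums.get("12C12C", 0), sums.get("13C12C", 0)
        s_cn, s_cnm = sums.get("12C14N", 0), sums.get("12C15N", 0)
        valid_c, valid_n = s_c2 > 0, s_cn > 0
        r_c = s_c2m / s_c2 if valid_c else float("nan")
        r_n = s_cnm / s_cn if valid_n else float("nan")
        ap_c = atom_fraction(r_c, calib_c.cf)[1] if valid_c else float("nan")
        ap_n = atom_fraction(r_n, calib_n.cf)[1] if valid_n else float("nan")
        out.append(
            RoiMeasurement(
                roi_id=roi.id,
                category=roi.category,
                counts=sums,
                r_c=r_c,
                r_n=r_n,
                atom_pct_c=ap_c,
                atom_pct_n=ap_n,
                valid_c=valid_c,
                valid_n=valid_n,
                sample_id=roi.sample_id,
                timepoint_h=roi.timepoint_h,
                treatment=roi.treatment,
            )
        )
    return out


def measurements_frame(measurements: list[RoiMeasurement]) -> pd.DataFrame:
    """Tabulate measurements (one row per ROI)."""
    return pd.DataFrame(
        {
            "roi_id": [m.roi_id for m in measurements],
            "category": [m.category for m in measurements],
            "sample_id": [m.sample_id for m in measurements],
            "timepoint_h": [m.timepoint_h for m in measurements],
            "treatment": [m.treatment for m in measurements],
            "r_c": [m.r_c for m in measurements],
            "r_n": [m.r_n for m in measurements],
            "atom_pct_c": [m.atom_pct_c for m in measurements],
            "atom_pct_n": [m.atom_pct_n for m in measurements],
            "valid_c": [m.valid_c for m in measurements],
            "valid_n": [m.valid_n for m in measurements],
            "enriched_c": [m.enriched_c for m in measurements],
            "enriched_n": [m.enriched_n for m in measurements],
        }
    )


def measurements_from_frame(df: pd.DataFrame) -> list[RoiMeasurement]:
    """Rebuild measurement objects from a :func:`measurements_frame` table.

    Per-species count sums are not stored in the table and come back empty.
    """
    out = []
    for row in df.itertuples(index=False):
        enr_c = None if pd.isna(row.enriched_c) else bool(row.enriched_c)
        enr_n = None if pd.isna(row.enriched_n) else bool(row.enriched_n)
        out.append(
            RoiMeasurement(
                roi_id=int(row.roi_id),
                category=row.category,
                counts={},
                r_c=float(row.r_c),
                r_n=float(row.r_n),
                atom_pct_c=float(row.atom_pct_c),
                atom_pct_n=float(row.atom_pct_n),
                valid_c=bool(row.valid_c),
                valid_n=bool(row.valid_n),
                sample_id="" if pd.isna(row.sample_id) else str(row.sample_id),
                timepoint_h=float(row.timepoint_h),
                treatment="" if pd.isna(row.treatment) else str(row.treatment),
                enriched_c=enr_c,
                enriched_n=enr_n,
            )
        )
    return out


def control_stats(
    control_measurements: list[RoiMeasurement], category: str, isotope: str
) -> ControlStats:
    """Natural-abundance statistics from unlabelled-control ROIs.

    Uses the sample standard deviation (n-1).  Requires at least two valid
    control measurements in the category.
    """
    vals = [
        m.atom_pct(isotope)
        for m in control_measurements
        if m.category == category and m.is_valid(isotope)
    ]
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 valid control ROIs for {category}/{isotope}, got {len(vals)}"
        )
    return ControlStats(
        category=category,
        isotope=isotope,
        mean_atom_pct=float(np.mean(vals)),
        sd_atom_pct=float(np.std(vals, ddof=1)),
        n_controls=len(vals),
    )


def classify_enrichment(m: RoiMeasurement, cs: ControlStats) -> bool | None:
    """Call enrichment for one ROI against its category's control stats.

    Enriched iff Atom% strictly exceeds control mean + 3 SD.  Invalid
    measurements propagate as ``None``.  Mutates the measurement's
    ``enriched_c`` / ``enriched_n`` flag and returns the call.
    """
    if m.category != cs.category:
        raise ValueError(
            f"category mismatch: measurement {m.category!r} vs controls {cs.category!r}"
        )
    if not m.is_valid(cs.isotope):
        call = None
    else:
        call = bool(m.atom_pct(cs.isotope) > cs.threshold_atom_pct)
    if cs.isotope == "13C":
        m.enriched_c = call
    else:
        m.enriched_n = call
    return call


def classify_all(
    measurements: list[RoiMeasurement],
    controls: dict[tuple[str, str], ControlStats],
) -> None:
    """Classify every measurement with the matching (category, isotope) stats."""
    for m in measurements:
        for isotope in ("13C", "15N"):
            cs = controls.get((m.category, isotope))
            if cs is not None:
                classify_enrichment(m, cs)


def fraction_enriched(
    measurements: list[RoiMeasurement],
    group_by: tuple[str, ...] = ("category", "timepoint_h"),
) -> pd.DataFrame:
    """Proportion of enriched ROIs per group and isotope.

    Proportion = enriched / valid classified total; groups with no valid
    classified ROIs are omitted with a warning.
    """
    df = measurements_frame(measurements)
    rows = []
    for isotope, col in (("13C", "enriched_c"), ("15N", "enriched_n")):
        sub = df[df[col].notna()]
        if sub.empty:
            continue
        for keys, g in sub.groupby(list(group_by), dropna=False):
            keys = keys if isinstance(keys, tuple) else (keys,)
            rows.append(
                dict(zip(group_by, keys))
                | {
                    "isotope": isotope,
                    "n_enriched": int(g[col].sum()),
                    "n_total": len(g),
                    "proportion_enriched": float(g[col].mean()),
                }
            )
    dropped = df[df["enriched_c"].isna() & df["enriched_n"].isna()]
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} ROI(s) had no valid classification and were omitted",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def summarize_by_category(
    measurements: list[RoiMeasurement],
    group_by: tuple[str, ...] = ("category", "timepoint_h"),
) -> pd.DataFrame:
    """Mean, median, quartiles and n of Atom% per group and isotope.

    Quartiles use linear interpolation (the convention behind box-plot
    hinges).  Order-invariant in the input.
    """
    df = measurements_frame(measurements)
    rows = []
    for isotope, col, vcol in (
        ("13C", "atom_pct_c", "valid_c"),
        ("15N", "atom_pct_n", "valid_n"),
    ):
        sub = df[df[vcol]]
        for keys, g in sub.groupby(list(group_by), dropna=False):
            keys = keys if isinstance(keys, tuple) else (keys,)
            v = g[col].to_numpy()
            rows.append(
                dict(zip(group_by, keys))
                | {
                    "isotope": isotope,
                    "n": len(v),
                    "mean_atom_pct": float(np.mean(v)),
                    "median_atom_pct": float(np.median(v)),
                    "q25_atom_pct": float(np.percentile(v, 25)),
                    "q75_atom_pct": float(np.percentile(v, 75)),
                }
            )
    return pd.DataFrame(rows)
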