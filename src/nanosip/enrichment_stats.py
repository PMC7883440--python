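"""Single-cell time-series inference on ROI Atom% distributions.

Compares per-category Atom% distributions between time points with the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test — chosen because single-cell
enrichment distributions are right-skewed with intracellular hotspots — and
adjusts across all comparisons in a run with Benjamini-Hochberg.  A
host-to-symbiont "translocation signature" is flagged when, from pulse end to
chase end, the microbe category increases significantly while no host
category significantly increases (an unambiguous source-to-sink pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .roi_quant import RoiMeasurement

DEFAULT_ALPHA = 0.05

HOST_CATEGORIES = ("choanocyte", "mesohyl_cell")
SYMBIONT_CATEGORY = "microbe"


@dataclass
class TimepointComparison:
    """One rank-sum comparison of Atom% between two time points."""

    category: str
    isotope: str
    timepoint_a_h: float
    timepoint_b_h: float
    statistic: float  # Mann-Whitney U of sample b vs sample a
    raw_p: float
    adjusted_p: float
    direction: str  # increase / decrease / none, b relative to a
    n_a: int
    n_b: int


def _atom_pcts(measurements, category, isotope, t):
    return np.array(
        [
            m.atom_pct(isotope)
            for m in measurements
            if m.category == category
            and m.is_valid(isotope)
            and m.timepoint_h == t
        ]
    )


def compare_timepoints(
    measurements: list[RoiMeasurement],
    category: str,
    isotope: str,
    t_a: float,
    t_b: float,
) -> TimepointComparison:
    """Two-sided rank-sum comparison of a category's Atom% at two time points.

    The direction is the sign of the median difference (b minus a).  The
    adjusted p equals the raw p until the comparison is pooled with others in
    :func:`bh_adjust`.
    """
    a = _atom_pcts(measurements, category, isotope, t_a)
    b = _atom_pcts(measurements, category, isotope, t_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"need >= 3 valid ROIs per time point for {category}/{isotope}; "
            f"got {len(a)} at t={t_a} and {len(b)} at t={t_b}"
        )
    u = stats.mannwhitneyu(b, a, alternative="two-sided")
    med_diff = float(np.median(b) - np.median(a))
    direction = "increase" if med_diff > 0 else "decrease" if med_diff < 0 else "none"
    return TimepointComparison(
        category=category,
        isotope=isotope,
        timepoint_a_h=t_a,
        timepoint_b_h=t_b,
        statistic=float(u.statistic),
        raw_p=float(u.pvalue),
        adjusted_p=float(u.pvalue),
        direction=direction,
        n_a=len(a),
        n_b=len(b),
    )


def bh_adjust(comparisons: list[TimepointComparison]) -> list[TimepointComparison]:
    """Benjamini-Hochberg adjustment across all comparisons of one run.

    Mutates ``adjusted_p`` in place and returns the list.
    """
    if not comparisons:
        return comparisons
    raw = [c.raw_p for c in comparisons]
    adj = multipletests(raw, method="fdr_bh")[1]
    for c, p in zip(comparisons, adj):
        c.adjusted_p = float(max(p, c.raw_p))
    return comparisons


def compare_many(
    measurements: list[RoiMeasurement],
    categories: tuple[str, ...],
    isotopes: tuple[str, ...],
    timepoint_pairs: list[tuple[float, float]],
) -> list[TimepointComparison]:
    """All category x isotope x pair comparisons, BH-adjusted jointly."""
    comps = [
        compare_timepoints(measurements, cat, iso, t_a, t_b)
        for cat in categories
        for iso in isotopes
        for (t_a, t_b) in timepoint_pairs
    ]
    return bh_adjust(comps)


def translocation_table(
    comparisons: list[TimepointComparison],
    alpha: float = DEFAULT_ALPHA,
    host_categories: tuple[str, ...] = HOST_CATEGORIES,
    symbiont_category: str = SYMBIONT_CATEGORY,
) -> dict:
    """Summarise pulse-end vs chase-end comparisons into a direction table.

    Returns ``{"rows": [...], "signature": {isotope: bool}}``.  The
    signature for an isotope is true when the symbiont category increases
    significantly (BH-adjusted p < alpha) while no host category also
    increases significantly — a concurrent host increase makes the symbiont
    gain ambiguous (it could come from continued uptake rather than
    translocation).
    """
    rows = [
        {
            "category": c.category,
            "isotope": c.isotope,
            "direction": c.direction,
            "adjusted_p": c.adjusted_p,
            "significant": c.adjusted_p < alpha,
        }
        for c in comparisons
    ]
    signature: dict[str, bool] = {}
    for iso in sorted({c.isotope for c in comparisons}):
        sym_up = any(
            c.isotope == iso
            and c.category == symbiont_category
            and c.direction == "increase"
            and c.adjusted_p < alpha
            for c in comparisons
        )
        host_up = any(
            c.isotope == iso
            and c.category in host_categories
            and c.direction == "increase"
            and c.adjusted_p < alpha
            for c in comparisons
        )
        signature[iso] = bool(sym_up and not host_up)
    return {"rows": rows, "signature": signature}
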