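"""Bulk-tissue tracer mathematics and pulse-phase statistics.

Implements the standard stable-isotope bookkeeping for pulse-chase bulk data:
delta-notation relative to international standards (VPDB for carbon,
atmospheric N2 for nitrogen), tracer excess over unlabelled controls
(Δδ), atom fractions from δ values, incorporation rates normalised per mole
of tissue element, ordinary-least-squares regression of enrichment on time
over the pulse window, and an interaction-term F test ("univariate ANOVA" on
regression coefficients) to compare incorporation rates between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import R_AIR_N, R_VPDB_C

#: Default pulse window in hours (the labelled-substrate exposure).
DEFAULT_PULSE_WINDOW_H = (0.0, 3.0)

R_STANDARD = {"C": R_VPDB_C, "N": R_AIR_N}


@dataclass
class PulseRegression:
    """OLS fit of a response against time over the pulse window."""

    group: str
    response: str
    slope_per_h: float
    slope_se: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (
            self.slope_per_h - tcrit * self.slope_se,
            self.slope_per_h + tcrit * self.slope_se,
        )


@dataclass
class SlopeComparison:
    """Interaction F test of slope difference between two groups."""

    slope_difference: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


def delta_value(r: float, r_standard: float):
    """Isotope ratio → δ in per mil: ``(r/r_standard - 1) * 1000``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("isotope ratio must be nonnegative")
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    d = (r / r_standard - 1.0) * 1000.0
    return float(d) if d.ndim == 0 else d


def delta_excess(delta_sample: float, control_mean_delta: float):
    """Δδ: per-mil excess of a sample over the unlabelled-control mean."""
    d = np.asarray(delta_sample, dtype=float) - control_mean_delta
    return float(d) if d.ndim == 0 else d


def atom_fraction_from_delta(delta_permil: float, r_standard: float):
    """Heavy-isotope atom fraction implied by a δ value.

    ``r = r_standard (1 + δ/1000)``; ``F = r/(1+r)``.
    """
    d = np.asarray(delta_permil, dtype=float)
    if np.any(d <= -1000):
        raise ValueError("delta must exceed -1000 permil")
    r = r_standard * (1.0 + d / 1000.0)
    f = r / (1.0 + r)
    return float(f) if f.ndim == 0 else f


def tracer_incorporation_rate(
    f_sample: float, f_control_mean: float, duration_h: float
):
    """Tracer incorporation in μmol tracer element per mmol tissue element per hour.

    ``rate = (F_sample - F_control) * 1000 / duration``: the atom-fraction
    excess is mol tracer per mol of the tissue element, and the factor 1000
    rescales mol/mol/h to μmol/mmol/h.  A negative excess yields a negative
    rate (reported, not clipped).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rate = (np.asarray(f_sample, dtype=float) - f_control_mean) * 1000.0 / duration_h
    return float(rate) if rate.ndim == 0 else rate


def pulse_frame(
    samples: pd.DataFrame,
    isotope: str,
    response: str = "delta_excess",
    window_h: tuple[float, float] = DEFAULT_PULSE_WINDOW_H,
) -> pd.DataFrame:
    """Extract (timepoint_h, response) pairs for labelled pulse-phase samples.

    Δδ is computed relative to the pooled unlabelled-control mean of the
    table.  ``response`` is ``"delta_excess"`` (‰) or ``"tracer_amount"``
    (atom-fraction excess × 1000, i.e. mmol tracer per mol tissue element).
    """
    col = "delta_c_permil" if isotope == "C" else "delta_n_permil"
    controls = samples[samples["treatment"] == "control"]
    if controls.empty:
        raise ValueError("no unlabelled controls in the sample table")
    control_mean = float(controls[col].mean())
    lab = samples[
        (samples["treatment"] != "control")
        & (samples["timepoint_h"] >= window_h[0])
        & (samples["timepoint_h"] <= window_h[1])
    ]
    dd = delta_excess(lab[col].to_numpy(), control_mean)
    if response == "delta_excess":
        y = dd
    elif response == "tracer_amount":
        r_std = R_STANDARD[isotope]
        f = atom_fraction_from_delta(control_mean + dd, r_std)
        f0 = atom_fraction_from_delta(control_mean, r_std)
        y = (f - f0) * 1000.0
    else:
        raise ValueError(f"unknown response {response!r}")
    return pd.DataFrame({"timepoint_h": lab["timepoint_h"].to_numpy(), "y": y})


def fit_pulse_regression(
    samples: pd.DataFrame,
    isotope: str,
    response: str = "delta_excess",
    window_h: tuple[float, float] = DEFAULT_PULSE_WINDOW_H,
    group: str = "",
) -> PulseRegression:
    """OLS regression of pulse-phase enrichment on time.

    Requires at least three labelled samples in the window and nonzero time
    variance.  The p value is the two-sided test of slope = 0.
    """
    pf = pulse_frame(samples, isotope, response, window_h)
    t, y = pf["timepoint_h"].to_numpy(), pf["y"].to_numpy()
    if len(t) < 3:
        raise ValueError(f"need >= 3 pulse-phase samples, got {len(t)}")
    if np.ptp(t) == 0:
        raise ValueError("no time variance in the pulse window")
    res = stats.linregress(t, y)
    return PulseRegression(
        group=group,
        response=response,
        slope_per_h=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(t),
    )


def compare_slopes(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    isotope: str,
    response: str = "delta_excess",
    window_h: tuple[float, float] = DEFAULT_PULSE_WINDOW_H,
) -> SlopeComparison:
    """Compare pulse slopes of two groups by the time x group interaction.

    Fits the combined model ``y ~ time + group + time:group`` by OLS and
    returns the F test (df1 = 1) of the interaction coefficient — the
    difference in slopes (group b minus group a).  Label-swapping the groups
    flips the difference's sign but not the p value.
    """
    frames = []
    for code, df in ((0.0, group_a), (1.0, group_b)):
        pf = pulse_frame(df, isotope, response, window_h)
        if len(pf) < 3 or np.ptp(pf["timepoint_h"].to_numpy()) == 0:
            raise ValueError("each group needs >= 3 pulse samples with time variance")
        pf = pf.assign(g=code)
        frames.append(pf)
    d = pd.concat(frames, ignore_index=True)
    t, g, y = d["timepoint_h"].to_numpy(), d["g"].to_numpy(), d["y"].to_numpy()
    x = np.column_stack([np.ones_like(t), t, g, t * g])
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df_den = len(y) - x.shape[1]
    mse = float(resid @ resid) / df_den
    xtx_inv = np.linalg.inv(x.T @ x)
    se_int = float(np.sqrt(mse * xtx_inv[3, 3])) if mse > 0 else 0.0
    slope_diff = float(beta[3])
    if se_int == 0.0:
        f_stat = float("inf") if abs(slope_diff) > 1e-12 else 0.0
        p = 0.0 if abs(slope_diff) > 1e-12 else 1.0
    else:
        f_stat = (slope_diff / se_int) ** 2
        p = float(stats.f.sf(f_stat, 1, df_den))
    return SlopeComparison(
        slope_difference=slope_diff,
        f_statistic=f_stat,
        df_num=1,
        df_den=df_den,
        p_value=p,
    )
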