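"""Small closed-form estimators: nucleosome repeat length by
regression-extrapolation, H1 stoichiometry from chromatographic peak areas,
qRT-PCR relative expression, qChIP relative enrichment, percent methylated
CpG.

NRL estimation follows the classic MNase time-course procedure: within each
digestion timepoint, polynucleosome band size (bp) is regressed on band
number, the slope being the apparent repeat length at that time (trimming by
exonucleolytic nibbling moves the intercept, not the slope); the apparent
lengths are then regressed on digestion time and extrapolated to time zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def nrl_at_timepoint(band_n, size_bp) -> float:
    """Apparent NRL at one timepoint: OLS slope of band size on band number."""
    band_n = np.asarray(band_n, dtype=float)
    size_bp = np.asarray(size_bp, dtype=float)
    if band_n.size < 2:
        raise ValueError("need >= 2 bands")
    if np.ptp(band_n) == 0:
        raise ValueError("all band numbers identical; slope undefined")
    return float(stats.linregress(band_n, size_bp).slope)


def nrl_extrapolate(times, slopes) -> tuple[float, float]:
    """OLS of apparent NRL on digestion time, extrapolated to time zero.

    Returns (NRL0, standard error of the intercept).
    """
    times = np.asarray(times, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if times.size < 2:
        raise ValueError("need >= 2 timepoints; with one timepoint use "
                         "nrl_at_timepoint directly")
    fit = stats.linregress(times, slopes)
    return float(fit.intercept), float(fit.intercept_stderr)


@dataclass(frozen=True)
class NRLEstimate:
    nrl0: float
    stderr: float
    per_timepoint: pd.DataFrame  # columns time_min, apparent_nrl


def estimate_nrl(observations: pd.DataFrame) -> NRLEstimate:
    """Full estimator on a ladder table (time_min, band_n, size_bp)."""
    rows = []
    for t, sub in observations.groupby("time_min"):
        rows.append((float(t), nrl_at_timepoint(sub["band_n"], sub["size_bp"])))
    per_t = pd.DataFrame(rows, columns=["time_min", "apparent_nrl"])
    nrl0, se = nrl_extrapolate(per_t["time_min"], per_t["apparent_nrl"])
    return NRLEstimate(nrl0, se, per_t)


def h1_per_nucleosome(h1_peaks: list[tuple[float, int]],
                      h2b_area: float, h2b_bonds: int) -> float:
    """H1 per nucleosome from A214 peak areas.

    Each peak area is first adjusted by its peptide-bond count (A214 absorbs
    per bond); the summed adjusted H1 signal is divided by half the adjusted
    H2B signal (a nucleosome carries two H2B copies).
    """
    if h2b_area <= 0:
        raise ValueError("H2B peak area must be > 0")
    for area, bonds in h1_peaks:
        if area < 0 or bonds < 1:
            raise ValueError("areas must be >= 0 and bond counts >= 1")
    h1_sum = sum(area / bonds for area, bonds in h1_peaks)
    return h1_sum / ((h2b_area / h2b_bonds) / 2.0)


def relative_expression(target_rt_plus: float, target_rt_minus: float,
                        ref_rt_plus: float, ref_rt_minus: float
                        ) -> tuple[float, bool]:
    """Mock-RT-subtracted target signal over the housekeeping reference.

    Signals are linear quantities.  A negative adjusted target is clamped to
    zero; the second return value flags the clamp.
    """
    ref = ref_rt_plus - ref_rt_minus
    if ref <= 0:
        raise ValueError("reference adjusted signal must be > 0")
    target = target_rt_plus - target_rt_minus
    if target < 0:
        return 0.0, True
    return target / ref, False


def qchip_relative_enrichment(chip_signal: float, igg_signal: float) -> float:
    """ChIP signal normalized over the IgG mock control."""
    if igg_signal <= 0:
        raise ValueError("IgG signal must be > 0")
    return chip_signal / igg_signal


def percent_methylated(calls) -> float:
    """Percent methylated CpG over a clone x CpG call matrix.

    Calls are 1 (methylated), 0 (unmethylated) or NaN (not scored; excluded
    from the denominator).
    """
    m = np.asarray(calls, dtype=float)
    if m.size == 0:
        raise ValueError("empty call matrix")
    scored = ~np.isnan(m)
    if not scored.any():
        raise ValueError("no scored calls")
    return float(100.0 * np.nansum(m) / scored.sum())
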