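"""Genome-wide and per-chromosome Pearson correlation between signal tracks.

Tracks are rebinned to a common window (1 kb by default) by summation, then
correlated over all windows pooled across chromosomes (genome scope) or per
chromosome.  Windows where either track is missing (NaN, e.g. all-N GC
windows) are dropped pairwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import SignalTrack, _check_compatible, rebin


@dataclass(frozen=True)
class CorrelationResult:
    label_a: str
    label_b: str
    scope: str  # "genome" or a chromosome name
    n: int
    r: float
    p: float


def _pearson(x: np.ndarray, y: np.ndarray, labels, scope: str,
             drop_zero: bool) -> CorrelationResult:
    ok = ~(np.isnan(x) | np.isnan(y))
    if drop_zero:
        ok &= (x != 0) | (y != 0)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"fewer than 3 paired windows in scope {scope}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(*labels, scope, int(x.size),
                                 float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(*labels, scope, int(x.size), float(r), float(p))


def genome_correlation(a: SignalTrack, b: SignalTrack, W: int = 1000,
                       labels: tuple[str, str] = ("a", "b"),
                       drop_zero: bool = False) -> CorrelationResult:
    """Pooled Pearson R over all W-bp windows of the genome.

    Both tracks are rebinned to W by summation first; p is the usual
    two-sided t-transform p-value.  Zero-variance input yields R = NaN
    (undefined), not an error.
    """
    _check_compatible(a, b)
    ra, rb = rebin(a, W), rebin(b, W)
    x = np.concatenate([ra.data[c] for c in ra.chroms()])
    y = np.concatenate([rb.data[c] for c in rb.chroms()])
    return _pearson(x, y, labels, "genome", drop_zero)


def per_chromosome_correlation(a: SignalTrack, b: SignalTrack, W: int = 1000,
                               labels: tuple[str, str] = ("a", "b"),
                               drop_zero: bool = False
                               ) -> list[CorrelationResult]:
    _check_compatible(a, b)
    ra, rb = rebin(a, W), rebin(b, W)
    return [_pearson(ra.data[c], rb.data[c], labels, c, drop_zero)
            for c in ra.chroms()]
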