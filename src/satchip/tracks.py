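"""Windowed signal tracks: read counting, per-10M normalization, IP-IN
subtraction, GC%, rebinning and region summaries.

A :class:`SignalTrack` holds one value per fixed-width window tiling each
chromosome ([0, L) in steps of `window`; the last window may be partial).
Reads are counted at their fragment midpoint, which is unbiased for the
simulator's known fragment length and keeps read-count conservation exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

RAW = "raw"
PER10M = "per10M"
IPIN = "IP-IN"


@dataclass
class SignalTrack:
    data: dict[str, np.ndarray]
    window: int
    norm: str
    chrom_sizes: dict[str, int]
    total_reads: int | None = None

    def __post_init__(self):
        for chrom, values in self.data.items():
            expect = math.ceil(self.chrom_sizes[chrom] / self.window)
            if len(values) != expect:
                raise ValueError(
                    f"{chrom}: {len(values)} windows, expected {expect}")

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.data.values()))

    def chroms(self) -> list[str]:
        return sorted(self.data)


def _check_compatible(a: SignalTrack, b: SignalTrack) -> None:
    if a.window != b.window:
        raise ValueError(f"window sizes differ: {a.window} vs {b.window}")
    if set(a.data) != set(b.data):
        raise ValueError("chromosome sets differ")


def window_counts(read_intervals: pd.DataFrame, chrom_sizes: dict[str, int],
                  w: int = 100) -> SignalTrack:
    """Count fragment midpoints per window.

    `read_intervals` needs columns chrom/start/end (BED-like, 0-based
    half-open); each record contributes 1 to the window containing
    (start + end) // 2.
    """
    data = {c: np.zeros(math.ceil(L / w)) for c, L in chrom_sizes.items()}
    n = 0
    for chrom, sub in read_intervals.groupby("chrom", observed=True):
        chrom = str(chrom)
        if chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {chrom}")
        L = chrom_sizes[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = np.flatnonzero((starts < 0) | (ends > L))
        if bad.size:
            rec = sub.iloc[bad[0]]
            raise ValueError(
                f"read {rec.get('name', sub.index[bad[0]])} "
                f"[{rec['start']},{rec['end']}) outside {chrom} of length {L}")
        mids = (starts + ends) // 2
        counts = np.bincount(mids // w, minlength=data[chrom].size)
        data[chrom] += counts
        n += len(sub)
    return SignalTrack(data, w, RAW, dict(chrom_sizes), total_reads=n)


def normalize_per_10M(track: SignalTrack, total_mapped: int | None = None
                      ) -> SignalTrack:
    """Scale every window by 1e7 / total mapped reads of the library."""
    if total_mapped is None:
        total_mapped = track.total_reads
    if not total_mapped or total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    factor = 1e7 / total_mapped
    return replace(track,
                   data={c: v * factor for c, v in track.data.items()},
                   norm=PER10M)


def ipin(chip: SignalTrack, input_: SignalTrack) -> SignalTrack:
    """ChIP minus input, both already normalized per 10 million reads."""
    _check_compatible(chip, input_)
    if chip.norm != PER10M or input_.norm != PER10M:
        raise ValueError("ipin expects per-10M-normalized tracks")
    return replace(chip,
                   data={c: chip.data[c] - input_.data[c] for c in chip.data},
                   norm=IPIN, total_reads=None)


def gc_track(genome: dict[str, str], w: int = 100) -> SignalTrack:
    """Per-window GC percent, 100*(G+C)/(A+C+G+T); all-N windows are NaN."""
    data = {}
    sizes = {}
    for chrom, seq in genome.items():
        codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        gc = (codes == ord("G")) | (codes == ord("C"))
        acgt = gc | (codes == ord("A")) | (codes == ord("T"))
        nwin = math.ceil(len(seq) / w)
        pad = nwin * w - len(seq)
        gcs = np.pad(gc.astype(float), (0, pad)).reshape(nwin, w).sum(axis=1)
        den = np.pad(acgt.astype(float), (0, pad)).reshape(nwin, w).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, 100.0 * gcs / den, np.nan)
        data[chrom] = vals
        sizes[chrom] = len(seq)
    return SignalTrack(data, w, "GC%", sizes)


def rebin(track: SignalTrack, W: int) -> SignalTrack:
    """Sum consecutive windows into W-bp bins; W must be a multiple of the
    current window.  Preserves the track total (NaN propagates)."""
    w = track.window
    if W % w:
        raise ValueError(f"target window {W} is not a multiple of {w}")
    k = W // w
    data = {}
    for chrom, v in track.data.items():
        nout = math.ceil(v.size / k)
        padded = np.pad(v, (0, nout * k - v.size))
        data[chrom] = padded.reshape(nout, k).sum(axis=1)
    return replace(track, data=data, window=W)


def region_signal(track: SignalTrack, regions: list[tuple[str, int, int]]
                  ) -> np.ndarray:
    """Mean window value over each region, weighted by overlap length.

    Regions are (chrom, start, end), 0-based half-open; windows with NaN
    values are excluded from the mean.
    """
    w = track.window
    out = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        L = track.chrom_sizes[chrom]
        if start < 0 or end > L or end <= start:
            raise ValueError(f"region {chrom}:[{start},{end}) out of bounds")
        values = track.data[chrom]
        first, last = start // w, (end - 1) // w
        idx = np.arange(first, last + 1)
        win_starts = idx * w
        win_ends = np.minimum(win_starts + w, L)
        overlap = (np.minimum(win_ends, end)
                   - np.maximum(win_starts, start)).astype(float)
        vals = values[idx]
        ok = ~np.isnan(vals)
        denom = overlap[ok].sum()
        out[i] = np.nan if denom == 0 else float(
            (vals[ok] * overlap[ok]).sum() / denom)
    return out
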