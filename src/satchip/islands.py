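"""Window-cluster island calling and region-set operations.

The caller follows the SICER scheme: a window of the raw ChIP track is
*eligible* when its read count is improbably high under a uniform Poisson
background (upper-tail p <= p0 at rate lambda = total_reads * w /
(effective_fraction * genome_length)); eligible windows separated by at most
`gap` bp of ineligible space merge into islands scored by the summed
-ln(Poisson p) of their eligible windows.  Two filters follow: a score
threshold calibrated by seeded Monte Carlo so the expected number of
background islands above it is at most the E-value, and an empirical FDR
against islands called identically on the input library (Benjamini-Hochberg
on the empirical upper-tail p of each ChIP island score in the input score
distribution).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import RAW, SignalTrack

ISLAND_COLUMNS = ["chrom", "start", "end", "score", "n_eligible", "q"]


@dataclass(frozen=True)
class IslandParams:
    window: int = 200
    gap: int = 600
    e_value: float = 1000.0
    effective_fraction: float = 0.8
    q_threshold: float = 0.001
    p0: float = 0.2  # window-eligibility Poisson p threshold

    def __post_init__(self):
        if self.gap % self.window or not (0 <= self.gap <= 3 * self.window):
            raise ValueError("gap must be one of {0, w, 2w, 3w}")
        if self.e_value <= 0:
            raise ValueError("E-value must be > 0")
        if not (0 < self.effective_fraction <= 1):
            raise ValueError("effective genome fraction must be in (0, 1]")
        if not (0 < self.q_threshold <= 1) or not (0 < self.p0 <= 1):
            raise ValueError("thresholds must be in (0, 1]")


def background_rate(total_reads: int, params: IslandParams,
                    genome_length: int) -> float:
    """Expected reads per window under the uniform background model."""
    lam = total_reads * params.window / (params.effective_fraction
                                         * genome_length)
    if lam <= 0:
        raise ValueError("background rate is zero; empty library?")
    return lam


def _islands_one_chrom(counts: np.ndarray, lam: float, params: IslandParams,
                       chrom: str, chrom_len: int) -> list[tuple]:
    w = params.window
    max_gap_windows = params.gap // w
    # upper-tail Poisson p for each window count; count 0 is never eligible
    pvals = stats.poisson.sf(counts - 1, lam)
    eligible = np.flatnonzero((counts > 0) & (pvals <= params.p0))
    out = []
    if eligible.size == 0:
        return out
    nll = -np.log(pvals)
    run = [eligible[0]]
    for i in eligible[1:]:
        if i - run[-1] - 1 <= max_gap_windows:
            run.append(i)
        else:
            out.append(run)
            run = [i]
    out.append(run)
    islands = []
    for run in out:
        start = run[0] * w
        end = min((run[-1] + 1) * w, chrom_len)
        score = float(nll[run].sum())
        islands.append((chrom, start, end, score, len(run)))
    return islands


def raw_islands(chip: SignalTrack, params: IslandParams,
                total_reads: int | None = None) -> pd.DataFrame:
    """Eligible-window clusters with scores, before E-value and FDR filters."""
    if chip.norm != RAW:
        raise ValueError("island calling runs on raw count tracks")
    if chip.window != params.window:
        raise ValueError(f"track window {chip.window} != params.window "
                         f"{params.window}")
    genome_length = sum(chip.chrom_sizes.values())
    if total_reads is None:
        total_reads = int(chip.total())
    lam = background_rate(total_reads, params, genome_length)
    rows = []
    for chrom in chip.chroms():
        rows.extend(_islands_one_chrom(chip.data[chrom], lam, params, chrom,
                                       chip.chrom_sizes[chrom]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score",
                                     "n_eligible"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def mc_score_threshold(total_reads: int, genome_length: int,
                       params: IslandParams, seed: int,
                       n_rep: int = 5) -> float:
    """Smallest island-score threshold whose expected background island count
    is <= the E-value, estimated by simulating `n_rep` uniform libraries over
    the effective genome and calling islands identically."""
    eff_len = int(round(params.effective_fraction * genome_length))
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_rep):
        mids = rng.integers(0, eff_len, size=total_reads)
        counts = np.bincount(mids // params.window,
                             minlength=math.ceil(eff_len / params.window))
        track = SignalTrack({"bg": counts.astype(float)}, params.window, RAW,
                            {"bg": eff_len}, total_reads=total_reads)
        # same lambda as the real call: n * w / (eff_fraction * G) with the
        # background genome being exactly the effective genome
        bg_params = IslandParams(params.window, params.gap, params.e_value,
                                 1.0, params.q_threshold, params.p0)
        df = raw_islands(track, bg_params, total_reads=total_reads)
        scores.extend(df["score"].tolist())
    if not scores:
        return 0.0
    scores = np.sort(np.asarray(scores))[::-1]
    # expected count above threshold s: |{scores >= s}| / n_rep
    if scores.size / n_rep <= params.e_value:
        return 0.0
    # keep the e_value * n_rep highest background scores below threshold
    k = int(math.floor(params.e_value * n_rep))
    return float(np.nextafter(scores[k], np.inf))


def empirical_fdr(chip_scores: np.ndarray, null_scores: np.ndarray
                  ) -> np.ndarray:
    """Benjamini-Hochberg q-values from the empirical upper-tail p of each
    score in the null score distribution."""
    chip_scores = np.asarray(chip_scores, dtype=float)
    if chip_scores.size == 0:
        return chip_scores
    null_sorted = np.sort(np.asarray(null_scores, dtype=float))
    n_null = null_sorted.size
    if n_null == 0:
        pvals = np.zeros_like(chip_scores)
    else:
        ge = n_null - np.searchsorted(null_sorted, chip_scores, side="left")
        pvals = ge / n_null
    m = chip_scores.size
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def call_islands(chip: SignalTrack, input_: SignalTrack, params: IslandParams,
                 seed: int) -> pd.DataFrame:
    """Full island call: cluster, E-value score threshold (Monte Carlo),
    empirical FDR vs the input library; keeps q <= q_threshold."""
    genome_length = sum(chip.chrom_sizes.values())
    chip_islands = raw_islands(chip, params)
    if not len(chip_islands):
        chip_islands["q"] = pd.Series(dtype=float)
        return chip_islands
    s_e = mc_score_threshold(int(chip.total()), genome_length, params, seed)
    chip_islands = chip_islands[chip_islands["score"] >= s_e].reset_index(drop=True)
    input_islands = raw_islands(input_, params)
    q = empirical_fdr(chip_islands["score"].to_numpy(),
                      input_islands["score"].to_numpy())
    chip_islands = chip_islands.assign(q=q)
    return chip_islands[chip_islands["q"] <= params.q_threshold].reset_index(
        drop=True)


def optimize_gap(chip: SignalTrack, input_: SignalTrack, params: IslandParams,
                 seed: int, gaps: tuple[int, ...] | None = None
                 ) -> tuple[int, pd.DataFrame]:
    """Call islands at each candidate gap and keep the gap maximizing the
    aggregate score of significant islands; ties go to the smallest gap."""
    w = params.window
    if gaps is None:
        gaps = (0, w, 2 * w, 3 * w)
    rows = []
    best_gap, best_score = None, -np.inf
    for g in sorted(gaps):
        p = IslandParams(w, g, params.e_value, params.effective_fraction,
                         params.q_threshold, params.p0)
        df = call_islands(chip, input_, p, seed)
        agg = float(df["score"].sum())
        rows.append({"gap": g, "n_islands": len(df), "aggregate_score": agg})
        if agg > best_score:
            best_gap, best_score = g, agg
    return best_gap, pd.DataFrame(rows)


def _as_intervals(df: pd.DataFrame):
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def common_unique(a: pd.DataFrame, b: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Common = intersected spans of overlapping (>= 1 bp) island pairs;
    unique = islands of one set with zero overlap with the other."""
    cols = ["chrom", "start", "end"]
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in _as_intervals(b):
        b_by_chrom.setdefault(chrom, []).append((s, e))
    a_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in _as_intervals(a):
        a_by_chrom.setdefault(chrom, []).append((s, e))

    common_rows, a_unique, b_unique = [], [], []
    for chrom, s, e in _as_intervals(a):
        overlaps = [(max(s, bs), min(e, be))
                    for bs, be in b_by_chrom.get(chrom, [])
                    if bs < e and be > s]
        if overlaps:
            common_rows.extend((chrom, lo, hi) for lo, hi in overlaps)
        else:
            a_unique.append((chrom, s, e))
    for chrom, s, e in _as_intervals(b):
        if not any(as_ < e and ae > s
                   for as_, ae in a_by_chrom.get(chrom, [])):
            b_unique.append((chrom, s, e))
    mk = lambda rows: pd.DataFrame(rows, columns=cols).sort_values(
        cols, ignore_index=True)
    return mk(common_rows), mk(a_unique), mk(b_unique)


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame,
                     proximal_flank: int = 5000) -> pd.DataFrame:
    """Classify each region by its midpoint: inside a gene span (TSS-TTS) ->
    'gene'; within proximal_flank of a gene boundary -> 'proximal'; else
    'distal'.  Returns per-category counts and fractions (summing to 1)."""
    cats = ["gene", "proximal", "distal"]
    if not len(regions):
        return pd.DataFrame({"category": cats, "count": 0, "fraction": np.nan})
    spans: dict[str, list[tuple[int, int]]] = {}
    for row in genes.itertuples():
        lo, hi = sorted((row.tss, row.tts))
        spans.setdefault(row.chrom, []).append((lo, hi + 1))
    counts = dict.fromkeys(cats, 0)
    for row in regions.itertuples():
        mid = (int(row.start) + int(row.end)) // 2
        chrom_spans = spans.get(row.chrom, [])
        if any(lo <= mid < hi for lo, hi in chrom_spans):
            counts["gene"] += 1
        elif any(lo - proximal_flank <= mid < hi + proximal_flank
                 for lo, hi in chrom_spans):
            counts["proximal"] += 1
        else:
            counts["distal"] += 1
    total = sum(counts.values())
    return pd.DataFrame({"category": cats,
                         "count": [counts[c] for c in cats],
                         "fraction": [counts[c] / total for c in cats]})


def top_fraction_regions(islands: pd.DataFrame, fraction: float = 0.10
                         ) -> pd.DataFrame:
    """Top ceil(fraction * N) islands by score; ties at the cut broken by
    genomic order (chrom, start)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not len(islands):
        return islands.copy()
    k = math.ceil(fraction * len(islands))
    ranked = islands.sort_values(["score", "chrom", "start"],
                                 ascending=[False, True, True], kind="stable")
    return ranked.head(k).reset_index(drop=True)


def islands_to_bed(islands: pd.DataFrame) -> pd.DataFrame:
    """BED6 frame: name = score rank (1 = best), score = island score x 10
    rounded, strand '.'"""
    ranked = islands.sort_values(["score", "chrom", "start"],
                                 ascending=[False, True, True], kind="stable")
    ranked = ranked.reset_index(drop=True)
    bed = pd.DataFrame({
        "chrom": ranked["chrom"],
        "start": ranked["start"].astype(int),
        "end": ranked["end"].astype(int),
        "name": [f"island_{i + 1}" for i in range(len(ranked))],
        "score": (ranked["score"] * 10).round().astype(int),
        "strand": ".",
    })
    return bed.sort_values(["chrom", "start"], ignore_index=True)
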