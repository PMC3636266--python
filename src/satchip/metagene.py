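"""Anchor-centred average profiles and gene partitions.

Genes are carried as a table (gene_id, chrom, strand, tss, tts, expression);
TSS/TTS are genome coordinates, so on the minus strand TSS > TTS.  Profiles
are averaged per gene group over fixed-bp bins around the anchor, with minus
strand genes mirrored so every profile reads 5' to 3'.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .tracks import SignalTrack, region_signal

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts", "expression"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    if len(genes) and not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (genes["tss"] == genes["tts"]).any():
        raise ValueError("TSS must differ from TTS")
    bad = genes[(genes["strand"] == "-") & (genes["tss"] <= genes["tts"])]
    if len(bad):
        raise ValueError(f"minus-strand genes with TSS <= TTS: "
                         f"{bad['gene_id'].tolist()[:5]}")
    return genes


@dataclass(frozen=True)
class GeneGrouping:
    """A labelled partition of the gene set: every gene in exactly one group."""

    scheme: str
    labels: dict[str, str]  # gene_id -> group label
    group_order: tuple[str, ...]

    def genes_in(self, group: str) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == group]


def _ranked_split(ordered_ids: list[str], k: int, labels: list[str]
                  ) -> dict[str, str]:
    """Split an ordered id list into k groups with ceiling-allocated bounds
    (group sizes differ by at most 1, earlier groups take the remainder)."""
    n = len(ordered_ids)
    out = {}
    prev = 0
    for i in range(k):
        hi = math.ceil((i + 1) * n / k)
        for g in ordered_ids[prev:hi]:
            out[g] = labels[i]
        prev = hi
    return out


def partition_by_expression(genes: pd.DataFrame,
                            scheme: str = "deciles_extremes") -> GeneGrouping:
    """Partition genes by expression rank.

    ``deciles_extremes``: top 10% -> 'top10', bottom 10% -> 'bottom10', the
    rest 'mid80' (profiles over *all* genes are requested separately at
    profile time).  ``quintiles``: five rank groups q1 (lowest) .. q5
    (highest).  Ties broken by stable gene-id order.
    """
    validate_gene_table(genes)
    if not len(genes):
        raise ValueError("empty gene table")
    asc = genes.sort_values(["expression", "gene_id"],
                            kind="stable")["gene_id"].tolist()
    n = len(asc)
    if scheme == "deciles_extremes":
        if n < 10:
            raise ValueError("need >= 10 genes for decile extremes")
        k = math.ceil(0.1 * n)
        labels = {}
        for g in asc[:k]:
            labels[g] = "bottom10"
        for g in asc[-k:]:
            labels[g] = "top10"
        for g in asc[k:-k]:
            labels[g] = "mid80"
        return GeneGrouping("deciles_extremes", labels,
                            ("top10", "mid80", "bottom10"))
    if scheme == "quintiles":
        labels = _ranked_split(asc, 5, [f"q{i}" for i in range(1, 6)])
        return GeneGrouping("quintiles", labels, tuple(f"q{i}" for i in range(1, 6)))
    raise ValueError(f"unknown scheme {scheme!r}")


def partition_by_mark(genes: pd.DataFrame, mark_track: SignalTrack,
                      k: int = 5, tss_halfwidth: int = 2000) -> GeneGrouping:
    """Rank genes by mean mark signal over TSS +/- tss_halfwidth and split
    into k equal groups m1 (lowest) .. mk (highest)."""
    validate_gene_table(genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if not len(genes):
        raise ValueError("empty gene table")
    regions = []
    for row in genes.itertuples():
        L = mark_track.chrom_sizes[row.chrom]
        lo = max(0, row.tss - tss_halfwidth)
        hi = min(L, row.tss + tss_halfwidth)
        regions.append((row.chrom, lo, hi))
    scores = region_signal(mark_track, regions)
    order = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                          "score": scores})
    asc = order.sort_values(["score", "gene_id"],
                            kind="stable")["gene_id"].tolist()
    labels = _ranked_split(asc, k, [f"m{i}" for i in range(1, k + 1)])
    return GeneGrouping(f"mark_k{k}", labels,
                        tuple(f"m{i}" for i in range(1, k + 1)))


def _interval_trees(regions: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def classify_bivalent(genes: pd.DataFrame,
                      k4_regions: list[tuple[str, int, int]],
                      k27_regions: list[tuple[str, int, int]],
                      tss_halfwidth: int = 1000) -> GeneGrouping:
    """Four promoter classes by overlap of TSS +/- halfwidth (half-open) with
    H3K4me3 and H3K27me3 region sets: K4+K27+, K4+K27-, K4-K27+, K4-K27-."""
    validate_gene_table(genes)
    k4 = _interval_trees(k4_regions)
    k27 = _interval_trees(k27_regions)
    labels = {}
    for row in genes.itertuples():
        lo, hi = row.tss - tss_halfwidth, row.tss + tss_halfwidth
        has4 = row.chrom in k4 and bool(k4[row.chrom].overlap(lo, hi))
        has27 = row.chrom in k27 and bool(k27[row.chrom].overlap(lo, hi))
        labels[row.gene_id] = (f"K4{'+' if has4 else '-'}"
                               f"K27{'+' if has27 else '-'}")
    return GeneGrouping("bivalency", labels,
                        ("K4+K27+", "K4+K27-", "K4-K27+", "K4-K27-"))


def metagene_profile(track: SignalTrack, genes: pd.DataFrame,
                     grouping: GeneGrouping | None = None,
                     anchor: str = "TSS", flank: int = 5000,
                     bin: int = 100) -> pd.DataFrame:
    """Per-group mean signal in `bin`-bp offsets over anchor +/- flank.

    `bin` must equal the track window and `flank` a multiple of `bin`.  For
    minus-strand genes offsets are mirrored so they run 5' to 3'.  Offsets
    are labelled by bin start relative to the anchor (the bin [0, bin) starts
    at the anchor).  Bins falling off a chromosome end are excluded from that
    offset's mean.  Returns columns group, offset, mean, n_genes, n_obs.
    """
    if bin != track.window:
        raise ValueError("bin must equal the track window size")
    if flank % bin:
        raise ValueError("flank must be a multiple of bin")
    validate_gene_table(genes)
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    nbins = 2 * flank // bin
    rel_centers = -flank + bin * np.arange(nbins) + bin / 2.0
    offsets = (-flank + bin * np.arange(nbins)).astype(int)

    if grouping is None:
        grouping = GeneGrouping("all", {g: "all" for g in genes["gene_id"]},
                                ("all",))
    sums = {g: np.zeros(nbins) for g in grouping.group_order}
    counts = {g: np.zeros(nbins) for g in grouping.group_order}
    n_genes = {g: 0 for g in grouping.group_order}
    skipped = 0
    for row in genes.itertuples():
        group = grouping.labels.get(row.gene_id)
        if group is None or group not in sums:
            continue
        a = row.tss if anchor == "TSS" else row.tts
        L = track.chrom_sizes[row.chrom]
        if not (0 <= a < L):
            skipped += 1
            continue
        n_genes[group] += 1
        sign = 1.0 if row.strand == "+" else -1.0
        pos = a + sign * rel_centers
        idx = np.floor(pos / bin).astype(int)
        ok = (idx >= 0) & (idx < track.data[row.chrom].size)
        vals = track.data[row.chrom][idx[ok]]
        finite = ~np.isnan(vals)
        sel = np.flatnonzero(ok)[finite]
        sums[group][sel] += vals[finite]
        counts[group][sel] += 1
    rows = []
    for g in grouping.group_order:
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts[g] > 0, sums[g] / counts[g], np.nan)
        for j in range(nbins):
            rows.append((g, int(offsets[j]), means[j], n_genes[g],
                         int(counts[g][j])))
    out = pd.DataFrame(rows, columns=["group", "offset", "mean", "n_genes",
                                      "n_obs"])
    out.attrs["skipped_genes"] = skipped
    return out


def distal_decay(track: SignalTrack, genes: pd.DataFrame,
                 distances: list[int], exclusion_radius: int) -> pd.DataFrame:
    """Window values at signed offsets +/-D from each TSS, dropping points
    whose window lies within `exclusion_radius` of any *other* gene's TSS.

    Returns columns gene_id, offset, value (one row per retained point);
    distributions per offset feed box plots and medians.
    """
    validate_gene_table(genes)
    if any(d < 0 for d in distances):
        raise ValueError("distances must be >= 0")
    w = track.window
    tss_by_chrom: dict[str, np.ndarray] = {
        str(c): sub["tss"].to_numpy()
        for c, sub in genes.groupby("chrom", observed=True)}
    rows = []
    for row in genes.itertuples():
        others = tss_by_chrom[row.chrom]
        others = others[others != row.tss]
        offs = sorted({o for d in distances for o in (-d, d)})
        for off in offs:
            pos = row.tss + off
            idx = pos // w
            if not (0 <= pos < track.chrom_sizes[row.chrom]):
                continue
            win_lo, win_hi = idx * w, idx * w + w
            if others.size and np.any((others > win_lo - exclusion_radius)
                                      & (others < win_hi + exclusion_radius)):
                continue
            v = track.data[row.chrom][idx]
            if not np.isnan(v):
                rows.append((row.gene_id, off, float(v)))
    return pd.DataFrame(rows, columns=["gene_id", "offset", "value"])
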