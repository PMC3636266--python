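"""Read assignment to a repeat consensus library and enrichment statistics.

A read is assigned by seed matching: its first `seed_len` bases are compared
against every library entry at every offset, on both strands, allowing up to
`max_mismatch` mismatches.  Each consensus is doubled (two concatenated
copies) before scanning so seeds spanning tandem-monomer junctions are still
found — satellite reads frequently cross junctions.  Reads hitting several
entries are placed uniformly at random among them with a seeded generator,
mirroring random placement of multireads in short-read aligners.

Matching uses a pigeonhole index: the seed is split into max_mismatch + 1
parts, so any alignment with <= max_mismatch mismatches contains at least
one exactly matching part; candidate offsets come from exact k-mer lookup
and are then verified by Hamming count.  This is exact, not heuristic.

Enrichment per repeat class is the percent of library reads assigned to the
class; fold enrichment is ChIP percent over input percent, with a two-sided
Fisher exact test on the 2x2 read-count table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import revcomp


@dataclass(frozen=True)
class RepeatLibrary:
    """Entries of (name, class label, consensus sequence); names unique."""

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("repeat entry names must be unique")
        for name, _, seq in self.entries:
            if set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"entry {name} has characters outside ACGTN")

    @classmethod
    def from_fasta(cls, path) -> "RepeatLibrary":
        """Headers are 'name|class'; a header without '|' uses the name as
        its own class."""
        from .formats import read_fasta

        entries = []
        for header, seq in read_fasta(path).items():
            name, _, label = header.partition("|")
            entries.append((name, label or name, seq))
        return cls(tuple(entries))

    def name_to_class(self) -> dict[str, str]:
        return {name: label for name, label, _ in self.entries}

    def classes(self) -> list[str]:
        return sorted({label for _, label, _ in self.entries})


def _split_parts(seed_len: int, max_mismatch: int) -> list[tuple[int, int]]:
    k = max_mismatch + 1
    base, extra = divmod(seed_len, k)
    parts, off = [], 0
    for i in range(k):
        plen = base + (1 if i < extra else 0)
        parts.append((off, plen))
        off += plen
    return parts


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    """True if Hamming distance <= limit; N never counts as a match."""
    mism = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mism += 1
            if mism > limit:
                return False
    return True


class _SeedIndex:
    """Exact pigeonhole k-mer index over doubled entries, both strands."""

    def __init__(self, library: RepeatLibrary, seed_len: int, max_mismatch: int):
        if seed_len < max_mismatch + 1:
            raise ValueError("seed too short for the mismatch budget")
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self.parts = _split_parts(seed_len, max_mismatch)
        self.targets: list[tuple[int, str]] = []  # (entry index, sequence)
        self.index: list[dict[str, list[tuple[int, int]]]] = [
            {} for _ in self.parts]
        for ei, (name, _, seq) in enumerate(library.entries):
            seq = seq.upper()
            if len(seq) < seed_len:
                raise ValueError(
                    f"entry {name} shorter than the seed length {seed_len}")
            for target in (seq + seq, revcomp(seq + seq)):
                ti = len(self.targets)
                self.targets.append((ei, target))
                for pi, (poff, plen) in enumerate(self.parts):
                    idx = self.index[pi]
                    for p in range(len(target) - plen + 1):
                        kmer = target[p:p + plen]
                        if "N" in kmer:
                            continue
                        idx.setdefault(kmer, []).append((ti, p))

    def hit_entries(self, seed: str) -> set[int]:
        """Entry indices hit by this seed at any offset on either strand."""
        candidates: set[tuple[int, int]] = set()
        for pi, (poff, plen) in enumerate(self.parts):
            kmer = seed[poff:poff + plen]
            for ti, p in self.index[pi].get(kmer, ()):
                off = p - poff
                if off >= 0 and off + self.seed_len <= len(self.targets[ti][1]):
                    candidates.add((ti, off))
        hits: set[int] = set()
        for ti, off in candidates:
            ei, target = self.targets[ti]
            if ei in hits:
                continue
            if _hamming_leq(seed, target[off:off + self.seed_len],
                            self.max_mismatch):
                hits.add(ei)
        return hits


def assign_reads_to_repeats(reads, library: RepeatLibrary,
                            seed_len: int = 35, max_mismatch: int = 2,
                            rng_seed: int = 0) -> pd.DataFrame:
    """Assign each read to at most one repeat entry.

    `reads` is an iterable of (read id, sequence).  Returns a frame with
    columns read_id, repeat (entry name or NA), cls (class label or NA),
    n_hits (number of entries the seed matched).  Ties are broken uniformly
    at random among the hit entries with the seeded generator, so repeated
    runs with one seed are identical.
    """
    index = _SeedIndex(library, seed_len, max_mismatch)
    names = [name for name, _, _ in library.entries]
    classes = [label for _, label, _ in library.entries]
    rng = np.random.default_rng(rng_seed)
    rows = []
    for rid, seq in reads:
        if len(seq) < seed_len:
            raise ValueError(f"read {rid} shorter than seed length {seed_len}")
        hits = sorted(index.hit_entries(seq[:seed_len].upper()))
        if not hits:
            rows.append((rid, pd.NA, pd.NA, 0))
            continue
        chosen = hits[0] if len(hits) == 1 else hits[rng.integers(len(hits))]
        rows.append((rid, names[chosen], classes[chosen], len(hits)))
    return pd.DataFrame(rows, columns=["read_id", "repeat", "cls", "n_hits"])


def percent_mapped(assignment: pd.DataFrame, total_reads: int) -> dict[str, float]:
    """Percent of all library reads assigned to each class (entries sharing
    a class label aggregate)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    assigned = assignment.dropna(subset=["repeat"])
    if len(assigned) > total_reads:
        raise ValueError("more assigned reads than total_reads")
    counts = assigned.groupby("cls", observed=True).size()
    return {cls: 100.0 * n / total_reads for cls, n in counts.items()}


def fold_enrichment(chip_pct: float, input_pct: float) -> float:
    """ChIP percent over input percent; NaN (undefined) when the input
    percent is zero but the ChIP percent is not."""
    if input_pct == 0:
        return 0.0 if chip_pct == 0 else float("nan")
    return chip_pct / input_pct


def repeat_exact_test(chip_in: int, chip_total: int,
                      input_in: int, input_total: int) -> float:
    """Two-sided Fisher exact p on [[chip_in, chip_out], [input_in, input_out]].

    Computed by direct enumeration of the conditional hypergeometric
    distribution over the fixed margins: the p-value is the total probability
    of all tables at most as probable as the observed one (with the customary
    1e-7 relative tolerance for ties).  Vectorized in log space, so it is
    exact-to-double for library-scale counts where tabulated implementations
    get slow.
    """
    for v in (chip_in, chip_total, input_in, input_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if chip_in > chip_total or input_in > input_total:
        raise ValueError("in-class count exceeds library total")
    r1, r2 = chip_total, input_total
    c1 = chip_in + input_in
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    # log P(A = a | margins) up to the constant -log C(n, c1)
    logpmf = (_logcomb(r1, support) + _logcomb(r2, c1 - support)
              - _logcomb(n, c1))
    obs = logpmf[support.searchsorted(chip_in)]
    p = float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum())
    return min(p, 1.0)


def _logcomb(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def enrichment_table(chip_assignment: pd.DataFrame, chip_total: int,
                     input_assignment: pd.DataFrame, input_total: int,
                     library: RepeatLibrary) -> pd.DataFrame:
    """Per-class enrichment summary: counts, percents, fold, exact-test p."""
    chip_counts = chip_assignment.dropna(subset=["repeat"]).groupby(
        "cls", observed=True).size()
    input_counts = input_assignment.dropna(subset=["repeat"]).groupby(
        "cls", observed=True).size()
    rows = []
    for cls in library.classes():
        ci = int(chip_counts.get(cls, 0))
        ii = int(input_counts.get(cls, 0))
        chip_pct = 100.0 * ci / chip_total
        input_pct = 100.0 * ii / input_total
        rows.append({
            "cls": cls,
            "chip_in": ci, "chip_total": chip_total,
            "input_in": ii, "input_total": input_total,
            "chip_pct": chip_pct, "input_pct": input_pct,
            "fold": fold_enrichment(chip_pct, input_pct),
            "p_value": repeat_exact_test(ci, chip_total, ii, input_total),
        })
    return pd.DataFrame(rows)
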