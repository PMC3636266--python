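"""Synthetic mini-genomes, ChIP/input libraries and MNase digestion ladders.

This module generates every input the analysis stages consume, with known
ground truth, so the whole pipeline is testable at desk scale:

* a mini-genome with tandem satellite-like arrays (monomer copies with
  per-base divergence) and gene models with expression values;
* ChIP and input read libraries drawn from an explicit per-base weight
  landscape: class weights for repeat/gene features and multiplicative
  Gaussian occupancy dips around TSSs whose depth scales with expression
  rank (deep dips at highly expressed genes, shallow at silent ones);
* MNase time-course ladders in which the apparent nucleosome repeat length
  shrinks linearly with digestion time.

All randomness is driven by explicit seeds; a simulation is a pure function
of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FeatureOverlapError(ValueError):
    """Raised when placed genome features collide; carries the offenders."""

    def __init__(self, collisions):
        self.collisions = collisions
        detail = "; ".join(
            f"{a_name}[{a_start},{a_end}) overlaps {b_name}[{b_start},{b_end}) on {chrom}"
            for chrom, a_name, a_start, a_end, b_name, b_start, b_end in collisions
        )
        super().__init__(f"overlapping features: {detail}")


@dataclass(frozen=True)
class RepeatArraySpec:
    """A tandem array: `copies` copies of `monomer`, each base independently
    substituted at rate `divergence`, placed at [start, start+len) on `chrom`."""

    chrom: str
    start: int
    monomer: str
    copies: int
    divergence: float = 0.0
    label: str = "satellite"

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError("copy number must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")

    @property
    def end(self) -> int:
        return self.start + len(self.monomer) * self.copies


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")
        if self.end <= self.start:
            raise ValueError("gene interval must be non-empty")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes plus the features to place on them.

    `at_fraction` sets the background base composition (P(A)=P(T)=at/2).
    """

    chromosomes: dict[str, int]
    repeats: tuple[RepeatArraySpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    at_fraction: float = 0.58

    def __post_init__(self):
        if not (0.0 <= self.at_fraction <= 1.0):
            raise ValueError("at_fraction must be in [0, 1]")
        object.__setattr__(self, "repeats", tuple(self.repeats))
        object.__setattr__(self, "genes", tuple(self.genes))
        self._validate()

    def _features(self):
        for r in self.repeats:
            yield r.chrom, r.start, r.end, f"{r.label}", r.label, "+"
        for g in self.genes:
            yield g.chrom, g.start, g.end, g.gene_id, "gene", g.strand

    def _validate(self):
        per_chrom: dict[str, list] = {}
        for chrom, start, end, name, cls, strand in self._features():
            if chrom not in self.chromosomes:
                raise ValueError(f"feature {name} on unknown chromosome {chrom}")
            if start < 0 or end > self.chromosomes[chrom]:
                raise ValueError(
                    f"feature {name} [{start},{end}) outside {chrom} "
                    f"of length {self.chromosomes[chrom]}")
            per_chrom.setdefault(chrom, []).append((start, end, name))
        collisions = []
        for chrom, feats in per_chrom.items():
            feats.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(feats, feats[1:]):
                if s2 < e1:
                    collisions.append((chrom, n1, s1, e1, n2, s2, e2))
        if collisions:
            raise FeatureOverlapError(collisions)


@dataclass(frozen=True)
class EnrichmentSpec:
    """Sampling-weight model for one library.

    `class_weights` maps a feature class label to its sampling weight f >= 0
    (background weight is 1; an input library uses an empty map).  The TSS
    dip multiplies the landscape by 1 - d_g * exp(-(x - TSS)^2 / (2 sigma^2))
    around every TSS, where d_g = tss_dip_depth * p_g**dip_expression_power
    and p_g in (0, 1] is the gene's expression percentile rank (1 = most
    expressed).  d < 1 keeps the density positive.
    """

    class_weights: dict[str, float] = field(default_factory=dict)
    tss_dip_depth: float = 0.0
    tss_dip_sigma: float = 500.0
    dip_expression_power: float = 1.0

    def __post_init__(self):
        for cls, w in self.class_weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for class {cls!r} must be finite and >= 0")
        if not (0.0 <= self.tss_dip_depth < 1.0):
            raise ValueError("tss_dip_depth must be in [0, 1)")
        if self.tss_dip_sigma <= 0:
            raise ValueError("tss_dip_sigma must be > 0")


@dataclass(frozen=True)
class LadderSpec:
    """MNase time-course model: band n at time t runs at
    n * (nrl0 - shortening_rate * t) + intercept + Normal(0, noise_sd^2) bp."""

    nrl0: float
    shortening_rate: float
    timepoints: tuple[float, ...]
    n_bands: int
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        if self.nrl0 <= 0:
            raise ValueError("nrl0 must be > 0")
        if self.n_bands < 2:
            raise ValueError("need >= 2 bands per timepoint")
        tp = self.timepoints
        if not tp or any(t <= 0 for t in tp) or list(tp) != sorted(set(tp)):
            raise ValueError("timepoints must be strictly positive and increasing")
        if self.nrl0 - self.shortening_rate * max(tp) <= 0:
            raise ValueError(
                "apparent repeat length is non-positive at the last timepoint; "
                "the digestion model collapses")


def _mutate(monomer_codes: np.ndarray, divergence: float,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently at `divergence` to a different base."""
    out = monomer_codes.copy()
    if divergence == 0:
        return out
    hit = rng.random(out.size) < divergence
    idx = np.flatnonzero(hit)
    if idx.size:
        # pick one of the three non-identical bases per hit
        cur = np.searchsorted(BASES, out[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = BASES[(cur + shift) % 4]
    return out


def build_genome(spec: GenomeSpec, seed: int) -> tuple[dict[str, str], pd.DataFrame]:
    """Materialize a GenomeSpec into sequences and a feature annotation.

    Returns ``(sequences, annotation)`` where annotation is a BED-like frame
    with columns chrom, start, end, name, cls, strand, expression (NaN for
    non-gene features), 0-based half-open, sorted by (chrom, start).
    """
    rng = np.random.default_rng(seed)
    at = spec.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    seqs: dict[str, np.ndarray] = {
        chrom: BASES[rng.choice(4, size=length, p=probs)]
        for chrom, length in spec.chromosomes.items()
    }
    rows = []
    for rep in spec.repeats:
        monomer = np.frombuffer(rep.monomer.upper().encode(), dtype=np.uint8)
        copies = [_mutate(monomer, rep.divergence, rng) for _ in range(rep.copies)]
        array = np.concatenate(copies)
        seqs[rep.chrom][rep.start:rep.end] = array
        rows.append((rep.chrom, rep.start, rep.end, rep.label, rep.label,
                     "+", np.nan))
    for g in spec.genes:
        rows.append((g.chrom, g.start, g.end, g.gene_id, "gene", g.strand,
                     g.expression))
    annotation = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "cls", "strand",
                       "expression"])
    annotation = annotation.sort_values(["chrom", "start"], kind="stable",
                                        ignore_index=True)
    sequences = {c: a.tobytes().decode() for c, a in seqs.items()}
    return sequences, annotation


def gene_table(spec_or_annotation) -> pd.DataFrame:
    """Gene model table (gene_id, chrom, strand, tss, tts, expression)."""
    if isinstance(spec_or_annotation, GenomeSpec):
        genes = spec_or_annotation.genes
        rows = [(g.gene_id, g.chrom, g.strand, g.tss, g.tts, g.expression)
                for g in genes]
    else:
        ann = spec_or_annotation
        sub = ann[ann["cls"] == "gene"]
        rows = [
            (r.name_, r.chrom, r.strand,
             r.start if r.strand == "+" else r.end - 1,
             r.end - 1 if r.strand == "+" else r.start,
             r.expression)
            for r in sub.rename(columns={"name": "name_"}).itertuples()
        ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "tts", "expression"])


def weight_landscape(chrom_sizes: dict[str, int], annotation: pd.DataFrame,
                     enrich: EnrichmentSpec) -> dict[str, np.ndarray]:
    """Per-base sampling weight for each chromosome.

    w(i) = class_weight(feature covering i) * prod over TSSs of
    (1 - d_g * exp(-(i - TSS)^2 / (2 sigma^2))); background weight is 1.
    """
    weights = {c: np.ones(length) for c, length in chrom_sizes.items()}
    for row in annotation.itertuples():
        f = enrich.class_weights.get(row.cls)
        if f is not None:
            weights[row.chrom][row.start:row.end] *= f
    if enrich.tss_dip_depth > 0:
        genes = gene_table(annotation)
        if len(genes):
            # percentile rank: 1 = most expressed; ties by stable gene id
            order = genes.sort_values(["expression", "gene_id"],
                                      kind="stable").reset_index()
            pct = (np.arange(1, len(order) + 1)) / len(order)
            sigma = enrich.tss_dip_sigma
            half = int(np.ceil(5 * sigma))
            for rank_pos, row in enumerate(order.itertuples()):
                d = enrich.tss_dip_depth * pct[rank_pos] ** enrich.dip_expression_power
                w = weights[row.chrom]
                lo = max(0, row.tss - half)
                hi = min(len(w), row.tss + half + 1)
                x = np.arange(lo, hi) - row.tss
                w[lo:hi] *= 1.0 - d * np.exp(-(x * x) / (2 * sigma * sigma))
    return weights


def simulate_library(genome: dict[str, str], annotation: pd.DataFrame,
                     enrich: EnrichmentSpec, n_reads: int, read_len: int,
                     fragment_len: int, seed: int,
                     with_sequences: bool = True,
                     ) -> tuple[list[tuple[str, str]] | None, pd.DataFrame]:
    """Draw a sequencing library from the weight landscape.

    Fragment start positions are sampled with probability proportional to the
    landscape weight at the fragment midpoint; each fragment is assigned a
    strand with probability 1/2 and the read is the first `read_len` bases of
    the fragment read from that strand's 5' end.  Returns
    ``(reads, origins)``; `origins` records the true fragment interval,
    strand and midpoint of every read.  With ``with_sequences=False`` the
    read list is None (origins only), which is cheaper when only coverage is
    needed.  Deterministic for fixed seed.
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    if not (0 < read_len <= fragment_len <= min(chrom_sizes.values())):
        raise ValueError("need read_len <= fragment_len <= min chromosome length")
    weights = weight_landscape(chrom_sizes, annotation, enrich)
    chroms = sorted(chrom_sizes)
    mid_off = fragment_len // 2
    per_chrom_w = []
    for c in chroms:
        n_starts = chrom_sizes[c] - fragment_len + 1
        per_chrom_w.append(weights[c][mid_off:mid_off + n_starts])
    flat = np.concatenate(per_chrom_w)
    total = flat.sum()
    if total <= 0:
        raise ValueError("weight landscape is identically zero; nothing to sample")
    rng = np.random.default_rng(seed)
    picks = rng.choice(flat.size, size=n_reads, p=flat / total)
    strands = rng.random(n_reads) < 0.5  # True -> minus strand

    bounds = np.cumsum([0] + [w.size for w in per_chrom_w])
    chrom_idx = np.searchsorted(bounds, picks, side="right") - 1
    starts = picks - bounds[chrom_idx]

    origins = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(chrom_idx, categories=chroms),
        "start": starts,
        "end": starts + fragment_len,
        "name": [f"r{i:07d}" for i in range(n_reads)],
        "score": 0,
        "strand": np.where(strands, "-", "+"),
    })
    origins["midpoint"] = origins["start"] + mid_off

    reads = None
    if with_sequences:
        reads = []
        chrom_names = origins["chrom"].astype(str).to_numpy()
        for i in range(n_reads):
            s = int(starts[i])
            frag = genome[chrom_names[i]][s:s + fragment_len]
            if strands[i]:
                frag = revcomp(frag)
            reads.append((f"r{i:07d}", frag[:read_len]))
    return reads, origins


def simulate_mnase_ladder(spec: LadderSpec) -> pd.DataFrame:
    """Band-size observations (time_min, band_n, size_bp) for an MNase
    time course; band n at time t has expected size
    n * (nrl0 - rate * t) + intercept."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.timepoints:
        apparent = spec.nrl0 - spec.shortening_rate * t
        for n in range(1, spec.n_bands + 1):
            size = n * apparent + spec.intercept
            if spec.noise_sd > 0:
                size += rng.normal(0.0, spec.noise_sd)
            rows.append((t, n, size))
    return pd.DataFrame(rows, columns=["time_min", "band_n", "size_bp"])
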