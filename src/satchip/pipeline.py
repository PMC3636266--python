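"""End-to-end orchestration: simulate -> signal -> metagene -> correlate ->
islands -> repeats -> quant, driven by a single YAML config.

Each stage reads its inputs from and writes its outputs to the configured
output directory, so stages can be rerun individually.  Every stage is a
pure function of (config, files on disk); reruns with one config are
byte-identical, and ``run_pipeline`` records a manifest with the config echo
and the SHA-256 of every artifact.
"""
from __future__ import annotations

import hashlib
import json
import time
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlate, formats, islands, metagene, quant, repeats, synthetic
from . import tracks

log = logging.getLogger("satchip")

STAGES = ("simulate", "signal", "metagene", "correlate", "islands",
          "repeats", "quant")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for key in ("outdir", "seed", "simulate"):
        if key not in cfg:
            raise ValueError(f"config lacks required key {key!r}")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    for key in ("gene_table", "genome_fasta", "repeat_library"):
        path = cfg.get("paths", {}).get(key)
        if path is not None and not Path(path).exists():
            raise ValueError(f"configured {key} path does not exist: {path}")


def _genome_spec(cfg: dict) -> synthetic.GenomeSpec:
    g = cfg["simulate"]["genome"]
    return synthetic.GenomeSpec(
        chromosomes=dict(g["chromosomes"]),
        repeats=tuple(synthetic.RepeatArraySpec(**r) for r in g.get("repeats", [])),
        genes=tuple(synthetic.GeneSpec(**s) for s in g.get("genes", [])),
        at_fraction=g.get("at_fraction", 0.58),
    )


def _enrichment_spec(section: dict) -> synthetic.EnrichmentSpec:
    return synthetic.EnrichmentSpec(
        class_weights=dict(section.get("class_weights", {})),
        tss_dip_depth=section.get("tss_dip_depth", 0.0),
        tss_dip_sigma=section.get("tss_dip_sigma", 500.0),
        dip_expression_power=section.get("dip_expression_power", 1.0),
    )


def _island_params(cfg: dict) -> islands.IslandParams:
    sec = cfg.get("islands", {})
    return islands.IslandParams(
        window=sec.get("window", 200),
        gap=sec.get("gap", 600),
        e_value=sec.get("e_value", 1000.0),
        effective_fraction=sec.get("effective_fraction", 0.8),
        q_threshold=sec.get("q_threshold", 0.001),
        p0=sec.get("p0", 0.2),
    )


def _read_genome(outdir: Path) -> dict[str, str]:
    return formats.read_fasta(outdir / "genome.fa")


def _load_track(outdir: Path, library: str, chrom_sizes: dict[str, int],
                w: int) -> tracks.SignalTrack:
    bed = formats.read_bed(outdir / f"{library}.bed")
    return tracks.window_counts(bed, chrom_sizes, w)


def _ipin_track(cfg: dict, outdir: Path, w: int) -> tracks.SignalTrack:
    genome = _read_genome(outdir)
    sizes = {c: len(s) for c, s in genome.items()}
    chip = tracks.normalize_per_10M(_load_track(outdir, "chip", sizes, w))
    inp = tracks.normalize_per_10M(_load_track(outdir, "input", sizes, w))
    return tracks.ipin(chip, inp)


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    sim = cfg["simulate"]
    seed = cfg["seed"]
    spec = _genome_spec(cfg)
    genome, annotation = synthetic.build_genome(spec, seed)
    out = []

    def emit(name, writer):
        path = outdir / name
        writer(path)
        out.append(path)

    emit("genome.fa", lambda p: formats.write_fasta(p, sorted(genome.items())))
    ann = annotation.assign(score=0)
    emit("annotation.bed", lambda p: formats.write_bed6(p, ann))
    genes = synthetic.gene_table(spec)
    emit("genes.tsv", lambda p: formats.write_tsv(p, genes))

    lib_entries = []
    for rep in spec.repeats:
        if rep.label not in {e[0] for e in lib_entries}:
            lib_entries.append((rep.label, rep.label, rep.monomer))
    if lib_entries:
        emit("repeat_library.fa", lambda p: formats.write_fasta(
            p, [(f"{n}|{c}", s) for n, c, s in lib_entries]))

    chip_spec = _enrichment_spec(sim.get("chip_enrichment", {}))
    input_spec = synthetic.EnrichmentSpec()
    n_reads = sim.get("n_reads", 30000)
    read_len = sim.get("read_len", 50)
    frag = sim.get("fragment_len", 200)
    for name, enr, lib_seed in (("chip", chip_spec, seed + 1),
                                ("input", input_spec, seed + 2)):
        reads, origins = synthetic.simulate_library(
            genome, annotation, enr, n_reads, read_len, frag, lib_seed)
        emit(f"{name}.fastq", lambda p, r=reads: formats.write_fastq(p, r))
        emit(f"{name}.bed", lambda p, o=origins: formats.write_bed6(p, o))

    lad = sim.get("ladder")
    if lad:
        ladder = synthetic.simulate_mnase_ladder(synthetic.LadderSpec(
            nrl0=lad["nrl0"], shortening_rate=lad.get("shortening_rate", 0.0),
            timepoints=tuple(lad["timepoints"]), n_bands=lad.get("n_bands", 8),
            intercept=lad.get("intercept", 0.0),
            noise_sd=lad.get("noise_sd", 0.0), seed=seed + 3))
        emit("ladder.tsv", lambda p: formats.write_tsv(p, ladder))
    return out


def stage_signal(cfg: dict, outdir: Path) -> list[Path]:
    w = cfg.get("signal", {}).get("window", 100)
    genome = _read_genome(outdir)
    sizes = {c: len(s) for c, s in genome.items()}
    chip = tracks.normalize_per_10M(_load_track(outdir, "chip", sizes, w))
    inp = tracks.normalize_per_10M(_load_track(outdir, "input", sizes, w))
    diff = tracks.ipin(chip, inp)
    gc = tracks.gc_track(genome, w)
    out = []
    for name, tr in (("ipin.bedgraph", diff), ("gc.bedgraph", gc)):
        path = outdir / name
        formats.write_bedgraph(path, tr)
        out.append(path)
    return out


def stage_metagene(cfg: dict, outdir: Path) -> list[Path]:
    sec = cfg.get("metagene", {})
    w = cfg.get("signal", {}).get("window", 100)
    genes = formats.read_tsv(outdir / "genes.tsv")
    track = _ipin_track(cfg, outdir, w)
    grouping = metagene.partition_by_expression(
        genes, sec.get("scheme", "deciles_extremes"))
    prof = metagene.metagene_profile(track, genes, grouping, anchor="TSS",
                                     flank=sec.get("flank", 5000), bin=w)
    prof_all = metagene.metagene_profile(track, genes, None, anchor="TSS",
                                         flank=sec.get("flank", 5000), bin=w)
    path = outdir / "metagene_tss.tsv"
    formats.write_tsv(path, pd.concat([prof, prof_all], ignore_index=True))
    return [path]


def stage_correlate(cfg: dict, outdir: Path) -> list[Path]:
    W = cfg.get("correlation", {}).get("window", 1000)
    w = cfg.get("signal", {}).get("window", 100)
    genome = _read_genome(outdir)
    diff = _ipin_track(cfg, outdir, w)
    gc = tracks.gc_track(genome, w)
    results = [correlate.genome_correlation(diff, gc, W, ("IP-IN", "GC%"))]
    results += correlate.per_chromosome_correlation(diff, gc, W, ("IP-IN", "GC%"))
    df = pd.DataFrame([{"track_a": r.label_a, "track_b": r.label_b,
                        "scope": r.scope, "n": r.n, "R": r.r, "p": r.p}
                       for r in results])
    path = outdir / "correlations.tsv"
    formats.write_tsv(path, df)
    return [path]


def stage_islands(cfg: dict, outdir: Path) -> list[Path]:
    params = _island_params(cfg)
    genome = _read_genome(outdir)
    sizes = {c: len(s) for c, s in genome.items()}
    chip = _load_track(outdir, "chip", sizes, params.window)
    inp = _load_track(outdir, "input", sizes, params.window)
    seed = cfg["seed"] + 10
    best_gap, diagnostics = islands.optimize_gap(chip, inp, params, seed)
    best = islands.IslandParams(params.window, best_gap, params.e_value,
                                params.effective_fraction, params.q_threshold,
                                params.p0)
    called = islands.call_islands(chip, inp, best, seed)
    genes = formats.read_tsv(outdir / "genes.tsv")
    breakdown = islands.annotate_regions(called, genes)
    out = []
    for name, writer in (
            ("islands.bed", lambda p: formats.write_bed6(
                p, islands.islands_to_bed(called))),
            ("islands_gap_diagnostics.tsv", lambda p: formats.write_tsv(
                p, diagnostics)),
            ("islands_annotation.tsv", lambda p: formats.write_tsv(
                p, breakdown))):
        path = outdir / name
        writer(path)
        out.append(path)
    return out


def stage_repeats(cfg: dict, outdir: Path) -> list[Path]:
    sec = cfg.get("repeats", {})
    library = repeats.RepeatLibrary.from_fasta(outdir / "repeat_library.fa")
    seed = cfg["seed"] + 20
    assignments = {}
    totals = {}
    for lib in ("chip", "input"):
        rds = list(formats.read_fastq(outdir / f"{lib}.fastq"))
        totals[lib] = len(rds)
        assignments[lib] = repeats.assign_reads_to_repeats(
            rds, library, sec.get("seed_len", 35), sec.get("max_mismatch", 2),
            rng_seed=seed)
    table = repeats.enrichment_table(assignments["chip"], totals["chip"],
                                     assignments["input"], totals["input"],
                                     library)
    path = outdir / "repeat_enrichment.tsv"
    formats.write_tsv(path, table)
    return [path]


def stage_quant(cfg: dict, outdir: Path) -> list[Path]:
    ladder_path = outdir / "ladder.tsv"
    if not ladder_path.exists():
        return []
    obs = formats.read_tsv(ladder_path)
    est = quant.estimate_nrl(obs)
    df = pd.DataFrame({"quantity": ["nrl0", "nrl0_stderr"],
                       "value": [est.nrl0, est.stderr]})
    path = outdir / "nrl.tsv"
    formats.write_tsv(path, df)
    per_t = outdir / "nrl_per_timepoint.tsv"
    formats.write_tsv(per_t, est.per_timepoint)
    return [path, per_t]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "signal": stage_signal,
    "metagene": stage_metagene,
    "correlate": stage_correlate,
    "islands": stage_islands,
    "repeats": stage_repeats,
    "quant": stage_quant,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages and write a manifest of produced artifacts.

    The manifest echoes the config and lists every output with its SHA-256;
    rerunning with an identical config reproduces it byte for byte.
    """
    validate_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.monotonic()
        try:
            produced.extend(_STAGE_FUNCS[stage](cfg, outdir))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1f s", stage, time.monotonic() - t0)
    manifest = {
        "config": cfg,
        "outputs": {p.name: _sha256(p) for p in sorted(set(produced))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest


def demo_config(outdir: str = "satchip_demo", seed: int = 1) -> dict:
    """A self-contained demo: 300-kb chromosome, one 15-kb satellite array
    (ChIP weight 4), 60 genes with lognormal expression and
    expression-scaled TSS dips, 30k reads per library, and an MNase ladder
    with a 200-bp zero-time repeat length."""
    rng = np.random.default_rng(seed)
    monomer = "".join(rng.choice(list("ACGT"), p=[0.34, 0.16, 0.16, 0.34])
                      for _ in range(234))
    copies = 64  # 14,976 bp array
    genes = []
    expr = np.round(rng.lognormal(mean=2.0, sigma=1.5, size=60), 3)
    for i in range(60):
        start = 20000 + i * 4000
        genes.append({"gene_id": f"g{i:03d}", "chrom": "chr1",
                      "start": start, "end": start + 2000,
                      "strand": "+" if i % 2 == 0 else "-",
                      "expression": float(expr[i])})
    return {
        "outdir": outdir,
        "seed": seed,
        "simulate": {
            "n_reads": 30000,
            "read_len": 50,
            "fragment_len": 200,
            "genome": {
                "chromosomes": {"chr1": 300000},
                "at_fraction": 0.58,
                "repeats": [{"chrom": "chr1", "start": 270000,
                             "monomer": monomer, "copies": copies,
                             "divergence": 0.05, "label": "satMajor"}],
                "genes": genes,
            },
            "chip_enrichment": {
                "class_weights": {"satMajor": 4.0, "gene": 0.7},
                "tss_dip_depth": 0.6,
                "tss_dip_sigma": 300.0,
                "dip_expression_power": 1.0,
            },
            "ladder": {"nrl0": 200.0, "shortening_rate": 1.0,
                       "timepoints": [2.5, 5.0, 10.0], "n_bands": 8,
                       "intercept": -20.0, "noise_sd": 5.0},
        },
        "signal": {"window": 100},
        "metagene": {"flank": 3000, "scheme": "deciles_extremes"},
        "correlation": {"window": 1000},
        "islands": {"window": 200, "gap": 600, "e_value": 1000.0,
                    "effective_fraction": 0.8, "q_threshold": 0.001,
                    "p0": 0.2},
        "repeats": {"seed_len": 35, "max_mismatch": 2},
    }
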