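"""End-to-end run orchestration: configuration, staging, manifest.

A run chains generation → simulation → alignment → retention scoring →
windowed depth → differential coverage → composition, writing every stage
output as a text table so each stage is individually re-runnable from
disk.  One global seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import diffcov, retention, windows
from .genome import (
    GeneratorConfig,
    GenomeModel,
    make_genome,
    write_bed,
    write_fasta,
    write_generator_config,
    write_ies_gff3,
)
from .mapping import SeedIndex, map_readset
from .readsim import (
    GERMLINE,
    STUDY_SAMPLE_FRACTIONS,
    PGM,
    SOMATIC,
    MixtureSpec,
    ReadSimConfig,
    simulate_sample,
)

logger = logging.getLogger(__name__)

SEED_OFFSETS = {"genome": 11, "simulate": 101, "align": 0, "diffcov": 301}

CLASS_SOURCE = {"MIC": GERMLINE, "MAC": SOMATIC, "PGM": PGM}


@dataclass
class SampleSpec:
    label: str
    klass: str  # MIC | MAC | PGM
    coverage: float = 50.0
    replicates: int = 3


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "micmac_run"
    genome: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(total_length=200_000, n_contigs=2))
    samples: list[SampleSpec] = field(
        default_factory=lambda: [
            SampleSpec("mic", "MIC"),
            SampleSpec("mac", "MAC"),
            SampleSpec("pgm", "PGM"),
        ]
    )
    retention_fractions: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_SAMPLE_FRACTIONS)
    )
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 100.0
    substitution_rate: float = 0.002
    retention_coverage: float = 50.0
    depth_threshold: float = 20.0
    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_mapq: int = 30
    min_baseq: int = 30
    max_mismatch: int = 1

    def validate(self) -> None:
        for thr in (self.depth_threshold, self.fc_threshold, self.alpha, self.min_mapq, self.min_baseq):
            if thr <= 0:
                raise ValueError("all thresholds must be positive")
        classes = {s.klass for s in self.samples}
        missing = {"MIC", "MAC", "PGM"} - classes
        if missing:
            raise ValueError(f"sample table must cover classes MIC, MAC, PGM; missing {sorted(missing)}")
        for s in self.samples:
            if s.klass not in CLASS_SOURCE:
                raise ValueError(f"unknown sample class {s.klass!r}")
            if s.replicates < 2:
                raise ValueError("compartment testing needs >=2 replicates per class")


def load_run_config(path) -> RunConfig:
    """Parse a flat key=value config file.

    Genome keys are prefixed ``genome.``; samples are comma lists like
    ``sample.mic = MIC,50,3``.
    """
    cfg = RunConfig()
    gkw: dict = {}
    samples: list[SampleSpec] = []
    fractions: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("genome."):
            name = key[len("genome."):]
            f_ = {f.name: f for f in dataclasses.fields(GeneratorConfig)}.get(name)
            if f_ is None:
                raise ValueError(f"unknown genome parameter {name!r}")
            if "," in value:
                gkw[name] = tuple(float(x) if "." in x else int(x) for x in value.split(","))
            elif value in ("True", "False"):
                gkw[name] = value == "True"
            elif f_.type in ("int", int):
                gkw[name] = int(value)
            elif f_.type in ("float", float):
                gkw[name] = float(value)
            else:
                gkw[name] = value
        elif key.startswith("sample."):
            klass, cov, reps = value.split(",")
            samples.append(SampleSpec(key[len("sample."):], klass.strip(), float(cov), int(reps)))
        elif key.startswith("fraction."):
            fractions[key[len("fraction."):]] = float(value)
        elif hasattr(cfg, key):
            cur = getattr(cfg, key)
            setattr(cfg, key, type(cur)(value) if not isinstance(cur, (dict, list)) else cur)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if gkw:
        cfg.genome = GeneratorConfig(**gkw)
    if samples:
        cfg.samples = samples
    if fractions:
        cfg.retention_fractions = fractions
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict):
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    logger.info("generating genome (seed %d)", seed)

    model = make_genome(config.genome, seed + SEED_OFFSETS["genome"])
    write_fasta(out / "germline.fasta", model.contigs, seed=model.seed)
    write_fasta(out / "somatic.fasta", model.somatic_contigs, seed=model.seed)
    write_ies_gff3(out / "ies.gff3", model)
    write_bed(out / "compartments.bed", model.compartment_truth, seed=model.seed)
    write_bed(
        out / "te.bed",
        [(t.contig, t.start, t.end, t.family, 0, t.strand) for t in model.te_copies],
        seed=model.seed,
    )
    write_bed(
        out / "tandem.bed",
        [(t.contig, t.start, t.end, f"period={t.period};copies={t.copies:.1f}") for t in model.tandem_repeats],
        seed=model.seed,
    )
    write_generator_config(out / "generator.config", config.genome, model.seed)

    sim_base = ReadSimConfig(
        read_length=config.read_length,
        fragment_mean=config.fragment_mean,
        fragment_sd=config.fragment_sd,
        substitution_rate=config.substitution_rate,
        coverage=config.retention_coverage,
    )
    g_index = SeedIndex(model.contigs)
    s_index = SeedIndex(model.somatic_contigs)

    # --- retention stage on the five study sample classes
    logger.info("retention stage: %d samples", len(config.retention_fractions))
    summary_rows = []
    for i, (label, f) in enumerate(config.retention_fractions.items()):
        cfg_i = dataclasses.replace(sim_base, seed=seed + SEED_OFFSETS["simulate"] + i)
        from .readsim import mixture_for_fraction

        rs = simulate_sample(model, mixture_for_fraction(f, config.retention_coverage, label), cfg_i)
        aln_g = map_readset(g_index, rs, max_mismatches=3)
        aln_s = map_readset(s_index, rs, max_mismatches=3)
        recs = retention.count_boundary_reads(
            aln_g, aln_s, model, max_mismatch=config.max_mismatch
        )
        retention.write_retention_tsv(out / f"retention.{label}.tsv", recs, seed=cfg_i.seed)
        summ = retention.retention_summary(recs)
        summary_rows.append(
            {"sample": label, "unexcised_fraction": f, "mean_score": summ.mean,
             "sd": summ.sd, "n_defined": summ.n_defined, "n_undefined": summ.n_undefined}
        )
    _write_tsv(out / "retention_summary.tsv", pd.DataFrame(summary_rows), {"seed": seed})

    # --- windows + differential coverage on the class replicates
    logger.info("compartment stage")
    win = windows.make_windows(model.contig_lengths)
    counts = []
    classes = []
    depth_cols = {}
    rep_seed = seed + SEED_OFFSETS["diffcov"]
    for smp in config.samples:
        for r in range(smp.replicates):
            rep_seed += 1
            cfg_i = dataclasses.replace(sim_base, coverage=smp.coverage, seed=rep_seed)
            mix = MixtureSpec(((CLASS_SOURCE[smp.klass], smp.coverage),), label=f"{smp.label}_r{r+1}")
            rs = simulate_sample(model, mix, cfg_i)
            aln = map_readset(g_index, rs, max_mismatches=3)
            counts.append(windows.unique_read_counts(aln, win, min_mapq=config.min_mapq))
            classes.append(smp.klass)
            depth = windows.per_nt_depth(aln, model.contig_lengths, config.min_baseq, config.min_mapq)
            raw = windows.window_depth(aln, win, model.contig_lengths, depth=depth)
            norm = windows.normalize_depth(raw, windows.sample_nt_sequenced(rs))
            depth_cols[f"{smp.label}_r{r+1}_raw"] = raw
            depth_cols[f"{smp.label}_r{r+1}_norm"] = norm
    count_matrix = np.column_stack(counts)
    calls = diffcov.compartment_pipeline(
        win, count_matrix, classes, fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    depth_df = pd.concat([win, pd.DataFrame(depth_cols)], axis=1)
    _write_tsv(out / "depth.tsv", depth_df, {"seed": seed, "reference_nt": "1e9"})
    _write_tsv(out / "diffcov.tsv", calls.to_frame(), {"seed": seed, "fc_threshold": config.fc_threshold, "alpha": config.alpha})
    write_bed(
        out / "compartments_called.bed",
        list(zip(calls.windows["contig"], calls.windows["start"], calls.windows["end"], calls.label)),
        seed=seed,
    )
    count_df = pd.concat(
        [win, pd.DataFrame(count_matrix, columns=[f"{c}_{i}" for i, c in enumerate(classes)])], axis=1
    )
    _write_tsv(out / "counts.tsv", count_df, {"seed": seed})

    # --- composition of the called compartments
    logger.info("composition stage")
    calls_df = calls.to_frame()[["contig", "start", "end", "label"]]
    table = comp.composition_table(model.contigs, calls_df, model.ies_set, model.te_library)
    tests = []
    if {"MIC_PGM", "MIC_ONLY"}.issubset(table.index):
        for feat in ("tandem", "te"):
            p = comp.compartment_enrichment_test(
                int(table.loc["MIC_ONLY", f"{feat}_bp"]),
                int(table.loc["MIC_ONLY", "bp"]),
                int(table.loc["MIC_PGM", f"{feat}_bp"]),
                int(table.loc["MIC_PGM", "bp"]),
            )
            tests.append({"feature": feat, "compartments": "MIC_ONLY vs MIC_PGM", "pvalue": p})
    _write_tsv(out / "composition.tsv", table.reset_index(), {"seed": seed})
    _write_tsv(out / "tests.tsv", pd.DataFrame(tests), {"seed": seed})

    manifest = {
        "seed": seed,
        "package": "micmac",
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
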