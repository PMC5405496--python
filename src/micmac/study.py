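"""Study-scale computations: the simulation conditions behind the headline
numbers (retention-score recovery, pooled mixture depth, the two-cloud
density grid, compartment recovery).

These functions pin the problem sizes used for validation: a 1-Mb genome
with ~480 IESs at 50x coverage for retention and pooled-depth checks (the
scale at which the retention means 0.005/0.69/0.82/0.04/0.38 and the
40x + 60x = 100x arithmetic are recovered), and a 300-kb genome for
compartment recovery and the density grid, where 300 windows give ample
resolution for a window-accuracy measurement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import composition as comp
from . import diffcov, retention, windows
from .genome import GeneratorConfig, GenomeModel, MAC_DESTINED, MIC_ONLY, MIC_PGM, make_genome
from .mapping import SeedIndex, map_readset
from .readsim import (
    GERMLINE,
    STUDY_SAMPLE_FRACTIONS,
    SOMATIC,
    MixtureSpec,
    ReadSimConfig,
    mixture_for_fraction,
    simulate_sample,
)

RETENTION_GENOME = GeneratorConfig(total_length=1_000_000, n_contigs=5)
COMPARTMENT_GENOME = GeneratorConfig(total_length=300_000, n_contigs=3)


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 10_007 + offset) % (2**31 - 1)


def retention_genome(seed: int) -> GenomeModel:
    return make_genome(RETENTION_GENOME, _sub_seed(seed, 1))


def compartment_genome(seed: int) -> GenomeModel:
    return make_genome(COMPARTMENT_GENOME, _sub_seed(seed, 2))


@dataclass
class RetentionOutcome:
    sample: str
    unexcised_fraction: float
    mean_score: float
    n_scored: int


def retention_recovery(
    model: GenomeModel,
    fractions: dict[str, float] | None = None,
    coverage: float = 50.0,
    seed: int = 0,
    g_index: SeedIndex | None = None,
    s_index: SeedIndex | None = None,
) -> list[RetentionOutcome]:
    """Simulate each sample class, map to both references, score IESs."""
    fractions = dict(STUDY_SAMPLE_FRACTIONS if fractions is None else fractions)
    g_index = g_index or SeedIndex(model.contigs)
    s_index = s_index or SeedIndex(model.somatic_contigs)
    out = []
    for i, (label, f) in enumerate(fractions.items()):
        cfg = ReadSimConfig(coverage=coverage, seed=_sub_seed(seed, 10 + i))
        rs = simulate_sample(model, mixture_for_fraction(f, coverage, label), cfg)
        aln_g = map_readset(g_index, rs, max_mismatches=3)
        aln_s = map_readset(s_index, rs, max_mismatches=3)
        recs = retention.count_boundary_reads(aln_g, aln_s, model, max_mismatch=1)
        summ = retention.retention_summary(recs)
        out.append(RetentionOutcome(label, f, summ.mean, summ.n_defined))
    return out


def window_truth_labels(model: GenomeModel, win) -> np.ndarray:
    """Ground-truth compartment of each window by majority base pairs."""
    truth = {}
    for c, s, e, lab in model.compartment_truth:
        truth.setdefault(c, []).append((s, e, lab))
    labels = []
    for c, s, e in zip(win["contig"], win["start"], win["end"]):
        best, best_bp = MAC_DESTINED, 0
        for ts, te, lab in truth[c]:
            bp = max(0, min(te, e) - max(ts, s))
            if bp > best_bp:
                best, best_bp = lab, bp
        labels.append(best)
    return np.array(labels, dtype=object)


@dataclass
class PooledDepthOutcome:
    mean_mac_destined: float
    mean_mic_limited: float
    n_mac_windows: int
    n_mic_windows: int


def pooled_mixture_depth(
    model: GenomeModel, seed: int = 0, cov_germline: float = 40.0, cov_somatic: float = 60.0
) -> PooledDepthOutcome:
    """The 40x germline + 60x somatic pooled simulation, mapped to germline.

    MAC-destined windows see both components (≈100x); MIC-limited windows
    only the germline component (≈40x).
    """
    mix = MixtureSpec(((GERMLINE, cov_germline), (SOMATIC, cov_somatic)), label="pooled")
    cfg = ReadSimConfig(coverage=cov_germline + cov_somatic, seed=_sub_seed(seed, 20))
    rs = simulate_sample(model, mix, cfg)
    index = SeedIndex(model.contigs)
    aln = map_readset(index, rs, max_mismatches=3)
    win = windows.make_windows(model.contig_lengths)
    raw = windows.window_depth(aln, win, model.contig_lengths)
    labels = window_truth_labels(model, win)
    mac = labels == MAC_DESTINED
    mic = ~mac
    return PooledDepthOutcome(
        float(raw[mac].mean()), float(raw[mic].mean()), int(mac.sum()), int(mic.sum())
    )


def two_cloud_grid(model: GenomeModel, seed: int = 0):
    """Density grid of a simulated PGM-80% vs MIC-40% pair (normalized depth)."""
    index = SeedIndex(model.contigs)
    win = windows.make_windows(model.contig_lengths)
    norms = {}
    for label, f, off in (("sim_PGM", 0.80, 30), ("sim_MIC", 0.40, 31)):
        mix = MixtureSpec(
            ((GERMLINE, f * 100.0), (SOMATIC, (1 - f) * 100.0)), label=label
        )
        cfg = ReadSimConfig(coverage=100.0, seed=_sub_seed(seed, off))
        rs = simulate_sample(model, mix, cfg)
        aln = map_readset(index, rs, max_mismatches=3)
        raw = windows.window_depth(aln, win, model.contig_lengths)
        norms[label] = windows.normalize_depth(raw, windows.sample_nt_sequenced(rs), 1e9)
    hi = max(float(v.max()) for v in norms.values()) * 1.05
    edges = np.linspace(0, hi, 30)
    return windows.depth_density_grid(norms["sim_MIC"], norms["sim_PGM"], edges)


@dataclass
class CompartmentOutcome:
    accuracy: float
    n_windows: int
    tandem_p: float
    te_p: float
    tandem_direction_up: bool
    te_direction_down: bool
    composition: object  # pd.DataFrame


def compartment_recovery(model: GenomeModel, seed: int = 0, coverage: float = 50.0,
                         replicates: int = 3) -> CompartmentOutcome:
    """Three replicate classes at 50x → NB compartment calls vs truth, plus
    the MIC_ONLY vs MIC_PGM tandem-repeat / TE enrichment tests on the
    *called* compartments (detector-based, not truth-based)."""
    index = SeedIndex(model.contigs)
    win = windows.make_windows(model.contig_lengths)
    counts, classes = [], []
    i = 0
    for klass, source in (("MIC", GERMLINE), ("MAC", SOMATIC), ("PGM", "PGM")):
        for _ in range(replicates):
            cfg = ReadSimConfig(coverage=coverage, seed=_sub_seed(seed, 40 + i))
            rs = simulate_sample(model, MixtureSpec(((source, coverage),), label=f"{klass}{i}"), cfg)
            aln = map_readset(index, rs, max_mismatches=3)
            counts.append(windows.unique_read_counts(aln, win))
            classes.append(klass)
            i += 1
    calls = diffcov.compartment_pipeline(win, np.column_stack(counts), classes)
    truth = window_truth_labels(model, win)
    accuracy = float((calls.label == truth).mean())

    calls_df = calls.to_frame()[["contig", "start", "end", "label"]]
    table = comp.composition_table(model.contigs, calls_df, model.ies_set, model.te_library)
    tandem_p = te_p = float("nan")
    t_up = t_down = False
    if {MIC_PGM, MIC_ONLY}.issubset(table.index):
        tandem_p = comp.compartment_enrichment_test(
            int(table.loc[MIC_ONLY, "tandem_bp"]), int(table.loc[MIC_ONLY, "bp"]),
            int(table.loc[MIC_PGM, "tandem_bp"]), int(table.loc[MIC_PGM, "bp"]),
        )
        te_p = comp.compartment_enrichment_test(
            int(table.loc[MIC_ONLY, "te_bp"]), int(table.loc[MIC_ONLY, "bp"]),
            int(table.loc[MIC_PGM, "te_bp"]), int(table.loc[MIC_PGM, "bp"]),
        )
        t_up = table.loc[MIC_ONLY, "tandem_frac"] > table.loc[MIC_PGM, "tandem_frac"]
        t_down = table.loc[MIC_ONLY, "te_frac"] < table.loc[MIC_PGM, "te_frac"]
    return CompartmentOutcome(accuracy, len(win), tandem_p, te_p, t_up, t_down, table)


def null_type_one_error(
    seed: int = 0,
    n_windows: int = 2000,
    mu: float = 200.0,
    dispersion: float = 0.05,
    replicates: int = 25,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the NB Wald test under the null.

    Null windows are NB with identical class means, true dispersion above
    the floor, and large replicate numbers (the regime in which the
    per-window moment estimator is consistent).
    """
    rng = np.random.default_rng(_sub_seed(seed, 60))
    n = dispersion and 1.0 / dispersion
    counts = rng.negative_binomial(n, n / (n + mu), size=(n_windows, 2 * replicates))
    sf = np.ones(2 * replicates)
    res = diffcov.nb_wald_test(
        counts, sf, np.arange(replicates), np.arange(replicates, 2 * replicates), adjust=False
    )
    return float((res.pvalue < alpha).mean())
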