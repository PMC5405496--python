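"""Synthetic germline/somatic genome generator for programmed DNA elimination.

This module builds a germline ("MIC-like") genome with the statistical
structure that the downstream analysis assumes:

* a three-way compartment partition of every contig into MAC-destined,
  MIC-PGM and MIC-only intervals (kb-aligned by default so 1-kb window
  recovery is unambiguous);
* short TA-bounded IESs (lognormal lengths, median 51 nt, >=90% under
  100 nt) placed almost entirely in MAC-destined sequence;
* transposon copies drawn from a small synthetic consensus library,
  concentrated in MIC-PGM intervals;
* tandem-repeat (satellite) arrays, concentrated in MIC-only intervals.

Three derived genome views are produced with coordinate liftovers:

* ``somatic`` (MAC-like): IESs excised with one boundary TA retained, and
  every MIC-limited (MIC-PGM + MIC-only) interval deleted;
* ``pgm`` (PGM-silenced): only MIC-only intervals deleted — IESs and
  MIC-PGM sequence retained, emulating DNA from cells in which the
  excision endonuclease is depleted.

All randomness flows through one ``numpy`` Generator seeded explicitly, so
a (config, seed) pair is a complete, byte-reproducible description of the
genome and its ground-truth annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .seqcodes import decode, encode, mutate, random_codes, revcomp

MAC_DESTINED = "MAC_DESTINED"
MIC_PGM = "MIC_PGM"
MIC_ONLY = "MIC_ONLY"
COMPARTMENTS = (MAC_DESTINED, MIC_PGM, MIC_ONLY)


class GeneratorError(ValueError):
    """Raised for configurations the generator refuses to realize."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic genome.

    Lengths are nucleotides; fractions are of compartment base pairs.
    ``proportions`` are (MAC-destined, MIC-PGM, MIC-only) genome fractions
    and must sum to 1.  ``te_fraction``/``tr_fraction`` give the target
    transposon and tandem-repeat content per compartment in the same order;
    the defaults encode a x4 satellite enrichment and /3 transposon
    depletion of MIC-only relative to MIC-PGM.
    """

    total_length: int = 1_000_000
    n_contigs: int = 5
    proportions: tuple[float, float, float] = (0.80, 0.17, 0.03)
    gc: float = 0.28
    ies_per_mac_kb: float = 0.6
    ies_length_median: float = 51.0
    ies_length_sigma: float = 0.456
    ies_min_length: int = 10
    ies_max_length: int = 2000
    boundary: str = "TA"
    ies_mac_fraction: float = 0.98
    te_families: int = 3
    te_consensus_length: int = 1500
    te_min_copy_length: int = 200
    te_max_divergence: float = 0.08
    te_fraction: tuple[float, float, float] = (0.012, 0.21, 0.07)
    tr_fraction: tuple[float, float, float] = (0.008, 0.05, 0.20)
    tr_period_range: tuple[int, int] = (2, 10)
    tr_array_range: tuple[int, int] = (120, 800)
    tr_mut_rate: float = 0.01
    mic_pgm_block_kb: tuple[int, int] = (4, 16)
    mic_only_block_kb: tuple[int, int] = (2, 6)
    feature_margin: int = 150
    ragged: bool = False

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise GeneratorError(
                f"compartment proportions must sum to 1, got {self.proportions}"
            )
        if min(self.proportions) < 0:
            raise GeneratorError("compartment proportions must be non-negative")
        if self.total_length < 10_000:
            raise GeneratorError("total_length below 10 kb is not supported")
        if len(self.boundary) != 2:
            raise GeneratorError("boundary motif must be a dinucleotide")
        if not 0 <= self.ies_mac_fraction <= 1:
            raise GeneratorError("ies_mac_fraction must be in [0, 1]")
        # IESs must plausibly fit into MAC-destined sequence
        mac_bp = self.proportions[0] * self.total_length
        expect_ies_bp = self.ies_per_mac_kb * mac_bp / 1000 * self.ies_length_median * 1.6
        if expect_ies_bp > 0.5 * mac_bp:
            raise GeneratorError(
                "IES density/length too high: IESs cannot fit in MAC-destined intervals"
            )


@dataclass
class IesAnnotation:
    """One internal eliminated sequence on germline coordinates.

    ``start``/``end`` are 0-based half-open and include both boundary TA
    dinucleotides.  Under the one-TA-retained excision convention the
    excised segment is ``[start+2, end)``; ``left_boundary`` and
    ``right_boundary`` are the two germline excision junction coordinates.
    """

    id: str
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def left_boundary(self) -> int:
        return self.start + 2

    @property
    def right_boundary(self) -> int:
        return self.end


@dataclass
class TeCopy:
    contig: str
    start: int
    end: int
    family: str
    strand: str  # "+" or "-"


@dataclass
class TandemRepeat:
    contig: str
    start: int
    end: int
    period: int
    copies: float


@dataclass
class Liftover:
    """Bijective coordinate map between retained germline and derived positions.

    ``g2d[contig][i]`` is the derived-genome position of germline base ``i``
    or -1 if the base was deleted; ``d2g`` is the inverse.
    """

    g2d: dict[str, np.ndarray]
    d2g: dict[str, np.ndarray]

    def to_derived(self, contig: str, pos: int) -> int:
        return int(self.g2d[contig][pos])


@dataclass
class GenomeModel:
    """Germline genome plus annotations and derived genome views."""

    config: GeneratorConfig
    seed: int
    contigs: dict[str, np.ndarray]
    ies_set: list[IesAnnotation]
    te_copies: list[TeCopy]
    tandem_repeats: list[TandemRepeat]
    compartment_truth: list[tuple[str, int, int, str]]
    te_library: dict[str, np.ndarray]
    somatic_contigs: dict[str, np.ndarray] = field(default_factory=dict)
    pgm_contigs: dict[str, np.ndarray] = field(default_factory=dict)
    somatic_liftover: Liftover | None = None
    pgm_liftover: Liftover | None = None

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def sequence(self, contig: str) -> str:
        return decode(self.contigs[contig])

    def truth_intervals(self, label: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, lab in self.compartment_truth if lab == label]

    def compartment_bp(self) -> dict[str, int]:
        out = {lab: 0 for lab in COMPARTMENTS}
        for _, s, e, lab in self.compartment_truth:
            out[lab] += e - s
        return out


# ---------------------------------------------------------------------------
# compartment layout


def _layout_compartments(
    cfg: GeneratorConfig, rng: np.random.Generator, contig_kb: list[int]
) -> list[np.ndarray]:
    """Assign a compartment label to every kb unit of every contig.

    MIC-PGM and MIC-only blocks (contiguous runs of kb units) are dropped at
    random positions into an initially MAC-destined genome until the target
    kb totals are met.
    """
    total_kb = sum(contig_kb)
    targets = {
        MIC_PGM: int(round(cfg.proportions[1] * total_kb)),
        MIC_ONLY: int(round(cfg.proportions[2] * total_kb)),
    }
    labels = [np.zeros(kb, dtype=np.int8) for kb in contig_kb]  # 0 = MAC
    code = {MIC_PGM: 1, MIC_ONLY: 2}
    ranges = {MIC_PGM: cfg.mic_pgm_block_kb, MIC_ONLY: cfg.mic_only_block_kb}

    for lab in (MIC_PGM, MIC_ONLY):
        remaining = targets[lab]
        lo, hi = ranges[lab]
        while remaining > 0:
            size = min(int(rng.integers(lo, hi + 1)), remaining)
            placed = False
            for _ in range(300):
                ci = int(rng.integers(len(labels)))
                arr = labels[ci]
                if len(arr) < size + 2:
                    continue
                start = int(rng.integers(1, len(arr) - size))  # keep contig ends MAC
                if np.all(arr[start : start + size] == 0):
                    arr[start : start + size] = code[lab]
                    placed = True
                    break
            if not placed:
                # deterministic fallback: first free run anywhere
                for arr in labels:
                    free = np.flatnonzero(arr == 0)
                    if len(free) >= size:
                        runs = np.split(free, np.flatnonzero(np.diff(free) > 1) + 1)
                        for run in runs:
                            if len(run) >= size:
                                arr[run[0] : run[0] + size] = code[lab]
                                placed = True
                                break
                    if placed:
                        break
            if not placed:
                raise GeneratorError(f"could not place {lab} blocks; genome too small")
            remaining -= size
    return labels


def _labels_to_intervals(
    names: list[str], labels: list[np.ndarray], cfg: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[str, int, int, str]]:
    decode_lab = {0: MAC_DESTINED, 1: MIC_PGM, 2: MIC_ONLY}
    out: list[tuple[str, int, int, str]] = []
    for name, arr in zip(names, labels):
        bounds = [0, *((np.flatnonzero(np.diff(arr)) + 1) * 1000).tolist(), len(arr) * 1000]
        if cfg.ragged:
            # offset internal boundaries to exercise partial-window behaviour
            bounds = (
                [0]
                + [
                    max(1, b + int(rng.integers(-400, 401)))
                    for b in bounds[1:-1]
                ]
                + [len(arr) * 1000]
            )
            bounds = sorted(set(bounds))
        for s, e in zip(bounds[:-1], bounds[1:]):
            lab = decode_lab[int(arr[min(s // 1000, len(arr) - 1)])]
            if out and out[-1][0] == name and out[-1][3] == lab and out[-1][2] == s:
                out[-1] = (name, out[-1][1], e, lab)
            else:
                out.append((name, s, e, lab))
    return out


# ---------------------------------------------------------------------------
# feature planting


def _interval_sampler(intervals: list[tuple[int, str, int, int]], rng, weights):
    idx = rng.choice(len(intervals), p=weights)
    return intervals[idx]


def _plant_features(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    contigs: dict[str, np.ndarray],
    truth: list[tuple[str, int, int, str]],
):
    """Plant tandem-repeat arrays, TE copies and IESs into the raw sequence.

    Features never overlap each other (a shared occupancy tree per contig)
    and never cross a compartment boundary.
    """
    occupied = {name: IntervalTree() for name in contigs}
    by_label: dict[str, list[tuple[str, int, int]]] = {lab: [] for lab in COMPARTMENTS}
    for c, s, e, lab in truth:
        by_label[lab].append((c, s, e))

    def free_spot(length: int, label: str, margin: int) -> tuple[str, int] | None:
        ivs = by_label[label]
        if not ivs:
            return None
        lens = np.array([e - s for _, s, e in ivs], dtype=float)
        ok = lens >= length + 2 * margin
        if not ok.any():
            return None
        w = np.where(ok, lens, 0.0)
        w /= w.sum()
        for _ in range(200):
            c, s, e = ivs[int(rng.choice(len(ivs), p=w))]
            lo, hi = s + margin, e - margin - length
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if not occupied[c].overlap(pos - 2, pos + length + 2):
                occupied[c].addi(pos, pos + length)
                return c, pos
        return None

    comp_bp = {lab: sum(e - s for _, s, e in by_label[lab]) for lab in COMPARTMENTS}

    # --- tandem repeats
    tandem: list[TandemRepeat] = []
    for lab, frac in zip(COMPARTMENTS, cfg.tr_fraction):
        budget = frac * comp_bp[lab]
        while budget > 0:
            period = int(rng.integers(cfg.tr_period_range[0], cfg.tr_period_range[1] + 1))
            arr_len = int(rng.integers(*cfg.tr_array_range))
            arr_len = max(arr_len, 2 * period)
            spot = free_spot(arr_len, lab, 20)
            if spot is None:
                break
            c, pos = spot
            motif = random_codes(rng, period, cfg.gc)
            array = np.tile(motif, arr_len // period + 1)[:arr_len]
            contigs[c][pos : pos + arr_len] = mutate(rng, array, cfg.tr_mut_rate)
            tandem.append(TandemRepeat(c, pos, pos + arr_len, period, arr_len / period))
            budget -= arr_len

    # --- transposon copies
    library = {
        f"TE{f + 1}": random_codes(rng, cfg.te_consensus_length, cfg.gc)
        for f in range(cfg.te_families)
    }
    fams = list(library)
    tes: list[TeCopy] = []
    for lab, frac in zip(COMPARTMENTS, cfg.te_fraction):
        budget = frac * comp_bp[lab]
        while budget > 0:
            fam = fams[int(rng.integers(len(fams)))]
            cons = library[fam]
            if rng.random() < 0.5:
                copy_len = len(cons)
                cstart = 0
            else:
                copy_len = int(rng.integers(cfg.te_min_copy_length, len(cons) + 1))
                cstart = int(rng.integers(0, len(cons) - copy_len + 1))
            spot = free_spot(copy_len, lab, 20)
            if spot is None:
                break
            c, pos = spot
            seg = mutate(rng, cons[cstart : cstart + copy_len], rng.uniform(0, cfg.te_max_divergence))
            strand = "+"
            if rng.random() < 0.5:
                seg = revcomp(seg)
                strand = "-"
            contigs[c][pos : pos + copy_len] = seg
            tes.append(TeCopy(c, pos, pos + copy_len, fam, strand))
            budget -= copy_len

    # --- IESs
    n_ies = int(round(cfg.ies_per_mac_kb * comp_bp[MAC_DESTINED] / 1000))
    lengths = []
    while len(lengths) < n_ies:
        draw = rng.lognormal(np.log(cfg.ies_length_median), cfg.ies_length_sigma, n_ies)
        draw = draw[(draw >= cfg.ies_min_length) & (draw <= cfg.ies_max_length)]
        lengths.extend(int(round(x)) for x in draw)
    lengths = lengths[:n_ies]
    bnd = encode(cfg.boundary)
    ies_set: list[IesAnnotation] = []
    for i, length in enumerate(lengths):
        lab = MAC_DESTINED if rng.random() < cfg.ies_mac_fraction else MIC_PGM
        spot = free_spot(length, lab, cfg.feature_margin)
        if spot is None and lab == MIC_PGM:
            spot = free_spot(length, MAC_DESTINED, cfg.feature_margin)
        if spot is None:
            continue
        c, pos = spot
        contigs[c][pos : pos + 2] = bnd
        contigs[c][pos + length - 2 : pos + length] = bnd
        ies_set.append(IesAnnotation(f"IES.{c}.{i + 1}", c, pos, pos + length))
    if len(ies_set) < 0.9 * n_ies:
        raise GeneratorError("IESs cannot fit in MAC-destined intervals at this density")
    ies_set.sort(key=lambda a: (a.contig, a.start))
    return tandem, tes, ies_set, library


# ---------------------------------------------------------------------------
# public operations


def build_germline_genome(config: GeneratorConfig, seed: int) -> GenomeModel:
    """Generate the germline genome and all ground-truth annotations.

    Deterministic for a fixed (config, seed).  The derived somatic/PGM views
    are *not* populated; see :func:`derive_somatic_genome` / :func:`make_genome`.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    kb_each = config.total_length // config.n_contigs // 1000
    contig_kb = [kb_each] * config.n_contigs
    contig_kb[-1] += config.total_length // 1000 - kb_each * config.n_contigs
    names = [f"contig_{i + 1}" for i in range(config.n_contigs)]

    labels = _layout_compartments(config, rng, contig_kb)
    truth = _labels_to_intervals(names, labels, config, rng)
    contigs = {name: random_codes(rng, kb * 1000, config.gc) for name, kb in zip(names, contig_kb)}
    tandem, tes, ies_set, library = _plant_features(config, rng, contigs, truth)

    return GenomeModel(
        config=config,
        seed=seed,
        contigs=contigs,
        ies_set=ies_set,
        te_copies=tes,
        tandem_repeats=tandem,
        compartment_truth=truth,
        te_library=library,
    )


def _delete_intervals(
    contigs: dict[str, np.ndarray], deletions: dict[str, list[tuple[int, int]]]
) -> tuple[dict[str, np.ndarray], Liftover]:
    new_contigs: dict[str, np.ndarray] = {}
    g2d: dict[str, np.ndarray] = {}
    d2g: dict[str, np.ndarray] = {}
    for name, seq in contigs.items():
        keep = np.ones(len(seq), dtype=bool)
        for s, e in deletions.get(name, []):
            if keep[s:e].sum() != e - s:
                raise GeneratorError(f"overlapping deletion intervals on {name} at {s}-{e}")
            keep[s:e] = False
        idx = np.flatnonzero(keep)
        new_contigs[name] = seq[idx]
        fwd = np.full(len(seq), -1, dtype=np.int64)
        fwd[idx] = np.arange(len(idx))
        g2d[name] = fwd
        d2g[name] = idx.astype(np.int64)
    return new_contigs, Liftover(g2d, d2g)


def derive_somatic_genome(model: GenomeModel) -> GenomeModel:
    """Populate the somatic (MAC-like) and PGM genome views with liftovers.

    Somatic: every MIC-limited interval deleted and every MAC-destined IES
    excised as ``[start+2, end)`` (one boundary TA retained).  PGM: only
    MIC-only intervals deleted.
    """
    mic_limited: dict[str, list[tuple[int, int]]] = {}
    mic_only: dict[str, list[tuple[int, int]]] = {}
    for c, s, e, lab in model.compartment_truth:
        if lab in (MIC_PGM, MIC_ONLY):
            mic_limited.setdefault(c, []).append((s, e))
        if lab == MIC_ONLY:
            mic_only.setdefault(c, []).append((s, e))

    def inside_mic_limited(a: IesAnnotation) -> bool:
        for s, e in mic_limited.get(a.contig, []):
            if a.start >= s and a.end <= e:
                return True
            if a.start < e and a.end > s:
                raise GeneratorError(f"IES {a.id} partially overlaps a MIC-limited interval")
        return False

    somatic_dels: dict[str, list[tuple[int, int]]] = {
        c: list(v) for c, v in mic_limited.items()
    }
    for a in model.ies_set:
        if not inside_mic_limited(a):
            somatic_dels.setdefault(a.contig, []).append((a.start + 2, a.end))
    for v in somatic_dels.values():
        v.sort()

    model.somatic_contigs, model.somatic_liftover = _delete_intervals(model.contigs, somatic_dels)
    model.pgm_contigs, model.pgm_liftover = _delete_intervals(model.contigs, mic_only)
    return model


def make_genome(config: GeneratorConfig | None = None, seed: int = 0) -> GenomeModel:
    """Convenience: build the germline genome and derive all genome views."""
    return derive_somatic_genome(build_germline_genome(config or GeneratorConfig(), seed))


# ---------------------------------------------------------------------------
# text-format output


def write_fasta(path, contigs: dict[str, np.ndarray], seed: int | None = None, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            tag = f" seed={seed}" if seed is not None else ""
            fh.write(f">{name}{tag}\n")
            s = decode(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_ies_gff3(path, model: GenomeModel):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!seed {model.seed}\n")
        for a in model.ies_set:
            fh.write(
                f"{a.contig}\tmicmac\tinternal_eliminated_sequence\t{a.start + 1}\t{a.end}"
                f"\t.\t+\t.\tID={a.id}\n"
            )


def write_bed(path, rows: Sequence[tuple], seed: int | None = None):
    """Write (contig, start, end, *extras) rows as BED with a seed comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_ies_gff3(path) -> list[IesAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "internal_eliminated_sequence":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append(IesAnnotation(attrs.get("ID", "?"), f[0], int(f[3]) - 1, int(f[4])))
    return out


def write_generator_config(path, config: GeneratorConfig, seed: int):
    with open(path, "w") as fh:
        fh.write(f"# micmac generator config, seed={seed}\n")
        fh.write(f"seed={seed}\n")
        for f_ in dataclasses.fields(config):
            v = getattr(config, f_.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f_.name}={v}\n")
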