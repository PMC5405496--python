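"""Paired-end DNA-seq simulation from mixtures of genome copies.

Samples are mixtures of genome *views* (germline, somatic, PGM-silenced,
contaminant) at stated fold-coverages.  Fragment lengths are normal
(default 300 +/- 100 nt), fragment positions uniform within a contig, and
errors are uniform substitutions at a flat rate with a constant base
quality — the simplest model consistent with short-read mixtures of fully
and partially rearranged genomes.  Every read pair carries its provenance
(source view, contig, fragment interval), which downstream tests use as
ground truth.

The five study sample classes (control, unsorted/sorted PGM-silenced,
unsorted/sorted MIC-enriched) are expressed as the fraction ``f`` of genome
copies that retain all IESs: a sample at total coverage ``c`` is simulated
as germline at ``f*c`` plus somatic at ``(1-f)*c``, so that the expected
IES retention score equals ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .seqcodes import decode, mutate, random_codes, revcomp

GERMLINE = "GERMLINE"
SOMATIC = "SOMATIC"
PGM = "PGM"
CONTAMINANT = "CONTAMINANT"
SOURCES = (GERMLINE, SOMATIC, PGM, CONTAMINANT)

#: unexcised genome-copy fraction f for the five study sample classes
STUDY_SAMPLE_FRACTIONS: dict[str, float] = {
    "control": 0.0,
    "unsorted_PGM": 0.69,
    "sorted_PGM": 0.82,
    "unsorted_MIC": 0.04,
    "sorted_MIC": 0.38,
}


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 100.0
    substitution_rate: float = 0.002
    coverage: float = 50.0
    base_quality: int = 35
    seed: int = 0

    def validate(self) -> None:
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed read_length")


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture of genome views at given fold-coverages.

    ``components`` is a list of (source, coverage) with source one of
    GERMLINE/SOMATIC/PGM; ``contaminant_fraction`` is the fraction of read
    pairs drawn from a separate contaminant sequence set.
    """

    components: tuple[tuple[str, float], ...]
    contaminant_fraction: float = 0.0
    label: str = "sample"

    def validate(self) -> None:
        for src, cov in self.components:
            if src not in SOURCES:
                raise ValueError(f"unknown source {src!r}")
            if cov <= 0:
                raise ValueError("component coverages must be > 0")
        if not 0 <= self.contaminant_fraction <= 0.5:
            raise ValueError("contaminant_fraction must be in [0, 0.5]")


@dataclass
class ReadSet:
    """Simulated reads with per-read provenance.

    Reads are interleaved: rows ``2i`` and ``2i+1`` of ``reads`` are the two
    mates of pair ``i``, stored in sequencing orientation.  Per-read arrays
    (``pos``, ``strand``) are on the coordinates of the *source* genome view.
    """

    label: str
    read_length: int
    base_quality: int
    reads: np.ndarray  # (2*n_pairs, read_length) uint8
    source: np.ndarray  # per pair, index into SOURCES
    contig_idx: np.ndarray  # per pair
    frag_start: np.ndarray  # per pair
    frag_end: np.ndarray  # per pair
    pos: np.ndarray  # per read, leftmost position on source contig
    strand: np.ndarray  # per read, 0 = forward, 1 = reverse
    contig_names: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.source)

    @property
    def n_reads(self) -> int:
        return self.reads.shape[0]

    def read_name(self, row: int) -> str:
        return f"{self.label}:{row // 2}"

    def pair_sources(self) -> np.ndarray:
        return np.array([SOURCES[i] for i in self.source])

    def to_fastq(self, path1, path2) -> None:
        qual = chr(self.base_quality + 33) * self.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@{self.label}:{i}/1\n{decode(self.reads[2 * i])}\n+\n{qual}\n")
                f2.write(f"@{self.label}:{i}/2\n{decode(self.reads[2 * i + 1])}\n+\n{qual}\n")

    def provenance_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair\tsource\tcontig\tstart\tend\n")
            for i in range(self.n_pairs):
                fh.write(
                    f"{self.label}:{i}\t{SOURCES[self.source[i]]}\t"
                    f"{self.contig_names[self.contig_idx[i]] if self.contig_names else self.contig_idx[i]}\t"
                    f"{self.frag_start[i]}\t{self.frag_end[i]}\n"
                )


def _view(model: GenomeModel, source: str) -> dict[str, np.ndarray]:
    if source == GERMLINE:
        return model.contigs
    if source == SOMATIC:
        if not model.somatic_contigs:
            raise ValueError("somatic genome not derived; call derive_somatic_genome first")
        return model.somatic_contigs
    if source == PGM:
        if not model.pgm_contigs:
            raise ValueError("PGM genome not derived; call derive_somatic_genome first")
        return model.pgm_contigs
    raise ValueError(f"unknown source {source!r}")


def _simulate_component(
    rng: np.random.Generator,
    contigs: list[np.ndarray],
    n_pairs_per_contig: np.ndarray,
    cfg: ReadSimConfig,
):
    """Vectorised fragment + mate sampling for one mixture component."""
    R = cfg.read_length
    all_contig, all_start, all_end = [], [], []
    r1_list, r2_list = [], []
    for ci, (seq, n) in enumerate(zip(contigs, n_pairs_per_contig)):
        n = int(n)
        if n == 0:
            continue
        L = len(seq)
        flen = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n)).astype(np.int64)
        # resample out-of-range fragments (bounded retries, then clip)
        for _ in range(10):
            bad = (flen < R) | (flen > L)
            if not bad.any():
                break
            flen[bad] = np.rint(
                rng.normal(cfg.fragment_mean, cfg.fragment_sd, int(bad.sum()))
            ).astype(np.int64)
        np.clip(flen, R, L, out=flen)
        start = rng.integers(0, L - flen + 1)
        end = start + flen
        idx = np.arange(R)
        fwd = seq[start[:, None] + idx]  # 5' mate on forward strand
        rev = revcomp(seq[(end - R)[:, None] + idx])
        all_contig.append(np.full(n, ci, dtype=np.int32))
        all_start.append(start)
        all_end.append(end)
        r1_list.append(fwd)
        r2_list.append(rev)
    if not all_contig:
        z = np.zeros(0, dtype=np.int64)
        return z.astype(np.int32), z, z, np.zeros((0, R), np.uint8), np.zeros((0, R), np.uint8)
    contig = np.concatenate(all_contig)
    start = np.concatenate(all_start)
    end = np.concatenate(all_end)
    r1 = np.vstack(r1_list)
    r2 = np.vstack(r2_list)
    # with p=0.5 the fragment was sequenced from the other strand: swap mates
    swap = rng.random(len(contig)) < 0.5
    r1[swap], r2[swap] = r2[swap].copy(), r1[swap].copy()
    return contig, start, end, r1, r2, swap


def simulate_sample(
    model: GenomeModel,
    mix: MixtureSpec,
    cfg: ReadSimConfig,
    contaminant_contigs: dict[str, np.ndarray] | None = None,
) -> ReadSet:
    """Simulate one paired-end sample from a mixture of genome views.

    The expected pair count of each component is
    ``coverage * component_length / (2 * read_length)``.
    """
    cfg.validate()
    mix.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.read_length

    views = {}
    for src, _ in mix.components:
        views[src] = _view(model, src)
    contig_names = list(model.contigs)  # germline naming is the reference frame
    pieces = []

    def add_component(src: str, contigs_map: dict[str, np.ndarray], n_pairs: int):
        names = list(contigs_map)
        seqs = [contigs_map[n] for n in names]
        lens = np.array([len(s) for s in seqs], dtype=float)
        per_contig = rng.multinomial(n_pairs, lens / lens.sum())
        contig, start, end, r1, r2, swap = _simulate_component(rng, seqs, per_contig, cfg)
        pieces.append((src, names, contig, start, end, r1, r2, swap))

    total_pairs = 0
    for src, cov in mix.components:
        comp_len = sum(len(s) for s in views[src].values())
        n_pairs = int(round(cov * comp_len / (2 * R)))
        add_component(src, views[src], n_pairs)
        total_pairs += n_pairs

    if mix.contaminant_fraction > 0:
        if contaminant_contigs is None:
            contaminant_contigs = {
                "contaminant_1": random_codes(np.random.default_rng(cfg.seed + 77), 20_000, 0.5)
            }
        n_cont = int(round(mix.contaminant_fraction / (1 - mix.contaminant_fraction) * total_pairs))
        add_component(CONTAMINANT, contaminant_contigs, n_cont)

    n_all = sum(len(p[2]) for p in pieces)
    reads = np.empty((2 * n_all, R), dtype=np.uint8)
    source = np.empty(n_all, dtype=np.int8)
    contig_idx = np.empty(n_all, dtype=np.int32)
    frag_start = np.empty(n_all, dtype=np.int64)
    frag_end = np.empty(n_all, dtype=np.int64)
    pos = np.empty(2 * n_all, dtype=np.int64)
    strand = np.empty(2 * n_all, dtype=np.int8)

    off = 0
    for src, names, contig, start, end, r1, r2, swap in pieces:
        n = len(contig)
        sl = slice(off, off + n)
        source[sl] = SOURCES.index(src)
        contig_idx[sl] = contig
        frag_start[sl] = start
        frag_end[sl] = end
        reads[2 * off : 2 * (off + n) : 2] = r1
        reads[2 * off + 1 : 2 * (off + n) + 1 : 2] = r2
        # mate positions: un-swapped (r1 fwd at start, r2 rev at end-R); swapped inverse
        p1 = np.where(swap, end - R, start)
        p2 = np.where(swap, start, end - R)
        s1 = swap.astype(np.int8)  # swapped r1 is the reverse-strand mate
        s2 = 1 - s1
        pos[2 * off : 2 * (off + n) : 2] = p1
        pos[2 * off + 1 : 2 * (off + n) + 1 : 2] = p2
        strand[2 * off : 2 * (off + n) : 2] = s1
        strand[2 * off + 1 : 2 * (off + n) + 1 : 2] = s2
        off += n

    reads = mutate(rng, reads, cfg.substitution_rate)
    return ReadSet(
        label=mix.label,
        read_length=R,
        base_quality=cfg.base_quality,
        reads=reads,
        source=source,
        contig_idx=contig_idx,
        frag_start=frag_start,
        frag_end=frag_end,
        pos=pos,
        strand=strand,
        contig_names=contig_names,
    )


def mixture_for_fraction(f: float, coverage: float, label: str) -> MixtureSpec:
    """Mixture spec for an unexcised genome-copy fraction ``f`` at total coverage."""
    if not 0 <= f <= 1:
        raise ValueError("unexcised fraction must be in [0, 1]")
    comps = []
    if f > 0:
        comps.append((GERMLINE, f * coverage))
    if f < 1:
        comps.append((SOMATIC, (1 - f) * coverage))
    return MixtureSpec(components=tuple(comps), label=label)


def build_study_samples(
    model: GenomeModel,
    unexcised_fraction: dict[str, float] | None = None,
    cfg: ReadSimConfig | None = None,
) -> dict[str, ReadSet]:
    """Simulate the five study sample classes (or any label→fraction map)."""
    cfg = cfg or ReadSimConfig()
    fractions = dict(STUDY_SAMPLE_FRACTIONS if unexcised_fraction is None else unexcised_fraction)
    out = {}
    for i, (label, f) in enumerate(fractions.items()):
        if not 0 <= f <= 1:
            raise ValueError(f"fraction for {label!r} outside [0, 1]")
        sub = ReadSimConfig(
            read_length=cfg.read_length,
            fragment_mean=cfg.fragment_mean,
            fragment_sd=cfg.fragment_sd,
            substitution_rate=cfg.substitution_rate,
            coverage=cfg.coverage,
            base_quality=cfg.base_quality,
            seed=cfg.seed + 1000 * (i + 1),
        )
        out[label] = simulate_sample(model, mixture_for_fraction(f, cfg.coverage, label), sub)
    return out
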