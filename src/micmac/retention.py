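"""Per-IES retention scores by the boundary method.

A retention score estimates, for each IES, the fraction of sequenced
genome copies in which the element is still present.  Reads are aligned to
two references — the IES-containing (germline) assembly and the
IES-excised (somatic) assembly.  At each of the two IES boundaries, reads
crossing the germline junction (with at most ``max_mismatch`` mismatches
and at least ``min_overhang`` aligned nucleotides on both sides) support
the retained form (IES+); reads crossing the corresponding excision
junction on the somatic reference support the excised form (IES-).  The
single somatic junction serves both boundaries.

boundary score = plus / (plus + minus)      (undefined when no coverage)
retention score = mean of the defined boundary scores

0 means fully excised, 1 fully retained.  Reads supporting both forms of
the same IES (possible only for degenerate boundaries) are discarded.
Clipped alignments and mates are counted independently per boundary; no
fragment-level deduplication is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel, IesAnnotation
from .mapping import AlignmentTable


@dataclass
class RetentionRecord:
    ies_id: str
    left_plus: int = 0
    left_minus: int = 0
    right_plus: int = 0
    right_minus: int = 0
    excluded: bool = False  # not liftable to the somatic reference

    @property
    def left_score(self) -> float:
        n = self.left_plus + self.left_minus
        return self.left_plus / n if n else math.nan

    @property
    def right_score(self) -> float:
        n = self.right_plus + self.right_minus
        return self.right_plus / n if n else math.nan

    @property
    def retention_score(self) -> float:
        scores = [s for s in (self.left_score, self.right_score) if not math.isnan(s)]
        return sum(scores) / len(scores) if scores else math.nan

    @property
    def defined(self) -> bool:
        return not self.excluded and not math.isnan(self.retention_score)


class _JunctionCounter:
    """Sorted full-length alignment starts per contig for fast junction counts."""

    def __init__(self, table: AlignmentTable, max_mismatch: int):
        full = (
            table.mapped
            & (table.nm <= max_mismatch)
            & (table.clip_left == 0)
            & (table.clip_right == 0)
        )
        self.L = table.read_length
        self.by_contig: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        idx = np.flatnonzero(full)
        if len(idx) == 0:
            return
        order = np.lexsort((table.pos[idx], table.contig[idx]))
        idx = idx[order]
        contigs = table.contig[idx]
        bounds = np.flatnonzero(np.concatenate([[True], contigs[1:] != contigs[:-1]]))
        bounds = np.append(bounds, len(idx))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            ci = int(contigs[b0])
            self.by_contig[ci] = (table.pos[idx[b0:b1]], idx[b0:b1])

    def crossing(self, contig_index: int, junction: int, min_overhang: int):
        """Read rows whose alignment covers [junction-ov, junction+ov)."""
        if contig_index not in self.by_contig:
            return np.zeros(0, dtype=np.int64)
        pos, rows = self.by_contig[contig_index]
        lo = np.searchsorted(pos, junction + min_overhang - self.L, side="left")
        hi = np.searchsorted(pos, junction - min_overhang, side="right")
        return rows[lo:hi]


def count_boundary_reads(
    aln_germline: AlignmentTable,
    aln_somatic: AlignmentTable,
    model: GenomeModel,
    max_mismatch: int = 1,
    min_overhang: int = 5,
    ies_set: list[IesAnnotation] | None = None,
) -> list[RetentionRecord]:
    """Count IES+/IES- junction-supporting reads for every IES.

    Both alignment tables must come from the same read set (row-aligned),
    mapped to the germline and somatic references respectively.
    """
    ies_set = model.ies_set if ies_set is None else ies_set
    g_counter = _JunctionCounter(aln_germline, max_mismatch)
    s_counter = _JunctionCounter(aln_somatic, max_mismatch)
    g_names = aln_germline.contig_names
    s_names = aln_somatic.contig_names
    lift = model.somatic_liftover
    records = []
    for a in ies_set:
        rec = RetentionRecord(a.id)
        g2s = lift.g2d[a.contig]
        # somatic junction: immediately after the last retained base (the kept TA)
        anchor = g2s[a.start + 1]
        if anchor < 0:
            rec.excluded = True
            records.append(rec)
            continue
        s_junction = int(anchor) + 1
        gci = g_names.index(a.contig)
        sci = s_names.index(a.contig)
        left_plus = g_counter.crossing(gci, a.left_boundary, min_overhang)
        right_plus = g_counter.crossing(gci, a.right_boundary, min_overhang)
        minus = s_counter.crossing(sci, s_junction, min_overhang)
        # a read may not support both the retained and excised form
        both = np.intersect1d(np.union1d(left_plus, right_plus), minus)
        if len(both):
            left_plus = np.setdiff1d(left_plus, both)
            right_plus = np.setdiff1d(right_plus, both)
            minus = np.setdiff1d(minus, both)
        rec.left_plus = len(left_plus)
        rec.right_plus = len(right_plus)
        rec.left_minus = rec.right_minus = len(minus)
        records.append(rec)
    return records


@dataclass
class RetentionSummary:
    mean: float
    sd: float
    n_defined: int
    n_undefined: int
    histogram: np.ndarray  # counts over the fixed bin edges
    bin_edges: np.ndarray


HIST_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


def retention_summary(records: list[RetentionRecord]) -> RetentionSummary:
    """Mean/sd/histogram over *defined* records (fixed 0.05-wide bins)."""
    scores = np.array([r.retention_score for r in records if r.defined])
    n_undef = len(records) - len(scores)
    if len(scores) == 0:
        raise ValueError(
            f"all {len(records)} retention records are undefined (no junction coverage)"
        )
    hist, _ = np.histogram(scores, bins=HIST_EDGES)
    return RetentionSummary(
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        n_defined=len(scores),
        n_undefined=n_undef,
        histogram=hist,
        bin_edges=HIST_EDGES,
    )


def write_retention_tsv(path, records: list[RetentionRecord], seed: int | None = None):
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(
            "ies_id\tleft_plus\tleft_minus\tright_plus\tright_minus"
            "\tleft_score\tright_score\tretention_score\n"
        )
        for r in records:
            fh.write(
                f"{r.ies_id}\t{r.left_plus}\t{r.left_minus}\t{r.right_plus}\t{r.right_minus}"
                f"\t{r.left_score:.4f}\t{r.right_score:.4f}\t{r.retention_score:.4f}\n"
            )
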