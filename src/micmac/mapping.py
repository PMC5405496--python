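"""Seed-and-extend ungapped read mapping with mismatch accounting.

The mapper serves the role an external short-read aligner plays in real
pipelines: exact k-mer seeds (default k=21) at ``max_mismatches + 1``
evenly spaced offsets guarantee, by pigeonhole, that every ungapped hit
with at most ``max_mismatches`` substitutions is found whenever
``read_length >= (max_mismatches + 1) * k``.  Candidate loci are verified
by vectorised Hamming counting against the concatenated reference.

Mapping quality: 60 for a best hit that is unique by a margin of >=2
mismatches, 30 for a margin of 1, 0 for a tie.  Downstream "uniquely
mapped" filters use mapq >= 30.

Reads with no full-length hit (typically reads spanning an excision
junction of the *other* genome view) optionally fall back to a clipped
prefix/suffix alignment, emulating the soft-clipping of local-mode
aligners; clipped alignments never contribute to junction-support counts
but do contribute to depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .seqcodes import encode, revcomp

logger = logging.getLogger(__name__)

UNMAPPED = -1


@dataclass
class Alignment:
    """A single ungapped (possibly end-clipped) alignment."""

    read_id: str
    contig: str
    start: int  # 0-based, of the first aligned base
    strand: str  # "+" or "-"
    mismatch_count: int
    mapq: int
    clip_left: int = 0
    clip_right: int = 0
    aligned_length: int = 0
    mate: "Alignment | None" = None
    base_quality: int = 35


class AlignmentTable:
    """Structure-of-arrays of best alignments, one row per input read.

    ``pos`` is the contig-local position of the first *aligned* base.
    Unmapped reads have ``contig == -1``.
    """

    __slots__ = (
        "contig_names",
        "contig",
        "pos",
        "strand",
        "nm",
        "mapq",
        "clip_left",
        "clip_right",
        "read_length",
        "base_quality",
    )

    def __init__(self, contig_names, n_reads, read_length, base_quality=35):
        self.contig_names = list(contig_names)
        self.contig = np.full(n_reads, UNMAPPED, dtype=np.int32)
        self.pos = np.zeros(n_reads, dtype=np.int64)
        self.strand = np.zeros(n_reads, dtype=np.int8)
        self.nm = np.zeros(n_reads, dtype=np.int16)
        self.mapq = np.zeros(n_reads, dtype=np.int16)
        self.clip_left = np.zeros(n_reads, dtype=np.int16)
        self.clip_right = np.zeros(n_reads, dtype=np.int16)
        self.read_length = read_length
        self.base_quality = base_quality

    def __len__(self):
        return len(self.contig)

    @property
    def mapped(self) -> np.ndarray:
        return self.contig != UNMAPPED

    @property
    def aligned_length(self) -> np.ndarray:
        return self.read_length - self.clip_left.astype(np.int64) - self.clip_right

    @property
    def end(self) -> np.ndarray:
        """Exclusive end of the aligned segment on the contig."""
        return self.pos + self.aligned_length


class SeedIndex:
    """Exact k-mer index over both strands of a reference (forward stored;
    reads are also queried as reverse complements)."""

    def __init__(self, contigs: dict[str, np.ndarray | str], k: int = 21, max_hits: int = 256):
        if not contigs:
            raise ValueError("empty contig set")
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        self.k = k
        self.max_hits = max_hits
        self.names = list(contigs)
        arrays = [encode(contigs[n]) for n in self.names]
        for name, arr in zip(self.names, arrays):
            if len(arr) < k:
                warnings.warn(f"contig {name!r} shorter than k={k}: indexed as unalignable")
        self.lengths = np.array([len(a) for a in arrays], dtype=np.int64)
        sep = np.full(1, 4, dtype=np.uint8)
        parts = []
        offsets = []
        off = 0
        for arr in arrays:
            offsets.append(off)
            parts.append(arr)
            parts.append(sep)
            off += len(arr) + 1
        self.ref = np.concatenate(parts) if parts else sep
        self.offsets = np.array(offsets, dtype=np.int64)

        codes = self.ref.astype(np.int64)
        n = len(codes) - k + 1
        if n <= 0:
            self.sorted_keys = np.zeros(0, dtype=np.int64)
            self.sorted_pos = np.zeros(0, dtype=np.int64)
            return
        key = np.zeros(n, dtype=np.int64)
        for j in range(k):
            key = (key << 2) | (codes[j : j + n] & 3)
        bad = np.cumsum(np.concatenate([[0], (self.ref >= 4).astype(np.int64)]))
        invalid = (bad[k:] - bad[:-k]) > 0
        valid_pos = np.flatnonzero(~invalid)
        keys = key[valid_pos]
        order = np.argsort(keys, kind="stable")
        self.sorted_keys = keys[order]
        self.sorted_pos = valid_pos[order]

    def global_to_contig(self, gpos: np.ndarray):
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci, gpos - self.offsets[ci]

    def contig_to_global(self, contig_index: int, pos: int) -> int:
        return int(self.offsets[contig_index] + pos)


def index_reference(contigs: dict[str, np.ndarray | str], k: int = 21) -> SeedIndex:
    """Build a :class:`SeedIndex` over a contig set."""
    return SeedIndex(contigs, k=k)


def _read_keys(mat: np.ndarray, off: int, k: int) -> np.ndarray:
    codes = mat[:, off : off + k].astype(np.int64)
    key = np.zeros(len(mat), dtype=np.int64)
    for j in range(k):
        key = (key << 2) | (codes[:, j] & 3)
    # reads containing non-ACGT in the seed window get an impossible key
    key[(mat[:, off : off + k] >= 4).any(axis=1)] = -1
    return key


def _candidates_for(index: SeedIndex, mat: np.ndarray, offsets) -> tuple[np.ndarray, np.ndarray]:
    """All (read, global_start) candidate loci from exact seed hits."""
    n, L = mat.shape
    rid_parts, pos_parts = [], []
    for off in offsets:
        q = _read_keys(mat, off, index.k)
        lo = np.searchsorted(index.sorted_keys, q, side="left")
        hi = np.searchsorted(index.sorted_keys, q, side="right")
        counts = np.minimum(hi - lo, index.max_hits)
        tot = int(counts.sum())
        if tot == 0:
            continue
        rid = np.repeat(np.arange(n), counts)
        cum = np.concatenate([[0], np.cumsum(counts)])
        within = np.arange(tot) - np.repeat(cum[:-1], counts)
        hitpos = index.sorted_pos[np.repeat(lo, counts) + within]
        start = hitpos - off
        ok = start >= 0
        rid_parts.append(rid[ok])
        pos_parts.append(start[ok])
    if not rid_parts:
        z = np.zeros(0, dtype=np.int64)
        return z, z
    rid = np.concatenate(rid_parts)
    start = np.concatenate(pos_parts)
    # in-bounds within a single contig
    ci = np.searchsorted(index.offsets, start, side="right") - 1
    ok = (start - index.offsets[ci] + L) <= index.lengths[ci]
    rid, start = rid[ok], start[ok]
    packed = rid * np.int64(len(index.ref) + L + 1) + start
    packed = np.unique(packed)
    return packed // np.int64(len(index.ref) + L + 1), packed % np.int64(len(index.ref) + L + 1)


def _hamming(index: SeedIndex, mat: np.ndarray, rid, start, chunk=200_000) -> np.ndarray:
    L = mat.shape[1]
    nm = np.empty(len(rid), dtype=np.int32)
    idx = np.arange(L)
    for i in range(0, len(rid), chunk):
        sl = slice(i, i + chunk)
        window = index.ref[start[sl].reshape(-1, 1) + idx]
        nm[sl] = (window != mat[rid[sl]]).sum(axis=1)
    return nm


def _clip_candidate(read_codes, window, max_mm):
    """Best prefix or suffix ungapped alignment with <= max_mm mismatches.

    Returns (clip_left, clip_right, nm) of the kept segment, or None.
    """
    diff = np.flatnonzero(window != read_codes)
    L = len(read_codes)
    if len(diff) <= max_mm:
        return 0, 0, len(diff)
    # prefix: ends before the (max_mm+1)-th mismatch
    plen = int(diff[max_mm])
    pnm = max_mm
    while plen > 0 and pnm > 0 and diff[pnm - 1] == plen - 1:
        plen -= 1
        pnm -= 1
    # suffix: starts after the (max_mm+1)-th mismatch from the right
    sstart = int(diff[-(max_mm + 1)]) + 1
    snm = max_mm
    while sstart < L and snm > 0 and diff[-snm] == sstart:
        sstart += 1
        snm -= 1
    slen = L - sstart
    if plen >= slen:
        return 0, L - plen, pnm
    return sstart, 0, snm


def map_reads(
    index: SeedIndex,
    reads: np.ndarray,
    max_mismatches: int = 3,
    clip_fallback: bool = True,
    min_clip_aligned: int = 30,
    base_quality: int = 35,
) -> AlignmentTable:
    """Map a batch of reads (uint8 matrix) returning the best hit per read.

    Deterministic: ties are broken by (contig order, coordinate, strand).
    """
    n, L = reads.shape
    k = index.k
    n_seeds = max_mismatches + 1
    if L < n_seeds * k:
        n_seeds = max(1, L // k)
    offsets = np.unique(np.linspace(0, L - k, n_seeds).astype(int))

    table = AlignmentTable(index.names, n, L, base_quality)
    rc = revcomp(reads)
    best_nm = np.full(n, 10**6, dtype=np.int64)
    best_pos = np.zeros(n, dtype=np.int64)
    best_strand = np.zeros(n, dtype=np.int8)
    second_nm = np.full(n, 10**6, dtype=np.int64)
    cand_store = []  # for clip fallback

    for strand, mat in ((0, reads), (1, rc)):
        rid, start = _candidates_for(index, mat, offsets)
        if len(rid) == 0:
            continue
        nm = _hamming(index, mat, rid, start)
        cand_store.append((strand, rid, start, nm))
        order = np.lexsort((start, nm, rid))
        rid_o, start_o, nm_o = rid[order], start[order], nm[order]
        first = np.concatenate([[True], rid_o[1:] != rid_o[:-1]])
        f_idx = np.flatnonzero(first)
        r1 = rid_o[f_idx]
        # best hit this strand
        upd = nm_o[f_idx] < best_nm[r1]
        tie = nm_o[f_idx] == best_nm[r1]
        # strand-level merge keeps earlier (forward) on equal nm; record as second
        second_nm[r1[tie]] = np.minimum(second_nm[r1[tie]], nm_o[f_idx][tie])
        second_nm[r1[upd]] = np.minimum(second_nm[r1[upd]], best_nm[r1[upd]])
        best_nm[r1[upd]] = nm_o[f_idx][upd]
        best_pos[r1[upd]] = start_o[f_idx][upd]
        best_strand[r1[upd]] = strand
        # second-best within this strand
        nxt = f_idx + 1
        has_next = nxt < len(rid_o)
        nxt = nxt[has_next]
        same = rid_o[nxt] == r1[has_next]
        r2 = rid_o[nxt][same]
        second_nm[r2] = np.minimum(second_nm[r2], nm_o[nxt][same])

    hit = best_nm <= max_mismatches
    margin = second_nm - best_nm
    mapq = np.where(margin >= 2, 60, np.where(margin == 1, 30, 0)).astype(np.int16)
    ci, local = index.global_to_contig(best_pos)
    table.contig[hit] = ci[hit]
    table.pos[hit] = local[hit]
    table.strand[hit] = best_strand[hit]
    table.nm[hit] = best_nm[hit]
    table.mapq[hit] = mapq[hit]

    if clip_fallback:
        _clip_unmapped(
            index, reads, rc, table, ~hit, cand_store, max_mismatches, min_clip_aligned
        )
    return table


def _clip_unmapped(index, reads, rc, table, need, cand_store, max_mm, min_aligned):
    """Clipped prefix/suffix rescue for reads without a full-length hit."""
    need_idx = np.flatnonzero(need)
    if len(need_idx) == 0:
        return
    need_set = np.zeros(len(reads), dtype=bool)
    need_set[need_idx] = True
    per_read: dict[int, list[tuple[int, int, int]]] = {}
    for strand, rid, start, nm in cand_store:
        sel = need_set[rid]
        for r, s, m in zip(rid[sel], start[sel], nm[sel]):
            per_read.setdefault(int(r), []).append((int(m), int(s), strand))
    L = reads.shape[1]
    idx = np.arange(L)
    for r, cands in per_read.items():
        cands.sort()
        best = None  # (neg aligned_len, clip_l, clip_r, nm, start, strand)
        n_best = 0
        for m, s, strand in cands[:8]:
            mat = reads if strand == 0 else rc
            window = index.ref[s + idx]
            res = _clip_candidate(mat[r], window, max_mm)
            if res is None:
                continue
            cl, cr, nm2 = res
            alen = L - cl - cr
            if alen < min_aligned:
                continue
            key = (-alen, nm2, s, strand)
            if best is None or key < best[0]:
                best = (key, cl, cr, nm2, s, strand)
                n_best = 1
            elif key[0] == best[0][0] and key[1] == best[0][1]:
                n_best += 1
        if best is None:
            continue
        _, cl, cr, nm2, s, strand = best
        ci = int(np.searchsorted(index.offsets, s, side="right") - 1)
        table.contig[r] = ci
        table.pos[r] = s - index.offsets[ci] + cl
        table.strand[r] = strand
        table.nm[r] = nm2
        table.clip_left[r] = cl
        table.clip_right[r] = cr
        table.mapq[r] = 60 if n_best == 1 else 0


def map_read(
    index: SeedIndex, read: str | np.ndarray, max_mismatches: int = 3
) -> list[Alignment]:
    """Map a single read, returning *all* hits with <= max_mismatches.

    Hits are sorted by (mismatch_count, contig order, coordinate, strand);
    mapq is 60/30/0 by the uniqueness-margin rule, identical on tied hits.
    """
    codes = encode(read)
    if len(codes) < index.k:
        raise ValueError("read shorter than seed length")
    L = len(codes)
    n_seeds = min(max_mismatches + 1, max(1, L // index.k))
    offsets = np.unique(np.linspace(0, L - index.k, n_seeds).astype(int))
    hits = []
    for strand, mat in ((0, codes[None, :]), (1, revcomp(codes)[None, :])):
        rid, start = _candidates_for(index, mat, offsets)
        if len(rid) == 0:
            continue
        nm = _hamming(index, mat, rid, start)
        for s, m in zip(start, nm):
            if m <= max_mismatches:
                hits.append((int(m), int(s), strand))
    hits.sort()
    if not hits:
        return []
    best = hits[0][0]
    n_at_best = sum(1 for h in hits if h[0] == best)
    second = hits[1][0] if len(hits) > 1 else 10**6
    if n_at_best > 1:
        q = 0
    elif second - best >= 2:
        q = 60
    else:
        q = 30
    out = []
    for m, s, strand in hits:
        ci, local = index.global_to_contig(np.array([s]))
        out.append(
            Alignment(
                read_id="read",
                contig=index.names[int(ci[0])],
                start=int(local[0]),
                strand="+-"[strand],
                mismatch_count=m,
                mapq=q if m == best else 0,
                aligned_length=L,
            )
        )
    return out


def map_readset(index: SeedIndex, rs, max_mismatches: int = 3, clip_fallback: bool = True) -> AlignmentTable:
    """Map every read of a ReadSet (both mates) against the index."""
    return map_reads(
        index,
        rs.reads,
        max_mismatches=max_mismatches,
        clip_fallback=clip_fallback,
        base_quality=rs.base_quality,
    )
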