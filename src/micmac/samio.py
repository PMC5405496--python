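"""SAM read/write so external aligners can substitute the built-in mapper.

Alignments are ungapped with optional end clipping, so CIGARs are of the
form ``[xS] nM [yS]``.  Mates are paired by adjacent rows of the read set
(rows 2i and 2i+1); the proper-pair flag is set when both mates map to the
same contig in FR orientation with an insert within 4 SD of the fragment
mean.  Externally produced coordinate-sorted SAM/BAM (including gapped
records) can be imported; only positions, mapq, NM and clipping are used
downstream.
"""

from __future__ import annotations

import numpy as np
import pysam

from .mapping import UNMAPPED, AlignmentTable
from .seqcodes import decode


def write_sam(
    path,
    table: AlignmentTable,
    readset,
    contig_lengths: dict[str, int],
    fragment_mean: float = 300.0,
    fragment_sd: float = 100.0,
) -> None:
    """Write the best alignments of a ReadSet as a SAM file with @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(contig_lengths[n])} for n in table.contig_names],
    }
    L = table.read_length
    qual_char = chr(readset.base_quality + 33)
    n = len(table)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n):
            mate = i ^ 1
            a = pysam.AlignedSegment(out.header)
            a.query_name = readset.read_name(i)
            seq = decode(readset.reads[i])
            mapped = table.contig[i] != UNMAPPED
            m_mapped = mate < n and table.contig[mate] != UNMAPPED
            flag = 0x1 | (0x40 if i % 2 == 0 else 0x80)
            if not mapped:
                flag |= 0x4
            if not m_mapped:
                flag |= 0x8
            if mapped and table.strand[i]:
                flag |= 0x10
            if m_mapped and table.strand[mate]:
                flag |= 0x20
            proper = (
                mapped
                and m_mapped
                and table.contig[i] == table.contig[mate]
                and table.strand[i] != table.strand[mate]
            )
            tlen = 0
            if proper:
                lo = min(int(table.pos[i]) - int(table.clip_left[i]),
                         int(table.pos[mate]) - int(table.clip_left[mate]))
                hi = max(int(table.end[i]) + int(table.clip_right[i]),
                         int(table.end[mate]) + int(table.clip_right[mate]))
                tlen = hi - lo
                if abs(tlen - fragment_mean) > 4 * fragment_sd:
                    proper = False
            if proper:
                flag |= 0x2
            a.flag = flag
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual_char * L)
            if mapped:
                a.reference_id = int(table.contig[i])
                a.reference_start = int(table.pos[i])
                a.mapping_quality = int(table.mapq[i])
                cl, cr = int(table.clip_left[i]), int(table.clip_right[i])
                cig = []
                if cl:
                    cig.append((4, cl))
                cig.append((0, L - cl - cr))
                if cr:
                    cig.append((4, cr))
                a.cigartuples = cig
                a.set_tag("NM", int(table.nm[i]))
            if m_mapped:
                a.next_reference_id = int(table.contig[mate])
                a.next_reference_start = int(table.pos[mate])
                if proper:
                    sign = 1 if table.pos[i] <= table.pos[mate] else -1
                    a.template_length = sign * tlen
            out.write(a)


def read_sam(path) -> tuple[AlignmentTable, list[str]]:
    """Read a SAM/BAM into an AlignmentTable (one row per record, in file order).

    Gapped CIGARs are accepted: the aligned span is taken from the reference
    consumption; insertions count toward clipping bookkeeping only loosely.
    Returns the table and the per-row read names.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        names = list(fh.references)
        records = list(fh)
    L = max((r.query_length or 0) for r in records) if records else 0
    table = AlignmentTable(names, len(records), L)
    read_names: list[str] = []
    for i, r in enumerate(records):
        read_names.append(r.query_name + ("/1" if r.is_read1 else "/2" if r.is_read2 else ""))
        if r.is_unmapped or r.reference_id < 0:
            continue
        table.contig[i] = r.reference_id
        table.pos[i] = r.reference_start
        table.strand[i] = 1 if r.is_reverse else 0
        table.mapq[i] = r.mapping_quality
        table.nm[i] = r.get_tag("NM") if r.has_tag("NM") else 0
        cig = r.cigartuples or []
        cl = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
        cr = cig[-1][1] if len(cig) > 1 and cig[-1][0] in (4, 5) else 0
        span = sum(ln for op, ln in cig if op in (0, 2, 7, 8))  # reference consumed
        table.clip_left[i] = cl
        table.clip_right[i] = L - cl - span if L else cr
        if r.query_qualities is not None and len(r.query_qualities):
            table.base_quality = int(r.query_qualities[0])
    return table, read_names
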