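"""Windowed depth: 1-kb tiling, quality-filtered pileup, normalization,
per-nucleotide compartment thresholding, and the two-sample density grid.

Depth counts aligned (non-clipped) bases from alignments with
mapq >= ``min_mapq`` whose base quality passes ``min_baseq`` — the same
filters as ``samtools depth -q 30 -Q 30``.  Contigs are tiled with
non-overlapping 1-kb windows; a terminal remainder is kept only when
longer than 400 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mapping import AlignmentTable

MIC_LIMITED_LABEL = "MIC_LIMITED"
MAC_DESTINED_LABEL = "MAC_DESTINED"


def make_windows(
    contig_lengths: dict[str, int], size: int = 1000, min_end: int = 401
) -> pd.DataFrame:
    """Tile contigs with non-overlapping windows.

    Full ``size``-nt windows, plus a terminal remainder kept iff its length
    is at least ``min_end`` (default 401, i.e. strictly more than 400 nt).
    """
    rows = []
    for name, L in contig_lengths.items():
        if L < 1:
            raise ValueError(f"contig {name!r} has non-positive length")
        n_full = L // size
        for i in range(n_full):
            rows.append((name, i * size, (i + 1) * size))
        rem = L - n_full * size
        if rem >= min_end:
            rows.append((name, n_full * size, L))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def per_nt_depth(
    table: AlignmentTable,
    contig_lengths: dict[str, int],
    min_baseq: int = 30,
    min_mapq: int = 30,
) -> dict[str, np.ndarray]:
    """Per-nucleotide depth per contig under the quality filters.

    The simulator emits a single constant base quality per read, so the
    base-quality filter accepts or rejects whole reads.
    """
    depth = {name: np.zeros(L + 1, dtype=np.int64) for name, L in contig_lengths.items()}
    ok = table.mapped & (table.mapq >= min_mapq)
    if table.base_quality < min_baseq:
        ok &= False
    idx = np.flatnonzero(ok)
    starts = table.pos[idx]
    ends = table.end[idx]
    contigs = table.contig[idx]
    for ci, name in enumerate(table.contig_names):
        if name not in depth:
            continue
        sel = contigs == ci
        d = depth[name]
        np.add.at(d, starts[sel], 1)
        np.add.at(d, ends[sel], -1)
    return {name: np.cumsum(d[:-1]) for name, d in depth.items()}


def window_depth(
    table: AlignmentTable,
    windows: pd.DataFrame,
    contig_lengths: dict[str, int],
    min_baseq: int = 30,
    min_mapq: int = 30,
    depth: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean raw depth per window (same order as ``windows``)."""
    if depth is None:
        depth = per_nt_depth(table, contig_lengths, min_baseq, min_mapq)
    out = np.empty(len(windows), dtype=float)
    csums = {name: np.concatenate([[0], np.cumsum(d)]) for name, d in depth.items()}
    for i, (c, s, e) in enumerate(zip(windows["contig"], windows["start"], windows["end"])):
        if c not in csums or e > contig_lengths[c]:
            raise ValueError(f"window {c}:{s}-{e} outside contig")
        cs = csums[c]
        out[i] = (cs[e] - cs[s]) / (e - s)
    return out


def sample_nt_sequenced(readset, exclude_contaminants: bool = True) -> int:
    """Total sequenced nucleotides of a simulated sample, optionally after
    excluding provenance-tagged contaminant read pairs."""
    from .readsim import CONTAMINANT, SOURCES

    n_pairs = readset.n_pairs
    if exclude_contaminants:
        n_pairs -= int((readset.source == SOURCES.index(CONTAMINANT)).sum())
    return int(n_pairs) * 2 * readset.read_length


def normalize_depth(raw: np.ndarray | float, sample_nt: float, reference_nt: float = 1e9):
    """Scale depth by sequencing effort: normalized = raw * reference_nt / sample_nt.

    Any fixed ``reference_nt`` preserves between-sample ratios; the default
    1e9 is recorded in output metadata.
    """
    if sample_nt <= 0:
        raise ValueError("sample_nt must be positive (zero non-contaminant nucleotides?)")
    return np.asarray(raw, dtype=float) * (reference_nt / sample_nt)


def classify_nt_by_depth(
    depth: dict[str, np.ndarray], threshold: float = 20.0
) -> dict[str, np.ndarray]:
    """Per-nucleotide label from somatic-sample depth: < threshold → MIC-limited.

    Returns boolean arrays (True = MIC_LIMITED) per contig.
    """
    return {name: d < threshold for name, d in depth.items()}


def nt_class_intervals(classified: dict[str, np.ndarray]) -> list[tuple[str, int, int, str]]:
    """Merge per-nucleotide labels into (contig, start, end, label) runs."""
    out = []
    for name, mask in classified.items():
        if len(mask) == 0:
            continue
        change = np.flatnonzero(np.diff(mask.astype(np.int8)))
        bounds = np.concatenate([[0], change + 1, [len(mask)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            lab = MIC_LIMITED_LABEL if mask[s] else MAC_DESTINED_LABEL
            out.append((name, int(s), int(e), lab))
    return out


def unique_read_counts(
    table: AlignmentTable, windows: pd.DataFrame, min_mapq: int = 30
) -> np.ndarray:
    """Uniquely-mapped read count per window.

    A read is assigned to the window containing its leftmost aligned base;
    reads landing in a dropped terminal remainder are not counted.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    ok = table.mapped & (table.mapq >= min_mapq)
    idx = np.flatnonzero(ok)
    name_to_ci = {n: i for i, n in enumerate(table.contig_names)}
    for c, grp in windows.groupby("contig", sort=False):
        ci = name_to_ci.get(c)
        if ci is None:
            continue
        sel = idx[table.contig[idx] == ci]
        pos = np.sort(table.pos[sel])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        counts[grp.index] = hi - lo
    return counts


@dataclass
class DensityGrid:
    counts: np.ndarray  # (nx, ny)
    xedges: np.ndarray
    yedges: np.ndarray


def depth_density_grid(depth_a: np.ndarray, depth_b: np.ndarray, bin_edges) -> DensityGrid:
    """2-D histogram of windows over (depth_a, depth_b).

    Both depth vectors must come from the same window list.
    """
    depth_a = np.asarray(depth_a, float)
    depth_b = np.asarray(depth_b, float)
    if depth_a.shape != depth_b.shape:
        raise ValueError("mismatched window lists")
    if isinstance(bin_edges, tuple):
        xe, ye = bin_edges
    else:
        xe = ye = np.asarray(bin_edges, float)
    counts, xe, ye = np.histogram2d(depth_a, depth_b, bins=(xe, ye))
    return DensityGrid(counts, xe, ye)


def count_modes(grid: DensityGrid, smooth: int = 3, min_rel: float = 0.15) -> int:
    """Number of local maxima of the smoothed density grid.

    A mode is a cell greater than or equal to its 8-neighbourhood after a
    uniform ``smooth`` x ``smooth`` filter and reaching at least
    ``min_rel`` of the height of the dominant mode — a relative rule, so
    the count does not depend on the absolute number of windows or the
    bin width.
    """
    z = ndimage.uniform_filter(grid.counts.astype(float), size=smooth, mode="constant")
    mx = ndimage.maximum_filter(z, size=3, mode="constant")
    peaks = (z == mx) & (z >= min_rel * z.max()) & (z > 0)
    # collapse plateaus: count connected components of the peak mask
    _, n = ndimage.label(peaks)
    return int(n)
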