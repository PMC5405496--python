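"""Per-compartment sequence characterization and enrichment tests.

Covers GC content, low-complexity masking (poly-purine/pyrimidine runs and
windows of extreme AT/GC content), a simplified tandem-repeat finder
(seeded period detection with +2/-7 match/mismatch extension), a
simplified consensus-library repeat masker (k-mer seeded ungapped local
matches), IES-to-window assignment, and base-pair-level exact binomial
enrichment tests between compartments.

The binomial tests treat nucleotides as independent trials, which is
anti-conservative for clustered features; the resulting p-values are for
ranking and directional claims, exactly as bp-level genome composition
tests are normally used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcodes import encode, revcomp

# ---------------------------------------------------------------------------
# GC and low complexity


def gc_content(seq: str | np.ndarray) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases excluded from the denominator.

    Returns NaN for an all-ambiguous (or empty denominator) sequence.
    """
    codes = encode(seq)
    if len(codes) == 0:
        raise ValueError("empty sequence")
    acgt = int((codes < 4).sum())
    if acgt == 0:
        return math.nan
    gcs = int(((codes == 1) | (codes == 2)).sum())
    return gcs / acgt


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def mask_low_complexity(
    seq: str | np.ndarray,
    window: int = 100,
    at_max: float = 0.87,
    gc_max: float = 0.89,
    min_run: int = 30,
) -> list[tuple[int, int]]:
    """Low-complexity intervals: extreme-composition windows and purine runs.

    A sliding ``window`` is masked when its AT fraction strictly exceeds
    ``at_max`` or its GC fraction strictly exceeds ``gc_max``; in addition,
    poly-purine and poly-pyrimidine runs of at least ``min_run`` nt are
    masked.  Overlapping intervals are merged.
    """
    codes = encode(seq)
    n = len(codes)
    iv: list[tuple[int, int]] = []
    if n >= window:
        is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
        is_at = ((codes == 0) | (codes == 3)).astype(np.int64)
        cg = np.concatenate([[0], np.cumsum(is_gc)])
        ca = np.concatenate([[0], np.cumsum(is_at)])
        gc_frac = (cg[window:] - cg[:-window]) / window
        at_frac = (ca[window:] - ca[:-window]) / window
        hits = np.flatnonzero((at_frac > at_max) | (gc_frac > gc_max))
        iv.extend((int(h), int(h) + window) for h in hits)
    for klass in (((codes == 0) | (codes == 2)), ((codes == 1) | (codes == 3))):
        # purine (A/G) and pyrimidine (C/T) runs
        x = klass.astype(np.int8)
        change = np.flatnonzero(np.diff(x))
        bounds = np.concatenate([[0], change + 1, [n]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if x[s] and e - s >= min_run:
                iv.append((int(s), int(e)))
    return _merge_intervals(iv)


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass
class TandemArray:
    start: int
    end: int
    period: int
    copies: float
    score: int


def _best_segment(w: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment (start, end, score), vectorised."""
    ps = np.concatenate([[0], np.cumsum(w)])
    m = np.minimum.accumulate(ps)
    amin = np.where(ps == m, np.arange(len(ps)), -1)
    amin = np.maximum.accumulate(amin)
    gains = ps[1:] - m[:-1]
    j = int(np.argmax(gains))
    return int(amin[j]), j + 1, int(gains[j])


def _extend_period(codes: np.ndarray, pos: int, period: int, match: int, mismatch: int, max_span: int):
    """Best-scoring segment of the self-alignment at lag ``period`` around pos.

    Works on the match series m[j] = (s[j] == s[j-period]); returns
    (array_start, array_end, score) where the array spans one period before
    the matched region.
    """
    n = len(codes)
    lo = max(period, pos - max_span)
    hi = min(n, pos + max_span)
    m = codes[lo:hi] == codes[lo - period : hi - period]
    w = np.where(m, match, mismatch).astype(np.int64)
    best_s, best_e, best = _best_segment(w)
    return lo + best_s - period, lo + best_e, best


def find_tandem_repeats(
    seq: str | np.ndarray,
    max_period: int = 500,
    min_copies: float = 2.0,
    min_score: int = 50,
    match: int = 2,
    mismatch: int = -7,
    seed_k: int = 10,
    max_span: int = 5000,
) -> list[TandemArray]:
    """Seeded tandem-repeat detection with match/mismatch extension.

    Candidate periods come from recurring ``seed_k``-mers at distances up
    to ``max_period``; each candidate is extended by maximising the
    +match/-mismatch score of the lag-``period`` self-comparison.  Arrays
    with score >= ``min_score`` and >= ``min_copies`` copies are reported;
    overlapping calls are resolved by score, then smaller period, then
    leftmost position.
    """
    codes = encode(seq)
    n = len(codes)
    if n < 2 * seed_k:
        return []
    # rolling seed keys
    key = np.zeros(n - seed_k + 1, dtype=np.int64)
    c64 = codes.astype(np.int64)
    for j in range(seed_k):
        key = (key << 2) | (c64[j : j + n - seed_k + 1] & 3)
    order = np.argsort(key, kind="stable")
    ks = key[order]
    same = np.flatnonzero(ks[1:] == ks[:-1])
    prev_pos = order[same]
    cur_pos = order[same + 1]
    # argsort is stable so equal keys keep genomic order only within ties of
    # the sort; enforce orientation
    a = np.minimum(prev_pos, cur_pos)
    b = np.maximum(prev_pos, cur_pos)
    d = b - a
    sel = (d >= 2) & (d <= max_period)
    cands = sorted(zip(b[sel].tolist(), d[sel].tolist()))

    arrays: list[TandemArray] = []
    covered_until: dict[int, int] = {}
    for pos, period in cands:
        if covered_until.get(period, -1) >= pos:
            continue
        s, e, score = _extend_period(codes, pos, period, match, mismatch, max_span)
        covered_until[period] = e
        copies = (e - s) / period
        if score >= min_score and copies >= min_copies:
            arrays.append(TandemArray(int(s), int(e), int(period), float(copies), score))

    # resolve overlaps: best score, then smallest period, then leftmost
    arrays.sort(key=lambda t: (-t.score, t.period, t.start))
    kept: list[TandemArray] = []
    for t in arrays:
        if all(t.end <= u.start or t.start >= u.end for u in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


# ---------------------------------------------------------------------------
# TE masking


@dataclass
class TeMatch:
    start: int
    end: int
    family: str
    strand: str
    identity: float


def _seed_hits(codes: np.ndarray, cons: np.ndarray, k: int):
    """(genome_pos, consensus_pos) pairs of exact shared k-mers."""
    def keys(arr):
        m = len(arr) - k + 1
        if m <= 0:
            return np.zeros(0, dtype=np.int64)
        out = np.zeros(m, dtype=np.int64)
        a64 = arr.astype(np.int64)
        for j in range(k):
            out = (out << 2) | (a64[j : j + m] & 3)
        return out

    gk = keys(codes)
    ck = keys(cons)
    order = np.argsort(ck, kind="stable")
    cs = ck[order]
    lo = np.searchsorted(cs, gk, "left")
    hi = np.searchsorted(cs, gk, "right")
    counts = hi - lo
    tot = int(counts.sum())
    if tot == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    gpos = np.repeat(np.arange(len(gk)), counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    within = np.arange(tot) - np.repeat(cum[:-1], counts)
    cpos = order[np.repeat(lo, counts) + within]
    return gpos, cpos


def mask_tes(
    seq: str | np.ndarray,
    consensus_library: dict[str, str | np.ndarray],
    min_identity: float = 0.80,
    min_length: int = 80,
    seed_k: int = 13,
) -> list[TeMatch]:
    """Ungapped local matches of a consensus library against a sequence.

    Seeds (shared exact k-mers, both strands) are grouped by diagonal; each
    diagonal is verified by a banded ungapped comparison, keeping the best
    segment with identity >= ``min_identity`` over >= ``min_length`` nt
    (+1/-4 match/mismatch scoring, i.e. an 80% identity density cut-off).
    Overlaps are resolved per position by the best-scoring family.
    """
    import warnings

    codes = encode(seq)
    n = len(codes)
    raw: list[TeMatch] = []
    for fam, cons in consensus_library.items():
        cons = encode(cons)
        if len(cons) < min_length:
            warnings.warn(f"consensus {fam!r} shorter than min_length; skipped")
            continue
        for strand, carr in (("+", cons), ("-", revcomp(cons))):
            gpos, cpos = _seed_hits(codes, carr, seed_k)
            if len(gpos) == 0:
                continue
            diags = np.unique(gpos - cpos)
            for d in diags:
                g0 = max(0, int(d))
                g1 = min(n, int(d) + len(carr))
                if g1 - g0 < min_length:
                    continue
                m = codes[g0:g1] == carr[g0 - int(d) : g1 - int(d)]
                w = np.where(m, 1, -4).astype(np.int64)
                best_s, best_e, best = _best_segment(w)
                length = best_e - best_s
                if length < min_length:
                    continue
                ident = float(m[best_s:best_e].mean())
                if ident >= min_identity:
                    raw.append(TeMatch(g0 + best_s, g0 + best_e, fam, strand, ident))
    # resolve overlaps: keep best (identity*length) first
    raw.sort(key=lambda t: (-(t.end - t.start) * t.identity, t.start))
    kept: list[TeMatch] = []
    for t in raw:
        if all(t.end <= u.start or t.start >= u.end for u in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


# ---------------------------------------------------------------------------
# compartment assignment and enrichment


def assign_ies_to_compartments(
    ies_set,
    window_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each IES to the window containing its start position.

    ``window_calls`` needs columns contig/start/end/label.  IESs whose
    start falls in no window (dropped terminal remainders) are counted
    under the label ``"unassigned"``.  Returns per-label IES counts and bp.
    """
    counts: dict[str, int] = {}
    bp: dict[str, int] = {}
    by_contig = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(), g["label"].to_numpy())
        for c, g in window_calls.groupby("contig", sort=False)
    }
    for a in ies_set:
        lab = "unassigned"
        if a.contig in by_contig:
            starts, ends, labels = by_contig[a.contig]
            i = np.searchsorted(starts, a.start, side="right") - 1
            if i >= 0 and a.start < ends[i]:
                lab = labels[i]
        counts[lab] = counts.get(lab, 0) + 1
        bp[lab] = bp.get(lab, 0) + a.length
    return pd.DataFrame(
        {"label": list(counts), "n_ies": list(counts.values()), "ies_bp": [bp[k] for k in counts]}
    ).set_index("label")


def compartment_enrichment_test(
    feature_bp_a: int, total_bp_a: int, feature_bp_b: int, total_bp_b: int
) -> float:
    """Two-sided exact binomial p for feature content of A versus B.

    The null proportion is B's feature fraction; the test asks whether
    observing ``feature_bp_a`` of ``total_bp_a`` base pairs is compatible
    with it (two-sided by summation of outcomes no more likely than the
    observation).
    """
    if total_bp_a <= 0 or total_bp_b <= 0:
        raise ValueError("compartment totals must be positive")
    if feature_bp_a > total_bp_a or feature_bp_b > total_bp_b:
        raise ValueError("feature bp cannot exceed total bp")
    p0 = feature_bp_b / total_bp_b
    if p0 in (0.0, 1.0):
        p0 = min(max(p0, 0.5 / total_bp_b), 1 - 0.5 / total_bp_b)
    return float(stats.binomtest(int(feature_bp_a), int(total_bp_a), p0).pvalue)


def interval_bp_in(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Base pairs of (already merged) intervals falling inside [lo, hi)."""
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in intervals)


def composition_table(
    contigs: dict[str, np.ndarray],
    window_calls: pd.DataFrame,
    ies_set,
    te_library: dict[str, np.ndarray],
    tr_kwargs: dict | None = None,
    te_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Compartment x feature composition matrix (bp and fractions).

    Runs the tandem-repeat and TE detectors and the low-complexity masker
    on every contig, then aggregates masked bp per compartment label of
    ``window_calls`` along with GC content and IES counts.
    """
    tr_kwargs = tr_kwargs or {}
    te_kwargs = te_kwargs or {}
    feats: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for name, seq in contigs.items():
        feats[name] = {
            "tandem": _merge_intervals(
                [(t.start, t.end) for t in find_tandem_repeats(seq, **tr_kwargs)]
            ),
            "te": _merge_intervals([(t.start, t.end) for t in mask_tes(seq, te_library, **te_kwargs)]),
            "lowc": mask_low_complexity(seq),
        }
    labels = sorted(window_calls["label"].unique())
    rows = []
    gc_codes = {lab: [0, 0] for lab in labels}  # gc, acgt
    agg = {lab: {"bp": 0, "tandem": 0, "te": 0, "lowc": 0} for lab in labels}
    for _, w in window_calls.iterrows():
        lab = w["label"]
        agg[lab]["bp"] += w["end"] - w["start"]
        for feat in ("tandem", "te", "lowc"):
            agg[lab][feat] += interval_bp_in(feats[w["contig"]][feat], w["start"], w["end"])
        codes = contigs[w["contig"]][w["start"] : w["end"]]
        gc_codes[lab][0] += int(((codes == 1) | (codes == 2)).sum())
        gc_codes[lab][1] += int((codes < 4).sum())
    ies_df = assign_ies_to_compartments(ies_set, window_calls)
    for lab in labels:
        bp = agg[lab]["bp"]
        rows.append(
            {
                "label": lab,
                "bp": bp,
                "fraction_of_windows": bp / window_calls.eval("end-start").sum(),
                "gc": gc_codes[lab][0] / max(gc_codes[lab][1], 1),
                "tandem_bp": agg[lab]["tandem"],
                "tandem_frac": agg[lab]["tandem"] / max(bp, 1),
                "te_bp": agg[lab]["te"],
                "te_frac": agg[lab]["te"] / max(bp, 1),
                "low_complexity_frac": agg[lab]["lowc"] / max(bp, 1),
                "n_ies": int(ies_df["n_ies"].get(lab, 0)),
            }
        )
    return pd.DataFrame(rows).set_index("label")
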