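"""Sequence characterization: GC, low-complexity thresholds, the tandem
repeat detector, consensus masking, IES assignment, and the exact binomial
enrichment test against a pmf-enumeration oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micmac.composition import (
    assign_ies_to_compartments,
    compartment_enrichment_test,
    find_tandem_repeats,
    gc_content,
    interval_bp_in,
    mask_low_complexity,
    mask_tes,
)
from micmac.genome import IesAnnotation
from micmac.seqcodes import decode, random_codes, revcomp_str


# --- GC -------------------------------------------------------------------

def test_gc_content_examples(rng):
    assert gc_content("ATGC") == 0.5
    assert gc_content("AAAA") == 0.0
    assert gc_content("ANGN") == 0.5  # Ns excluded from the denominator
    assert math.isnan(gc_content("NNN"))
    with pytest.raises(ValueError):
        gc_content("")
    seq = decode(random_codes(rng, 10_000, gc=0.28))
    sd = np.sqrt(0.28 * 0.72 / 10_000)
    assert abs(gc_content(seq) - 0.28) < 3 * sd


# --- low complexity -------------------------------------------------------

def _with_at(n, frac, r):
    """n-nt sequence with an exact AT fraction."""
    n_at = int(round(frac * n))
    bases = ["A"] * n_at + ["G"] * (n - n_at)
    r.shuffle(bases)
    return "".join(bases)


def test_low_complexity_at_threshold_strict():
    r = np.random.default_rng(1)
    hot = _with_at(100, 0.90, r)
    cold = _with_at(100, 0.87, r)
    pad = "ACGT" * 50  # 50% AT padding
    assert any(s <= 200 < e or (s < 300 and e > 200) for s, e in mask_low_complexity(pad + hot + pad))
    # exactly 87% is NOT masked (strict inequality); avoid purine-run hits
    masked = mask_low_complexity(pad + cold + pad, min_run=10**6)
    assert masked == []


def test_low_complexity_purine_run():
    r = np.random.default_rng(2)
    run = "".join(r.choice(["A", "G"], 40))
    # embed in alternating purine/pyrimidine context so only the run masks
    seq = "ACTG" * 30 + run + "ACTG" * 30
    masked = mask_low_complexity(seq, min_run=30)
    assert any(e - s >= 40 for s, e in masked)


# --- tandem repeats -------------------------------------------------------

def test_tandem_perfect_dimer(rng):
    seq = decode(random_codes(rng, 2000, 0.4)) + "AC" * 25 + decode(random_codes(rng, 2000, 0.4))
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    t = arrays[0]
    assert t.period == 2 and t.copies >= 24
    assert 1995 <= t.start <= 2005 and 2045 <= t.end <= 2055


def test_tandem_null_random_sequence(rng):
    seq = decode(random_codes(rng, 10_000, 0.5))
    assert find_tandem_repeats(seq) == []


def test_tandem_pentamer_with_substitution():
    base = "ACGTT" * 12
    mutated = base[:31] + ("G" if base[31] != "G" else "C") + base[32:]
    r = np.random.default_rng(3)
    seq = decode(random_codes(r, 1500, 0.4)) + mutated + decode(random_codes(r, 1500, 0.4))
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    t = arrays[0]
    assert t.period == 5
    # rescoring oracle with the stated +2/-7 weights over the reported span
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = codes[t.start + t.period : t.end] == codes[t.start : t.end - t.period]
    score = int(np.where(m, 2, -7).sum())
    assert score == t.score and score >= 50


def test_tandem_strand_symmetry(rng):
    seq = decode(random_codes(rng, 1000, 0.4)) + "ACGTT" * 12 + decode(random_codes(rng, 1000, 0.4))
    fwd = find_tandem_repeats(seq)
    rev = find_tandem_repeats(revcomp_str(seq))
    assert len(fwd) == len(rev) == 1
    assert fwd[0].period == rev[0].period
    assert fwd[0].end - fwd[0].start == rev[0].end - rev[0].start


# --- TE masking -----------------------------------------------------------

@pytest.fixture(scope="module")
def te_setup():
    r = np.random.default_rng(4)
    cons = random_codes(r, 600, 0.3)
    genome = random_codes(r, 8000, 0.3)
    return r, cons, genome


def test_te_exact_copy_recovered(te_setup):
    r, cons, genome = te_setup
    g = genome.copy()
    g[3000:3600] = cons
    hits = mask_tes(g, {"fam1": cons})
    assert len(hits) == 1
    h = hits[0]
    assert abs(h.start - 3000) <= 5 and abs(h.end - 3600) <= 5
    assert h.family == "fam1" and h.strand == "+" and h.identity > 0.99


def test_te_diverged_copy_recovered(te_setup):
    r, cons, genome = te_setup
    g = genome.copy()
    copy = cons.copy()
    mut = r.choice(600, size=90, replace=False)  # 85% identity
    copy[mut] = (copy[mut] + 1) % 4
    g[1000:1600] = copy
    hits = mask_tes(g, {"fam1": cons})
    assert any(h.start < 1600 and h.end > 1000 and h.identity >= 0.80 for h in hits)


def test_te_reverse_complement_copy(te_setup):
    from micmac.seqcodes import revcomp

    r, cons, genome = te_setup
    g = genome.copy()
    g[5000:5600] = revcomp(cons)
    hits = mask_tes(g, {"fam1": cons})
    assert any(h.strand == "-" and abs(h.start - 5000) <= 5 for h in hits)


def test_te_short_consensus_skipped(te_setup):
    _, _, genome = te_setup
    with pytest.warns(UserWarning):
        assert mask_tes(genome, {"tiny": "ACGTACGT"}) == []


# --- IES assignment -------------------------------------------------------

def test_assign_ies_window_conventions():
    calls = pd.DataFrame(
        {
            "contig": ["c", "c"],
            "start": [0, 1000],
            "end": [1000, 2000],
            "label": ["MAC_DESTINED", "MIC_PGM"],
        }
    )
    ies = [
        IesAnnotation("a", "c", 1000, 1060),  # start exactly at window boundary
        IesAnnotation("b", "c", 10, 70),
        IesAnnotation("d", "c", 2500, 2560),  # beyond all windows
    ]
    out = assign_ies_to_compartments(ies, calls)
    assert out.loc["MIC_PGM", "n_ies"] == 1
    assert out.loc["MAC_DESTINED", "n_ies"] == 1
    assert out.loc["unassigned", "n_ies"] == 1
    assert assign_ies_to_compartments([], calls).empty


# --- enrichment test ------------------------------------------------------

def _binom_two_sided_oracle(k, n, p0):
    """Two-sided exact p by summing outcomes no more likely than observed."""
    pk = stats.binom.pmf(k, n, p0)
    return sum(
        stats.binom.pmf(i, n, p0) for i in range(n + 1) if stats.binom.pmf(i, n, p0) <= pk * (1 + 1e-9)
    )


@pytest.mark.parametrize("k,n,p0", [(5, 10, 0.2), (0, 10, 0.5), (10, 10, 0.9), (3, 17, 0.33)])
def test_binomial_matches_enumeration_oracle(k, n, p0):
    p = compartment_enrichment_test(k, n, int(round(p0 * 1000)), 1000)
    oracle = _binom_two_sided_oracle(k, n, int(round(p0 * 1000)) / 1000)
    assert p == pytest.approx(oracle, abs=1e-12)


def test_binomial_identity_and_monotonicity():
    assert compartment_enrichment_test(200, 1000, 200, 1000) >= 0.95
    ps = [compartment_enrichment_test(200 + d, 1000, 200, 1000) for d in (0, 40, 80, 120)]
    assert all(a >= b for a, b in zip(ps[:-1], ps[1:]))
    with pytest.raises(ValueError):
        compartment_enrichment_test(5, 0, 1, 10)


def test_interval_bp_in():
    iv = [(0, 10), (20, 30)]
    assert interval_bp_in(iv, 5, 25) == 10
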