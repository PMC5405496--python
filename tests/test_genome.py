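"""Generator invariants: compartment bookkeeping, IES geometry, determinism."""

import numpy as np
import pytest

from micmac.genome import (
    MAC_DESTINED,
    MIC_ONLY,
    MIC_PGM,
    GeneratorConfig,
    GeneratorError,
    IesAnnotation,
    build_germline_genome,
    derive_somatic_genome,
    make_genome,
    read_ies_gff3,
    write_fasta,
    write_ies_gff3,
)
from micmac.seqcodes import decode, encode


def test_compartment_proportions_and_partition(small_model):
    """Truth intervals partition each contig and realize the configured ratios."""
    bp = small_model.compartment_bp()
    total = sum(small_model.contig_lengths.values())
    assert sum(bp.values()) == total
    for lab, target in zip((MAC_DESTINED, MIC_PGM, MIC_ONLY), small_model.config.proportions):
        assert abs(bp[lab] / total - target) < 0.02
    # no overlap, no gap, per contig
    for name, L in small_model.contig_lengths.items():
        ivs = sorted((s, e) for c, s, e, _ in small_model.compartment_truth if c == name)
        assert ivs[0][0] == 0 and ivs[-1][1] == L
        for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
            assert e1 == s2


def test_determinism_same_seed(tmp_path):
    cfg = GeneratorConfig(total_length=50_000, n_contigs=1)
    a = make_genome(cfg, seed=5)
    b = make_genome(cfg, seed=5)
    for name in a.contigs:
        assert np.array_equal(a.contigs[name], b.contigs[name])
        assert np.array_equal(a.somatic_contigs[name], b.somatic_contigs[name])
    assert [x.id for x in a.ies_set] == [x.id for x in b.ies_set]
    # byte-identical FASTA
    write_fasta(tmp_path / "a.fa", a.contigs, seed=5)
    write_fasta(tmp_path / "b.fa", b.contigs, seed=5)
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


def test_ies_length_distribution(small_model):
    """Median within [45, 57] and >=90% below 100 nt; all TA-bounded."""
    lengths = np.array([a.length for a in small_model.ies_set])
    assert len(lengths) >= 50
    assert 45 <= np.median(lengths) <= 57
    assert (lengths < 100).mean() >= 0.90
    assert lengths.min() >= 10
    for a in small_model.ies_set:
        seq = decode(small_model.contigs[a.contig][a.start : a.end])
        assert seq.startswith("TA") and seq.endswith("TA")


def test_ies_placement_in_mac_destined(small_model):
    mac = {
        (c, s, e)
        for c, s, e, lab in small_model.compartment_truth
        if lab == MAC_DESTINED
    }
    in_mac = 0
    total_nt = 0
    for a in small_model.ies_set:
        total_nt += a.length
        if any(c == a.contig and s <= a.start and a.end <= e for c, s, e in mac):
            in_mac += a.length
    assert in_mac / total_nt >= 0.95


def test_excision_convention_single_ies():
    """Germline AAATA[ccc]TAGGG with IES TAcccTA excises to AAATAGGG."""
    cfg = GeneratorConfig(total_length=10_000, n_contigs=1)
    model = build_germline_genome(cfg, seed=1)
    # overwrite with a tiny hand-built case on fresh structures
    model.contigs = {"c": encode("AAATACCCTAGGG")}
    model.compartment_truth = [("c", 0, 13, MAC_DESTINED)]
    model.ies_set = [IesAnnotation("ies1", "c", 3, 10)]
    model.te_copies, model.tandem_repeats = [], []
    derive_somatic_genome(model)
    assert decode(model.somatic_contigs["c"]) == "AAATAGGG"
    # liftover bijection around the junction
    lift = model.somatic_liftover
    assert lift.g2d["c"][4] == 4 and lift.g2d["c"][5] == -1 and lift.g2d["c"][10] == 5


def test_somatic_identity_without_features():
    cfg = GeneratorConfig(
        total_length=20_000,
        n_contigs=1,
        proportions=(1.0, 0.0, 0.0),
        ies_per_mac_kb=0.0,
        te_fraction=(0, 0, 0),
        tr_fraction=(0, 0, 0),
    )
    model = make_genome(cfg, seed=3)
    assert decode(model.somatic_contigs["contig_1"]) == decode(model.contigs["contig_1"])


def test_somatic_roundtrip_and_bookkeeping(small_model):
    """Excise-then-reinsert restores the germline; lengths balance exactly."""
    m = small_model
    mic_nt = m.compartment_bp()[MIC_PGM] + m.compartment_bp()[MIC_ONLY]
    mic_ivs = {lab: m.truth_intervals(lab) for lab in (MIC_PGM, MIC_ONLY)}

    def in_mic(a):
        return any(
            c == a.contig and s <= a.start and a.end <= e
            for lab in mic_ivs
            for c, s, e in mic_ivs[lab]
        )

    excised_ies_nt = sum(a.length - 2 for a in m.ies_set if not in_mic(a))
    g = sum(m.contig_lengths.values())
    s = sum(len(v) for v in m.somatic_contigs.values())
    assert g == s + excised_ies_nt + mic_nt
    # round-trip: somatic equals germline restricted to retained positions
    for name in m.contigs:
        kept = m.somatic_liftover.d2g[name]
        assert np.array_equal(m.contigs[name][kept], m.somatic_contigs[name])
        fwd = m.somatic_liftover.g2d[name]
        retained = np.flatnonzero(fwd >= 0)
        assert np.array_equal(fwd[retained], np.arange(len(kept)))  # bijection


def test_pgm_view_deletes_only_mic_only(small_model):
    m = small_model
    only_nt = m.compartment_bp()[MIC_ONLY]
    g = sum(m.contig_lengths.values())
    p = sum(len(v) for v in m.pgm_contigs.values())
    assert g == p + only_nt


def test_invalid_configs_rejected():
    with pytest.raises(GeneratorError):
        GeneratorConfig(proportions=(0.5, 0.4, 0.2)).validate()
    with pytest.raises(GeneratorError):
        GeneratorConfig(ies_per_mac_kb=50.0).validate()


def test_gff3_roundtrip(tmp_path, small_model):
    path = tmp_path / "ies.gff3"
    write_ies_gff3(path, small_model)
    back = read_ies_gff3(path)
    assert [(a.id, a.contig, a.start, a.end) for a in back] == [
        (a.id, a.contig, a.start, a.end) for a in small_model.ies_set
    ]
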