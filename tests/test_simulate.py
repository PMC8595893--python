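"""Simulator: haplotype construction, read projection, determinism, evaluation."""

import hashlib

import numpy as np
import pysam
import pytest

from crypticsv.junctiondb import SVType
from crypticsv.simulate import (
    Haplotype,
    SimConfig,
    TruthVariant,
    default_repeat_panel,
    evaluate_against_truth,
    implant_svs,
    make_targets,
    random_dna,
    simulate_reads,
)
from crypticsv.splitread import ReadFilterParams, extract_split_reads

CHROM = "chr1"


@pytest.fixture(scope="module")
def ref():
    return random_dna(np.random.default_rng(2), 200_000)


def _cfg(**kw):
    base = dict(
        seed=5,
        ref_length=200_000,
        n_targets=20,
        error_rate=0.0,
        artifact_clip_rate=0.0,
        n_artifact_sites=0,
    )
    base.update(kw)
    return SimConfig(**base)


def _var(svtype, start, length, seq=None, family=None):
    return TruthVariant(
        svtype=svtype, chrom=CHROM, start=start, length=length, carrier="MOTHER",
        inserted_seq=seq, repeat_family=family,
    )


def test_zero_variants_identity(ref):
    hap, truth = implant_svs(ref, [])
    assert hap.seq == ref and truth == []
    assert hap.blocks == [(0, 0, len(ref))]


def test_deletion_length_conservation(ref):
    hap, _ = implant_svs(ref, [_var(SVType.DEL, 50_000, 100)])
    assert len(hap.seq) == len(ref) - 100
    assert hap.seq[49_990:50_010] == ref[49_990:50_000] + ref[50_100:50_110]


def test_duplication_doubles_segment(ref):
    hap, _ = implant_svs(ref, [_var(SVType.DUP, 60_000, 80)])
    assert len(hap.seq) == len(ref) + 80
    assert hap.seq[60_000:60_160] == ref[60_000:60_080] * 2


def test_mei_insert_matches_panel_exactly(ref):
    panel = default_repeat_panel()
    ins = panel["Alu"][20:]
    hap, _ = implant_svs(ref, [_var(SVType.MEI, 70_000, len(ins), seq=ins, family="Alu")])
    assert len(hap.seq) == len(ref) + len(ins)
    assert ins in hap.seq
    assert hap.seq[70_000 : 70_000 + len(ins)] == ins


def test_overlapping_variants_rejected(ref):
    with pytest.raises(ValueError, match="overlap"):
        implant_svs(ref, [_var(SVType.DEL, 1000, 500), _var(SVType.DEL, 1200, 50)])


def test_projection_roundtrip_outside_variants(ref):
    variants = [
        _var(SVType.DEL, 30_000, 200),
        _var(SVType.INS, 80_000, 50, seq=random_dna(np.random.default_rng(3), 50)),
        _var(SVType.DUP, 120_000, 120),
    ]
    hap, _ = implant_svs(ref, variants)
    rng = np.random.default_rng(4)
    for ref_pos in rng.integers(0, len(ref), 500):
        ref_pos = int(ref_pos)
        inside = any(
            v.start <= ref_pos < v.start + (v.length if v.svtype is SVType.DEL else 0)
            for v in variants
        )
        images = hap.ref_to_hap(ref_pos)
        if inside:
            assert images == []
        else:
            assert images, f"ref position {ref_pos} lost"
            for hp in images:
                assert hap.hap_to_ref(hp) == ref_pos
                assert hap.seq[hp] == ref[ref_pos]


def test_length_bookkeeping(ref):
    variants = [
        _var(SVType.DEL, 30_000, 333),
        _var(SVType.DUP, 60_000, 75),
        _var(SVType.INS, 90_000, 41, seq=random_dna(np.random.default_rng(6), 41)),
    ]
    hap, _ = implant_svs(ref, variants)
    assert len(hap.seq) - len(ref) == sum(v.signed_len() for v in variants)


def test_same_seed_gives_byte_identical_bam(tmp_path, ref):
    cfg = _cfg(error_rate=0.001, artifact_clip_rate=0.005, n_artifact_sites=3)
    targets = make_targets(cfg)
    hap, _ = implant_svs(ref, [_var(SVType.DEL, targets[5][0] + 80, 120)])
    ref_hap = Haplotype(seq=ref, blocks=[(0, 0, len(ref))])
    digests = []
    for name in ("a.bam", "b.bam"):
        path = tmp_path / name
        simulate_reads([hap, ref_hap], cfg, targets, ref, path, "S1", np.random.default_rng(77))
        digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
    assert digests[0] == digests[1]


def test_perfect_data_has_no_clips(tmp_path, ref):
    cfg = _cfg()
    targets = make_targets(cfg)
    ref_hap = Haplotype(seq=ref, blocks=[(0, 0, len(ref))])
    bam = tmp_path / "clean.bam"
    simulate_reads([ref_hap, ref_hap], cfg, targets, ref, bam, "S1", np.random.default_rng(8))
    with pysam.AlignmentFile(str(bam)) as af:
        n = 0
        for read in af.fetch():
            n += 1
            assert read.cigartuples == [(0, cfg.read_len)]
            # error-free reads must match the reference verbatim
            assert read.query_sequence == ref[read.reference_start : read.reference_start + cfg.read_len]
    assert n > 1000


def test_junction_clip_count_matches_expectation(tmp_path, ref):
    """Het deletion at 30x: clips with >=20 bp on both sides of the junction
    should appear ~ coverage/2 * (read_len - 2*20)/read_len = 9 times."""
    cfg = _cfg(coverage=30.0)
    targets = make_targets(cfg)
    ts, _ = targets[10]
    var = _var(SVType.DEL, ts + 100, 100)
    hap, _ = implant_svs(ref, [var])
    ref_hap = Haplotype(seq=ref, blocks=[(0, 0, len(ref))])
    expected = cfg.coverage / 2 * (cfg.read_len - 2 * 20) / cfg.read_len
    counts = []
    for seed in range(10):
        bam = tmp_path / f"d{seed}.bam"
        simulate_reads([hap, ref_hap], cfg, targets, ref, bam, "S1", np.random.default_rng(seed))
        srs = extract_split_reads(bam, params=ReadFilterParams(min_clip_len=20))
        counts.append(
            sum(1 for sr in srs if sr.clip_pos in (var.start, var.start + var.length))
        )
        assert abs(counts[-1] - expected) <= 3 * np.sqrt(expected)
    assert abs(np.mean(counts) - expected) <= 3 * np.sqrt(expected / len(counts))


class _FakeCall:
    def __init__(self, sample_id, svtype, bp1, svlen=None, chrom=CHROM):
        self.sample_id = sample_id
        self.svtype = svtype
        self.bp1 = bp1
        self.svlen = svlen
        self.chrom = chrom


def _truth(sample, svtype, start, length):
    return TruthVariant(
        svtype=svtype, chrom=CHROM, start=start, length=length, carrier="MOTHER",
        sample_id=sample, inserted_seq="A" * length if svtype in (SVType.INS, SVType.MEI) else None,
    )


def test_evaluation_perfect_caller():
    truth = [_truth("s", SVType.DEL, 1000, 100), _truth("s", SVType.INS, 5000, 40)]
    calls = [_FakeCall("s", SVType.DEL, 1000, -100), _FakeCall("s", SVType.INS, 5000, 40)]
    m = evaluate_against_truth(calls, truth)
    assert m["recall"] == 1.0 and m["precision"] == 1.0
    assert m["breakpoint_exact_fraction"] == 1.0 and m["svlen_exact_fraction"] == 1.0


def test_evaluation_empty_calls():
    truth = [_truth("s", SVType.DEL, 1000, 100)]
    assert evaluate_against_truth([], truth)["recall"] == 0.0


def test_evaluation_tolerant_match_counts_but_not_exact():
    truth = [_truth("s", SVType.DEL, 1000, 100)]
    calls = [_FakeCall("s", SVType.DEL, 1003, -100)]
    m = evaluate_against_truth(calls, truth, match_tol=5)
    assert m["recall"] == 1.0 and m["breakpoint_exact_fraction"] == 0.0


def test_evaluation_requires_matching_svtype_and_sample():
    truth = [_truth("s", SVType.DEL, 1000, 100)]
    assert evaluate_against_truth([_FakeCall("s", SVType.DUP, 1000, 100)], truth)["recall"] == 0.0
    assert evaluate_against_truth([_FakeCall("other", SVType.DEL, 1000, -100)], truth)["recall"] == 0.0
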