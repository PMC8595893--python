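"""Split-read extraction, read filters, and sequence entropy."""

import math

import numpy as np
import pysam
import pytest

from crypticsv.splitread import (
    ExtractionStats,
    ReadFilterParams,
    Side,
    SplitRead,
    extract_split_reads,
    passes_read_filters,
    read_splitreads,
    relaxed_parent_filters,
    sequence_entropy,
    write_splitreads,
)
from conftest import CHROM, make_bam


def _sr(seq="ACGTACGTACGTACGTACGT", quals=None, mapq=60, pos=100, side=Side.RIGHT):
    quals = tuple(quals) if quals is not None else tuple([35] * len(seq))
    return SplitRead(
        sample_id="S1",
        chrom=CHROM,
        clip_pos=pos,
        side=side,
        clipped_seq=seq,
        clipped_quals=quals,
        aligned_len=80,
        mapq=mapq,
        read_name="r1",
    )


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAA", 0.0),
        ("ACGT", 2.0),
        ("AACG", 1.5),
        ("ACGTN", math.log2(5)),
        ("NNNN", 0.0),
    ],
)
def test_entropy_known_values(seq, expected):
    assert sequence_entropy(seq) == pytest.approx(expected)


def test_entropy_rejects_empty_and_bad_alphabet():
    with pytest.raises(ValueError):
        sequence_entropy("")
    with pytest.raises(ValueError):
        sequence_entropy("ACGX")


def test_each_filter_gate_rejects_independently():
    params = ReadFilterParams(min_clip_len=20, min_mapq=20, min_mean_clip_baseq=15, min_entropy_bits=1.0, max_n_fraction=0.2)
    assert passes_read_filters(_sr(), params)
    assert not passes_read_filters(_sr(seq="ACGTACGTACGTACGTACG"), params)  # 19 bp clip
    assert passes_read_filters(_sr(seq="ACGTACGTACGTACGTACGT"), params)  # 20 bp clip
    assert not passes_read_filters(_sr(mapq=19), params)
    assert not passes_read_filters(_sr(quals=[14] * 20), params)
    assert not passes_read_filters(_sr(seq="A" * 25, quals=[35] * 25), params)  # entropy 0
    assert not passes_read_filters(_sr(seq="N" * 20, quals=[35] * 20), params)  # all N


def test_relaxed_filters_are_superset_of_strict():
    strict, relaxed = ReadFilterParams(), relaxed_parent_filters()
    assert relaxed.min_clip_len <= strict.min_clip_len
    assert relaxed.min_mapq <= strict.min_mapq
    assert relaxed.min_mean_clip_baseq <= strict.min_mean_clip_baseq
    assert relaxed.min_entropy_bits <= strict.min_entropy_bits
    assert relaxed.max_n_fraction >= strict.max_n_fraction
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        seq = "".join(rng.choice(list("ACGTN"), n))
        sr = _sr(seq=seq, quals=list(rng.integers(2, 41, n)), mapq=int(rng.integers(0, 61)))
        if passes_read_filters(sr, strict):
            assert passes_read_filters(sr, relaxed)


def _seq(n, base="A"):
    # deterministic high-entropy sequence
    return ("ACGT" * (n // 4 + 1))[:n]


def test_extraction_examples(tmp_path):
    reads = [
        {"name": "full", "pos": 500, "cigar": [(0, 100)], "seq": _seq(100)},
        {"name": "unmapped", "pos": None, "flag": 4, "cigar": None, "seq": _seq(100)},
        {"name": "rightclip", "pos": 1000, "cigar": [(0, 60), (4, 40)], "seq": _seq(60) + "G" * 15 + "C" * 25},
        {"name": "leftclip", "pos": 2000, "cigar": [(4, 30), (0, 70)], "seq": "T" * 15 + "A" * 15 + _seq(70)},
        {"name": "bothends", "pos": 3000, "cigar": [(4, 20), (0, 60), (4, 20)], "seq": _seq(100)},
        {"name": "secondary", "pos": 4000, "flag": 256, "cigar": [(0, 50), (4, 50)], "seq": _seq(100)},
        {"name": "duplicate", "pos": 5000, "flag": 1024, "cigar": [(0, 50), (4, 50)], "seq": _seq(100)},
        {"name": "hardonly", "pos": 6000, "cigar": [(5, 20), (0, 100)], "seq": _seq(100)},
    ]
    bam = make_bam(tmp_path / "t.bam", reads)
    stats = ExtractionStats()
    srs = extract_split_reads(bam, params=None, stats=stats)

    names = [(sr.read_name, sr.side) for sr in srs]
    assert ("full", Side.LEFT) not in names and ("full", Side.RIGHT) not in names
    assert not any(n == "unmapped" for n, _ in names)
    assert not any(n in ("secondary", "duplicate") for n, _ in names)

    right = next(sr for sr in srs if sr.read_name == "rightclip")
    assert right.side is Side.RIGHT
    assert right.clip_pos == 1060  # 1000 + 60M, half-open end
    assert right.clipped_seq == "G" * 15 + "C" * 25  # last 40 read bases

    left = next(sr for sr in srs if sr.read_name == "leftclip")
    assert left.side is Side.LEFT and left.clip_pos == 2000
    assert left.clipped_seq == "T" * 15 + "A" * 15

    both = [sr for sr in srs if sr.read_name == "bothends"]
    assert {sr.side for sr in both} == {Side.LEFT, Side.RIGHT}
    assert stats.hardclip_ends_skipped == 1

    positions = [(sr.chrom, sr.clip_pos) for sr in srs]
    assert positions == sorted(positions)


def test_extraction_requires_index(tmp_path):
    bam = make_bam(tmp_path / "noidx.bam", [{"name": "r", "pos": 10, "cigar": [(0, 50)], "seq": _seq(50)}], index=False)
    with pytest.raises(FileNotFoundError, match="samtools index"):
        extract_split_reads(bam)


def _oracle_cigar_walk(bam_path):
    """Independent brute-force scan: walk every record's CIGAR by hand."""
    out = set()
    with pysam.AlignmentFile(str(bam_path), "rb") as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate or read.is_qcfail:
                continue
            cig = read.cigartuples or []
            if read.query_sequence is None:
                continue
            # reference consumption: M/D/N/=/X consume reference
            ref_len = sum(ln for op, ln in cig if op in (0, 2, 3, 7, 8))
            i = 1 if cig and cig[0][0] == 5 else 0
            if i < len(cig) and cig[i][0] == 4:
                out.add((read.query_name, "LEFT", read.reference_start, read.query_sequence[: cig[i][1]]))
            j = len(cig) - (2 if cig and cig[-1][0] == 5 else 1)
            if j > i and cig[j][0] == 4:
                out.add(
                    (
                        read.query_name,
                        "RIGHT",
                        read.reference_start + ref_len,
                        read.query_sequence[-cig[j][1] :],
                    )
                )
    return out


def test_extraction_equals_bruteforce_oracle(tmp_path, rng):
    reads = []
    for i in range(2000):
        pos = int(rng.integers(0, 90_000))
        kind = rng.integers(0, 5)
        seq = "".join(rng.choice(list("ACGT"), 100))
        if kind == 0:
            cigar = [(0, 100)]
        elif kind == 1:
            cigar = [(0, 60), (4, 40)]
        elif kind == 2:
            cigar = [(4, 30), (0, 70)]
        elif kind == 3:
            cigar = [(4, 20), (0, 50), (4, 30)]
        else:
            cigar = [(0, 40), (2, int(rng.integers(1, 30))), (0, 60)]  # with deletion
        reads.append({"name": f"r{i}", "pos": pos, "cigar": cigar, "seq": seq})
    bam = make_bam(tmp_path / "rand.bam", reads)
    srs = extract_split_reads(bam, params=None)
    got = {(sr.read_name, sr.side.value, sr.clip_pos, sr.clipped_seq) for sr in srs}
    assert got == _oracle_cigar_walk(bam)
    pos_order = [(sr.chrom, sr.clip_pos) for sr in srs]
    assert pos_order == sorted(pos_order)


def test_roundtrip_single_deletion_clips_only_at_breakpoints(tmp_path):
    from crypticsv.junctiondb import SVType
    from crypticsv.simulate import Haplotype, SimConfig, TruthVariant, implant_svs, make_targets, random_dna, simulate_reads

    cfg = SimConfig(
        seed=5, ref_length=200_000, n_targets=20, error_rate=0.0, artifact_clip_rate=0.0, n_artifact_sites=0
    )
    rng = np.random.default_rng(cfg.seed)
    ref = random_dna(rng, cfg.ref_length)
    targets = make_targets(cfg)
    ts, te = targets[10]
    var = TruthVariant(svtype=SVType.DEL, chrom=cfg.chrom, start=ts + 100, length=400, carrier="MOTHER")
    hap, _ = implant_svs(ref, [var])
    ref_hap = Haplotype(seq=ref, blocks=[(0, 0, len(ref))])
    bam = tmp_path / "del.bam"
    simulate_reads([hap, ref_hap], cfg, targets, ref, bam, "S1", np.random.default_rng(9))
    srs = extract_split_reads(bam, params=ReadFilterParams())
    assert srs, "expected split reads at the deletion junction"
    assert {sr.clip_pos for sr in srs} <= {var.start, var.start + var.length}
    sides = {(sr.clip_pos, sr.side) for sr in srs}
    assert (var.start, Side.RIGHT) in sides or (var.start + var.length, Side.LEFT) in sides


def test_splitreads_tsv_roundtrip(tmp_path):
    srs = [
        _sr(pos=10, side=Side.LEFT),
        _sr(pos=99, side=Side.RIGHT, seq="TTTTGGGGCCCCAAAATTTT", quals=list(range(20, 40))),
    ]
    path = tmp_path / "sr.tsv.gz"
    write_splitreads(path, srs, ReadFilterParams())
    back = read_splitreads(path, "S1")
    assert [(s.clip_pos, s.side, s.clipped_seq, s.clipped_quals) for s in back] == [
        (s.clip_pos, s.side, s.clipped_seq, s.clipped_quals) for s in srs
    ]
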