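"""Junction consensus, realignment, SV classification, cohort merge."""

import numpy as np
import pytest

from crypticsv.align import find_alignments, revcomp, smith_waterman
from crypticsv.clustering import SplitReadCluster
from crypticsv.junctiondb import (
    CohortRecord,
    JunctionSeq,
    SVType,
    TargetKind,
    build_junction_consensus,
    classify_sv,
    dedup_calls,
    merge_cohort,
    realign_junction,
)
from crypticsv.simulate import random_dna
from crypticsv.splitread import Side, SplitRead
from conftest import CHROM


def _sr(pos, seq, side=Side.RIGHT, quals=None, sample="S1", name="r"):
    quals = tuple(quals) if quals is not None else tuple([35] * len(seq))
    return SplitRead(
        sample_id=sample,
        chrom=CHROM,
        clip_pos=pos,
        side=side,
        clipped_seq=seq,
        clipped_quals=quals,
        aligned_len=80,
        mapq=60,
        read_name=name,
    )


def _cluster(members, sample="S1", score=0.9):
    pos = sorted(m.clip_pos for m in members)[(len(members) - 1) // 2]
    c = SplitReadCluster(
        sample_id=sample, chrom=CHROM, pos=pos, side=members[0].side, members=members
    )
    c.score = score
    return c


# ---------------------------------------------------------------------------
# Smith-Waterman


def test_sw_exact_substring():
    aln = smith_waterman("ACGTACGTAC", "TTT" + "ACGTACGTAC" + "GGG")
    assert (aln.target_start, aln.target_end) == (3, 13)
    assert aln.identity == 1.0 and aln.score == 10.0


def test_sw_scores_mismatch_and_gap():
    # one mismatch: +1*9 - 1 = 8
    assert smith_waterman("ACGTACGTAC", "ACGTTCGTAC").score == 8.0
    # one 1-bp gap: 10 matches - (open 2 + extend 0.5) = 7.5
    assert smith_waterman("ACGTACGTAC", "ACGTAGCGTAC").score == 7.5


def test_sw_local_ignores_flanking_noise():
    aln = smith_waterman("AAAAAAAA", "CGCGCGAAAAAAAACGCGCG")
    assert (aln.query_start, aln.query_end) == (0, 8)
    assert (aln.target_start, aln.target_end) == (6, 14)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_singleton():
    j = build_junction_consensus([_cluster([_sr(100, "ACGTAC")])])
    assert j.seq == "ACGTAC"
    assert j.cluster_key == (CHROM, 100, Side.RIGHT)
    assert (j.n_contributing_reads, j.n_contributing_samples) == (1, 1)


def test_consensus_longest_extension():
    c = _cluster([_sr(100, "ACGTAC", name="a"), _sr(100, "ACGTACGTAA", name="b")])
    assert build_junction_consensus([c]).seq == "ACGTACGTAA"


def test_consensus_quality_weighted_majority():
    c = _cluster(
        [
            _sr(100, "ACGTA", quals=[40] * 5, name="hi"),
            _sr(100, "ACCTA", quals=[10] * 5, name="lo"),
        ]
    )
    assert build_junction_consensus([c]).seq == "ACGTA"


def test_consensus_left_clips_anchor_at_junction():
    # LEFT clips abut the junction at their right end; a shorter clip must
    # agree with the suffix of the longer one.
    c = _cluster(
        [
            _sr(100, "GTAC", side=Side.LEFT, name="short"),
            _sr(100, "ACGTGTAC", side=Side.LEFT, name="long"),
        ]
    )
    assert build_junction_consensus([c]).seq == "ACGTGTAC"


def test_consensus_mixed_sides_fatal():
    with pytest.raises(ValueError, match="LEFT and RIGHT"):
        build_junction_consensus(
            [_cluster([_sr(100, "ACGTAC")]), _cluster([_sr(100, "ACGTAC", side=Side.LEFT)])]
        )


# ---------------------------------------------------------------------------
# realignment


@pytest.fixture(scope="module")
def genome():
    return {CHROM: random_dna(np.random.default_rng(42), 100_000)}


def _junction(seq, pos=5000, side=Side.RIGHT):
    return JunctionSeq(cluster_key=(CHROM, pos, side), seq=seq, n_contributing_reads=5, n_contributing_samples=1)


def test_realign_exact_substring(genome):
    seq = genome[CHROM][40_000:40_060]
    hits = realign_junction(_junction(seq), genome, None)
    assert hits and hits[0].target == TargetKind.GENOME
    assert (hits[0].target_start, hits[0].target_end) == (40_000, 40_060)
    assert hits[0].identity == 1.0 and hits[0].strand == "+"


def test_realign_revcomp_hits_minus_strand(genome):
    seq = revcomp(genome[CHROM][40_000:40_060])
    hits = realign_junction(_junction(seq), genome, None)
    assert hits and hits[0].strand == "-"
    assert (hits[0].target_start, hits[0].target_end) == (40_000, 40_060)


def test_realign_absent_sequence_finds_nothing(genome):
    rng = np.random.default_rng(7)
    for _ in range(5):
        probe = random_dna(rng, 40)
        if probe in genome[CHROM] or revcomp(probe) in genome[CHROM]:
            continue
        assert realign_junction(_junction(probe), genome, None) == []


def test_strand_safety_revcomp_flips_all_hits(genome):
    seq = genome[CHROM][10_000:10_050] + genome[CHROM][60_000:60_030]
    fwd = realign_junction(_junction(seq), genome, None)
    rev = realign_junction(_junction(revcomp(seq)), genome, None)
    flip = {"+": "-", "-": "+"}
    assert sorted((h.target_start, h.target_end, flip[h.strand]) for h in fwd) == sorted(
        (h.target_start, h.target_end, h.strand) for h in rev
    )


def test_repeat_panel_hits(genome):
    panel = {"Alu": random_dna(np.random.default_rng(8), 300)}
    hits = realign_junction(_junction(panel["Alu"][:60]), genome, panel)
    assert hits[0].target == TargetKind.REPEAT_PANEL and hits[0].target_name == "Alu"


# ---------------------------------------------------------------------------
# classification


def _classify(genome, pos, side, seq, panel=None, **kw):
    cluster = _cluster([_sr(pos, seq, side=side, name=f"m{i}") for i in range(5)])
    junction = build_junction_consensus([cluster])
    hits = realign_junction(junction, genome, panel)
    return classify_sv(cluster, hits, junction, **kw)


def test_classify_clean_deletion(genome):
    ref = genome[CHROM]
    bp1, svlen = 20_000, 100
    call = _classify(genome, bp1, Side.RIGHT, ref[bp1 + svlen : bp1 + svlen + 60])
    assert call.svtype is SVType.DEL
    assert (call.bp1, call.bp2, call.svlen) == (bp1, bp1 + svlen, -svlen)


def test_classify_deletion_from_left_clip(genome):
    ref = genome[CHROM]
    bp1, bp2 = 20_000, 20_100
    call = _classify(genome, bp2, Side.LEFT, ref[bp1 - 60 : bp1])
    assert call.svtype is SVType.DEL
    assert (call.bp1, call.bp2, call.svlen) == (bp1, bp2, -100)


def test_classify_tandem_duplication(genome):
    ref = genome[CHROM]
    s, L = 30_000, 80
    e = s + L
    # RIGHT clip at the end of the first copy: clipped bases restart at s
    call = _classify(genome, e, Side.RIGHT, ref[s : s + 60])
    assert call.svtype is SVType.DUP
    assert (call.bp1, call.bp2, call.svlen) == (e, s, L)


def test_classify_short_insertion_with_exact_length(genome):
    ref = genome[CHROM]
    bp1, ins = 45_000, random_dna(np.random.default_rng(3), 30)
    junction = ins + ref[bp1 : bp1 + 40]
    call = _classify(genome, bp1, Side.RIGHT, junction)
    assert call.svtype is SVType.INS
    assert call.svlen == 30


def test_classify_nontemplated_insertion_no_hits(genome):
    probe = random_dna(np.random.default_rng(12), 45)
    assert probe not in genome[CHROM] and revcomp(probe) not in genome[CHROM]
    call = _classify(genome, 45_000, Side.RIGHT, probe)
    assert call.svtype is SVType.INS and call.svlen == 45


def test_classify_mei_from_repeat_panel(genome):
    panel = {"Alu": random_dna(np.random.default_rng(8), 300)}
    call = _classify(genome, 45_000, Side.RIGHT, panel["Alu"][:70], panel=panel)
    assert call.svtype is SVType.MEI and call.repeat_family == "Alu"


def test_classify_other_chromosome_is_tra_segdup(genome):
    two = {CHROM: genome[CHROM], "chr2": random_dna(np.random.default_rng(9), 50_000)}
    call = _classify(two, 45_000, Side.RIGHT, two["chr2"][10_000:10_060])
    assert call.svtype is SVType.TRA_SEGDUP


def test_classify_beyond_span_is_tra_segdup(genome):
    ref = genome[CHROM]
    call = _classify(genome, 5_000, Side.RIGHT, ref[90_000:90_060], max_event_span=10_000)
    assert call.svtype is SVType.TRA_SEGDUP


def test_classify_minus_strand_is_complex(genome):
    ref = genome[CHROM]
    call = _classify(genome, 20_000, Side.RIGHT, revcomp(ref[20_300:20_360]))
    assert call.svtype is SVType.COMPLEX


def test_classify_short_junction_unresolved(genome):
    probe = random_dna(np.random.default_rng(13), 12)
    cluster = _cluster([_sr(45_000, probe, name=f"m{i}") for i in range(5)])
    junction = build_junction_consensus([cluster])
    call = classify_sv(cluster, [], junction)
    assert call.svtype is SVType.UNRESOLVED and call.bp2 is None and call.svlen is None


def test_classification_total_and_deterministic(genome):
    rng = np.random.default_rng(99)
    ref = genome[CHROM]
    for i in range(25):
        kind = i % 5
        pos = int(rng.integers(1000, 90_000))
        if kind == 0:
            seq = ref[pos + 200 : pos + 250]
        elif kind == 1:
            seq = random_dna(rng, 40)
        elif kind == 2:
            seq = revcomp(ref[pos : pos + 50])
        elif kind == 3:
            seq = ref[max(0, pos - 300) : max(0, pos - 300) + 50]
        else:
            seq = ref[pos : pos + 25] + random_dna(rng, 25)
        c1 = _classify(genome, pos, Side.RIGHT, seq)
        c2 = _classify(genome, pos, Side.RIGHT, seq)
        assert isinstance(c1.svtype, SVType)
        assert (c1.svtype, c1.bp1, c1.bp2, c1.svlen) == (c2.svtype, c2.bp1, c2.bp2, c2.svlen)


# ---------------------------------------------------------------------------
# cohort merge


def test_merge_single_sample_degenerate_cohort():
    c = _cluster([_sr(100, "ACGTACGTACGT")])
    (rec,) = merge_cohort([("S1", [c])])
    assert rec.call_frequency == 1.0 and rec.carrier_count == 1 and rec.cohort_size == 1


def test_merge_carrier_arithmetic():
    entries = []
    for i in range(1000):
        sid = f"s{i}"
        clusters = []
        if i < 3:
            clusters = [_cluster([_sr(500, "ACGTACGTACGT", sample=sid)], sample=sid)]
        entries.append((sid, clusters))
    (rec,) = merge_cohort(entries)
    assert rec.carrier_count == 3 and rec.call_frequency == pytest.approx(0.003)


def test_merge_duplicate_sample_fatal():
    with pytest.raises(ValueError, match="duplicate"):
        merge_cohort([("S1", []), ("S1", [])])


def test_merge_conserves_carriers(rng):
    entries = []
    total_clusters = 0
    for i in range(12):
        sid = f"s{i}"
        clusters = []
        for p in sorted(rng.integers(0, 5000, rng.integers(0, 8))):
            clusters.append(_cluster([_sr(int(p), "ACGTACGTACGT", sample=sid, name=f"{sid}.{p}")], sample=sid))
        # one sample's clusters are >2bp apart with high probability; drop collisions
        seen = []
        keep = []
        for c in clusters:
            if all(abs(c.pos - q) > 2 for q in seen):
                keep.append(c)
                seen.append(c.pos)
        total_clusters += len(keep)
        entries.append((sid, keep))
    records = merge_cohort(entries, cluster_tolerance=2)
    assert sum(r.carrier_count for r in records) == total_clusters


def test_cohort_record_validation():
    with pytest.raises(ValueError):
        CohortRecord(cluster_key=(CHROM, 1, Side.RIGHT), carrier_count=0, cohort_size=5, call_frequency=0.0, sample_ids=[])


def test_dedup_reciprocal_calls(genome):
    ref = genome[CHROM]
    bp1, bp2 = 20_000, 20_100
    right = _classify(genome, bp1, Side.RIGHT, ref[bp2 : bp2 + 60])
    left = _classify(genome, bp2, Side.LEFT, ref[bp1 - 60 : bp1])
    assert {c.svtype for c in (right, left)} == {SVType.DEL}
    kept = dedup_calls([right, left])
    assert len(kept) == 1
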