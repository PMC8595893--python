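"""Junction resolution and the cross-sample frequency database (Database).

Retained clusters sharing a locus across samples are merged; their clipped
sequences are quality-merged into the longest junction consensus, which is
realigned to the genome and to a panel of repeat consensi. The realignment
determines the missing breakpoint, the variant length, and the SV class
(deletion, duplication, insertion, MEI, translocation/segmental duplication,
complex, or unresolved). Carrier counts over the cohort give each cluster a
call frequency used later for rarity filtering.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from ._io import meta_lines, read_tsv, write_tsv
from .align import find_alignments, revcomp
from .clustering import SplitReadCluster, _lower_median
from .splitread import Side

log = logging.getLogger(__name__)


class TargetKind(str, enum.Enum):
    GENOME = "GENOME"
    REPEAT_PANEL = "REPEAT_PANEL"


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    MEI = "MEI"
    TRA_SEGDUP = "TRA_SEGDUP"
    COMPLEX = "COMPLEX"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class JunctionSeq:
    """Longest quality-merged clipped sequence at one cluster key."""

    cluster_key: tuple  # (chrom, pos, side)
    seq: str
    n_contributing_reads: int
    n_contributing_samples: int


@dataclass
class AlignmentHit:
    target: TargetKind
    target_name: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    aligned_len: int
    query_start: int
    query_end: int
    score: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.target_end <= self.target_start:
            raise ValueError("target_end must exceed target_start")


@dataclass
class SVCall:
    sample_id: str
    chrom: str
    bp1: int
    bp2: int | None
    svtype: SVType
    svlen: int | None
    repeat_family: str | None
    junction: JunctionSeq
    score: float
    support: int
    side: Side
    cohort_key: tuple | None = None
    call_frequency: float | None = None
    carrier_count: int | None = None
    inheritance: str | None = None

    def __post_init__(self):
        if self.svtype is SVType.DEL:
            assert self.bp2 is not None and self.bp2 > self.bp1
            assert self.svlen == -(self.bp2 - self.bp1)
        elif self.svtype is SVType.DUP:
            assert self.bp2 is not None and self.bp2 <= self.bp1
        elif self.svtype is SVType.INS:
            assert self.svlen is not None and self.svlen > 0
        elif self.svtype is SVType.UNRESOLVED:
            assert self.bp2 is None and self.svlen is None


@dataclass
class CohortRecord:
    cluster_key: tuple  # (chrom, pos, side)
    carrier_count: int
    cohort_size: int
    call_frequency: float
    sample_ids: list
    clusters: list = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.carrier_count <= self.cohort_size:
            raise ValueError("carrier_count must lie in [1, cohort_size]")


def build_junction_consensus(cluster_group: Sequence[SplitReadCluster]) -> JunctionSeq:
    """Quality-weighted consensus of all clipped sequences in a cluster group.

    Clips are anchored at the breakpoint: LEFT clips are reversed so offset 0
    is the junction-adjacent base. Each offset takes the base with the highest
    summed base quality (ties: lexicographically smaller base); the consensus
    extends to the longest offset covered by any read. The returned sequence is
    in natural reference orientation for both sides.
    """
    if not cluster_group:
        raise ValueError("empty cluster group")
    sides = {c.side for c in cluster_group}
    if len(sides) > 1:
        raise ValueError("cluster group mixes LEFT and RIGHT clips (upstream bug)")
    side = sides.pop()
    chrom = cluster_group[0].chrom
    pos = _lower_median([c.pos for c in cluster_group])

    anchored = []
    n_reads = 0
    samples = set()
    for c in cluster_group:
        samples.add(c.sample_id)
        for m in c.members:
            n_reads += 1
            seq, quals = m.clipped_seq, m.clipped_quals
            if side is Side.LEFT:
                seq = seq[::-1]
                quals = quals[::-1]
            anchored.append((seq, quals))

    max_len = max(len(s) for s, _ in anchored)
    consensus = []
    for i in range(max_len):
        weights: dict = {}
        for seq, quals in anchored:
            if i < len(seq):
                weights[seq[i]] = weights.get(seq[i], 0) + int(quals[i])
        best = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        consensus.append(best)
    seq = "".join(consensus)
    if side is Side.LEFT:
        seq = seq[::-1]
    return JunctionSeq(
        cluster_key=(chrom, pos, side),
        seq=seq,
        n_contributing_reads=n_reads,
        n_contributing_samples=len(samples),
    )


def realign_junction(
    junction: JunctionSeq,
    reference: dict,
    repeat_panel: dict | None = None,
    min_identity: float = 0.9,
    min_hit_len: int = 20,
) -> list:
    """All local hits of the junction consensus, best-first.

    ``reference`` and ``repeat_panel`` map sequence names to strings. An empty
    hit list is a valid result (candidate non-templated insertion). A missing
    repeat panel skips repeat hits with a warning.
    """
    if reference is None:
        raise ValueError("reference sequences are required for realignment")
    hits = []
    for name, seq in reference.items():
        for aln in find_alignments(junction.seq, seq, min_identity=min_identity, min_hit_len=min_hit_len):
            hits.append(_hit_from_alignment(aln, TargetKind.GENOME, name))
    if repeat_panel:
        for name, seq in repeat_panel.items():
            for aln in find_alignments(junction.seq, seq, min_identity=min_identity, min_hit_len=min_hit_len):
                hits.append(_hit_from_alignment(aln, TargetKind.REPEAT_PANEL, name))
    else:
        log.warning("no repeat panel supplied; repeat hits skipped")
    hits.sort(
        key=lambda h: (
            -(h.identity * h.aligned_len),
            -h.score,
            h.strand != "+",
            h.target_name,
            h.target_start,
        )
    )
    return hits


def _hit_from_alignment(aln, kind: TargetKind, name: str) -> AlignmentHit:
    return AlignmentHit(
        target=kind,
        target_name=name,
        target_start=aln.target_start,
        target_end=aln.target_end,
        strand=aln.strand,
        identity=aln.identity,
        aligned_len=aln.n_columns,
        query_start=aln.query_start,
        query_end=aln.query_end,
        score=aln.score,
    )


def classify_sv(
    cluster: SplitReadCluster,
    hits: Sequence[AlignmentHit],
    junction: JunctionSeq,
    max_event_span: int = 10_000,
    min_ins_len: int = 20,
    min_sv_len: int = 20,
    slack: int = 10,
) -> SVCall:
    """Resolve one retained cluster to an SVCall (total, deterministic).

    Decision tree, first match wins:
      1. top hit in the repeat panel -> MEI with that repeat family;
      2. genome hit on the same chrom, + strand, partner downstream (RIGHT
         clips; upstream for LEFT) within max_event_span -> DEL;
      3. same chrom, + strand, partner placing the junction upstream/
         overlapping in tandem orientation -> DUP;
      4. same chrom, - strand -> COMPLEX (inversion-like);
      5. different chrom or beyond max_event_span -> TRA_SEGDUP;
      6. no hits and junction >= min_ins_len -> INS (non-templated);
         otherwise UNRESOLVED.

    For rules 2/3 the deleted/duplicated span and any novel inserted bases are
    derived from the hit's query offsets, so a short insertion whose clip runs
    through the insert back into reference sequence is typed INS with its exact
    length rather than a zero-length deletion.
    """
    base = dict(
        sample_id=cluster.sample_id,
        chrom=cluster.chrom,
        junction=junction,
        score=cluster.score if cluster.score is not None else float("nan"),
        support=cluster.support,
        side=cluster.side,
        repeat_family=None,
    )
    pos = cluster.pos
    jlen = len(junction.seq)

    if hits:
        top = hits[0]
        if top.target is TargetKind.REPEAT_PANEL:
            return SVCall(bp1=pos, bp2=None, svtype=SVType.MEI, svlen=None, **{**base, "repeat_family": top.target_name})
        genome_hits = [h for h in hits if h.target is TargetKind.GENOME]
        top = genome_hits[0] if genome_hits else top
        if top.target_name != cluster.chrom:
            return SVCall(bp1=pos, bp2=None, svtype=SVType.TRA_SEGDUP, svlen=None, **base)
        if top.strand == "-":
            return SVCall(bp1=pos, bp2=None, svtype=SVType.COMPLEX, svlen=None, **base)
        # signed reference span between the breakpoint and where the clipped
        # sequence resumes on the reference; novel bases sit between them.
        if cluster.side is Side.RIGHT:
            deleted = top.target_start - pos
            inserted = top.query_start
            partner = top.target_start
        else:
            deleted = pos - top.target_end
            inserted = jlen - top.query_end
            partner = top.target_end
        if abs(deleted) > max_event_span:
            return SVCall(bp1=pos, bp2=None, svtype=SVType.TRA_SEGDUP, svlen=None, **base)
        if deleted >= min_sv_len and inserted <= slack:
            bp1, bp2 = min(pos, partner), max(pos, partner)
            return SVCall(bp1=bp1, bp2=bp2, svtype=SVType.DEL, svlen=-(bp2 - bp1), **base)
        if deleted <= -min_sv_len and inserted <= slack:
            bp1, bp2 = max(pos, partner), min(pos, partner)
            return SVCall(bp1=bp1, bp2=bp2, svtype=SVType.DUP, svlen=bp1 - bp2, **base)
        if inserted >= min_ins_len and abs(deleted) <= slack:
            # Local alignment may extend a few columns past the true junction
            # into novel sequence; deleted < 0 measures that overshoot, so the
            # net inserted length adds it back.
            return SVCall(bp1=pos, bp2=None, svtype=SVType.INS, svlen=inserted + max(0, -deleted), **base)
        if abs(deleted) > slack or inserted > slack:
            return SVCall(bp1=pos, bp2=None, svtype=SVType.COMPLEX, svlen=None, **base)
        return SVCall(bp1=pos, bp2=None, svtype=SVType.UNRESOLVED, svlen=None, **base)

    if jlen >= min_ins_len:
        return SVCall(bp1=pos, bp2=None, svtype=SVType.INS, svlen=jlen, **base)
    return SVCall(bp1=pos, bp2=None, svtype=SVType.UNRESOLVED, svlen=None, **base)


def merge_cohort(
    per_sample_clusters: Sequence[tuple],
    cluster_tolerance: int = 2,
) -> list:
    """Cross-sample single linkage on (chrom, side, pos +/- tolerance).

    ``per_sample_clusters`` is a sequence of (sample_id, clusters) pairs, one
    per cohort sample (samples with zero clusters still count toward the
    cohort size). Returns CohortRecords sorted by (chrom, pos, side).
    """
    sample_ids = [sid for sid, _ in per_sample_clusters]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in cohort")
    cohort_size = len(sample_ids)
    flat = []
    for sid, clusters in per_sample_clusters:
        for c in clusters:
            if c.sample_id != sid:
                raise ValueError(f"cluster sample_id {c.sample_id} != manifest {sid}")
            flat.append(c)
    flat.sort(key=lambda c: (c.chrom, c.side.value, c.pos))
    records = []
    group: list = []

    def _close(group):
        if not group:
            return
        carriers = sorted({c.sample_id for c in group})
        pos = _lower_median([c.pos for c in group])
        records.append(
            CohortRecord(
                cluster_key=(group[0].chrom, pos, group[0].side),
                carrier_count=len(carriers),
                cohort_size=cohort_size,
                call_frequency=len(carriers) / cohort_size,
                sample_ids=carriers,
                clusters=list(group),
            )
        )

    for c in flat:
        if group and (
            c.chrom != group[-1].chrom
            or c.side != group[-1].side
            or c.pos - group[-1].pos > cluster_tolerance
        ):
            _close(group)
            group = []
        group.append(c)
    _close(group)
    records.sort(key=lambda r: (r.cluster_key[0], r.cluster_key[1], r.cluster_key[2].value))
    return records


def dedup_calls(calls: Iterable[SVCall], tolerance: int = 2) -> list:
    """Collapse reciprocal calls (both junctions of one event) per sample.

    Two calls from the same sample describing the same (svtype, bp1, bp2) within
    tolerance are merged, keeping the higher-support one.
    """
    kept: list = []
    for call in sorted(calls, key=lambda c: (-c.support, c.chrom, c.bp1)):
        dup = False
        for other in kept:
            if (
                other.sample_id == call.sample_id
                and other.svtype == call.svtype
                and other.chrom == call.chrom
                and abs(other.bp1 - call.bp1) <= tolerance
                and (
                    (other.bp2 is None and call.bp2 is None)
                    or (
                        other.bp2 is not None
                        and call.bp2 is not None
                        and abs(other.bp2 - call.bp2) <= tolerance
                    )
                )
            ):
                dup = True
                break
        if not dup:
            kept.append(call)
    kept.sort(key=lambda c: (c.chrom, c.bp1, c.svtype.value))
    return kept


# ---------------------------------------------------------------------------
# serialization

COHORT_COLUMNS = ["chrom", "pos", "side", "carrier_count", "cohort_size", "call_frequency", "sample_ids"]

CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "bp1",
    "bp2",
    "svtype",
    "svlen",
    "repeat_family",
    "side",
    "support",
    "score",
    "carrier_count",
    "call_frequency",
    "junction_seq",
    "inheritance",
]


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    rows = [
        (
            r.cluster_key[0],
            r.cluster_key[1] + 1,
            r.cluster_key[2].value,
            r.carrier_count,
            r.cohort_size,
            f"{r.call_frequency:.8g}",
            ",".join(r.sample_ids),
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_db(path, records, params: dict | None = None) -> None:
    write_tsv(cohort_to_frame(records), path, meta_lines("database", params))


def calls_to_frame(calls: Iterable[SVCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            (
                c.sample_id,
                c.chrom,
                c.bp1 + 1,
                "" if c.bp2 is None else c.bp2 + 1,
                c.svtype.value,
                "" if c.svlen is None else c.svlen,
                c.repeat_family or "",
                c.side.value,
                c.support,
                "" if c.score is None else round(c.score, 6),
                "" if c.carrier_count is None else c.carrier_count,
                "" if c.call_frequency is None else f"{c.call_frequency:.8g}",
                c.junction.seq if c.junction is not None else "",
                c.inheritance or "",
            )
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(path, calls, params: dict | None = None) -> None:
    write_tsv(calls_to_frame(calls), path, meta_lines("database", params))


def calls_from_frame(df: pd.DataFrame) -> list:
    calls = []
    for r in df.itertuples(index=False):
        side = Side(r.side)
        chrom = str(r.chrom)
        bp1 = int(r.bp1) - 1
        junction = JunctionSeq(
            cluster_key=(chrom, bp1, side), seq=str(r.junction_seq), n_contributing_reads=0, n_contributing_samples=0
        )
        calls.append(
            SVCall(
                sample_id=str(r.sample_id),
                chrom=chrom,
                bp1=bp1,
                bp2=None if str(r.bp2) == "" else int(float(r.bp2)) - 1,
                svtype=SVType(r.svtype),
                svlen=None if str(r.svlen) == "" else int(float(r.svlen)),
                repeat_family=str(r.repeat_family) or None,
                junction=junction,
                score=float("nan") if str(r.score) == "" else float(r.score),
                support=int(r.support),
                side=side,
                carrier_count=None if str(r.carrier_count) == "" else int(float(r.carrier_count)),
                call_frequency=None if str(r.call_frequency) == "" else float(r.call_frequency),
                inheritance=str(r.inheritance) or None,
            )
        )
    return calls


def read_calls(path) -> list:
    return calls_from_frame(
        read_tsv(
            path,
            dtype={
                "bp2": str,
                "svlen": str,
                "repeat_family": str,
                "score": str,
                "carrier_count": str,
                "call_frequency": str,
                "junction_seq": str,
                "inheritance": str,
                "chrom": str,
                "sample_id": str,
            },
        )
    )


def write_calls_vcf(path, calls, contigs: dict) -> None:
    """Symbolic-ALT VCF (SVTYPE/SVLEN/END/CHR2 INFO keys), deterministic."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=crypticsv {__version__}",
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Partner breakpoint">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome">',
        '##INFO=<ID=REPFAM,Number=1,Type=String,Description="Repeat family (MEI)">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Split-read support">',
        '##INFO=<ID=CALLFREQ,Number=1,Type=Float,Description="Cohort call frequency">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Tandem duplication">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=MEI,Description="Mobile element insertion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    rows = []
    for c in calls:
        if c.bp2 is not None:
            start = min(c.bp1, c.bp2)
            end = max(c.bp1, c.bp2)
        else:
            start = c.bp1
            end = c.bp1
        info = [f"SVTYPE={c.svtype.value}"]
        if c.svlen is not None:
            info.append(f"SVLEN={c.svlen}")
        info.append(f"END={end + 1}")
        info.append(f"CHR2={c.chrom}")
        if c.repeat_family:
            info.append(f"REPFAM={c.repeat_family}")
        info.append(f"SUPPORT={c.support}")
        if c.call_frequency is not None:
            info.append(f"CALLFREQ={c.call_frequency:.8g}")
        rows.append(
            (
                c.chrom,
                start + 1,
                (c.chrom, start, c.svtype.value),
                f"{c.chrom}\t{start + 1}\t.\tN\t<{c.svtype.value}>\t.\tPASS\t" + ";".join(info),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2][2]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, _, _, line in rows:
            fh.write(line + "\n")
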