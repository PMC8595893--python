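"""Per-locus aggregation of split reads and cluster features (Aggregate).

Split reads from one sample are grouped by single linkage within
(chrom, side): consecutive clip positions no more than ``cluster_tolerance``
apart join one cluster. LEFT and RIGHT clips never co-cluster because the two
sides carry distinct breakpoint semantics; they are paired later during
junction resolution. Each cluster gets the fixed-order feature vector consumed
by the random-forest scorer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._io import meta_lines, read_tsv, write_tsv
from .splitread import Side, SplitRead, sequence_entropy

log = logging.getLogger(__name__)

#: Model contract: feature order is fixed and embedded in saved model artifacts.
FEATURE_NAMES = [
    "support",
    "clip_ratio",
    "mean_mapq",
    "sd_mapq",
    "mean_clip_baseq",
    "max_clip_len",
    "mean_entropy",
    "side_code",
    "pos_stddev",
]


@dataclass
class FeatureVector:
    support: float
    clip_ratio: float
    mean_mapq: float
    sd_mapq: float
    mean_clip_baseq: float
    max_clip_len: float
    mean_entropy: float
    side_code: float
    pos_stddev: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class SplitReadCluster:
    """Co-located same-side split reads from one sample."""

    sample_id: str
    chrom: str
    pos: int
    side: Side
    members: list
    depth: int | None = None
    depth_flagged: bool = False
    features: FeatureVector | None = None
    score: float | None = None
    below_min_support: bool = False

    @property
    def support(self) -> int:
        return len(self.members)


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_split_reads(
    split_reads: Iterable[SplitRead],
    cluster_tolerance: int = 2,
    min_support: int = 5,
) -> list:
    """Single-linkage clustering of a (chrom, clip_pos)-sorted stream.

    Cluster position is the lower median of member clip positions (robust to a
    stray clip, deterministic on ties). Clusters with support < ``min_support``
    are emitted but flagged ``below_min_support``; the hard drop happens at
    scoring time. Unsorted input is fatal.
    """
    if cluster_tolerance < 0:
        raise ValueError("cluster_tolerance must be >= 0")
    clusters: list = []
    open_members: dict = {Side.LEFT: [], Side.RIGHT: []}
    cur_chrom = None
    last_pos = None
    seen_chroms: set = set()

    def _flush(side):
        members = open_members[side]
        if members:
            clusters.append(
                SplitReadCluster(
                    sample_id=members[0].sample_id,
                    chrom=members[0].chrom,
                    pos=_lower_median([m.clip_pos for m in members]),
                    side=side,
                    members=list(members),
                )
            )
            open_members[side] = []

    for sr in split_reads:
        if sr.chrom != cur_chrom:
            if sr.chrom in seen_chroms:
                raise ValueError("split reads are not sorted by (chrom, clip_pos)")
            _flush(Side.LEFT)
            _flush(Side.RIGHT)
            cur_chrom = sr.chrom
            seen_chroms.add(sr.chrom)
            last_pos = None
        if last_pos is not None and sr.clip_pos < last_pos:
            raise ValueError("split reads are not sorted by (chrom, clip_pos)")
        last_pos = sr.clip_pos
        members = open_members[sr.side]
        if members and sr.clip_pos - members[-1].clip_pos > cluster_tolerance:
            _flush(sr.side)
            members = open_members[sr.side]
        members.append(sr)
    _flush(Side.LEFT)
    _flush(Side.RIGHT)

    for c in clusters:
        c.below_min_support = c.support < min_support
    clusters.sort(key=lambda c: (c.chrom, c.pos, c.side.value))
    return clusters


class BamDepthSource:
    """Read depth at a point: non-duplicate primary alignments overlapping it."""

    def __init__(self, alignment_path, reference_fasta=None):
        path = str(alignment_path)
        mode = "rc" if path.endswith(".cram") else "rb"
        kwargs = {}
        if reference_fasta is not None:
            kwargs["reference_filename"] = str(reference_fasta)
        self._af = pysam.AlignmentFile(path, mode, **kwargs)

    def depth(self, chrom: str, pos: int) -> int:
        return self._af.count(
            chrom,
            max(0, pos),
            pos + 1,
            read_callback=lambda r: not (
                r.is_duplicate or r.is_secondary or r.is_supplementary or r.is_unmapped
            ),
        )

    def close(self):
        self._af.close()


def compute_cluster_features(cluster: SplitReadCluster, coverage_source=None) -> FeatureVector:
    """Fill the cluster's FeatureVector; depth failures flag clip_ratio=1.0."""
    depth = None
    if coverage_source is not None:
        try:
            depth = coverage_source.depth(cluster.chrom, cluster.pos)
        except Exception:  # depth query failure is non-fatal by contract
            log.warning("depth query failed at %s:%d", cluster.chrom, cluster.pos)
            depth = None
    if depth is None or depth <= 0:
        clip_ratio = 1.0
        cluster.depth_flagged = True
        cluster.depth = 0 if depth is None else depth
    else:
        clip_ratio = min(1.0, cluster.support / depth)
        cluster.depth = depth
    mapqs = np.array([m.mapq for m in cluster.members], dtype=float)
    positions = np.array([m.clip_pos for m in cluster.members], dtype=float)
    fv = FeatureVector(
        support=float(cluster.support),
        clip_ratio=float(clip_ratio),
        mean_mapq=float(mapqs.mean()),
        sd_mapq=float(mapqs.std()),
        mean_clip_baseq=float(np.mean([m.mean_clip_baseq for m in cluster.members])),
        max_clip_len=float(max(m.clip_len for m in cluster.members)),
        mean_entropy=float(np.mean([sequence_entropy(m.clipped_seq) for m in cluster.members])),
        side_code=1.0 if cluster.side is Side.RIGHT else 0.0,
        pos_stddev=float(positions.std()),
    )
    cluster.features = fv
    return fv


_MEMBER_SEP = ";"
_FIELD_SEP = "|"

CLUSTER_COLUMNS = (
    ["chrom", "pos", "side", "support", "depth", "depth_flagged", "below_min_support", "score"]
    + FEATURE_NAMES
    + ["members"]
)


def _pack_members(members) -> str:
    parts = []
    for m in members:
        quals = ",".join(str(q) for q in m.clipped_quals)
        parts.append(
            _FIELD_SEP.join([m.read_name, str(m.clip_pos), str(m.mapq), str(m.aligned_len), m.clipped_seq, quals])
        )
    return _MEMBER_SEP.join(parts)


def _unpack_members(blob: str, sample_id: str, chrom: str, side: Side) -> list:
    out = []
    for part in blob.split(_MEMBER_SEP):
        name, pos, mapq, alen, seq, quals = part.split(_FIELD_SEP)
        out.append(
            SplitRead(
                sample_id=sample_id,
                chrom=chrom,
                clip_pos=int(pos),
                side=side,
                clipped_seq=seq,
                clipped_quals=tuple(int(q) for q in quals.split(",")),
                aligned_len=int(alen),
                mapq=int(mapq),
                read_name=name,
            )
        )
    return out


def clusters_to_frame(clusters: Iterable[SplitReadCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        fv = c.features
        feats = list(fv.as_array()) if fv is not None else [np.nan] * len(FEATURE_NAMES)
        rows.append(
            [
                c.chrom,
                c.pos + 1,
                c.side.value,
                c.support,
                -1 if c.depth is None else c.depth,
                int(c.depth_flagged),
                int(c.below_min_support),
                "" if c.score is None else round(c.score, 6),
            ]
            + [round(float(x), 6) for x in feats]
            + [_pack_members(c.members)]
        )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def frame_to_clusters(df: pd.DataFrame, sample_id: str) -> list:
    out = []
    for row in df.itertuples(index=False):
        side = Side(row.side)
        chrom = str(row.chrom)
        members = _unpack_members(row.members, sample_id, chrom, side)
        c = SplitReadCluster(
            sample_id=sample_id,
            chrom=chrom,
            pos=int(row.pos) - 1,
            side=side,
            members=members,
            depth=None if int(row.depth) < 0 else int(row.depth),
            depth_flagged=bool(row.depth_flagged),
            below_min_support=bool(row.below_min_support),
            score=None if str(row.score) == "" else float(row.score),
        )
        c.features = FeatureVector(*[float(getattr(row, name)) for name in FEATURE_NAMES])
        out.append(c)
    return out


def write_clusters(path, clusters, params: dict | None = None) -> None:
    write_tsv(clusters_to_frame(clusters), path, meta_lines("aggregate", params))


def read_clusters(path, sample_id: str) -> list:
    df = read_tsv(path, dtype={"members": str, "score": str})
    return frame_to_clusters(df, sample_id)
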