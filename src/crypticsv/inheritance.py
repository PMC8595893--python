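"""Trio inheritance classification (denovo stage).

Each candidate breakpoint is tested for split-read support in the parental
alignments using RELAXED read filters (shorter clips, no mapping-quality or
entropy gates): missing true parental evidence would mislabel an inherited
variant as de novo, which is the costlier error. A parent is PRESENT with
>= min_parent_clips matching clips, ABSENT with fewer and adequate depth, and
UNINFORMATIVE when depth is below min_parent_depth or the file is missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .clustering import BamDepthSource
from .junctiondb import SVCall, SVType
from .splitread import ReadFilterParams, Side, extract_split_reads, relaxed_parent_filters


class Parent(str, enum.Enum):
    MOTHER = "MOTHER"
    FATHER = "FATHER"


class Verdict(str, enum.Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    UNINFORMATIVE = "UNINFORMATIVE"


class InheritanceStatus(str, enum.Enum):
    DE_NOVO = "DE_NOVO"
    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    BIPARENTAL = "BIPARENTAL"
    UNKNOWN = "UNKNOWN"


@dataclass
class ParentalSupport:
    parent: Parent
    supporting_clips: int
    depth_at_site: int
    verdict: Verdict


def parental_support(
    call: SVCall,
    parent_alignment,
    parent: Parent,
    tolerance: int = 2,
    relaxed_params: ReadFilterParams | None = None,
    min_parent_clips: int = 2,
    min_parent_depth: int = 10,
    reference_fasta=None,
    depth_source=None,
) -> ParentalSupport:
    """Count parental split reads witnessing the call's junction.

    Junction evidence is symmetric: the same junction-spanning parental reads
    surface as RIGHT clips at one breakpoint or LEFT clips at the partner
    breakpoint, depending on which read end anchored. Both positions are
    therefore queried — (bp1, RIGHT) and (bp2, LEFT) for resolved DEL/DUP,
    both sides at bp1 otherwise — halving the chance that a truly inherited
    variant shows too few parental clips. ``parent_alignment`` may be None
    (explicitly absent parent -> UNINFORMATIVE). An existing but unindexed
    parent file is fatal.
    """
    if parent_alignment is None:
        return ParentalSupport(parent, 0, 0, Verdict.UNINFORMATIVE)
    params = relaxed_params if relaxed_params is not None else relaxed_parent_filters()
    if call.svtype in (SVType.DEL, SVType.DUP) and call.bp2 is not None:
        probes = [(min(call.bp1, call.bp2), Side.RIGHT), (max(call.bp1, call.bp2), Side.LEFT)]
        if call.svtype is SVType.DUP:
            probes = [(max(call.bp1, call.bp2), Side.RIGHT), (min(call.bp1, call.bp2), Side.LEFT)]
    else:
        probes = [(call.bp1, Side.RIGHT), (call.bp1, Side.LEFT)]
    pad = tolerance + 400  # clips at a locus come from alignments anchored well around it
    regions = [(call.chrom, max(0, p - pad), p + pad) for p, _ in probes]
    srs = extract_split_reads(
        parent_alignment,
        regions=regions,
        params=params,
        reference_fasta=reference_fasta,
    )
    clips = sum(
        1
        for sr in srs
        if any(sr.side == side and abs(sr.clip_pos - p) <= tolerance for p, side in probes)
    )
    if depth_source is None:
        depth_source = BamDepthSource(parent_alignment, reference_fasta)
        depth = depth_source.depth(call.chrom, call.bp1)
        depth_source.close()
    else:
        depth = depth_source.depth(call.chrom, call.bp1)
    # Positive evidence wins regardless of point depth (clips can sit at a
    # breakpoint whose flank, not the point itself, is covered); calling a
    # site ABSENT does require adequate depth.
    if clips >= min_parent_clips:
        verdict = Verdict.PRESENT
    elif depth >= min_parent_depth:
        verdict = Verdict.ABSENT
    else:
        verdict = Verdict.UNINFORMATIVE
    return ParentalSupport(parent, clips, depth, verdict)


def classify_inheritance(mother: ParentalSupport | None, father: ParentalSupport | None) -> InheritanceStatus:
    """Map the pair of parental verdicts to an inheritance status.

    DE_NOVO requires both parents confidently ABSENT; a single PRESENT parent
    gives MATERNAL/PATERNAL (the other parent may be ABSENT or UNINFORMATIVE);
    both PRESENT gives BIPARENTAL; anything else is UNKNOWN. A missing parent
    counts as UNINFORMATIVE, so every verdict combination maps to exactly one
    status.
    """
    mv = mother.verdict if mother is not None else Verdict.UNINFORMATIVE
    fv = father.verdict if father is not None else Verdict.UNINFORMATIVE
    m_present = mv is Verdict.PRESENT
    f_present = fv is Verdict.PRESENT
    if m_present and f_present:
        return InheritanceStatus.BIPARENTAL
    if m_present:
        return InheritanceStatus.MATERNAL
    if f_present:
        return InheritanceStatus.PATERNAL
    if mv is Verdict.ABSENT and fv is Verdict.ABSENT:
        return InheritanceStatus.DE_NOVO
    return InheritanceStatus.UNKNOWN
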