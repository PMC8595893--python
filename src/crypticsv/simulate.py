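"""Synthetic truth-labeled trio exome data (fixtures, training, benchmarking).

The simulator builds a random reference with evenly spaced capture targets,
implants non-overlapping SVs (DEL/DUP/INS/MEI) into per-individual haplotypes,
and writes coordinate-sorted indexed BAMs. Alignments are synthesized by
projecting each read through the known haplotype-to-reference coordinate map,
so reads spanning an SV junction carry exact soft-clip CIGARs — no read
aligner is involved and every output is a pure function of the configuration.

What it emulates: clip-correct split reads at SV junctions, doubled coverage
across tandem duplications, heterozygous transmission in trios, uniform base
errors, and two artifact modes (scattered junk clips and recurrent low-quality
clipping sites). What it does not: aligner-specific clip jitter, GC/capture
bias, empirical error profiles, discordant-pair signal (unused downstream, so
reads are written single-end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from ._io import meta_lines, write_tsv
from .clustering import BamDepthSource, cluster_split_reads, compute_cluster_features
from .junctiondb import SVType
from .scoring import LABEL_ARTIFACT, LABEL_TRUE, LabeledExample
from .splitread import ReadFilterParams, extract_split_reads

log = logging.getLogger(__name__)

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Size strata used when planning variants and reporting recall.
SIZE_BINS = [(21, 50), (51, 100), (101, 500), (501, 10_000)]

#: Fixed seed for the synthetic repeat-consensus stand-ins (Alu/L1/SVA-like);
#: users substitute real consensus sequences for real data.
REPEAT_PANEL_SEED = 920_211


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode()


def default_repeat_panel() -> dict:
    rng = np.random.default_rng(REPEAT_PANEL_SEED)
    return {
        "Alu": random_dna(rng, 300),
        "L1": random_dna(rng, 6000),
        "SVA": random_dna(rng, 1300),
    }


@dataclass
class SimConfig:
    """Study conditions for one simulated exome.

    Defaults give a desk-scale exome: 5 Mb reference, 500 targets of 200 bp
    (100 kb on target), 30x coverage with 100 bp reads, 0.1% base error.
    """

    seed: int
    ref_length: int = 5_000_000
    n_targets: int = 500
    target_len: int = 200
    coverage: float = 30.0
    read_len: int = 100
    frag_mean: int = 300
    frag_sd: int = 50
    error_rate: float = 0.001
    artifact_clip_rate: float = 0.005
    n_artifact_sites: int = 15
    min_anchor: int = 20
    chrom: str = "chr1"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory (no wall-clock entropy)")
        for name in ("ref_length", "n_targets", "target_len", "coverage", "read_len", "frag_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthVariant:
    """Ground-truth implanted variant for one genome."""

    svtype: SVType
    chrom: str
    start: int
    length: int
    carrier: str  # PROBAND_DENOVO | MOTHER | FATHER
    sample_id: str = ""
    inserted_seq: str | None = None
    repeat_family: str | None = None
    zygosity: str = "HET"

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.svtype is SVType.MEI and not self.inserted_seq:
            raise ValueError("MEI requires an inserted sequence from a repeat consensus")

    def breakpoints(self) -> tuple:
        if self.svtype in (SVType.DEL, SVType.DUP):
            return (self.start, self.start + self.length)
        return (self.start,)

    def signed_len(self) -> int:
        return -self.length if self.svtype is SVType.DEL else self.length


@dataclass
class Haplotype:
    """One haplotype sequence plus its mapping back to the reference.

    ``blocks`` are (hap_start, ref_start, length) for reference-copied
    segments, merged when contiguous in both coordinate systems; inserted
    sequence lies in the gaps between blocks.
    """

    seq: str
    blocks: list

    def hap_to_ref(self, hap_pos: int) -> int | None:
        for hs, rs, ln in self.blocks:
            if hs <= hap_pos < hs + ln:
                return rs + (hap_pos - hs)
        return None

    def ref_to_hap(self, ref_pos: int) -> list:
        out = []
        for hs, rs, ln in self.blocks:
            if rs <= ref_pos < rs + ln:
                out.append(hs + (ref_pos - rs))
        return out

    def ref_interval_images(self, start: int, end: int) -> list:
        """Haplotype-coordinate images of a reference interval."""
        out = []
        for hs, rs, ln in self.blocks:
            lo, hi = max(start, rs), min(end, rs + ln)
            if hi > lo:
                out.append((hs + lo - rs, hs + hi - rs))
        return sorted(out)

    def mapped_segments(self, start: int, end: int) -> list:
        """(read_offset, ref_start, length) segments of hap interval [start, end)."""
        segs = []
        for hs, rs, ln in self.blocks:
            lo, hi = max(start, hs), min(end, hs + ln)
            if hi > lo:
                segs.append((lo - start, rs + lo - hs, hi - lo))
        return segs


def implant_svs(reference: str, variants) -> tuple:
    """Apply sorted non-overlapping variants to one haplotype.

    DEL removes [start, start+length); DUP tandem-inserts the copy after its
    source; INS/MEI insert ``inserted_seq`` at ``start``. Returns
    (Haplotype, variants).
    """
    variants = sorted(variants, key=lambda v: v.start)
    for a, b in zip(variants, variants[1:]):
        a_end = a.start + (a.length if a.svtype in (SVType.DEL, SVType.DUP) else 0)
        if b.start < a_end:
            raise ValueError("implanted variants overlap")
    pieces = []  # (sequence, ref_start or None)
    cur = 0
    for v in variants:
        if v.start < cur or v.start > len(reference):
            raise ValueError("variant outside remaining reference")
        if v.svtype is SVType.DEL:
            pieces.append((reference[cur : v.start], cur))
            cur = v.start + v.length
        elif v.svtype is SVType.DUP:
            pieces.append((reference[cur : v.start + v.length], cur))
            cur = v.start
        elif v.svtype in (SVType.INS, SVType.MEI):
            if v.inserted_seq is None or len(v.inserted_seq) != v.length:
                raise ValueError("insertion requires inserted_seq of the stated length")
            pieces.append((reference[cur : v.start], cur))
            pieces.append((v.inserted_seq, None))
            cur = v.start
        else:
            raise ValueError(f"simulator does not implant {v.svtype}")
    pieces.append((reference[cur:], cur))

    seq_parts = []
    blocks = []
    hap_pos = 0
    for piece, ref_start in pieces:
        if not piece:
            continue
        if ref_start is not None:
            if blocks and blocks[-1][0] + blocks[-1][2] == hap_pos and blocks[-1][1] + blocks[-1][2] == ref_start:
                hs, rs, ln = blocks[-1]
                blocks[-1] = (hs, rs, ln + len(piece))
            else:
                blocks.append((hap_pos, ref_start, len(piece)))
        seq_parts.append(piece)
        hap_pos += len(piece)
    return Haplotype(seq="".join(seq_parts), blocks=blocks), list(variants)


def make_targets(cfg: SimConfig) -> list:
    spacing = cfg.ref_length // (cfg.n_targets + 1)
    if spacing <= cfg.target_len:
        raise ValueError("reference too short for the requested targets")
    return [(i * spacing, i * spacing + cfg.target_len) for i in range(1, cfg.n_targets + 1)]


# ---------------------------------------------------------------------------
# read simulation


def _project_read(hap: Haplotype, start: int, read_len: int, min_anchor: int):
    """Alignment of a haplotype read: (ref_pos, cigartuples) or None.

    The longest reference-contiguous segment is aligned; the rest is
    soft-clipped (ties: leftmost). Reads whose best segment is shorter than
    ``min_anchor`` would not be confidently placed by an aligner and are
    dropped.
    """
    segs = hap.mapped_segments(start, start + read_len)
    if not segs:
        return None
    best = max(segs, key=lambda s: (s[2], -s[0]))
    off, ref_start, ln = best
    if ln < min_anchor:
        return None
    cigar = []
    if off > 0:
        cigar.append((4, off))
    cigar.append((0, ln))
    tail = read_len - off - ln
    if tail > 0:
        cigar.append((4, tail))
    return ref_start, cigar


def _mutate(seq_arr: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    if error_rate <= 0:
        return seq_arr
    mask = rng.random(seq_arr.shape) < error_rate
    if mask.any():
        shift = rng.integers(1, 4, mask.sum()).astype(np.uint8)
        idx = np.searchsorted(_DNA, seq_arr[mask])
        seq_arr = seq_arr.copy()
        seq_arr[mask] = _DNA[(idx + shift) % 4]
    return seq_arr


def simulate_reads(
    haplotypes,
    cfg: SimConfig,
    targets,
    reference: str,
    out_bam,
    sample_id: str,
    rng: np.random.Generator,
) -> int:
    """Write a sorted, indexed single-end BAM for one individual.

    Fragments are sampled per capture-target image on each haplotype at
    coverage/2; reads are projected through the haplotype block map so
    junction-spanning reads carry exact soft clips. Artifact clips (junk
    clipped tails with low base quality) are added at ``artifact_clip_rate``
    plus ``n_artifact_sites`` recurrent sites. Returns the read count.
    """
    rl = cfg.read_len
    per_hap_cov = cfg.coverage / len(haplotypes)
    records = []  # (pos, name, flag, cigar, seq, quals, mapq)
    serial = 0
    for hap_i, hap in enumerate(haplotypes):
        hap_len = len(hap.seq)
        # Merge the haplotype images of all targets: images that touch at an
        # SV junction would otherwise be sampled twice, doubling coverage at
        # exactly the loci under study.
        images: list = []
        for ts, te in targets:
            images.extend(hap.ref_interval_images(ts, te))
        images.sort()
        merged: list = []
        for iv_s, iv_e in images:
            if merged and iv_s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv_e))
            else:
                merged.append((iv_s, iv_e))
        for iv_s, iv_e in merged:
            window = (iv_e - iv_s) + cfg.frag_mean
            lam = per_hap_cov * window / (2.0 * rl)
            n_frag = rng.poisson(lam)
            if n_frag == 0:
                continue
            centers = rng.uniform(iv_s - cfg.frag_mean / 2.0, iv_e + cfg.frag_mean / 2.0, n_frag)
            flens = np.clip(rng.normal(cfg.frag_mean, cfg.frag_sd, n_frag), rl, None)
            starts = np.concatenate([centers - flens / 2.0, centers + flens / 2.0 - rl])
            starts = np.clip(np.floor(starts).astype(np.int64), 0, max(0, hap_len - rl))
            strands = rng.integers(0, 2, starts.size)
            for s, strand in zip(starts, strands):
                proj = _project_read(hap, int(s), rl, cfg.min_anchor)
                if proj is None:
                    continue
                ref_pos, cigar = proj
                seq_arr = np.frombuffer(hap.seq[s : s + rl].encode(), dtype=np.uint8)
                seq_arr = _mutate(seq_arr, rng, cfg.error_rate)
                quals = rng.integers(28, 41, rl).astype(np.uint8)
                name = f"{sample_id}.h{hap_i}.{serial}"
                serial += 1
                records.append(
                    (ref_pos, name, 16 if strand else 0, cigar, seq_arr.tobytes().decode(), quals, 60)
                )

    n_true = len(records)
    records.extend(
        _artifact_reads(cfg, targets, reference, rng, sample_id, n_true)
    )
    records.sort(key=lambda r: (r[0], r[1]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": cfg.ref_length}],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    out_bam = str(out_bam)
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for pos, name, flag, cigar, seq, quals, mapq in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = cigar
            a.query_sequence = seq
            a.query_qualities = quals.tolist()
            a.set_tag("RG", sample_id)
            bam.write(a)
    pysam.index(out_bam)
    return len(records)


def _artifact_reads(cfg, targets, reference: str, rng, sample_id: str, n_true: int):
    """Junk-clip artifact reads: scattered singles plus recurrent sites."""
    rl = cfg.read_len
    out = []
    serial = 0

    def _one(site: int, jitter: int):
        nonlocal serial
        pos = site + jitter
        clip_len = int(rng.integers(20, 41))
        aligned = rl - clip_len
        side_right = bool(rng.integers(0, 2))
        if side_right:
            ref_start = pos - aligned
            cigar = [(0, aligned), (4, clip_len)]
            body = reference[ref_start:pos]
            seq = body + random_dna(rng, clip_len)
            quals = np.concatenate(
                [rng.integers(28, 41, aligned), rng.integers(8, 26, clip_len)]
            ).astype(np.uint8)
        else:
            ref_start = pos
            cigar = [(4, clip_len), (0, aligned)]
            body = reference[pos : pos + aligned]
            seq = random_dna(rng, clip_len) + body
            quals = np.concatenate(
                [rng.integers(8, 26, clip_len), rng.integers(28, 41, aligned)]
            ).astype(np.uint8)
        if ref_start < 0 or len(body) < aligned:
            return
        name = f"{sample_id}.art.{serial}"
        serial += 1
        out.append((ref_start, name, 0, cigar, seq, quals, int(rng.integers(30, 61))))

    n_scatter = rng.poisson(cfg.artifact_clip_rate * n_true)
    t_idx = rng.integers(0, len(targets), n_scatter)
    for i in t_idx:
        ts, te = targets[i]
        _one(int(rng.integers(ts + 20, te - 20)), 0)

    site_targets = rng.choice(len(targets), size=min(cfg.n_artifact_sites, len(targets)), replace=False)
    for i in site_targets:
        ts, te = targets[i]
        site = int(rng.integers(ts + 30, te - 30))
        for _ in range(int(rng.integers(3, 8))):
            _one(site, int(rng.integers(-1, 2)))
    return out


# ---------------------------------------------------------------------------
# variant planning

_SINGLETON_MENU = [
    (SVType.DEL, 1),
    (SVType.DEL, 3),
    (SVType.DUP, 0),
    (SVType.DUP, 2),
    (SVType.INS, 0),
    (SVType.INS, 1),
    (SVType.MEI, "Alu"),
    (SVType.MEI, "L1"),
]
_MOTHER_MENU = [
    (SVType.DEL, 0),
    (SVType.DEL, 1),
    (SVType.DEL, 2),
    (SVType.DEL, 3),
    (SVType.DUP, 0),
    (SVType.DUP, 1),
    (SVType.DUP, 2),
    (SVType.INS, 0),
    (SVType.INS, 1),
    (SVType.MEI, "Alu"),
    (SVType.MEI, "SVA"),
]
_FATHER_MENU = [
    (SVType.DEL, 0),
    (SVType.DEL, 1),
    (SVType.DEL, 2),
    (SVType.DUP, 0),
    (SVType.DUP, 1),
    (SVType.DUP, 2),
    (SVType.DUP, 3),
    (SVType.INS, 0),
    (SVType.INS, 1),
    (SVType.MEI, "L1"),
]
_DENOVO_MENU = [
    (SVType.DEL, 1),
    (SVType.DUP, 0),
    (SVType.INS, 0),
    (SVType.MEI, "Alu"),
]


def _draw_variant(rng, kind, spec, panel):
    if kind is SVType.MEI:
        consensus = panel[spec]
        max_trunc = min(len(consensus) - 200, 400) if len(consensus) > 400 else 20
        trunc = int(rng.integers(0, max_trunc + 1))
        seq = consensus[trunc:]
        return kind, len(seq), seq, spec
    lo, hi = SIZE_BINS[spec]
    if kind is SVType.INS:
        hi = min(hi, 2000)  # long novel inserts only lengthen the junction
    length = int(rng.integers(lo, hi + 1))
    seq = None
    if kind is SVType.INS:
        seq = random_dna(rng, length)
    return kind, length, seq, None


def plan_variants(
    rng: np.random.Generator,
    menu,
    target_slots: list,
    targets,
    cfg: SimConfig,
    occupied: list,
    carrier: str,
    panel: dict,
) -> list:
    """Place each menu item at a distinct capture target, non-overlapping.

    Breakpoints are placed inside targets (offset 50-150 bp) so junction
    evidence is capturable; reference-span variants reserve their full span
    plus a 300 bp margin against other variants of the same genome.
    """
    out = []
    for kind, spec in menu:
        placed = False
        while target_slots:
            t_i = target_slots.pop()
            ts, te = targets[t_i]
            kind_, length, seq, family = _draw_variant(rng, kind, spec, panel)
            t_len = te - ts
            if kind_ in (SVType.DEL, SVType.DUP) and length <= t_len - 60:
                # exon-disrupting event with both breakpoints in the target,
                # the clinically typical configuration for short SVs
                bp1 = ts + int(rng.integers(25, t_len - length - 25))
            else:
                bp1 = ts + int(rng.integers(50, 151))
            span_end = bp1 + (length if kind_ in (SVType.DEL, SVType.DUP) else 0)
            lo, hi = bp1 - 300, span_end + 300
            if hi >= cfg.ref_length - 1000:
                continue
            if any(lo < o_hi and o_lo < hi for o_lo, o_hi in occupied):
                continue
            occupied.append((lo, hi))
            out.append(
                TruthVariant(
                    svtype=kind_,
                    chrom=cfg.chrom,
                    start=bp1,
                    length=length,
                    carrier=carrier,
                    inserted_seq=seq,
                    repeat_family=family,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place requested {kind.value}; placed {len(out)} variants")
    return out


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortSim:
    """Paths and truth for one simulated cohort."""

    outdir: Path
    cfg: SimConfig
    reference: dict
    ref_fasta: Path
    targets: list
    targets_bed: Path
    gene_model_bed: Path
    gene_modes_tsv: Path
    panel: dict
    panel_fasta: Path
    truth: list
    manifest: list  # dicts: sample_id, alignment, mother, father
    manifest_tsv: Path

    def truth_for(self, sample_id: str) -> list:
        return [t for t in self.truth if t.sample_id == sample_id]

    def trio_probands(self) -> list:
        return [m["sample_id"] for m in self.manifest if m["mother"] != "-"]


def _write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(path))


def _write_gene_model(path_bed, path_modes, targets, chrom, exons_per_gene: int = 5):
    """Group consecutive targets into genes; every gene mono-allelic."""
    rows_bed = []
    rows_modes = []
    for gi in range(0, len(targets), exons_per_gene):
        exons = targets[gi : gi + exons_per_gene]
        start, end = exons[0][0], exons[-1][1]
        name = f"GENE{gi // exons_per_gene:04d}"
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        offsets = ",".join(str(s - start) for s, _ in exons) + ","
        strand = "+" if (gi // exons_per_gene) % 2 == 0 else "-"
        rows_bed.append(
            f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t{len(exons)}\t{sizes}\t{offsets}"
        )
        rows_modes.append(f"{name}\tmonoallelic")
    Path(path_bed).write_text("\n".join(rows_bed) + "\n")
    Path(path_modes).write_text("\n".join(rows_modes) + "\n")


TRUTH_COLUMNS = ["sample_id", "carrier", "svtype", "chrom", "start", "length", "repeat_family"]


def write_truth(path, truth) -> None:
    rows = [
        (t.sample_id, t.carrier, t.svtype.value, t.chrom, t.start + 1, t.length, t.repeat_family or "")
        for t in truth
    ]
    write_tsv(pd.DataFrame(rows, columns=TRUTH_COLUMNS), path, meta_lines("simulate"))


def read_truth(path) -> list:
    from ._io import read_tsv

    df = read_tsv(path)
    out = []
    for r in df.itertuples(index=False):
        svtype = SVType(r.svtype)
        out.append(
            TruthVariant(
                svtype=svtype,
                chrom=str(r.chrom),
                start=int(r.start) - 1,
                length=int(r.length),
                carrier=str(r.carrier),
                sample_id=str(r.sample_id),
                inserted_seq="N" * int(r.length) if svtype in (SVType.INS, SVType.MEI) else None,
                repeat_family=str(r.repeat_family) or None,
            )
        )
    return out


def simulate_cohort(
    outdir,
    cfg: SimConfig,
    n_trios: int = 5,
    n_singletons: int = 5,
) -> CohortSim:
    """Simulate a cohort of trios plus unrelated singleton probands.

    Trio probands inherit every parental variant (the carrier haplotype is
    transmitted) and additionally carry de novo variants; all variants are
    heterozygous. Truth records are per genome: parents list their own
    variants, probands list inherited plus de novo ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    reference = {cfg.chrom: random_dna(rng, cfg.ref_length)}
    ref_seq = reference[cfg.chrom]
    targets = make_targets(cfg)
    panel = default_repeat_panel()

    ref_fasta = outdir / "reference.fa"
    _write_fasta(ref_fasta, reference)
    panel_fasta = outdir / "repeat_panel.fa"
    _write_fasta(panel_fasta, panel)
    targets_bed = outdir / "targets.bed"
    targets_bed.write_text("".join(f"{cfg.chrom}\t{s}\t{e}\n" for s, e in targets))
    gene_bed = outdir / "genes.bed12"
    gene_modes = outdir / "gene_modes.tsv"
    _write_gene_model(gene_bed, gene_modes, targets, cfg.chrom)

    slot_pool = list(rng.permutation(cfg.n_targets))
    ref_hap = Haplotype(seq=ref_seq, blocks=[(0, 0, len(ref_seq))])

    genomes = []  # (sample_id, haplotypes, truth_records, mother_id, father_id)
    truth_all = []

    def _with_samples(variants, sample_id, carrier=None):
        recs = []
        for v in variants:
            recs.append(replace(v, sample_id=sample_id, carrier=carrier or v.carrier))
        return recs

    for i in range(n_trios):
        pro, mom, dad = f"trio{i}_pro", f"trio{i}_mom", f"trio{i}_dad"
        occupied: list = []
        m_vars = plan_variants(rng, _MOTHER_MENU, slot_pool, targets, cfg, occupied, "MOTHER", panel)
        f_vars = plan_variants(rng, _FATHER_MENU, slot_pool, targets, cfg, occupied, "FATHER", panel)
        d_vars = plan_variants(rng, _DENOVO_MENU, slot_pool, targets, cfg, occupied, "PROBAND_DENOVO", panel)
        m_hap, _ = implant_svs(ref_seq, m_vars)
        f_hap, _ = implant_svs(ref_seq, f_vars)
        p_hap_m, _ = implant_svs(ref_seq, sorted(m_vars + d_vars, key=lambda v: v.start))
        genomes.append((mom, [m_hap, ref_hap], _with_samples(m_vars, mom), "-", "-"))
        genomes.append((dad, [f_hap, ref_hap], _with_samples(f_vars, dad), "-", "-"))
        genomes.append(
            (
                pro,
                [p_hap_m, f_hap],
                _with_samples(m_vars, pro) + _with_samples(f_vars, pro) + _with_samples(d_vars, pro),
                mom,
                dad,
            )
        )

    for i in range(n_singletons):
        sid = f"sample{i}"
        occupied = []
        s_vars = plan_variants(rng, _SINGLETON_MENU, slot_pool, targets, cfg, occupied, "PROBAND_DENOVO", panel)
        s_hap, _ = implant_svs(ref_seq, s_vars)
        genomes.append((sid, [s_hap, ref_hap], _with_samples(s_vars, sid), "-", "-"))

    manifest = []
    for g_i, (sid, haps, truth_recs, mom, dad) in enumerate(genomes):
        bam = outdir / f"{sid}.bam"
        child_rng = np.random.default_rng([cfg.seed, 7919, g_i])
        n = simulate_reads(haps, cfg, targets, ref_seq, bam, sid, child_rng)
        log.info("simulated %s: %d reads, %d truth variants", sid, n, len(truth_recs))
        truth_all.extend(truth_recs)
        manifest.append({"sample_id": sid, "alignment": str(bam), "mother": mom, "father": dad})

    manifest_tsv = outdir / "manifest.tsv"
    rows = [f"{m['sample_id']}\t{m['alignment']}\t{m['mother']}\t{m['father']}" for m in manifest]
    manifest_tsv.write_text("sample_id\talignment\tmother\tfather\n" + "\n".join(rows) + "\n")
    write_truth(outdir / "truth.tsv", truth_all)
    _write_truth_vcf(outdir / "truth.vcf", truth_all, cfg)

    return CohortSim(
        outdir=outdir,
        cfg=cfg,
        reference=reference,
        ref_fasta=ref_fasta,
        targets=targets,
        targets_bed=targets_bed,
        gene_model_bed=gene_bed,
        gene_modes_tsv=gene_modes,
        panel=panel,
        panel_fasta=panel_fasta,
        truth=truth_all,
        manifest=manifest,
        manifest_tsv=manifest_tsv,
    )


def _write_truth_vcf(path, truth, cfg: SimConfig) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=crypticsv-simulate {__version__}",
        f"##contig=<ID={cfg.chrom},length={cfg.ref_length}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier genome">',
        '##INFO=<ID=CARRIER,Number=1,Type=String,Description="Trio origin">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = []
    for t in sorted(truth, key=lambda t: (t.chrom, t.start, t.sample_id)):
        end = t.start + t.length if t.svtype in (SVType.DEL, SVType.DUP) else t.start
        info = (
            f"SVTYPE={t.svtype.value};SVLEN={t.signed_len()};END={end + 1};"
            f"SAMPLE={t.sample_id};CARRIER={t.carrier}"
        )
        body.append(f"{t.chrom}\t{t.start + 1}\t.\tN\t<{t.svtype.value}>\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines + body) + "\n")


def simulate_trio(outdir, cfg: SimConfig) -> CohortSim:
    return simulate_cohort(outdir, cfg, n_trios=1, n_singletons=0)


# ---------------------------------------------------------------------------
# truth-set training recipe and evaluation


def training_recipe_config(seed: int) -> SimConfig:
    """Reduced exome used to label training data for the default scorer."""
    return SimConfig(seed=seed, ref_length=1_500_000, n_targets=150)


def labeled_training_set(seed: int, workdir, read_filters: ReadFilterParams | None = None) -> list:
    """Simulate singleton exomes and label their clusters against truth.

    Clusters whose position lies within 5 bp of a truth breakpoint are
    TRUE_VARIANT; everything else is ARTIFACT. This is the documented recipe
    behind the default shipped model.
    """
    cfg = training_recipe_config(seed)
    sim = simulate_cohort(Path(workdir), cfg, n_trios=0, n_singletons=3)
    params = read_filters or ReadFilterParams()
    examples = []
    for m in sim.manifest:
        sid = m["sample_id"]
        srs = extract_split_reads(m["alignment"], params=params, sample_id=sid)
        clusters = cluster_split_reads(srs)
        depth = BamDepthSource(m["alignment"])
        bps = sorted({b for t in sim.truth_for(sid) for b in t.breakpoints()})
        for c in clusters:
            fv = compute_cluster_features(c, depth)
            is_true = any(abs(c.pos - b) <= 5 for b in bps)
            examples.append(
                LabeledExample(fv, LABEL_TRUE if is_true else LABEL_ARTIFACT, source_id=f"{sid}:{c.pos}")
            )
        depth.close()
    return examples


def evaluate_against_truth(calls, truth, match_tol: int = 10) -> dict:
    """Greedy one-to-one matching of calls to truth within each sample.

    A call matches a truth record iff svtype matches and bp1 lies within
    ``match_tol`` of a truth breakpoint; pairs are consumed by increasing
    distance. Returns overall recall/precision, the exact-breakpoint fraction,
    the exact-|svlen| fraction over matched DEL/DUP, and a per-size-bin table.
    """
    calls = list(calls)
    truth = list(truth)
    samples = sorted({t.sample_id for t in truth} | {c.sample_id for c in calls})
    matched_pairs = []
    matched_calls: set = set()
    matched_truth: set = set()
    for sid in samples:
        t_idx = [i for i, t in enumerate(truth) if t.sample_id == sid]
        c_idx = [i for i, c in enumerate(calls) if c.sample_id == sid]
        pairs = []
        for ti in t_idx:
            for ci in c_idx:
                if calls[ci].svtype is not truth[ti].svtype:
                    continue
                if calls[ci].chrom != truth[ti].chrom:
                    continue
                dist = min(abs(calls[ci].bp1 - b) for b in truth[ti].breakpoints())
                if dist <= match_tol:
                    pairs.append((dist, ti, ci))
        pairs.sort()
        for dist, ti, ci in pairs:
            if ti in matched_truth or ci in matched_calls:
                continue
            matched_truth.add(ti)
            matched_calls.add(ci)
            matched_pairs.append((dist, ti, ci))

    n_truth, n_calls = len(truth), len(calls)
    recall = len(matched_truth) / n_truth if n_truth else float("nan")
    precision = len(matched_calls) / n_calls if n_calls else float("nan")
    exact_bp = (
        sum(1 for d, _, _ in matched_pairs if d == 0) / len(matched_pairs) if matched_pairs else float("nan")
    )
    dd_pairs = [
        (ti, ci)
        for _, ti, ci in matched_pairs
        if truth[ti].svtype in (SVType.DEL, SVType.DUP)
    ]
    svlen_exact = (
        sum(
            1
            for ti, ci in dd_pairs
            if calls[ci].svlen is not None and abs(calls[ci].svlen) == truth[ti].length
        )
        / len(dd_pairs)
        if dd_pairs
        else float("nan")
    )
    bin_rows = []
    for lo, hi in SIZE_BINS:
        in_bin = [i for i, t in enumerate(truth) if lo <= t.length <= hi]
        got = sum(1 for i in in_bin if i in matched_truth)
        bin_rows.append((f"{lo}-{hi}", len(in_bin), got, got / len(in_bin) if in_bin else float("nan")))
    per_bin = pd.DataFrame(bin_rows, columns=["size_bin", "n_truth", "n_matched", "recall"])
    return {
        "recall": recall,
        "precision": precision,
        "breakpoint_exact_fraction": exact_bp,
        "svlen_exact_fraction": svlen_exact,
        "n_truth": n_truth,
        "n_calls": n_calls,
        "n_matched": len(matched_pairs),
        "per_bin": per_bin,
    }
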