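"""Gene intersection and the frequency-based filtering cascade (Annotate).

Candidate prioritisation follows three gates drawn from rare-disease
practice: the cluster must be rare in the cohort (call frequency below 0.04%,
with singleton carriers always passing), absent or rare in an external
frequency panel (MAF >= 1e-4 rejected, inclusive), and at least one breakpoint
must fall in or within +/-10 bp of an exon of a gene with an allowed
inheritance mode. Each rejected call is attributed to the FIRST failed rule so
the cascade can be audited.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._io import meta_lines, read_tsv, write_tsv
from .junctiondb import SVCall
from .splitread import Side

log = logging.getLogger(__name__)


class Relation(str, enum.Enum):
    EXONIC = "EXONIC"
    NEAR_EXON = "NEAR_EXON"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


_RELATION_RANK = {Relation.EXONIC: 0, Relation.NEAR_EXON: 1, Relation.INTRONIC: 2, Relation.INTERGENIC: 3}


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list  # half-open 0-based intervals
    inheritance_mode: str = ""

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id} exon {s}-{e} is empty")

    @property
    def span(self):
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class GeneAnnotation:
    gene_id: str | None
    relation: Relation
    distance_bp: int | None


class GeneModel:
    """Exon/gene interval lookup over a list of genes."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes = list(genes)
        self._exons: dict = {}
        self._spans: dict = {}
        for g in self.genes:
            etree = self._exons.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                etree[s:e] = g
            stree = self._spans.setdefault(g.chrom, IntervalTree())
            s, e = g.span
            stree[s:e] = g

    @classmethod
    def from_bed12(cls, path) -> "GeneModel":
        genes = []
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for row in df.itertuples(index=False):
            chrom, start, name, strand = row[0], int(row[1]), row[3], row[5]
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
            exons = [(start + off, start + off + size) for off, size in zip(offsets, sizes)]
            genes.append(Gene(gene_id=name, chrom=chrom, strand=strand, exons=exons))
        return cls(genes)

    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
        genes = []
        for g in db.features_of_type("gene"):
            exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
            if not exons:
                continue
            gid = g.attributes.get("ID", [g.id])[0]
            genes.append(Gene(gene_id=gid, chrom=g.seqid, strand=g.strand, exons=sorted(exons)))
        return cls(genes)

    def set_inheritance_modes(self, modes: dict) -> None:
        for g in self.genes:
            g.inheritance_mode = modes.get(g.gene_id, g.inheritance_mode)


def load_gene_modes(path) -> dict:
    """2-column TSV (gene_id, inheritance mode), disease-gene-panel style."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "mode"], comment="#", dtype=str)
    return dict(zip(df.gene_id, df["mode"]))


def _point_relation(gene: Gene, pos: int, padding: int):
    """(relation, distance) of one breakpoint to one gene."""
    best_dist = None
    for s, e in gene.exons:
        if s <= pos < e:
            return Relation.EXONIC, 0
        dist = s - pos if pos < s else pos - e + 1
        if best_dist is None or dist < best_dist:
            best_dist = dist
    if best_dist is not None and best_dist <= padding:
        return Relation.NEAR_EXON, best_dist
    s, e = gene.span
    if s <= pos < e:
        return Relation.INTRONIC, best_dist
    return Relation.INTERGENIC, best_dist


def intersect_genes(call: SVCall, model: GeneModel, padding: int = 10) -> list:
    """Best relation per gene over the call's breakpoints.

    A call annotates a gene when ANY breakpoint is EXONIC or NEAR_EXON; genes
    whose span merely contains a breakpoint are reported INTRONIC. With no
    overlapping gene a single INTERGENIC annotation is returned (also for
    chromosomes absent from the model, with a warning).
    """
    points = [call.bp1] + ([call.bp2] if call.bp2 is not None else [])
    if call.chrom not in self_spans(model):
        log.warning("chromosome %s absent from gene model", call.chrom)
        return [GeneAnnotation(None, Relation.INTERGENIC, None)]
    candidates: dict = {}
    etree = model._exons.get(call.chrom, IntervalTree())
    stree = model._spans.get(call.chrom, IntervalTree())
    genes = set()
    for p in points:
        for iv in etree.overlap(p - padding, p + padding + 1):
            genes.add(iv.data.gene_id)
            candidates[iv.data.gene_id] = iv.data
        for iv in stree.overlap(p, p + 1):
            genes.add(iv.data.gene_id)
            candidates[iv.data.gene_id] = iv.data
    annos = []
    for gid in sorted(genes):
        gene = candidates[gid]
        best = None
        for p in points:
            rel, dist = _point_relation(gene, p, padding)
            if best is None or _RELATION_RANK[rel] < _RELATION_RANK[best[0]]:
                best = (rel, dist)
        annos.append(GeneAnnotation(gid, best[0], best[1]))
    if not annos:
        return [GeneAnnotation(None, Relation.INTERGENIC, None)]
    return annos


def self_spans(model: GeneModel) -> set:
    return set(model._spans.keys())


@dataclass
class FilterConfig:
    """Thresholds of the candidate filtering cascade."""

    max_call_frequency: float = 0.0004
    panel_maf_exclude: float = 1e-4
    exon_padding: int = 10
    min_support: int = 5
    require_coding_overlap: bool = True
    allowed_modes: tuple | None = None  # None = any gene in the model

    def __post_init__(self):
        if not 0 < self.max_call_frequency <= 1 or not 0 < self.panel_maf_exclude <= 1:
            raise ValueError("frequency thresholds must lie in (0, 1]")
        if self.exon_padding < 0 or self.min_support < 0:
            raise ValueError("padding and support must be >= 0")


class PanelFrequencies:
    """Positional lookup into an external allele-frequency panel.

    Sites are matched by (chrom, side, pos +/- tolerance); the maximum MAF of
    any matching site is returned. Side '*' in the panel matches either side.
    """

    def __init__(self, sites=None, tolerance: int = 2):
        self.tolerance = tolerance
        self._sites: dict = {}
        for chrom, pos, side, af in sites or []:
            self._sites.setdefault((chrom, side), []).append((int(pos), float(af)))
        for v in self._sites.values():
            v.sort()

    @classmethod
    def from_tsv(cls, path, tolerance: int = 2) -> "PanelFrequencies":
        df = read_tsv(path, dtype={"chrom": str, "side": str})
        return cls(
            [(r.chrom, int(r.pos) - 1, str(r.side), float(r.af)) for r in df.itertuples(index=False)],
            tolerance=tolerance,
        )

    def lookup(self, chrom: str, pos: int, side: Side) -> float | None:
        best = None
        for key_side in (side.value, "*"):
            for p, af in self._sites.get((chrom, key_side), []):
                if abs(p - pos) <= self.tolerance:
                    best = af if best is None else max(best, af)
        return best


RULE_FREQUENCY = "call_frequency"
RULE_PANEL = "panel_frequency"
RULE_GENE = "gene_relation"
RULE_SUPPORT = "support"


def filter_calls(
    calls: Sequence[SVCall],
    cohort_db: dict | None,
    panel_freqs: PanelFrequencies | None,
    cfg: FilterConfig,
    gene_model: GeneModel | None = None,
):
    """Apply the cascade; returns (retained, rejection_table).

    Each call must carry its cohort frequency (set at the Database stage) or be
    resolvable through ``cohort_db`` keyed by cluster_key; a missing record is
    fatal (pipeline ordering bug). The rejection table attributes each dropped
    call to the first failed rule, in cascade order: cohort frequency, panel
    frequency, gene relation, split-read support.
    """
    retained = []
    rejected_rows = []
    annotations: dict = {}
    for call in calls:
        freq = call.call_frequency
        carriers = call.carrier_count
        if freq is None:
            rec = (cohort_db or {}).get(call.cohort_key)
            if rec is None:
                raise ValueError(
                    f"call at {call.chrom}:{call.bp1 + 1} has no cohort record (run the Database stage first)"
                )
            freq, carriers = rec.call_frequency, rec.carrier_count
        failed = None
        if (carriers is None or carriers > 1) and freq >= cfg.max_call_frequency:
            failed = RULE_FREQUENCY
        if failed is None and panel_freqs is not None:
            maf = panel_freqs.lookup(call.chrom, call.bp1, call.side)
            if maf is not None and maf >= cfg.panel_maf_exclude:
                failed = RULE_PANEL
        if failed is None and cfg.require_coding_overlap:
            if gene_model is None:
                raise ValueError("require_coding_overlap is set but no gene model was supplied")
            annos = intersect_genes(call, gene_model, cfg.exon_padding)
            annotations[id(call)] = annos
            ok = any(
                a.relation in (Relation.EXONIC, Relation.NEAR_EXON)
                and (
                    cfg.allowed_modes is None
                    or _gene_mode(gene_model, a.gene_id) in cfg.allowed_modes
                )
                for a in annos
                if a.gene_id is not None
            )
            if not ok:
                failed = RULE_GENE
        if failed is None and call.support < cfg.min_support:
            failed = RULE_SUPPORT
        if failed is None:
            retained.append(call)
        else:
            rejected_rows.append(
                (call.sample_id, call.chrom, call.bp1 + 1, call.svtype.value, failed)
            )
    rejection_table = pd.DataFrame(
        rejected_rows, columns=["sample_id", "chrom", "pos", "svtype", "failed_rule"]
    )
    return retained, rejection_table


def _gene_mode(model: GeneModel, gene_id: str) -> str:
    for g in model.genes:
        if g.gene_id == gene_id:
            return g.inheritance_mode
    return ""


def annotate_frame(calls: Sequence[SVCall], gene_model: GeneModel, padding: int) -> pd.DataFrame:
    rows = []
    for call in calls:
        annos = intersect_genes(call, gene_model, padding)
        best = min(annos, key=lambda a: _RELATION_RANK[a.relation])
        rows.append(
            (
                call.sample_id,
                call.chrom,
                call.bp1 + 1,
                "" if call.bp2 is None else call.bp2 + 1,
                call.svtype.value,
                "" if call.svlen is None else call.svlen,
                call.support,
                "" if call.call_frequency is None else f"{call.call_frequency:.8g}",
                best.gene_id or "",
                best.relation.value,
                "" if best.distance_bp is None else best.distance_bp,
                call.inheritance or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "pos",
            "bp2",
            "svtype",
            "svlen",
            "support",
            "call_frequency",
            "gene_id",
            "gene_relation",
            "exon_distance",
            "inheritance",
        ],
    )


def write_candidates(path, calls, gene_model, cfg: FilterConfig) -> None:
    write_tsv(
        annotate_frame(calls, gene_model, cfg.exon_padding),
        path,
        meta_lines("annotate", vars(cfg)),
    )


def write_rejections(path, rejection_table: pd.DataFrame, cfg: FilterConfig) -> None:
    write_tsv(rejection_table, path, meta_lines("annotate", vars(cfg)))
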