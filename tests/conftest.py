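"""Shared fixtures: hand-built BAMs and simulated cohorts (session-scoped)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
import pytest

from crypticsv.config import RunConfig
from crypticsv.junctiondb import read_calls
from crypticsv.pipeline import run_complete
from crypticsv.simulate import SimConfig, simulate_cohort

logging.getLogger("crypticsv").setLevel(logging.WARNING)

CHROM = "chr1"


def make_bam(path, reads, chrom_len: int = 100_000, chrom: str = CHROM, sample: str = "S1", index: bool = True):
    """Write a coordinate-sorted BAM from dicts with keys
    (name, pos, cigar, seq, quals?, mapq?, flag?)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
        "RG": [{"ID": sample, "SM": sample}],
    }
    # unmapped (NO_COOR) records must sort after all mapped ones
    reads = sorted(reads, key=lambda r: (r.get("pos") if r.get("pos") is not None else float("inf"), r["name"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r["name"]
            a.flag = r.get("flag", 0)
            if r.get("pos") is None or r.get("flag", 0) & 4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = 0
                a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            if r.get("cigar"):
                a.cigartuples = r["cigar"]
            a.query_sequence = r["seq"]
            quals = r.get("quals")
            if quals is None:
                quals = [35] * len(r["seq"])
            a.query_qualities = quals
            a.set_tag("RG", sample)
            bam.write(a)
    if index:
        pysam.index(str(path))
    return Path(path)


@dataclass
class CohortRun:
    sim: object
    outdir: Path
    config: RunConfig

    def calls(self, sample_id: str):
        return read_calls(self.outdir / f"{sample_id}.calls.tsv")

    def all_calls(self):
        out = []
        for m in self.sim.manifest:
            out.extend(self.calls(m["sample_id"]))
        return out


def _run_cohort(outdir: Path, sim_cfg: SimConfig, n_trios: int, n_singletons: int) -> CohortRun:
    sim = simulate_cohort(outdir / "sim", sim_cfg, n_trios=n_trios, n_singletons=n_singletons)
    cfg = RunConfig(
        seed=sim_cfg.seed,
        reference=str(sim.ref_fasta),
        repeat_panel=str(sim.panel_fasta),
        gene_model=str(sim.gene_model_bed),
        gene_modes=str(sim.gene_modes_tsv),
    )
    run_complete(cfg, sim.manifest_tsv, outdir / "out")
    return CohortRun(sim=sim, outdir=outdir / "out", config=cfg)


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory) -> CohortRun:
    """The default discovery-conditions cohort: 20 samples at 30x."""
    base = tmp_path_factory.mktemp("default-cohort")
    return _run_cohort(base, SimConfig(seed=1234), n_trios=5, n_singletons=5)


@pytest.fixture(scope="session")
def integrity_cohort(tmp_path_factory) -> CohortRun:
    """Deep trio cohort (60x) for inheritance-integrity checks: 105 inherited
    plus 20 de novo variants across 5 trios."""
    base = tmp_path_factory.mktemp("integrity-cohort")
    cfg = SimConfig(seed=77, ref_length=2_500_000, n_targets=250, coverage=60.0)
    return _run_cohort(base, cfg, n_trios=5, n_singletons=0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> CohortRun:
    """One trio plus one singleton on a reduced exome, for pipeline tests."""
    base = tmp_path_factory.mktemp("small-cohort")
    cfg = SimConfig(seed=55, ref_length=1_500_000, n_targets=150)
    return _run_cohort(base, cfg, n_trios=1, n_singletons=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
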