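"""Pipeline orchestration: per-sample run, batch mode, reports and plots.

``run_sample`` executes the three analysis stages in order — clonality
(map reads, depth, coverage-threshold calls), consensus (subcluster,
assemble, polish) and annotation (V/D/J assignment, identity, productivity,
SHM status) — writing every stage's intermediate artifact into a per-sample
directory so each reported number is traceable to a file on disk.

The sample-level mutational status aggregates over *productive* reported
clones: all unmutated -> ``unmutated``; all mutated -> ``mutated``;
disagreement -> ``discordant-multiclonal`` (flagged for human review, never
silently resolved); nothing reportable -> ``no result``.  The analysis path
contains no randomness, so re-running a sample reproduces its report
byte for byte.

Exit-code contract for the CLI: 0 = success, 2 = structured no-result
(empty input, no clonal gene, no productive consensus), 1 = crash.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import align as ali
from . import annotation as ann
from . import clonality as clo
from . import consensus as con
from .germline import GermlineDB

logger = logging.getLogger("nanovdj")

EXIT_OK = 0
EXIT_CRASH = 1
EXIT_NO_RESULT = 2

STATUS_UNMUTATED = "unmutated"
STATUS_MUTATED = "mutated"
STATUS_DISCORDANT = "discordant-multiclonal"
STATUS_NO_RESULT = "no result"
STATUS_NO_CLONAL = "no clonal rearrangement"

REPORT_COLUMNS = ["sample_id", "clone_id", "v_call", "d_call", "j_call",
                  "depth", "support", "tolerance", "consensus_status",
                  "failure_reason", "v_identity", "junction", "frame_ok",
                  "stop_free", "productive", "shm_status", "borderline"]


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their defaults."""

    coverage_threshold: float = 500.0
    tolerance_schedule: tuple = con.DEFAULT_SCHEDULE
    min_support: int = con.DEFAULT_MIN_SUPPORT
    max_polish_iter: int = con.DEFAULT_MAX_POLISH_ITER
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    score_floor: int = 40
    min_overlap_frac: float = 0.5
    identity_mode: str = "include_indels"
    merge_max_dist: int = 3
    write_sam: bool = False
    plot: bool = True

    def __post_init__(self) -> None:
        if self.coverage_threshold <= 0 or self.min_support < 2:
            raise ValueError("thresholds must be positive (min_support >= 2)")
        self.tolerance_schedule = con.validate_schedule(self.tolerance_schedule)

    @property
    def scoring(self) -> dict:
        return dict(match=self.match, mismatch=self.mismatch,
                    gap_open=self.gap_open, gap_extend=self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tolerance_schedule"] = list(self.tolerance_schedule)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class CloneResult:
    """Everything the pipeline derived for one consensus record."""

    call: clo.ClonalCall
    consensus: con.ConsensusRecord
    annotation: ann.VDJAnnotation | None = None
    shm: ann.SHMResult | None = None


@dataclass
class SampleReport:
    sample_id: str
    status: str
    clonal_calls: list[clo.ClonalCall] = field(default_factory=list)
    clones: list[CloneResult] = field(default_factory=list)
    n_reads: int = 0
    n_aligned: int = 0
    error: str | None = None

    @property
    def exit_code(self) -> int:
        return EXIT_OK if self.status in (STATUS_UNMUTATED, STATUS_MUTATED,
                                          STATUS_DISCORDANT) else EXIT_NO_RESULT

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cr in self.clones:
            a, s = cr.annotation, cr.shm
            rows.append({
                "sample_id": self.sample_id,
                "clone_id": cr.consensus.clone_id,
                "v_call": a.v_call if a else None,
                "d_call": a.d_call if a else None,
                "j_call": a.j_call if a else None,
                "depth": f"{cr.call.depth:.2f}",
                "support": cr.consensus.support,
                "tolerance": ("" if cr.consensus.tolerance is None
                              else f"{cr.consensus.tolerance:.2f}"),
                "consensus_status": cr.consensus.status,
                "failure_reason": (cr.consensus.failure_reason
                                   or (a.exclusion_reason if a else None) or ""),
                "v_identity": (f"{a.v_identity_pct:.2f}"
                               if a and a.v_identity_pct is not None else ""),
                "junction": (a.junction or "") if a else "",
                "frame_ok": _tristate(a.frame_ok if a else None),
                "stop_free": _tristate(a.stop_free if a else None),
                "productive": _tristate(a.productive if a else None),
                "shm_status": s.status if s else "",
                "borderline": _tristate(s.borderline if s else None),
            })
        if not rows:
            rows.append({**{c: "" for c in REPORT_COLUMNS},
                         "sample_id": self.sample_id})
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        df["sample_status"] = self.status
        return df


def _tristate(value: bool | None) -> str:
    return "" if value is None else str(value).lower()


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def aggregate_status(clones: list[CloneResult]) -> str:
    """Sample-level mutational status over productive reported clones."""
    statuses = {cr.shm.status for cr in clones
                if cr.shm is not None and cr.annotation is not None
                and cr.annotation.productive}
    if not statuses:
        return STATUS_NO_RESULT
    if len(statuses) > 1:
        return STATUS_DISCORDANT
    return statuses.pop()


def run_sample(fastq: str | Path, db: GermlineDB, config: PipelineConfig | None = None,
               out_dir: str | Path | None = None,
               sample_id: str | None = None) -> SampleReport:
    """Run clonality -> consensus -> annotation on one FASTQ."""
    config = config or PipelineConfig()
    fastq = Path(fastq)
    sample_id = sample_id or fastq.stem.removesuffix(".fastq")
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    reads = read_fastq(fastq)
    if not reads:
        logger.warning("%s: empty FASTQ", sample_id)
        report = SampleReport(sample_id, STATUS_NO_RESULT, error="empty FASTQ")
        _write_outputs(report, None, config, out)
        return report
    reads_by_id = dict(reads)

    # stage 1: clonality
    alignments = clo.align_reads(reads, db, config.scoring, config.score_floor)
    depth = clo.compute_depth(alignments, db)
    calls = clo.call_clonal_genes(depth, config.coverage_threshold)
    passed = [c for c in calls if c.passed]
    logger.info("%s: %d reads, %d aligned, %d clonal gene(s) [%.1fs]",
                sample_id, len(reads), len(alignments), len(passed),
                time.perf_counter() - t0)
    if out and config.write_sam:
        clo.write_sam(alignments, db, out / f"{sample_id}.alignments.sam", reads_by_id)

    report = SampleReport(sample_id, STATUS_NO_CLONAL, calls,
                          n_reads=len(reads), n_aligned=len(alignments))
    if not passed:
        _write_outputs(report, depth, config, out)
        return report

    # stages 2 + 3 per clonal gene
    for call in passed:
        cluster = clo.select_reads(alignments, call, db, reads_by_id,
                                   config.min_overlap_frac)
        records = con.build_consensus(cluster, config.tolerance_schedule,
                                      config.min_support)
        polished: list[con.ConsensusRecord] = []
        for rec in records:
            if rec.status != con.STATUS_OK:
                report.clones.append(CloneResult(call, rec))
                continue
            polished.append(con.polish(rec, cluster.reads, config.max_polish_iter))
        # partitions of one rearrangement converge to (nearly) the same
        # sequence after polishing: absorb records within the polish error
        # bar of a better-supported one
        polished.sort(key=lambda r: (-r.support, r.clone_id))
        merged: list[con.ConsensusRecord] = []
        for rec in polished:
            for kept in merged:
                if ali.edit_distance(rec.sequence, kept.sequence,
                                     k=config.merge_max_dist) >= 0:
                    kept.support += rec.support
                    kept.read_ids = kept.read_ids + rec.read_ids
                    break
            else:
                merged.append(rec)
        for rec in merged:
            a = ann.annotate(rec, db, config.scoring, config.identity_mode,
                             config.score_floor)
            shm = None
            if a.reportable and a.v_identity_pct is not None:
                shm = ann.classify_shm(rec.clone_id, a.v_identity_pct)
            report.clones.append(CloneResult(call, rec, a, shm))

    report.status = aggregate_status(report.clones)
    logger.info("%s: status '%s' [%.1fs total]", sample_id, report.status,
                time.perf_counter() - t0)
    _write_outputs(report, depth, config, out)
    return report


def _write_outputs(report: SampleReport, depth: pd.DataFrame | None,
                   config: PipelineConfig, out: Path | None) -> None:
    if out is None:
        return
    sid = report.sample_id
    report.to_frame().to_csv(out / f"{sid}.report.tsv", sep="\t", index=False)
    if depth is not None:
        d = depth.copy()
        d["depth"] = d["depth"].map(lambda x: f"{x:.2f}")
        d.to_csv(out / f"{sid}.depth.tsv", sep="\t")
        clo.calls_to_frame(report.clonal_calls).to_csv(
            out / f"{sid}.clonal_calls.tsv", sep="\t", index=False)
        if config.plot:
            clo.clonality_plot(depth, config.coverage_threshold,
                               out / f"{sid}.clonality.png", sid)
    with open(out / f"{sid}.consensus.fasta", "w") as fh:
        for cr in report.clones:
            rec = cr.consensus
            if rec.status == con.STATUS_OK:
                fh.write(f">{sid}|{rec.clone_id}|support={rec.support}"
                         f"|tolerance={rec.tolerance:.2f}|status={rec.status}\n"
                         f"{rec.sequence}\n")


def run_batch(sample_sheet: str | Path, db: GermlineDB,
              config: PipelineConfig | None = None,
              out_dir: str | Path = "nanovdj_out") -> pd.DataFrame:
    """Run every sample in a sheet (CSV: sample_id, fastq_path); never abort the batch.

    Writes one combined per-clone table plus a per-category summary mirroring
    the operational outcome classes (unmutated / mutated /
    discordant-multiclonal / no result / no clonal rearrangement / failed).
    """
    sheet = pd.read_csv(sample_sheet)
    if sheet.empty:
        raise ValueError("empty sample sheet")
    if not {"sample_id", "fastq_path"} <= set(sheet.columns):
        raise ValueError("sample sheet needs columns: sample_id, fastq_path")
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    statuses = []
    for row in sheet.itertuples(index=False):
        sid = str(row.sample_id)
        try:
            rep = run_sample(row.fastq_path, db, config, out / sid, sample_id=sid)
            frames.append(rep.to_frame())
            statuses.append((sid, rep.status))
        except Exception as exc:  # one sample must not sink the batch
            logger.error("sample %s failed: %s", sid, exc)
            fail = pd.DataFrame([{**{c: "" for c in REPORT_COLUMNS},
                                  "sample_id": sid,
                                  "failure_reason": str(exc)}],
                                columns=REPORT_COLUMNS)
            fail["sample_status"] = "failed"
            frames.append(fail)
            statuses.append((sid, "failed"))

    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out / "batch_report.tsv", sep="\t", index=False)
    summary = (pd.DataFrame(statuses, columns=["sample_id", "sample_status"])
               .groupby("sample_status").size().rename("n_samples").reset_index()
               .sort_values("sample_status"))
    summary.to_csv(out / "batch_summary.tsv", sep="\t", index=False)
    logger.info("batch: %d samples -> %s", len(statuses), out / "batch_report.tsv")
    return combined
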