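"""Clonality stage: read mapping, per-V-gene depth, coverage-threshold calls.

A leukemic clone shows up as a coverage peak over its rearranged V gene when
amplicon reads are aligned back to the germline locus.  This stage aligns
every read to the locus contig (best local alignment, both strands), folds
the alignments into a per-V-gene depth table, and calls clonotypic V genes
as those whose mean per-base depth reaches the coverage threshold (500X by
default, inclusive).  Reads supporting a called gene are then collected —
oriented to the plus strand — for consensus building.

Depth is *mean per-base coverage* over the gene interval: total aligned
(match/mismatch) bases falling inside the interval divided by gene length.
The overlapping-read count is reported alongside but never used for calling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .align import (DEFAULT_SCORE_FLOOR, DEFAULT_SCORING, LocalAlignment,
                    revcomp, strand_aware_align)
from .germline import GermlineDB

logger = logging.getLogger("nanovdj")


@dataclass
class ReadAlignment:
    """Best local alignment of one read on the locus contig.

    ``t_start``/``t_end`` are 0-based half-open contig coordinates; the
    embedded :class:`LocalAlignment` is in the oriented-read frame (i.e. on
    the reverse-complement for minus-strand reads).
    """

    read_id: str
    contig_id: str
    strand: str  # "+" or "-"
    alignment: LocalAlignment
    read_length: int

    @property
    def t_start(self) -> int:
        return self.alignment.t_start

    @property
    def t_end(self) -> int:
        return self.alignment.t_end

    @property
    def mapped_fraction(self) -> float:
        return (self.alignment.q_end - self.alignment.q_start) / self.read_length

    def ref_covered(self, start: int, end: int) -> int:
        """Aligned (match/mismatch) bases falling inside [start, end) on the contig."""
        covered = 0
        pos = self.t_start
        for op, n in self.alignment.ops:
            if op in "=X":
                lo, hi = max(pos, start), min(pos + n, end)
                if hi > lo:
                    covered += hi - lo
                pos += n
            elif op == "D":
                pos += n
        return covered


@dataclass
class ClonalCall:
    v_name: str
    depth: float
    n_reads: int
    passed: bool
    rank: int


@dataclass
class ReadCluster:
    """Reads supporting one candidate clonal V gene, oriented to the + strand."""

    v_name: str
    reads: list[tuple[str, str]]  # (read_id, plus-strand sequence)

    def __len__(self) -> int:
        return len(self.reads)


def align_reads(reads: list[tuple[str, str]], db: GermlineDB,
                scoring: dict | None = None,
                score_floor: int = DEFAULT_SCORE_FLOOR) -> list[ReadAlignment]:
    """Align each read to the locus contig; keep one best alignment per read.

    Both strands are tried and the higher-scoring local alignment kept;
    reads whose best score falls below ``score_floor`` are dropped.
    ``reads`` is a list of (read_id, sequence).
    """
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    if not reads:
        warnings.warn("empty read set: no alignments produced", stacklevel=2)
        return []
    out: list[ReadAlignment] = []
    n_unmapped = 0
    for read_id, seq in reads:
        best = strand_aware_align(seq, db.contig_seq, **scoring)
        if best is None or best[0].score < score_floor:
            n_unmapped += 1
            continue
        out.append(ReadAlignment(read_id, db.contig_id, best[1], best[0], len(seq)))
    logger.info("aligned %d/%d reads (floor %d)", len(out), len(reads), score_floor)
    return out


def compute_depth(alignments: list[ReadAlignment], db: GermlineDB) -> pd.DataFrame:
    """Per-V-gene mean depth and overlapping-read count.

    Returns a DataFrame indexed by V gene name with columns ``depth`` (mean
    per-base coverage over the gene interval) and ``n_reads`` (reads whose
    alignment overlaps the interval at all), covering every V gene in the DB.
    """
    v_genes = db.v_genes
    rows = {g.name: [0.0, 0] for g in v_genes}
    for ra in alignments:
        if ra.contig_id != db.contig_id:
            raise ValueError(f"alignment of {ra.read_id} on foreign contig {ra.contig_id}")
        for g in v_genes:
            _, start, end = g.interval
            if ra.t_end <= start or ra.t_start >= end:
                continue
            covered = ra.ref_covered(start, end)
            rows[g.name][0] += covered / g.length
            if covered > 0:
                rows[g.name][1] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["depth", "n_reads"])
    df.index.name = "v_name"
    df["n_reads"] = df["n_reads"].astype(int)
    return df


def call_clonal_genes(depth: pd.DataFrame, threshold: float = 500.0) -> list[ClonalCall]:
    """Call clonotypic V genes: depth >= threshold (inclusive).

    Output is sorted by depth descending, ties broken by gene name ascending;
    ``rank`` is the 1-based position in that order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    order = sorted(depth.index, key=lambda g: (-depth.at[g, "depth"], g))
    calls = [ClonalCall(g, float(depth.at[g, "depth"]), int(depth.at[g, "n_reads"]),
                        bool(depth.at[g, "depth"] >= threshold), rank)
             for rank, g in enumerate(order, 1)]
    n_passed = sum(c.passed for c in calls)
    logger.info("clonal calls: %d/%d V genes at >=%.0fX", n_passed, len(calls), threshold)
    return calls


def select_reads(alignments: list[ReadAlignment], call: ClonalCall, db: GermlineDB,
                 reads_by_id: dict[str, str],
                 min_overlap_frac: float = 0.5) -> ReadCluster:
    """Collect reads supporting a passed clonal call, oriented to the + strand.

    A read belongs to the cluster when its alignment overlaps the called gene
    interval by at least ``min_overlap_frac`` of the *gene* length.  Sequences
    of minus-strand reads are reverse-complemented so the whole cluster is in
    pipeline (locus) orientation.
    """
    if not call.passed:
        raise ValueError(f"select_reads requires a passed call ({call.v_name})")
    gene = db[call.v_name]
    _, start, end = gene.interval
    members: list[tuple[str, str]] = []
    for ra in alignments:
        overlap = min(ra.t_end, end) - max(ra.t_start, start)
        if overlap >= min_overlap_frac * gene.length:
            seq = reads_by_id[ra.read_id]
            members.append((ra.read_id, revcomp(seq) if ra.strand == "-" else seq))
    if not members:
        raise RuntimeError(
            f"internal inconsistency: {call.v_name} passed at {call.depth:.0f}X "
            "but no read meets the overlap rule")
    return ReadCluster(call.v_name, members)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def calls_to_frame(calls: list[ClonalCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"v_name": c.v_name, "depth": round(c.depth, 2), "n_reads": c.n_reads,
          "passed": str(c.passed).lower(), "rank": c.rank} for c in calls])


def write_sam(alignments: list[ReadAlignment], db: GermlineDB, path,
              reads_by_id: dict[str, str]) -> None:
    """Export alignments as plain SAM (soft-clipped ends, NM tag)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{db.contig_id}\tLN:{len(db.contig_seq)}\n")
        fh.write("@PG\tID:nanovdj\tPN:nanovdj\n")
        for ra in alignments:
            aln = ra.alignment
            seq = reads_by_id[ra.read_id]
            flag = 16 if ra.strand == "-" else 0
            if ra.strand == "-":
                seq = revcomp(seq)
            runs: list[tuple[str, int]] = []
            if aln.q_start:
                runs.append(("S", aln.q_start))
            for op, n in aln.ops:
                ch = "M" if op in "=X" else op
                if runs and runs[-1][0] == ch:
                    runs[-1] = (ch, runs[-1][1] + n)
                else:
                    runs.append((ch, n))
            tail = len(seq) - aln.q_end
            if tail:
                runs.append(("S", tail))
            cigar = [f"{n}{ch}" for ch, n in runs]
            nm = aln.n_mismatch + aln.n_ins + aln.n_del
            fh.write(f"{ra.read_id}\t{flag}\t{db.contig_id}\t{aln.t_start + 1}\t60\t"
                     f"{''.join(cigar)}\t*\t0\t0\t{seq}\t*\tNM:i:{nm}\tAS:i:{aln.score}\n")


def clonality_plot(depth: pd.DataFrame, threshold: float, path,
                   sample_id: str = "") -> None:
    """Per-V-gene depth bar chart with the coverage threshold marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(depth)), 3.2))
    ax.bar(depth.index, depth["depth"], color="#4878a8")
    ax.axhline(threshold, color="crimson", linestyle="--", linewidth=1,
               label=f"threshold {threshold:.0f}X")
    ax.set_ylabel("mean depth (X)")
    ax.set_title(f"Clonality {sample_id}".strip())
    ax.tick_params(axis="x", rotation=60)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
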