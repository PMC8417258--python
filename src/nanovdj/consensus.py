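"""Consensus stage: subcluster reads, assemble drafts, polish by re-calling.

Reads selected for one clonal V gene may mix several rearrangements (two
clones can share a V gene), so the cluster is first partitioned by greedy
centroid clustering on normalised edit distance.  Assembly then walks an
*escalating tolerance schedule*: at each acceptable-divergence level the
cluster is partitioned, partitions below the supporting-read minimum are
dropped, and a draft consensus is built per surviving partition; escalation
stops at the first level that yields at least one draft.  With ~10% read
error the low levels shatter the cluster into unsupported singletons and the
first workable level is the one that tolerates roughly twice the per-read
error rate — the schedule is how the pipeline adapts to the instrument's
error rate without knowing it.

Drafts are star alignments: every read is aligned to the partition's medoid
read and columns are called by majority, including insertion columns
supported by more than half of the covering reads (the medoid itself carries
~4% deletions; insertion columns are what recovers those bases).  Polishing
repeats the same re-call against the current consensus until the sequence is
a fixed point, which typically takes one or two rounds.

Everything is deterministic without a seed: reads are processed sorted by
length (descending) then read id, and all voting ties break alphabetically.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import edlib

from .align import norm_distance
from .clonality import ReadCluster

logger = logging.getLogger("nanovdj")

DEFAULT_SCHEDULE = (0.05, 0.10, 0.15, 0.20)
DEFAULT_MIN_SUPPORT = 20
DEFAULT_MAX_POLISH_ITER = 5
MAX_CENTROIDS = 64        # greedy clustering stops seeding new centroids here
MEDOID_SAMPLE = 40        # reads entering the all-pairs medoid computation
MAX_VOTING_READS = 500    # reads entering column voting / polishing

STATUS_OK = "ok"
STATUS_LOW_SUPPORT = "filtered_low_support"
STATUS_FAILED = "failed"


@dataclass
class ConsensusRecord:
    """One assembled (and optionally polished) clone consensus."""

    clone_id: str
    sequence: str
    support: int
    tolerance: float | None
    status: str
    failure_reason: str | None = None
    polish_iters: int = 0
    converged: bool = False
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == STATUS_OK and not self.sequence:
            raise ValueError("ok record with empty sequence")
        if self.status != STATUS_OK and self.sequence:
            raise ValueError("failed record must carry no sequence")


def validate_schedule(schedule) -> tuple[float, ...]:
    sched = tuple(float(t) for t in schedule)
    if not sched:
        raise ValueError("tolerance schedule must be non-empty")
    if any(not 0.0 < t < 0.5 for t in sched):
        raise ValueError("tolerances must be in (0, 0.5)")
    if any(b <= a for a, b in zip(sched, sched[1:])):
        raise ValueError("tolerance schedule must be strictly increasing")
    return sched


def _sorted_reads(reads: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return sorted(reads, key=lambda r: (-len(r[1]), r[0]))


def subcluster(cluster: ReadCluster, tolerance: float,
               max_centroids: int = MAX_CENTROIDS) -> list[list[tuple[str, str]]]:
    """Greedy centroid partitioning by normalised edit distance.

    Reads are processed sorted by length descending (ties by read id).  Each
    read joins the closest existing partition whose centroid — the partition's
    seeding read — lies within ``2 * tolerance`` normalised edit distance,
    otherwise it seeds a new partition.  Once ``max_centroids`` partitions
    exist, non-matching reads become singleton partitions that attract no
    further members (they are support-filtered downstream anyway).
    """
    if not len(cluster):
        raise ValueError("cannot subcluster an empty read cluster")
    reads = _sorted_reads(cluster.reads)
    cutoff = 2.0 * tolerance
    centroids: list[str] = []
    partitions: list[list[tuple[str, str]]] = []
    overflow: list[list[tuple[str, str]]] = []
    for read in reads:
        best_i, best_d = -1, cutoff
        for i, cent in enumerate(centroids):
            d = norm_distance(read[1], cent, k_frac=cutoff)
            if d <= best_d and (best_i < 0 or d < best_d):
                best_i, best_d = i, d
        if best_i >= 0:
            partitions[best_i].append(read)
        elif len(centroids) < max_centroids:
            centroids.append(read[1])
            partitions.append([read])
        else:
            overflow.append([read])
    return partitions + overflow


def _medoid(reads: list[tuple[str, str]]) -> str:
    """Medoid of (a deterministic sample of) the partition's reads."""
    sample = reads[:MEDOID_SAMPLE]
    if len(sample) == 1:
        return sample[0][1]
    n = len(sample)
    totals = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            d = norm_distance(sample[i][1], sample[j][1])
            totals[i] += d
            totals[j] += d
    best = min(range(n), key=lambda i: (totals[i], sample[i][0]))
    return sample[best][1]


def _tally(center: str, reads: list[tuple[str, str]]
           ) -> tuple[list[Counter], list[Counter], int]:
    """Column and insertion-junction vote tallies of reads aligned to ``center``."""
    m = len(center)
    base_votes = [Counter() for _ in range(m)]
    ins_votes: list[Counter] = [Counter() for _ in range(m + 1)]
    for _, seq in reads:
        res = edlib.align(seq, center, mode="NW", task="path")
        cigar = res["cigar"]
        qpos = tpos = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                for k in range(n):
                    base_votes[tpos + k][seq[qpos + k]] += 1
                qpos += n
                tpos += n
            elif ch == "I":  # consumes query: insertion relative to center
                ins_votes[tpos][seq[qpos:qpos + n]] += 1
                qpos += n
            elif ch == "D":  # consumes center: read has a gap here
                for k in range(n):
                    base_votes[tpos + k]["-"] += 1
                tpos += n
    return base_votes, ins_votes, len(reads)


def _recall_columns(center: str, reads: list[tuple[str, str]]) -> str:
    """Align reads to ``center`` and re-call every column by majority vote.

    Substitution columns: plurality base, ties to the alphabetically earliest;
    a column is deleted when gaps strictly outnumber the best base.  An
    insertion column between two center positions is emitted when more than
    half of the reads covering that junction carry an insertion there; the
    inserted sequence is the most common one (ties alphabetical).
    """
    voting = reads[:MAX_VOTING_READS]
    m = len(center)
    base_votes, ins_votes, cov = _tally(center, voting)
    junction_cov = [cov] * (m + 1)

    out: list[str] = []
    for j in range(m + 1):
        if ins_votes[j]:
            ins, count = sorted(ins_votes[j].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if count > 0.5 * junction_cov[j]:
                out.append(ins)
        if j == m:
            break
        votes = base_votes[j]
        if not votes:
            out.append(center[j])
            continue
        gap = votes.get("-", 0)
        bases = sorted((b for b in votes if b != "-"),
                       key=lambda b: (-votes[b], b))
        if not bases or gap > votes[bases[0]]:
            continue  # column deleted
        out.append(bases[0])
    return "".join(out)


def build_consensus(cluster: ReadCluster, schedule=DEFAULT_SCHEDULE,
                    min_support: int = DEFAULT_MIN_SUPPORT) -> list[ConsensusRecord]:
    """Assemble draft consensus sequences under the escalating tolerance schedule.

    Returns one ``ok`` record per surviving partition at the first tolerance
    level that yields any, ordered by support descending.  If every level
    fails, a single non-ok record explains why (machine-readable
    ``failure_reason``), mirroring real consensus-building failures where the
    clonal gene is called but the filters leave nothing to assemble.
    """
    if not len(cluster):
        raise ValueError("cannot build a consensus from an empty cluster")
    schedule = validate_schedule(schedule)
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    best_support_seen = 0
    for tol in schedule:
        partitions = subcluster(cluster, tol)
        surviving = [p for p in partitions if len(p) >= min_support]
        best_support_seen = max(best_support_seen, max(len(p) for p in partitions))
        if not surviving:
            logger.info("%s: tolerance %.2f -> %d partitions, none with >=%d reads",
                        cluster.v_name, tol, len(partitions), min_support)
            continue
        surviving.sort(key=lambda p: (-len(p), p[0][0]))
        records = []
        for idx, part in enumerate(surviving):
            part = _sorted_reads(part)
            draft = _recall_columns(_medoid(part), part)
            clone_id = f"{cluster.v_name}.{idx}"
            if not draft:
                records.append(ConsensusRecord(clone_id, "", len(part), tol,
                                               STATUS_FAILED, "empty_draft"))
                continue
            records.append(ConsensusRecord(clone_id, draft, len(part), tol, STATUS_OK,
                                           read_ids=[r[0] for r in part]))
        if any(r.status == STATUS_OK for r in records):
            logger.info("%s: assembled %d consensus at tolerance %.2f",
                        cluster.v_name, len(records), tol)
            return records
    reason = (f"min_support: largest partition {best_support_seen} < {min_support} "
              f"after exhausting tolerance schedule {list(schedule)}")
    logger.warning("%s: consensus building failed (%s)", cluster.v_name, reason)
    return [ConsensusRecord(f"{cluster.v_name}.0", "", best_support_seen, None,
                            STATUS_LOW_SUPPORT, reason)]


REFINE_TRIGGER = 0.30     # indel-pressure fraction that proposes a candidate edit
REFINE_SAMPLE = 150       # reads scoring candidate edits


def _total_distance(seq: str, reads: list[tuple[str, str]]) -> int:
    return sum(edlib.align(r, seq, mode="NW", task="distance")["editDistance"]
               for _, r in reads)


def _refine_indels(center: str, reads: list[tuple[str, str]]) -> str:
    """One steepest-descent indel edit, or ``center`` unchanged.

    Majority column calling is blind to short tandem repeats: when the
    consensus lacks (or carries an extra) repeat unit, the reads' compensating
    indels left-align to *different* junctions, so no single insertion string
    reaches a majority even though most reads carry the unit.  This step
    collects junctions with aggregate insertion pressure and columns with
    aggregate gap pressure of at least ``REFINE_TRIGGER``, turns each into a
    candidate edit (insert the plurality string / delete the column), and
    applies the candidate that most decreases the summed edit distance of the
    supporting reads — only if it strictly decreases it.
    """
    voting = reads[:MAX_VOTING_READS]
    scoring_reads = reads[:REFINE_SAMPLE]
    base_votes, ins_votes, cov = _tally(center, voting)
    candidates: list[str] = []
    for j, votes in enumerate(ins_votes):
        if sum(votes.values()) >= REFINE_TRIGGER * cov:
            ins = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            candidates.append(center[:j] + ins + center[j:])
    for j, votes in enumerate(base_votes):
        if votes.get("-", 0) >= REFINE_TRIGGER * cov:
            candidates.append(center[:j] + center[j + 1:])
    if not candidates:
        return center
    best_seq, best_total = center, _total_distance(center, scoring_reads)
    for cand in candidates:
        total = _total_distance(cand, scoring_reads)
        if total < best_total:
            best_seq, best_total = cand, total
    return best_seq


def polish(record: ConsensusRecord, reads: list[tuple[str, str]] | None = None,
           max_iter: int = DEFAULT_MAX_POLISH_ITER) -> ConsensusRecord:
    """Iteratively realign supporting reads to the consensus and re-call columns.

    Each round re-calls all columns by majority vote; once a round leaves the
    sequence unchanged, repeat-aware indel refinement proposes edits that
    majority voting cannot see (see :func:`_refine_indels`).  Stops after
    ``max_iter`` rounds or at a full fixed point (byte-identical sequence,
    no accepted refinement), flagged as convergence.
    """
    if record.status != STATUS_OK:
        raise ValueError(f"cannot polish a record with status {record.status}")
    if reads is None:
        raise ValueError("polish needs the supporting reads")
    pool = _sorted_reads([r for r in reads if r[0] in set(record.read_ids)] or reads)
    cur = record.sequence
    iters = 0
    converged = False
    for _ in range(max_iter):
        new = _recall_columns(cur, pool)
        if new == cur:
            new = _refine_indels(cur, pool)
        iters += 1
        if new == cur:
            converged = True
            break
        cur = new
    return ConsensusRecord(record.clone_id, cur, record.support, record.tolerance,
                           STATUS_OK, None, iters, converged, record.read_ids)
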