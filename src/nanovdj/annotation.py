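"""Annotation stage: germline V/D/J assignment, identity, productivity, SHM status.

A polished consensus is interrogated against the same germline database the
reads were mapped to: the best-scoring locally aligned V gene defines the
V-region span and the V-region identity; J is sought downstream of the V,
D between them (called only when enough of a D gene survives junctional
trimming to be recognisable); the junction is the consensus substring from
the last V-aligned base through the first J-aligned base.

V-region identity is ``100 * matches / (matches + mismatches + inserted +
deleted bases)`` over the aligned V region, reported to two decimals — the
number the 2% rule is applied to:

    identity >= 98.00  ->  unmutated
    identity <  98.00  ->  mutated      (borderline-flagged in [97.00, 98.00))

A rearrangement is *productive* when the V reading frame propagates through
the junction into J (junction-induced offset = 0 mod 3) and no in-frame stop
codon occurs from the V frame start through the aligned J.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import DEFAULT_SCORE_FLOOR, DEFAULT_SCORING, LocalAlignment, sw_align
from .consensus import STATUS_OK, ConsensusRecord
from .germline import GermlineDB, GermlineGene

logger = logging.getLogger("nanovdj")

UNMUTATED_MIN_IDENTITY = 98.00   # the ERIC 2% rule
BORDERLINE_MIN_IDENTITY = 97.00
D_MIN_ALIGNED = 10               # D called only on >=10 aligned nt ...
D_MIN_IDENTITY = 80.0            # ... at >=80% identity
J_SCORE_FLOOR = 30
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SHMResult:
    clone_id: str
    status: str                  # "mutated" | "unmutated"
    borderline: bool
    v_identity_pct: float


@dataclass
class VDJAnnotation:
    """Germline assignment and derived calls for one consensus."""

    clone_id: str
    v_call: str | None
    d_call: str | None
    j_call: str | None
    v_identity_pct: float | None
    v_region_span: tuple[int, int] | None
    junction: str | None
    frame_ok: bool | None
    stop_free: bool | None
    productive: bool | None
    v_alignment: LocalAlignment | None = None
    j_alignment: LocalAlignment | None = None
    j_gene_offset: int | None = None
    exclusion_reason: str | None = None

    @property
    def reportable(self) -> bool:
        """Eligible for SHM reporting: V and J assigned."""
        return self.v_call is not None and self.j_call is not None


# ---------------------------------------------------------------------------
# Gene assignment
# ---------------------------------------------------------------------------

def assign_v(consensus: ConsensusRecord | str, db: GermlineDB,
             scoring: dict | None = None,
             score_floor: int = DEFAULT_SCORE_FLOOR,
             ) -> tuple[str, LocalAlignment] | None:
    """Best-matching germline V gene for a consensus sequence.

    Every V gene is locally aligned (gene as query, consensus as target);
    the highest score wins, ties broken by higher identity then gene name.
    Returns None when no gene reaches the score floor.
    """
    seq = _consensus_seq(consensus)
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    best: tuple[float, float, str, LocalAlignment] | None = None
    for gene in db.v_genes:
        aln = sw_align(gene.sequence, seq, **scoring)
        if aln is None or aln.score < score_floor:
            continue
        key = (-aln.score, -aln.identity_pct, gene.name)
        if best is None or key < best[:3]:
            best = (*key, aln)
    if best is None:
        return None
    return best[2], best[3]


def assign_dj(consensus: ConsensusRecord | str, v_alignment: LocalAlignment,
              db: GermlineDB, scoring: dict | None = None,
              j_score_floor: int = J_SCORE_FLOOR,
              ) -> tuple[str | None, LocalAlignment | None, int | None,
                         str | None, str | None]:
    """Assign J (required) and D (optional) downstream of the V region.

    Returns ``(j_call, j_alignment_on_consensus, j_gene_offset, d_call,
    junction)``.  J is the best local alignment of any J gene within the
    consensus downstream of the V span.  D is searched between V end and J
    start and called only when >=10 nt of a D gene align at >=80% identity.
    The junction runs from the last V-aligned base to the first J-aligned
    base, inclusive of both anchors.
    """
    seq = _consensus_seq(consensus)
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    v_end = v_alignment.t_end
    tail = seq[v_end:]
    best_j: tuple[float, str, LocalAlignment, int] | None = None
    for gene in db.by_segment("J"):
        aln = sw_align(gene.sequence, tail, **scoring)
        if aln is None or aln.score < j_score_floor:
            continue
        key = (-aln.score, gene.name)
        if best_j is None or key < (best_j[0], best_j[1]):
            best_j = (*key, aln, aln.q_start)
    if best_j is None:
        return None, None, None, None, None
    j_call, j_aln, j_gene_offset = best_j[1], best_j[2].shifted(v_end), best_j[3]

    junction = seq[v_alignment.t_end - 1: j_aln.t_start + 1]

    d_call = None
    between = seq[v_end: j_aln.t_start]
    best_d: tuple[float, float, str] | None = None
    for gene in db.by_segment("D"):
        if len(between) < D_MIN_ALIGNED:
            break
        aln = sw_align(gene.sequence, between, **scoring)
        if aln is None:
            continue
        aligned_d = aln.n_match + aln.n_mismatch
        if aligned_d >= D_MIN_ALIGNED and aln.identity_pct >= D_MIN_IDENTITY:
            key = (-aln.score, -aln.identity_pct, gene.name)
            if best_d is None or key < best_d:
                best_d = key
    if best_d is not None:
        d_call = best_d[2]
    return j_call, j_aln, j_gene_offset, d_call, junction


def compute_identity(v_alignment: LocalAlignment,
                     mode: str = "include_indels") -> float:
    """V-region identity percent from the winning V alignment.

    ``include_indels`` (default): every inserted/deleted base counts once in
    the denominator.  ``substitutions_only``: indel bases are ignored and the
    denominator is matches + mismatches.  Rounded to 2 decimals.
    """
    m, x = v_alignment.n_match, v_alignment.n_mismatch
    if mode == "include_indels":
        denom = m + x + v_alignment.n_ins + v_alignment.n_del
    elif mode == "substitutions_only":
        denom = m + x
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    return round(100.0 * m / denom, 2) if denom else 0.0


# ---------------------------------------------------------------------------
# Productivity
# ---------------------------------------------------------------------------

def check_productivity(consensus: ConsensusRecord | str, v_alignment: LocalAlignment,
                       v_gene: GermlineGene, j_alignment: LocalAlignment,
                       j_gene: GermlineGene, j_gene_offset: int,
                       ) -> tuple[bool, bool, bool]:
    """(frame_ok, stop_free, productive) for an annotated consensus.

    The reading frame is anchored at the V gene's frame offset projected onto
    the consensus through the V alignment start; ``frame_ok`` holds when the
    first codon start inside the aligned J lands on that frame.  ``stop_free``
    holds when no in-frame stop codon occurs between the frame anchor and the
    end of the aligned J.
    """
    seq = _consensus_seq(consensus)
    v_frame = 0 if v_gene.frame_offset is None else v_gene.frame_offset
    # first gene base included in the alignment is q_start (gene is the query)
    f0 = v_alignment.t_start + ((v_frame - v_alignment.q_start) % 3)
    j_frame = 0 if j_gene.frame_offset is None else j_gene.frame_offset
    j_first_codon = j_alignment.t_start + ((j_frame - j_gene_offset) % 3)
    frame_ok = (j_first_codon - f0) % 3 == 0
    stop_free = True
    for i in range(f0, j_alignment.t_end - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            stop_free = False
            break
    return frame_ok, stop_free, frame_ok and stop_free


# ---------------------------------------------------------------------------
# SHM classification
# ---------------------------------------------------------------------------

def classify_shm(clone_id: str, v_identity_pct: float) -> SHMResult:
    """Apply the 2% rule: >=98.00 unmutated, <98.00 mutated.

    The borderline band [97.00, 98.00) is flagged — classification is least
    reliable there — but still classed mutated.
    """
    if not 0.0 <= v_identity_pct <= 100.0:
        raise ValueError(f"identity {v_identity_pct} outside [0, 100]")
    unmutated = v_identity_pct >= UNMUTATED_MIN_IDENTITY
    borderline = BORDERLINE_MIN_IDENTITY <= v_identity_pct < UNMUTATED_MIN_IDENTITY
    return SHMResult(clone_id, "unmutated" if unmutated else "mutated",
                     borderline, v_identity_pct)


# ---------------------------------------------------------------------------
# Full annotation of one consensus
# ---------------------------------------------------------------------------

def annotate(record: ConsensusRecord, db: GermlineDB, scoring: dict | None = None,
             identity_mode: str = "include_indels",
             score_floor: int = DEFAULT_SCORE_FLOOR) -> VDJAnnotation:
    """Run the full assignment chain on one ok consensus record."""
    if record.status != STATUS_OK:
        raise ValueError(f"cannot annotate record with status {record.status}")
    empty = VDJAnnotation(record.clone_id, None, None, None, None, None, None,
                          None, None, None)
    v_hit = assign_v(record, db, scoring, score_floor)
    if v_hit is None:
        empty.exclusion_reason = "no V assigned"
        return empty
    v_call, v_aln = v_hit
    identity = compute_identity(v_aln, identity_mode)
    j_call, j_aln, j_off, d_call, junction = assign_dj(record, v_aln, db, scoring)
    if j_call is None:
        return VDJAnnotation(record.clone_id, v_call, None, None, identity,
                             (v_aln.t_start, v_aln.t_end), None, None, None, None,
                             v_alignment=v_aln, exclusion_reason="no J assigned")
    frame_ok, stop_free, productive = check_productivity(
        record, v_aln, db[v_call], j_aln, db[j_call], j_off)
    return VDJAnnotation(record.clone_id, v_call, d_call, j_call, identity,
                         (v_aln.t_start, v_aln.t_end), junction,
                         frame_ok, stop_free, productive,
                         v_alignment=v_aln, j_alignment=j_aln, j_gene_offset=j_off)


def _consensus_seq(consensus: ConsensusRecord | str) -> str:
    return consensus if isinstance(consensus, str) else consensus.sequence
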