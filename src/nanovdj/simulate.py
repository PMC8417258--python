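"""Ground-truthed clonal IGH amplicon simulator.

Emulates the input of an FR1-primed IGH amplicon sequencing run: one or more
leukemic clones, each a VDJ rearrangement (exonuclease-trimmed V/D/J plus
untemplated N-additions), carrying somatic hypermutation (SHM) on the V
region, read out by a long-read instrument with substitution / insertion /
deletion errors.  Amplicons span the V gene's first full codon (FR1) through
the end of J, giving the ~0.35-0.5 kb products typical of FR1->J consensus
primers.

Deliberate simplifications (documented in the methods note): SHM is
substitution-only and uniform over the V region; sequencing errors are
i.i.d. and context-free; base qualities are constant placeholders (the
pipeline never consumes them); no chimeras or truncations.

Everything is deterministic for a fixed seed, including read orientation
(about half the reads are emitted reverse-complemented, as on a real
flowcell).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import revcomp
from .germline import GermlineDB, GermlineGene

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
PLACEHOLDER_QUAL = "?"  # Phred 30; constant, never used downstream


@dataclass
class CloneSpec:
    """Recipe for one clonal VDJ rearrangement."""

    v_name: str
    d_name: str
    j_name: str
    shm_rate: float = 0.0
    v_trim: int = 0
    d_trim_left: int = 0
    d_trim_right: int = 0
    j_trim: int = 0
    n1: str = ""
    n2: str = ""
    abundance: float = 1.0
    force_unproductive: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.shm_rate <= 0.2:
            raise ValueError("shm_rate must be in [0, 0.2]")
        if min(self.v_trim, self.d_trim_left, self.d_trim_right, self.j_trim) < 0:
            raise ValueError("trims must be non-negative")
        if not 0.0 < self.abundance <= 1.0:
            raise ValueError("abundance must be in (0, 1]")


@dataclass
class ErrorModel:
    """Per-base i.i.d. read error probabilities."""

    sub_rate: float = 0.03
    ins_rate: float = 0.03
    del_rate: float = 0.04

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(not 0.0 <= r <= 0.15 for r in rates):
            raise ValueError("each error rate must be in [0, 0.15]")
        if sum(rates) >= 0.3:
            raise ValueError("total error rate must be < 0.3")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class Junction:
    """Exact component boundaries of a rearranged amplicon (template coords)."""

    v_span: tuple[int, int]
    n1_span: tuple[int, int]
    d_span: tuple[int, int]
    n2_span: tuple[int, int]
    j_span: tuple[int, int]
    j_gene_offset: int  # first J gene base included (== j_trim)


@dataclass
class TruthRecord:
    """Ground truth for one simulated clone."""

    clone_id: str
    sequence: str
    v_name: str
    d_name: str
    j_name: str
    v_identity_pct: float
    productive: bool
    shm_positions: list[int]
    junction: Junction
    read_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    clone_id: str
    reverse: bool

    def fastq_block(self) -> str:
        return (f"@{self.read_id} clone={self.clone_id} strand="
                f"{'-' if self.reverse else '+'}\n{self.sequence}\n+\n"
                f"{PLACEHOLDER_QUAL * len(self.sequence)}\n")


# ---------------------------------------------------------------------------
# Rearrangement
# ---------------------------------------------------------------------------

def recombine(db: GermlineDB, spec: CloneSpec) -> tuple[str, Junction]:
    """Build the rearranged amplicon: trimmed V + n1 + trimmed D + n2 + trimmed J.

    The V contribution starts at the gene's first full codon (``frame_offset``)
    and ends ``v_trim`` bases before the gene end; D loses ``d_trim_left``/
    ``d_trim_right`` bases, J loses ``j_trim`` 5' bases.  Purely deterministic.
    """
    try:
        v, d, j = db[spec.v_name], db[spec.d_name], db[spec.j_name]
    except KeyError as exc:
        raise ValueError(f"unknown gene name {exc.args[0]!r}") from None
    v_part = v.sequence[v.frame_offset: len(v.sequence) - spec.v_trim]
    d_part = d.sequence[spec.d_trim_left: len(d.sequence) - spec.d_trim_right]
    j_part = j.sequence[spec.j_trim:]
    if not v_part or spec.v_trim >= len(v.sequence) - v.frame_offset:
        raise ValueError("v_trim removes the entire V contribution")
    if spec.d_trim_left + spec.d_trim_right > len(d.sequence):
        raise ValueError("D trims exceed D gene length")
    if not j_part:
        raise ValueError("j_trim removes the entire J gene")
    pos = 0
    spans = []
    for part in (v_part, spec.n1, d_part, spec.n2, j_part):
        spans.append((pos, pos + len(part)))
        pos += len(part)
    seq = v_part + spec.n1 + d_part + spec.n2 + j_part
    return seq, Junction(*spans, j_gene_offset=spec.j_trim)


def is_productive(seq: str, junction: Junction, j_gene: GermlineGene) -> tuple[bool, bool]:
    """(frame_ok, stop_free) of a rearranged template.

    The reading frame starts at template position 0 (the V frame start).
    ``frame_ok`` holds when the first codon start inside the included J part
    lands on a template codon boundary; ``stop_free`` when no in-frame stop
    occurs anywhere from the V start through the end of J.
    """
    j_start, j_end = junction.j_span
    offset_in_j = (j_gene.frame_offset - junction.j_gene_offset) % 3
    frame_ok = (j_start + offset_in_j) % 3 == 0
    stop_free = True
    for i in range(0, j_end - 2, 3):
        if seq[i:i + 3] in ("TAA", "TAG", "TGA"):
            stop_free = False
            break
    return frame_ok, stop_free


_STOP_CODONS = ("TAA", "TAG", "TGA")


def apply_shm(sequence: str, v_region_span: tuple[int, int], shm_rate: float,
              rng: np.random.Generator | int, frame: int = 0) -> tuple[str, list[int]]:
    """Apply substitution-only SHM uniformly over the V region.

    Each position in ``v_region_span`` mutates independently with probability
    ``shm_rate``, always to a different base.  Substitutions never create a
    stop codon in the reading frame anchored at ``frame`` (sequence
    coordinates): the rearrangements this assay sequences are expressed, so
    their SHM is under functional selection.  The draw order is fixed — one
    uniform per span position (position selection), then one choice per
    mutated site — so a given generator state always yields the same events.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    start, end = v_region_span
    if not 0 <= start <= end <= len(sequence):
        raise ValueError("v_region_span outside sequence")
    u = rng.random(end - start)
    positions = [start + int(i) for i in np.nonzero(u < shm_rate)[0]]
    seq = list(sequence)
    for pos in positions:
        codon_start = pos - ((pos - frame) % 3)
        allowed = []
        for b in "ACGT":
            if b == seq[pos]:
                continue
            if codon_start < 0:
                allowed.append(b)
                continue
            codon = seq[codon_start:codon_start + 3]
            codon[pos - codon_start] = b
            if "".join(codon) not in _STOP_CODONS:
                allowed.append(b)
        seq[pos] = allowed[int(rng.integers(len(allowed)))]
    return "".join(seq), positions


# ---------------------------------------------------------------------------
# Read-level error channel
# ---------------------------------------------------------------------------

def _corrupt(template: np.ndarray, em: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Pass one template copy through the per-base sub/ins/del channel."""
    n = len(template)
    dels = rng.random(n) < em.del_rate
    subs = rng.random(n) < em.sub_rate
    ins = rng.random(n + 1) < em.ins_rate  # insertion slots: before each base + at end
    out = np.empty(2 * n + 8, np.uint8)
    k = 0
    for i in range(n + 1):
        if ins[i]:
            out[k] = _BASES[rng.integers(4)]
            k += 1
        if i == n:
            break
        if dels[i]:
            continue
        if subs[i]:
            out[k] = _BASES[(np.searchsorted(_BASES, template[i]) + 1 + rng.integers(3)) % 4]
        else:
            out[k] = template[i]
        k += 1
    return out[:k]


def simulate_reads(template: str, n_reads: int, error_model: ErrorModel,
                   rng: np.random.Generator | int, clone_id: str = "clone0",
                   id_prefix: str = "read") -> list[SimulatedRead]:
    """Simulate ``n_reads`` error-bearing copies of ``template``.

    Each read independently passes through the i.i.d. substitution /
    insertion / deletion channel; about half the reads are emitted
    reverse-complemented, with orientation recorded on the read.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    tmpl = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    reads = []
    for i in range(n_reads):
        seq = _corrupt(tmpl, error_model, rng).tobytes().decode("ascii")
        reverse = bool(rng.random() < 0.5)
        if reverse:
            seq = revcomp(seq)
        reads.append(SimulatedRead(f"{id_prefix}_{i:06d}", seq, clone_id, reverse))
    return reads


# ---------------------------------------------------------------------------
# Whole-sample simulation
# ---------------------------------------------------------------------------

def _allocate(total: int, fractions: list[float]) -> list[int]:
    """Largest-remainder rounding of abundance shares to read counts."""
    raw = [total * f for f in fractions]
    counts = [int(x) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_sample(db: GermlineDB, clone_specs: list[CloneSpec], total_reads: int,
                    error_model: ErrorModel, rng_seed: int,
                    ) -> tuple[list[SimulatedRead], list[TruthRecord]]:
    """Simulate a complete sample of one or more clones.

    Per-clone read counts are the largest-remainder rounded abundance shares
    of ``total_reads``.  For a clone with ``force_unproductive`` set, a
    productive draw is made unproductive by lengthening n1 by one base (a
    frame-shifting N-addition), so the truth flag is guaranteed false.
    """
    if not clone_specs:
        raise ValueError("need at least one clone spec")
    ab_sum = sum(s.abundance for s in clone_specs)
    if abs(ab_sum - 1.0) > 1e-9:
        raise ValueError(f"clone abundances sum to {ab_sum}, expected 1")
    rng = np.random.default_rng(rng_seed)
    counts = _allocate(total_reads, [s.abundance for s in clone_specs])

    reads: list[SimulatedRead] = []
    truths: list[TruthRecord] = []
    for ci, (spec, n) in enumerate(zip(clone_specs, counts)):
        clone_id = f"clone{ci}_{spec.v_name}"
        template, junction = recombine(db, spec)
        if spec.force_unproductive and all(is_productive(template, junction, db[spec.j_name])):
            spec = CloneSpec(**{**spec.__dict__, "n1": spec.n1 + "A"})
            template, junction = recombine(db, spec)
        mutated, positions = apply_shm(template, junction.v_span, spec.shm_rate, rng)
        v_len = junction.v_span[1] - junction.v_span[0]
        identity = 100.0 * (1 - len(positions) / v_len)
        frame_ok, stop_free = is_productive(mutated, junction, db[spec.j_name])
        truth = TruthRecord(clone_id, mutated, spec.v_name, spec.d_name, spec.j_name,
                            identity, frame_ok and stop_free, positions, junction)
        if n > 0:
            clone_reads = simulate_reads(mutated, n, error_model, rng,
                                         clone_id=clone_id, id_prefix=f"S{ci}")
            truth.read_ids = [r.read_id for r in clone_reads]
            reads.extend(clone_reads)
        truths.append(truth)
    return reads, truths


def random_clone_spec(db: GermlineDB, rng: np.random.Generator | int,
                      v_name: str | None = None, shm_rate: float = 0.0,
                      abundance: float = 1.0, productive: bool = True,
                      max_tries: int = 200) -> CloneSpec:
    """Draw a random junction (trims + N-additions) with the requested productivity.

    Rejection-samples junction geometry until the *pre-SHM* template has the
    desired productive flag; SHM substitutions applied later can in principle
    create a stop codon, but never change the frame.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    v_names = sorted(g.name for g in db.by_segment("V"))
    d_names = sorted(g.name for g in db.by_segment("D"))
    j_names = sorted(g.name for g in db.by_segment("J"))
    v = v_name or v_names[int(rng.integers(len(v_names)))]
    for _ in range(max_tries):
        d = d_names[int(rng.integers(len(d_names)))]
        j = j_names[int(rng.integers(len(j_names)))]
        d_len = db[d].length
        spec = CloneSpec(
            v_name=v, d_name=d, j_name=j, shm_rate=shm_rate, abundance=abundance,
            v_trim=int(rng.integers(0, 6)),
            d_trim_left=int(rng.integers(0, max(d_len // 3, 1))),
            d_trim_right=int(rng.integers(0, max(d_len // 3, 1))),
            j_trim=int(rng.integers(0, 7)),
            n1="".join(chr(b) for b in _BASES[rng.integers(0, 4, int(rng.integers(0, 9)))]),
            n2="".join(chr(b) for b in _BASES[rng.integers(0, 4, int(rng.integers(0, 9)))]),
            force_unproductive=not productive,
        )
        template, junction = recombine(db, spec)
        if all(is_productive(template, junction, db[j])) == productive:
            return spec
    if not productive:
        return spec  # simulate_sample's frame-break fallback guarantees the flag
    raise RuntimeError("could not draw a productive junction; check the database")


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.fastq_block())


def write_truth(truths: list[TruthRecord], clone_path: str | Path,
                read_map_path: str | Path) -> None:
    """Write the clone table and the read->clone map as TSV."""
    with open(clone_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["clone_id", "v_name", "d_name", "j_name", "v_identity_pct",
                    "productive", "n_shm", "n_reads", "sequence"])
        for t in truths:
            w.writerow([t.clone_id, t.v_name, t.d_name, t.j_name,
                        f"{t.v_identity_pct:.2f}", str(t.productive).lower(),
                        len(t.shm_positions), len(t.read_ids), t.sequence])
    with open(read_map_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "clone_id"])
        for t in truths:
            for rid in t.read_ids:
                w.writerow([rid, t.clone_id])
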