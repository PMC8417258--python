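"""Amplicon simulator: recombination, SHM, error channel, sample assembly."""

import numpy as np
import pytest

import nanovdj as nv
from nanovdj.align import edit_distance, revcomp
from nanovdj.simulate import is_productive


def spec_for(db, **kw):
    base = dict(v_name="IGHV3-23", d_name="IGHD2-2", j_name="IGHJ4")
    base.update(kw)
    return nv.CloneSpec(**base)


class TestRecombine:
    def test_no_trim_no_n_is_pure_concatenation(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        v, d, j = db["IGHV3-23"], db["IGHD2-2"], db["IGHJ4"]
        assert seq == v.sequence[v.frame_offset:] + d.sequence + j.sequence
        assert junc.v_span == (0, v.length - v.frame_offset)

    def test_component_lengths_sum(self, db):
        # V(295, trim 0) + n1(3) + D(trimmed to 15) + n2(2) + J(48) = 363
        d = max(db.by_segment("D"), key=lambda g: g.length)
        assert d.length >= 15, "fixture guarantees a D gene of >=15 nt"
        trim = d.length - 15
        spec = spec_for(db, d_name=d.name, n1="ACG", n2="GT",
                        d_trim_left=trim // 2, d_trim_right=trim - trim // 2)
        seq, junc = nv.recombine(db, spec)
        assert len(seq) == 295 + 3 + 15 + 2 + 48 == 363
        assert junc.d_span[1] - junc.d_span[0] == 15

    def test_full_v_trim_rejected(self, db):
        with pytest.raises(ValueError):
            nv.recombine(db, spec_for(db, v_trim=db["IGHV3-23"].length))

    def test_unknown_gene_rejected(self, db):
        with pytest.raises(ValueError, match="unknown gene"):
            nv.recombine(db, spec_for(db, v_name="IGHV99-9"))


class TestApplySHM:
    def test_rate_zero_is_identity(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        out, positions = nv.apply_shm(seq, junc.v_span, 0.0, 1)
        assert out == seq and positions == []

    def test_rate_one_on_short_span_mutates_all(self, db):
        # shm_rate is capped at 0.2 for CloneSpec but apply_shm itself is total
        seq, junc = nv.recombine(db, spec_for(db))
        out, positions = nv.apply_shm(seq, (0, 10), 1.0, 3)
        assert sorted(positions) == list(range(10))
        assert all(out[i] != seq[i] for i in range(10))
        assert out[10:] == seq[10:]

    def test_mutation_count_matches_independent_bernoulli_redraw(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        span = (0, 300) if junc.v_span[1] >= 300 else junc.v_span
        _, positions = nv.apply_shm(seq, span, 0.03, 42)
        oracle = np.random.default_rng(42)
        expected = int((oracle.random(span[1] - span[0]) < 0.03).sum())
        assert len(positions) == expected

    def test_mutations_confined_to_span_and_substitution_only(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        out, positions = nv.apply_shm(seq, junc.v_span, 0.1, 5)
        assert len(out) == len(seq)
        start, end = junc.v_span
        assert all(start <= p < end for p in positions)
        diffs = [i for i in range(len(seq)) if seq[i] != out[i]]
        assert diffs == sorted(positions)

    def test_never_creates_in_frame_stop(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        for seed in range(10):
            out, _ = nv.apply_shm(seq, junc.v_span, 0.15, seed)
            codons = {out[i:i + 3] for i in range(0, junc.v_span[1] - 2, 3)}
            assert not codons & {"TAA", "TAG", "TGA"}


class TestSimulateReads:
    def test_zero_error_reads_equal_template(self, db):
        seq, _ = nv.recombine(db, spec_for(db))
        reads = nv.simulate_reads(seq, 50, nv.ErrorModel(0, 0, 0), 1)
        assert len(reads) == 50
        for r in reads:
            assert (revcomp(r.sequence) if r.reverse else r.sequence) == seq
        # both orientations occur
        assert 0 < sum(r.reverse for r in reads) < 50

    def test_mean_edit_distance_matches_error_budget(self, db):
        seq, _ = nv.recombine(db, spec_for(db))
        em = nv.ErrorModel(0.03, 0.03, 0.04)
        reads = nv.simulate_reads(seq, 2000, em, 7)
        dists = [edit_distance(revcomp(r.sequence) if r.reverse else r.sequence, seq)
                 for r in reads]
        mean_norm = np.mean(dists) / len(seq)
        assert abs(mean_norm - 0.10) <= 0.01

    @pytest.mark.parametrize("em,kind", [
        (nv.ErrorModel(0.0, 0.05, 0.0), "ins"),
        (nv.ErrorModel(0.0, 0.0, 0.05), "del"),
        (nv.ErrorModel(0.05, 0.0, 0.0), "sub"),
    ])
    def test_realized_rates_match_model_within_3_se(self, db, em, kind):
        """Each error channel, isolated over >=1e5 bases, hits its rate.

        Isolated channels make event counts exact: indels change the read
        length one-for-one, substitutions are positional mismatches.
        """
        seq, _ = nv.recombine(db, spec_for(db))
        n_reads = 10 ** 5 // len(seq) + 1
        reads = nv.simulate_reads(seq, n_reads, em, 11)
        if kind == "ins":
            events = sum(len(r.sequence) - len(seq) for r in reads)
            n_trials = n_reads * (len(seq) + 1)  # one slot before each base + end
            expected = em.ins_rate
        elif kind == "del":
            events = sum(len(seq) - len(r.sequence) for r in reads)
            n_trials = n_reads * len(seq)
            expected = em.del_rate
        else:
            events = sum(
                sum(a != b for a, b in
                    zip(revcomp(r.sequence) if r.reverse else r.sequence, seq))
                for r in reads)
            n_trials = n_reads * len(seq)
            expected = em.sub_rate
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(events / n_trials - expected) <= 3 * se

    def test_byte_reproducible_for_fixed_seed(self, db):
        seq, _ = nv.recombine(db, spec_for(db))
        em = nv.ErrorModel(0.03, 0.03, 0.04)
        a = nv.simulate_reads(seq, 20, em, 9)
        b = nv.simulate_reads(seq, 20, em, 9)
        assert [(r.read_id, r.sequence, r.reverse) for r in a] == \
               [(r.read_id, r.sequence, r.reverse) for r in b]


class TestSimulateSample:
    def test_single_clone_all_reads_mapped(self, db, error_model, tmp_path):
        reads, truths = nv.simulate_sample(db, [spec_for(db)], 100, error_model, 1)
        assert len(reads) == 100
        assert truths[0].read_ids == [r.read_id for r in reads]

    def test_abundance_rounding_is_exact(self, db, error_model):
        specs = [spec_for(db, abundance=0.7),
                 spec_for(db, v_name="IGHV1-2", abundance=0.3)]
        reads, truths = nv.simulate_sample(db, specs, 1000, error_model, 2)
        assert len(truths[0].read_ids) == 700
        assert len(truths[1].read_ids) == 300

    def test_abundances_must_sum_to_one(self, db, error_model):
        specs = [spec_for(db, abundance=0.7), spec_for(db, abundance=0.7)]
        with pytest.raises(ValueError, match="sum"):
            nv.simulate_sample(db, specs, 100, error_model, 1)

    def test_truth_identity_recomputable_from_positions(self, db, error_model):
        reads, truths = nv.simulate_sample(db, [spec_for(db, shm_rate=0.05)],
                                           50, error_model, 3)
        t = truths[0]
        v_len = t.junction.v_span[1] - t.junction.v_span[0]
        assert t.v_identity_pct == pytest.approx(
            100.0 * (1 - len(t.shm_positions) / v_len))

    def test_force_unproductive_flag_guaranteed(self, db, error_model):
        spec = spec_for(db, force_unproductive=True)
        _, truths = nv.simulate_sample(db, [spec], 10, error_model, 4)
        assert truths[0].productive is False

    def test_truth_productivity_matches_frame_rule(self, db):
        seq, junc = nv.recombine(db, spec_for(db))
        frame_ok, stop_free = is_productive(seq, junc, db["IGHJ4"])
        # pure concatenation of frame-0 V and the fixture J: recompute by hand
        j_start = junc.j_span[0]
        expected_frame = (j_start + (db["IGHJ4"].frame_offset % 3)) % 3 == 0
        assert frame_ok == expected_frame

    def test_sample_byte_reproducible(self, db, error_model):
        a = nv.simulate_sample(db, [spec_for(db, shm_rate=0.02)], 30, error_model, 8)
        b = nv.simulate_sample(db, [spec_for(db, shm_rate=0.02)], 30, error_model, 8)
        assert [(r.read_id, r.sequence) for r in a[0]] == \
               [(r.read_id, r.sequence) for r in b[0]]
        assert a[1][0].sequence == b[1][0].sequence
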