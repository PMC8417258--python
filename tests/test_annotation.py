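"""Annotation stage: V/D/J assignment, identity arithmetic, productivity, 2% rule."""

import numpy as np
import pytest

import nanovdj as nv
from nanovdj.align import LocalAlignment
from nanovdj.annotation import annotate, assign_dj, assign_v, classify_shm, compute_identity
from nanovdj.consensus import STATUS_OK
from nanovdj.germline import GermlineDB, GermlineGene


def record_for(seq, clone_id="c.0"):
    return nv.ConsensusRecord(clone_id, seq, 50, 0.05, STATUS_OK)


class TestAssignV:
    def test_exact_germline_copy(self, db):
        hit = assign_v(db["IGHV3-23"].sequence, db)
        assert hit is not None
        v_call, aln = hit
        assert v_call == "IGHV3-23"
        assert compute_identity(aln) == 100.00

    def test_lexicographic_tie_break(self):
        seq = "ACGATCGGATCGATTACGGCTAGCATCGATCGGCTA"
        genes = {
            "IGHVB-1": GermlineGene("IGHVB-1", "V", seq, ("c", 0, len(seq)), 0),
            "IGHVA-1": GermlineGene("IGHVA-1", "V", seq,
                                    ("c", 100, 100 + len(seq)), 0),
        }
        contig = seq + "T" * 64 + seq
        twin = GermlineDB("c", contig, genes)
        v_call, _ = assign_v(seq, twin, score_floor=10)
        assert v_call == "IGHVA-1"

    def test_simulated_clone_recovers_true_v(self, db, error_model):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = nv.random_clone_spec(db, rng, shm_rate=0.03)
            template, _ = nv.recombine(db, spec)
            mutated, _ = nv.apply_shm(template, (0, 290), 0.03, rng)
            v_call, _ = assign_v(mutated, db)
            assert v_call == spec.v_name

    def test_no_v_above_floor(self, db):
        assert assign_v("ACGT" * 10, db, score_floor=80) is None


class TestAssignDJ:
    def test_exact_construction_recovered(self, db):
        spec = nv.CloneSpec(v_name="IGHV3-23", d_name="IGHD3-10", j_name="IGHJ4")
        seq, junc = nv.recombine(db, spec)
        _, v_aln = assign_v(seq, db)
        j_call, j_aln, j_off, d_call, junction = assign_dj(seq, v_aln, db)
        assert (j_call, d_call) == ("IGHJ4", "IGHD3-10")
        assert j_off == 0
        assert j_aln.t_start == junc.j_span[0]

    def test_short_d_not_called_j_still_made(self, db):
        d = db["IGHD3-10"]
        keep = 6
        spec = nv.CloneSpec(v_name="IGHV3-23", d_name="IGHD3-10", j_name="IGHJ4",
                            d_trim_left=(d.length - keep) // 2,
                            d_trim_right=d.length - keep - (d.length - keep) // 2)
        seq, _ = nv.recombine(db, spec)
        _, v_aln = assign_v(seq, db)
        j_call, _, _, d_call, _ = assign_dj(seq, v_aln, db)
        assert j_call == "IGHJ4"
        assert d_call is None

    def test_junction_anchored_on_v_and_j(self, db):
        spec = nv.CloneSpec(v_name="IGHV3-23", d_name="IGHD2-2", j_name="IGHJ4",
                            n1="AAC", n2="GT")
        seq, junc = nv.recombine(db, spec)
        _, v_aln = assign_v(seq, db)
        _, j_aln, _, _, junction = assign_dj(seq, v_aln, db)
        expected = seq[junc.v_span[1] - 1: junc.j_span[0] + 1]
        assert junction == expected

    def test_n_additions_do_not_break_j_call(self, db, error_model):
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            spec = nv.random_clone_spec(db, rng)
            seq, junc = nv.recombine(db, spec)
            _, v_aln = assign_v(seq, db)
            j_call, _, _, d_call, _ = assign_dj(seq, v_aln, db)
            assert j_call == spec.j_name
            d_kept = (db[spec.d_name].length - spec.d_trim_left - spec.d_trim_right)
            if d_kept >= 10:
                assert d_call == spec.d_name


class TestComputeIdentity:
    def test_perfect_match(self):
        aln = LocalAlignment(590, 0, 295, 0, 295, [("=", 295)])
        assert compute_identity(aln) == 100.00

    def test_mismatch_arithmetic(self):
        # 294 matches + 6 mismatches: 294/300 = 98.00
        aln = LocalAlignment(0, 0, 300, 0, 300, [("=", 294), ("X", 6)])
        assert compute_identity(aln) == 98.00

    def test_indels_count_in_denominator(self):
        aln = LocalAlignment(0, 0, 0, 0, 0, [("=", 97), ("I", 2), ("D", 1)])
        assert compute_identity(aln) == 97.00
        assert compute_identity(aln, "substitutions_only") == 100.00

    def test_identity_matches_alignment_free_truth(self, db, error_model):
        """Pipeline identity equals the simulator's mutation-count identity."""
        for seed in (3, 9, 27):
            rng = np.random.default_rng(seed)
            spec = nv.random_clone_spec(db, rng, shm_rate=0.04)
            reads, truths = nv.simulate_sample(db, [spec], 5, error_model, seed)
            hit = assign_v(truths[0].sequence, db)
            ident = compute_identity(hit[1])
            assert ident == pytest.approx(truths[0].v_identity_pct, abs=0.35)


class TestProductivity:
    def test_clean_construction_productive(self, db):
        spec = nv.CloneSpec(v_name="IGHV3-23", d_name="IGHD2-2", j_name="IGHJ4")
        seq, junc = nv.recombine(db, spec)
        from nanovdj.simulate import is_productive
        if not all(is_productive(seq, junc, db["IGHJ4"])):
            rng = np.random.default_rng(0)
            spec = nv.random_clone_spec(db, rng, productive=True)
            seq, junc = nv.recombine(db, spec)
        a = annotate(record_for(seq), db)
        assert a.productive is True

    def test_in_frame_stop_in_junction_kills_productivity(self, db):
        rng = np.random.default_rng(1)
        spec = nv.random_clone_spec(db, rng, productive=True)
        seq, junc = nv.recombine(db, spec)
        a = annotate(record_for(seq), db)
        assert a.productive
        # splice a TAG into the junction on the reading frame
        n1_start = junc.n1_span[0]
        stop_pos = n1_start + (3 - n1_start % 3) % 3
        broken = seq[:stop_pos] + "TAG" + seq[stop_pos + 3:]
        b = annotate(record_for(broken), db)
        assert b.stop_free is False
        assert b.productive is False

    def test_force_unproductive_clones_flagged_by_annotation(self, db, error_model):
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            productive = seed % 2 == 0
            spec = nv.random_clone_spec(db, rng, productive=productive)
            _, truths = nv.simulate_sample(db, [spec], 3, error_model, seed)
            a = annotate(record_for(truths[0].sequence), db)
            assert a.productive == truths[0].productive
            assert a.productive == productive


class TestClassifySHM:
    @pytest.mark.parametrize("identity,status,borderline", [
        (97.00, "mutated", True),
        (97.80, "mutated", True),
        (97.99, "mutated", True),
        (98.00, "unmutated", False),
        (100.00, "unmutated", False),
        (96.99, "mutated", False),
        (0.00, "mutated", False),
    ])
    def test_boundaries(self, identity, status, borderline):
        res = classify_shm("c", identity)
        assert (res.status, res.borderline) == (status, borderline)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_shm("c", 101.0)
        with pytest.raises(ValueError):
            classify_shm("c", -0.5)

    def test_pure_total_function(self):
        for x in np.linspace(0, 100, 1001):
            res = classify_shm("c", float(round(x, 2)))
            assert res.status in ("mutated", "unmutated")
            assert res.status == ("unmutated" if round(x, 2) >= 98.0 else "mutated")
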