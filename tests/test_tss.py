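import numpy as np
import pytest

from conftest import make_experiment, step_experiment
from viraltc.annotation import AnnotatedFeature, GenomeAnnotation, Strand
from viraltc.tss import (
    TSSConfig,
    TSSOrientation,
    TSSRecord,
    call_antisense_genes,
    detect_tss,
    detect_tss_both_strands,
    group_tss_profile,
    orient_tss,
    tss_profile,
)


class TestDetect:
    def test_ideal_step_found_exactly(self):
        exp = step_experiment(step_at=100, depth=50.0)
        recs = detect_tss(exp, Strand.FORWARD)
        assert [r.position for r in recs] == [100]
        assert np.isinf(recs[0].step_ratio)

    def test_reverse_strand_step_found_exactly(self):
        exp = step_experiment(step_at=700, depth=50.0, strand=Strand.REVERSE)
        recs = detect_tss(exp, Strand.REVERSE)
        assert [r.position for r in recs] == [700]

    def test_linear_ramp_produces_no_tss(self):
        # ramp 0 -> 50 over 500 nt: wherever the window ratio could reach 5
        # the downstream mean is still below the 10x depth floor, so no
        # window pair qualifies (checked by direct window arithmetic below)
        L = 1000
        tracks = np.zeros((6, 3, 2, L))
        ramp = np.clip((np.arange(L) - 300) * 0.1, 0, 50)
        tracks[:, :, 0, :] = ramp
        exp = make_experiment(tracks)
        w, cfg = 20, TSSConfig()
        for p in range(w, L - w):
            up = ramp[p - w : p].mean()
            down = ramp[p : p + w].mean()
            ratio = np.inf if up == 0 and down > 0 else (down / up if up else 0)
            assert not (ratio >= cfg.step_ratio_min and down >= cfg.min_coverage)
        assert detect_tss(exp, Strand.FORWARD) == []

    def test_replicate_quorum_blocks_irreproducible_step(self):
        exp = step_experiment(step_at=100, depth=50.0, R=3)
        exp.tracks[:, 2, 0, :] = 0.0  # third replicate never sees the step
        assert detect_tss(exp, Strand.FORWARD, TSSConfig(replicate_quorum=3)) == []
        got = detect_tss(exp, Strand.FORWARD, TSSConfig(replicate_quorum=2))
        assert [r.position for r in got] == [100]

    def test_window_must_fit_genome(self):
        exp = step_experiment(L=30)
        with pytest.raises(ValueError, match="window"):
            detect_tss(exp, Strand.FORWARD, TSSConfig(window=30))

    def test_strand_mirror_symmetry(self, small_bundle):
        """Mirroring coordinates and swapping strands maps TSSs onto each other."""
        exp = small_bundle.experiment
        L = exp.genome_length
        mirrored = make_experiment(
            exp.tracks[:, :, ::-1, ::-1], exp.timepoints, exp.library_size
        )
        fwd = {t.position for t in detect_tss(exp, Strand.FORWARD)}
        rev_m = {L - 1 - t.position for t in detect_tss(mirrored, Strand.REVERSE)}
        assert fwd == rev_m


class TestOrient:
    ANN = GenomeAnnotation(
        "g",
        5000,
        [
            AnnotatedFeature("fwd1", 1000, 1600, Strand.FORWARD),
            AnnotatedFeature("rev1", 2500, 3100, Strand.REVERSE),
        ],
    )

    def test_upstream_of_same_strand_gene_is_sense(self):
        t = orient_tss(TSSRecord(850, Strand.FORWARD, 10.0), self.ANN)
        assert t.orientation is TSSOrientation.SENSE and t.target_feature == "fwd1"

    def test_inside_same_strand_gene_is_internal(self):
        t = orient_tss(TSSRecord(1300, Strand.FORWARD, 10.0), self.ANN)
        assert t.orientation is TSSOrientation.INTERNAL_SENSE and t.target_feature == "fwd1"

    def test_inside_opposite_strand_gene_is_antisense(self):
        t = orient_tss(TSSRecord(2800, Strand.FORWARD, 10.0), self.ANN)
        assert t.orientation is TSSOrientation.ANTISENSE and t.target_feature == "rev1"

    def test_past_three_prime_end_still_antisense(self):
        # forward TSS 50 nt left of a reverse gene's 3' end starts an asRNA
        # that reads into the gene
        t = orient_tss(TSSRecord(2460, Strand.FORWARD, 10.0), self.ANN)
        assert t.orientation is TSSOrientation.ANTISENSE

    def test_isolated_position_is_orphan(self):
        t = orient_tss(TSSRecord(4500, Strand.FORWARD, 10.0), self.ANN)
        assert t.orientation is TSSOrientation.ORPHAN and t.target_feature is None


class TestAntisenseCalls:
    def _exp(self, sense_by_tp, anti_by_tp, L=200):
        tracks = np.zeros((6, 2, 2, L))
        for i in range(6):
            tracks[i, :, 0, 50:150] = sense_by_tp[i]
            tracks[i, :, 1, 50:150] = anti_by_tp[i]
        return make_experiment(tracks)

    def _ann(self, L=200):
        return GenomeAnnotation("g", L, [AnnotatedFeature("g1", 50, 150, Strand.FORWARD)])

    @pytest.mark.parametrize(
        "anti,expected_n,called",
        [
            ([0, 0, 0, 9, 9, 9], 3, True),
            ([0, 0, 0, 9, 9, 0], 2, False),
            ([1, 1, 1, 1, 1, 1], 6, True),
        ],
    )
    def test_dominance_threshold(self, anti, expected_n, called):
        sense = [5, 5, 5, 5, 5, 5] if max(anti) > 1 else [0] * 6
        exp = self._exp(sense, anti)
        (call,) = call_antisense_genes(exp, self._ann())
        assert call.n_timepoints_antisense_dominant == expected_n
        assert call.called is called

    def test_invariant_under_replicate_permutation(self, small_bundle):
        exp = small_bundle.experiment
        shuffled = make_experiment(
            exp.tracks[:, ::-1], exp.timepoints, exp.library_size[:, ::-1]
        )
        a = call_antisense_genes(exp, small_bundle.annotation)
        b = call_antisense_genes(shuffled, small_bundle.annotation)
        assert a == b

    def test_planted_antisense_set_recovered(self, clean_bundle):
        calls = call_antisense_genes(clean_bundle.experiment, clean_bundle.annotation)
        got = sorted(c.feature_id for c in calls if c.called)
        assert got == clean_bundle.truth.antisense_dominant


class TestTSSProfile:
    def test_constant_coverage_flat_profile(self):
        tracks = np.full((6, 2, 2, 500), 7.0)
        exp = make_experiment(tracks)
        prof = tss_profile(exp, TSSRecord(100, Strand.FORWARD, 5.0))
        np.testing.assert_allclose(prof, 100.0)

    def test_late_shape_peaks_at_180(self):
        tracks = np.zeros((6, 1, 2, 500))
        for i, d in enumerate([0, 0, 10, 40, 100, 60]):
            tracks[i, 0, 0, 100:200] = d
        exp = make_experiment(tracks)
        prof = tss_profile(exp, TSSRecord(100, Strand.FORWARD, 5.0))
        assert int(np.argmax(prof)) == 4  # 180 min
        np.testing.assert_allclose(prof, [0, 0, 10, 40, 100, 60])

    def test_group_of_one_has_zero_sd(self):
        prof = np.array([0.0, 10, 20, 40, 100, 50])
        mean, sd = group_tss_profile([prof])
        np.testing.assert_allclose(mean, prof)
        np.testing.assert_allclose(sd, 0.0)

    def test_window_truncated_at_genome_end_warns(self):
        exp = make_experiment(np.full((6, 1, 2, 100), 3.0))
        with pytest.warns(UserWarning, match="truncated"):
            tss_profile(exp, TSSRecord(95, Strand.FORWARD, 5.0))


def test_noise_free_planted_tss_recovered_exactly(clean_bundle):
    dets = detect_tss_both_strands(clean_bundle.experiment)
    got = {(t.position, t.strand.value) for t in dets}
    want = {(t["position"], t["strand"]) for t in clean_bundle.truth.tss}
    assert got == want
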