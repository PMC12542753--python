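import itertools

import numpy as np
import pytest

from conftest import make_experiment
from viraltc.annotation import AnnotatedFeature, GenomeAnnotation, Strand
from viraltc.classify import TemporalClass
from viraltc.operons import Operon, OperonConfig, assemble, summarize
from viraltc.tss import TSSOrientation, TSSRecord

TPS2 = (5, 20)
CLASSES = [TemporalClass.EARLY, TemporalClass.MIDDLE, TemporalClass.MIDDLE_DOWN, TemporalClass.LATE]


def _sense(pos):
    return TSSRecord(pos, Strand.FORWARD, 10.0, TSSOrientation.SENSE, None)


def _internal(pos, target):
    return TSSRecord(pos, Strand.FORWARD, 10.0, TSSOrientation.INTERNAL_SENSE, target)


def _flat_exp(L, depth=50.0, T=6, lo=0, hi=None):
    tracks = np.zeros((T, 1, 2, L))
    tracks[:, :, 0, lo : hi if hi is not None else L] = depth
    return make_experiment(tracks)


class TestChaining:
    def test_three_features_one_unit(self):
        feats = [
            AnnotatedFeature("a", 100, 400, Strand.FORWARD),
            AnnotatedFeature("b", 400, 700, Strand.FORWARD),  # gap 0
            AnnotatedFeature("c", 696, 1000, Strand.FORWARD),  # gap -4
        ]
        ann = GenomeAnnotation("g", 2000, feats)
        classes = {f.feature_id: TemporalClass.MIDDLE for f in feats}
        exp = _flat_exp(2000, lo=60, hi=1000)
        units = assemble(ann, classes, exp, [_sense(60)])
        assert len(units) == 1
        (u,) = units
        assert u.members == ["a", "b", "c"] and not u.monocistronic
        assert u.leading_tss.position == 60 and u.flags == []

    def test_internal_promoter_splits_nine_gene_run(self):
        """A run of 4 middle-down + 5 middle genes with an internal promoter
        inside gene 5 yields two units split at that promoter, the second
        flagged 5'-truncated."""
        feats, pos = [], 100
        for i in range(9):
            feats.append(AnnotatedFeature(f"g{i + 1}", pos, pos + 300, Strand.FORWARD))
            pos += 300  # abutting stop/start
        ann = GenomeAnnotation("g", 4000, feats)
        classes = {
            f.feature_id: (TemporalClass.MIDDLE_DOWN if i < 4 else TemporalClass.MIDDLE)
            for i, f in enumerate(feats)
        }
        tss_internal_pos = feats[4].start + 150
        # unit 1 transcript covers genes 1-4; unit 2 starts inside gene 5
        tracks = np.zeros((6, 1, 2, 4000))
        tracks[:, :, 0, 60 : feats[3].end] = 50.0
        tracks[:, :, 0, tss_internal_pos : feats[8].end] = 50.0
        exp = make_experiment(tracks)
        tsss = [_sense(60), _internal(tss_internal_pos, "g5")]
        units = assemble(ann, classes, exp, tsss)
        assert [u.members for u in units] == [["g1", "g2", "g3", "g4"], ["g5", "g6", "g7", "g8", "g9"]]
        assert units[1].flags == ["truncated_first_member"]
        assert units[1].leading_tss.position == tss_internal_pos

    def test_uncovered_gap_breaks_continuity(self):
        feats = [
            AnnotatedFeature("a", 100, 400, Strand.FORWARD),
            AnnotatedFeature("b", 420, 700, Strand.FORWARD),  # gap 20, within gap_max
        ]
        ann = GenomeAnnotation("g", 1000, feats)
        classes = {"a": TemporalClass.LATE, "b": TemporalClass.LATE}
        tracks = np.zeros((6, 1, 2, 1000))
        tracks[:, :, 0, 60:400] = 50.0
        tracks[:, :, 0, 560:700] = 50.0  # second gene only half covered
        exp = make_experiment(tracks)
        units = assemble(ann, classes, exp, [_sense(60)])
        assert [u.members for u in units] == [["a"], ["b"]]

    def test_missing_class_rejected(self):
        ann = GenomeAnnotation("g", 500, [AnnotatedFeature("a", 10, 100, Strand.FORWARD)])
        with pytest.raises(ValueError, match="class map missing"):
            assemble(ann, {}, _flat_exp(500), [])

    def test_unit_without_tss_flagged_orphan(self):
        ann = GenomeAnnotation("g", 500, [AnnotatedFeature("a", 100, 400, Strand.FORWARD)])
        units = assemble(ann, {"a": TemporalClass.EARLY}, _flat_exp(500), [])
        assert units[0].flags == ["no_tss"] and units[0].leading_tss is None

    def test_tightening_gap_max_only_splits(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ann, classes, exp, tsss = _random_instance(rng, int(rng.integers(3, 9)))
            loose = assemble(ann, classes, exp, tsss, OperonConfig(gap_max=30))
            tight = assemble(ann, classes, exp, tsss, OperonConfig(gap_max=5))
            loose_units = [tuple(u.members) for u in loose]
            for t in tight:
                assert any(
                    set(t.members) <= set(lu) for lu in loose_units
                ), "tightening gap_max merged units"


# ---------------------------------------------------------------------------
# exhaustive oracle


def _random_instance(rng, n):
    """Random forward-strand instance: genes, classes, coverage, TSSs."""
    pos = 100
    feats = []
    gap_choices = [-4, 0, 10, 25, 40, 120]
    for i in range(n):
        if i:
            pos += int(rng.choice(gap_choices))
        length = int(rng.integers(60, 151))
        feats.append(AnnotatedFeature(f"g{i + 1}", pos, pos + length, Strand.FORWARD))
        pos += length
    L = pos + 200
    ann = GenomeAnnotation("g", L, feats)
    classes = {f.feature_id: CLASSES[int(rng.integers(4))] for f in feats}
    tracks = np.zeros((2, 2, 2, L))
    for f in feats:
        tracks[:, :, 0, f.start : f.end] = float(rng.choice([20.0, 50.0]))
    for u, v in zip(feats, feats[1:]):
        if v.start > u.end and rng.random() < 0.6:
            tracks[:, :, 0, u.end : v.start] = 20.0  # bridge the gap
    tsss = [_sense(60)]
    for u, v in zip(feats, feats[1:]):
        if v.start > u.end and rng.random() < 0.3:
            tsss.append(_sense((u.end + v.start) // 2))
    for f in feats:
        if rng.random() < 0.2:
            p = f.start + f.length // 2
            tracks[:, :, 0, p : f.end] += 10.0  # internal transcript signal
            tsss.append(_internal(p, f.feature_id))
    exp = make_experiment(tracks, TPS2)
    return ann, classes, exp, tsss


def _oracle_joinable(u, v, classes, exp, tsss, cfg=OperonConfig()):
    """Literal per-base re-statement of the three joining criteria."""
    if v.start - u.end > cfg.gap_max:
        return False
    if classes[u.feature_id] is not classes[v.feature_id]:
        return False
    for t in tsss:
        if t.strand is not Strand.FORWARD:
            continue
        if t.orientation is TSSOrientation.SENSE and u.end <= t.position < v.start:
            return False
        if (
            t.orientation is TSSOrientation.INTERNAL_SENSE
            and v.start < t.position < v.end
        ):
            return False
    lo, hi = u.start, v.end
    for t in tsss:
        if (
            t.orientation is TSSOrientation.INTERNAL_SENSE
            and u.start < t.position < u.end
        ):
            lo = max(lo, t.position)
    sums = []
    for ti in range(len(exp.timepoints)):
        sums.append(sum(exp.tracks[ti, :, 0, p].mean() for p in range(lo, hi)))
    best_tp = int(np.argmax(sums))
    covered = sum(
        1 for p in range(lo, hi) if exp.tracks[best_tp, :, 0, p].mean() >= cfg.continuity_min_cov
    )
    return covered / (hi - lo) >= cfg.continuity_frac


def test_assemble_matches_exhaustive_partition_enumeration():
    """assemble() returns the unique coarsest partition whose blocks satisfy
    the joining criteria, verified by enumerating all contiguous partitions
    on 200 random instances of up to 10 genes."""
    rng = np.random.default_rng(77)
    for _ in range(200):
        n = int(rng.integers(2, 11))
        ann, classes, exp, tsss = _random_instance(rng, n)
        feats = ann.features
        join = [_oracle_joinable(u, v, classes, exp, tsss) for u, v in zip(feats, feats[1:])]
        valid = []
        for breaks in itertools.product([False, True], repeat=n - 1):
            if all(b or j for b, j in zip(breaks, join)):
                valid.append(breaks)
        # the coarsest valid partition breaks exactly at unjoinable pairs
        coarsest = min(valid, key=sum)
        assert list(coarsest) == [not j for j in join]
        blocks, cur = [], [feats[0].feature_id]
        for b, f in zip(coarsest, feats[1:]):
            if b:
                blocks.append(cur)
                cur = []
            cur.append(f.feature_id)
        blocks.append(cur)
        got = [u.members for u in assemble(ann, classes, exp, tsss)]
        assert got == blocks


def test_noise_free_planted_partition_recovered(clean_bundle):
    from viraltc.tss import TSSConfig, detect_tss_both_strands, orient_tss

    b = clean_bundle
    classes = {k: TemporalClass(v) for k, v in b.truth.classes.items()}
    cfg = TSSConfig()
    tsss = [orient_tss(t, b.annotation, cfg) for t in detect_tss_both_strands(b.experiment, cfg)]
    units = assemble(b.annotation, classes, b.experiment, tsss)
    got = {tuple(u.members) for u in units}
    want = {tuple(o["members"]) for o in b.truth.operons}
    assert got == want
    # partition property: every classified feature appears exactly once
    flat = [m for u in units for m in u.members]
    assert len(flat) == len(set(flat)) == len(b.truth.classes)


class TestSummarize:
    def test_published_style_arithmetic(self):
        ops = [
            Operon(f"TU{i:03d}", ["x"], Strand.FORWARD, None, TemporalClass.LATE)
            for i in range(12)
        ]
        sizes = [5, 5, 5, 5] + [4] * 12  # 16 units, 68 genes
        for i, s in enumerate(sizes):
            ops.append(
                Operon(f"TUm{i}", [f"y{i}_{j}" for j in range(s)], Strand.FORWARD, None, TemporalClass.LATE)
            )
        s = summarize(ops)
        assert s["n_units"] == 28 and s["n_genes"] == 80 and s["n_monocistronic"] == 12
        assert s["pct_monocistronic"] == 42.9
        assert s["mean_genes_per_operon"] == pytest.approx(80 / 28)

    @pytest.mark.parametrize(
        "sizes,pct,mean",
        [([1], 100.0, 1.0), ([1, 3], 50.0, 2.0)],
    )
    def test_small_cases(self, sizes, pct, mean):
        ops = [
            Operon(f"TU{i}", [f"g{i}_{j}" for j in range(s)], Strand.FORWARD, None, TemporalClass.EARLY)
            for i, s in enumerate(sizes)
        ]
        s = summarize(ops)
        assert s["pct_monocistronic"] == pct and s["mean_genes_per_operon"] == mean

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
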