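import numpy as np
import pytest

from nasdeconv.clusters import cluster_isoforms, prepare_cluster
from nasdeconv.genome_io import CoverageTrack, GenomicInterval, MatureIsoform
from nasdeconv.simulate import make_tss_training_set
from nasdeconv.tss import (
    ConvTSSModel,
    LogisticTSSModel,
    TSSCall,
    build_training_set,
    classify_tss,
    compute_upr,
    extract_features,
    filter_design_matrix,
    rescue_isoforms,
)


def _bidirectional_track(tss=10000, amp=50.0):
    track = CoverageTrack()
    pos = np.arange(20000)
    sense = amp * np.exp(-(((pos - (tss + 120)) / 60.0) ** 2))
    anti = amp * np.exp(-(((pos - (tss - 120)) / 60.0) ** 2))
    track.add_counts("chr1", "+", 0, sense)
    track.add_counts("chr1", "-", 0, anti)
    return track


class TestFeatures:
    def test_window_is_1071_bp(self):
        # a single read just inside/outside the window flips the features
        # window spans [tss - 535, tss + 536): centre bin [tss - 25, tss + 26)
        track = CoverageTrack()
        track.add_counts("chr1", "+", 10000 + 536, np.array([1.0]))  # first base outside
        track.add_counts("chr1", "+", 10000 - 536, np.array([1.0]))  # outside on the left
        f = extract_features(10000, "+", "chr1", track)
        assert np.all(f == 0)
        track.add_counts("chr1", "+", 10000 + 535, np.array([1.0]))  # last base inside
        f = extract_features(10000, "+", "chr1", track)
        assert np.any(f != 0)

    def test_all_zero_window_gives_zero_vector(self):
        f = extract_features(5000, "+", "chr1", CoverageTrack())
        assert f.shape == (42,) and np.all(f == 0)

    def test_symmetric_peak_mirrors_between_strands(self):
        track = _bidirectional_track()
        f = extract_features(10000, "+", "chr1", track)
        sense, anti = f[:21], f[21:]
        np.testing.assert_allclose(sense, anti[::-1], atol=1e-9)

    def test_translation_equivariance(self):
        t1 = _bidirectional_track(tss=6000)
        t2 = _bidirectional_track(tss=9300)
        f1 = extract_features(6000, "+", "chr1", t1)
        f2 = extract_features(9300, "+", "chr1", t2)
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    def test_zscore_scale_invariance(self):
        t1 = _bidirectional_track(amp=10.0)
        t2 = _bidirectional_track(amp=1000.0)
        np.testing.assert_allclose(
            extract_features(10000, "+", "chr1", t1),
            extract_features(10000, "+", "chr1", t2),
            atol=1e-9,
        )

    def test_minus_strand_orientation(self):
        # mirrored construction: sense peak downstream of a minus-strand TSS
        track = CoverageTrack()
        pos = np.arange(20000)
        track.add_counts("chr1", "-", 0, 50 * np.exp(-(((pos - 9880) / 60.0) ** 2)))
        track.add_counts("chr1", "+", 0, 50 * np.exp(-(((pos - 10120) / 60.0) ** 2)))
        f_minus = extract_features(10000, "-", "chr1", track)
        f_plus = extract_features(10000, "+", "chr1", _bidirectional_track())
        np.testing.assert_allclose(f_minus, f_plus, atol=1e-6)


class TestClassifier:
    def test_untrained_model_errors(self):
        f = np.ones(42)
        with pytest.raises(RuntimeError, match="untrained"):
            classify_tss(f, ConvTSSModel())

    def test_all_zero_features_inactive_without_model(self):
        call = classify_tss(np.zeros(42), ConvTSSModel())  # untrained model ok here
        assert not call.active and call.probability == 0.0

    def test_threshold_boundary_inclusive(self):
        class Fixed:
            trained = True

            def predict_proba(self, X):
                return np.full(len(X), 0.5)

        assert classify_tss(np.ones(42), Fixed(), threshold=0.5).active

    @pytest.mark.parametrize("backend", [ConvTSSModel, LogisticTSSModel])
    def test_heldout_accuracy_on_synthetic_labels(self, backend, small_dataset):
        feats, labels, _ = make_tss_training_set(small_dataset, seed=5)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(labels))
        n_test = len(labels) // 4
        test, train = idx[:n_test], idx[n_test:]
        model = backend(seed=0).fit(feats[train], labels[train])
        pred = model.predict_proba(feats[test]) >= 0.5
        acc = (pred == labels[test].astype(bool)).mean()
        assert acc >= 0.9

    def test_conv_model_save_load_round_trip(self, tmp_path, small_dataset):
        feats, labels, _ = make_tss_training_set(small_dataset, seed=5)
        model = ConvTSSModel(seed=0).fit(feats, labels)
        p = tmp_path / "weights.npz"
        model.save(str(p))
        back = ConvTSSModel.load(str(p))
        np.testing.assert_allclose(
            model.predict_proba(feats[:10]), back.predict_proba(feats[:10])
        )


class TestTrainingSetLabeling:
    CANDS = [("chr1", 100, "+"), ("chr1", 150, "+"), ("chr1", 5000, "+"), ("chr1", 240, "+")]

    def test_max_signal_candidate_kept_per_peak(self):
        peaks = [("chr1", 90, 200, 1.0)]
        reads = [("chr1", 150), ("chr1", 151), ("chr1", 100)]
        pos, neg = build_training_set(self.CANDS, peaks, reads)
        assert pos == [("chr1", 150, "+")]

    def test_candidate_near_positive_dropped(self):
        peaks = [("chr1", 90, 200, 1.0)]
        reads = [("chr1", 150)]
        pos, neg = build_training_set(self.CANDS, peaks, reads)
        # 240 is 90 bp from the positive at 150 -> dropped, not negative
        assert ("chr1", 240, "+") not in neg and ("chr1", 240, "+") not in pos

    def test_candidate_near_cap_read_dropped(self):
        peaks = [("chr1", 90, 120, 1.0)]
        reads = [("chr1", 100), ("chr1", 5020)]
        pos, neg = build_training_set(self.CANDS, peaks, reads)
        # 5000 is 20 bp (<= 25) from a cap read -> neither class
        assert ("chr1", 5000, "+") not in neg

    def test_clean_candidate_is_negative(self):
        peaks = [("chr1", 90, 120, 1.0)]
        reads = [("chr1", 100)]
        pos, neg = build_training_set(self.CANDS, peaks, reads)
        assert ("chr1", 5000, "+") in neg

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            build_training_set(self.CANDS, [], [])


def _upr_cluster(inside_density, upstream_density, tss=20000, length=15000):
    track = CoverageTrack()
    track.add_counts("chr1", "+", tss + 500, np.full(1500, inside_density))
    track.add_counts("chr1", "+", tss - 3000, np.full(2500, upstream_density))
    iso = MatureIsoform("T", "G", GenomicInterval("chr1", tss, tss + length, "+"))
    cl = cluster_isoforms([iso])[0]
    prepare_cluster(cl, track)
    return cl.isoforms[0], track, cl


class TestUPR:
    def test_ratio_five_is_eligible(self):
        iso, track, _ = _upr_cluster(10.0, 2.0)
        stat = compute_upr(iso, track)
        assert stat.ratio == pytest.approx(5.0)
        assert stat.eligible

    def test_no_inside_signal_ineligible(self):
        iso, track, _ = _upr_cluster(0.0, 2.0)
        stat = compute_upr(iso, track)
        assert stat.ratio == 0.0 and not stat.eligible

    def test_zero_upstream_infinite_ratio(self):
        iso, track, _ = _upr_cluster(1.0, 0.0)
        stat = compute_upr(iso, track)
        assert stat.ratio == np.inf and stat.eligible

    def test_just_below_threshold_ineligible(self):
        iso, track, _ = _upr_cluster(9.8, 2.0)
        assert not compute_upr(iso, track).eligible  # UPR 4.9


class TestRescue:
    def _setup(self, active_offset=None, upr_inside=10.0):
        """A failed isoform at 20 kb, optionally an active isoform nearby."""
        iso, track, cl = _upr_cluster(upr_inside, 2.0)
        clusters = [cl]
        calls = {cl.isoforms[0].id: TSSCall(cl.isoforms[0].tss, 0.1, False)}
        if active_offset is not None:
            other_tss = 20000 + active_offset
            iso2 = MatureIsoform(
                "T2", "G2", GenomicInterval("chr1", other_tss, other_tss + 8000, "+")
            )
            cl2 = cluster_isoforms([iso2])[0]
            prepare_cluster(cl2, track)
            clusters.append(cl2)
            calls[cl2.isoforms[0].id] = TSSCall(other_tss, 0.9, True)
        return calls, clusters, track, cl.isoforms[0].id

    def test_isolated_high_upr_rescued(self):
        calls, clusters, track, key = self._setup(active_offset=-7000)
        rescue_isoforms(calls, clusters, track)
        assert calls[key].active and calls[key].rescued

    def test_active_isoform_3kb_upstream_blocks_rescue(self):
        calls, clusters, track, key = self._setup(active_offset=-3000)
        rescue_isoforms(calls, clusters, track)
        assert not calls[key].active

    def test_low_upr_not_rescued(self):
        calls, clusters, track, key = self._setup(active_offset=None, upr_inside=9.8)
        rescue_isoforms(calls, clusters, track)
        assert not calls[key].active

    def test_rescue_never_removes_active_calls(self):
        calls, clusters, track, key = self._setup(active_offset=-7000)
        before = {k for k, c in calls.items() if c.active}
        rescue_isoforms(calls, clusters, track)
        after = {k for k, c in calls.items() if c.active}
        assert before <= after


class TestFilterDesignMatrix:
    def test_columns_removed_for_disallowed(self):
        isos = [
            MatureIsoform("a", "G", GenomicInterval("chr1", 0, 20000, "+")),
            MatureIsoform("b", "G", GenomicInterval("chr1", 5000, 20000, "+")),
        ]
        cl = cluster_isoforms(isos)[0]
        prepare_cluster(cl)
        allowed = {cl.isoforms[0].id}
        X, keep = filter_design_matrix(cl, allowed)
        assert X.shape[1] == 1 and keep == [0]

    def test_empty_disallow_leaves_matrix(self):
        isos = [MatureIsoform("a", "G", GenomicInterval("chr1", 0, 20000, "+"))]
        cl = cluster_isoforms(isos)[0]
        prepare_cluster(cl)
        X, keep = filter_design_matrix(cl, {i.id for i in cl.isoforms})
        assert X.shape == cl.X.shape

    def test_all_disallowed_expressed_cluster_warns(self):
        iso, track, cl = _upr_cluster(10.0, 2.0)
        with pytest.warns(UserWarning, match="disallowed"):
            X, keep = filter_design_matrix(cl, set())
        assert X.shape[1] == 0
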