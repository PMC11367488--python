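import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cytotype.annotate import (
    UNASSIGNED,
    CamParams,
    RfmConfig,
    annotate,
    annotate_df,
    critical_r,
    find_correlation,
    get_annotation,
    rfm_predict,
    rfm_train,
    transfer_labels,
)
from cytotype.events import EventTable
from cytotype.synthetic import SimSpec, simulate


class TestCriticalR:
    def test_thirteen_marker_panel_threshold(self):
        """The 13-point correlation significance bound at alpha 0.05."""
        assert round(critical_r(13, 0.05), 3) == 0.553

    def test_alpha_one_limit_is_zero(self):
        assert critical_r(13, 0.999999) < 1e-4

    def test_matches_grid_scan_oracle_at_n6(self):
        """Smallest r whose two-tailed p under the exact t transform is
        <= alpha, scanned at 1e-5 resolution."""
        n, alpha = 6, 0.05
        grid = np.arange(0.0, 1.0, 1e-5)
        t = grid * np.sqrt((n - 2) / (1 - grid**2))
        p = 2 * sps.t.sf(t, n - 2)
        oracle = grid[np.argmax(p <= alpha)]
        assert abs(critical_r(n, alpha) - oracle) < 1e-4

    def test_monotone_in_n_and_alpha(self):
        rs = [critical_r(n, 0.05) for n in range(3, 30)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        alphas = [0.2, 0.1, 0.05, 0.01]
        rs = [critical_r(13, a) for a in alphas]
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2)


def _events_from_rows(rows, markers=None):
    rows = np.asarray(rows, dtype=float)
    markers = markers or [f"M{j + 1}" for j in range(rows.shape[1])]
    return EventTable(rows, markers, np.repeat("s1", len(rows)))


class TestCam:
    def test_exact_profile_gets_r_one_single_label(self, wide_reference):
        row = wide_reference.values.iloc[2].to_numpy()
        ev = _events_from_rows([10 + 5 * row], list(wide_reference.markers))
        out = find_correlation(ev, wide_reference, CamParams(min_corr=0.553))
        assert out["cam_r_best"].iloc[0] == pytest.approx(1.0)
        assert out["cam_label"].iloc[0] == "type2"

    def test_symmetric_cell_gets_double_label(self):
        """A cell equally correlated with two reference rows (profile = their
        mean under mirror symmetry) must take the hyphenated double label."""
        ref = pd.DataFrame(
            [[1.0, 0.0, 0.5, 0.2], [0.0, 1.0, 0.5, 0.2]],
            index=["alpha", "beta"],
            columns=["M1", "M2", "M3", "M4"],
        )
        from cytotype.reference import ReferenceMatrix

        rm = ReferenceMatrix(ref)
        cell = ref.to_numpy().mean(axis=0)
        # brute-force check the construction really ties the correlations
        r = [np.corrcoef(cell, ref.to_numpy()[i])[0, 1] for i in range(2)]
        assert abs(r[0] - r[1]) < 1e-12
        out = find_correlation(
            _events_from_rows([cell], list(ref.columns)), rm, CamParams(min_corr=0.0)
        )
        assert out["cam_label"].iloc[0] == "alpha-beta"

    def test_planted_labels_recovered(self, wide_reference):
        """Cells drawn from reference profiles with modest noise keep a label
        containing their planted type in >= 95% of cases at min_corr 0.553."""
        spec = SimSpec.single_sample(
            wide_reference, np.full(9, 1 / 9), 2000, noise_sd=0.2, seed=3
        )
        ev = simulate(spec)
        out = find_correlation(ev, wide_reference, CamParams(min_corr=0.553))
        hit = [
            t in l for t, l in zip(ev.obs["true_label"], out["cam_label"])
        ]
        assert np.mean(hit) >= 0.95

    def test_affine_invariance_of_labels(self, wide_reference):
        spec = SimSpec.single_sample(wide_reference, np.full(9, 1 / 9), 300, seed=4)
        ev = simulate(spec)
        out1 = find_correlation(ev, wide_reference)
        scaled = ev.copy(intensities=2.5 * ev.intensities + 7.0)
        out2 = find_correlation(scaled, wide_reference)
        assert (out1["cam_label"] == out2["cam_label"]).all()

    def test_assigned_count_monotone_in_min_corr(self, wide_reference):
        spec = SimSpec.single_sample(
            wide_reference, np.full(9, 1 / 9), 1000, noise_sd=0.6, seed=5
        )
        ev = simulate(spec)
        counts = []
        for thr in (0.553, 0.3, 0.1, -1.0):
            out = find_correlation(ev, wide_reference, CamParams(min_corr=thr))
            counts.append(int((out["cam_label"] != UNASSIGNED).sum()))
        assert counts == sorted(counts)
        assert counts[-1] == 1000  # everything assigned at the floor

    def test_zero_variance_cell_flagged_unassigned(self, wide_reference):
        ev = _events_from_rows(
            [np.full(13, 3.0)], list(wide_reference.markers)
        )
        out = find_correlation(ev, wide_reference)
        assert out["cam_label"].iloc[0] == UNASSIGNED
        assert out["cam_flag"].iloc[0] == "zero_variance"

    def test_too_few_shared_markers_is_error(self, wide_reference):
        ev = _events_from_rows([[1.0, 2.0]], ["M1", "M2"])
        with pytest.raises(ValueError, match="shared markers"):
            find_correlation(ev, wide_reference)


SMALL_RFM = RfmConfig(
    features_per_split=(1, 2), n_trees=(60, 120), max_nodes=(15, 25), seed=0
)


class TestRfm:
    def test_separable_blobs_high_holdout_accuracy(self, blob_events):
        model = rfm_train(blob_events, blob_events.obs["true_label"], SMALL_RFM)
        assert model.holdout_accuracy >= 0.95

    def test_shuffled_labels_score_at_chance(self, blob_events):
        rng = np.random.default_rng(0)
        y = rng.permutation(blob_events.obs["true_label"].to_numpy())
        model = rfm_train(blob_events, y, SMALL_RFM)
        assert abs(model.holdout_accuracy - 1 / 3) <= 0.1

    def test_grid_choice_deterministic(self, blob_events):
        y = blob_events.obs["true_label"]
        a = rfm_train(blob_events, y, SMALL_RFM)
        b = rfm_train(blob_events, y, SMALL_RFM)
        assert a.best_params == b.best_params

    def test_self_prediction_and_probabilities(self, blob_events):
        y = blob_events.obs["true_label"]
        model = rfm_train(blob_events, y, SMALL_RFM)
        pred = rfm_predict(model, blob_events)
        assert (pred["rfm_label"] == y).mean() >= 0.99
        probs = pred[[c for c in pred.columns if c.startswith("p_")]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        one = rfm_predict(model, blob_events.select(np.array([0])))
        assert len(one) == 1

    def test_rare_class_is_an_error(self, blob_events):
        y = blob_events.obs["true_label"].to_numpy().copy()
        y[:2] = "rare"
        with pytest.raises(ValueError, match="rare"):
            rfm_train(blob_events, y, SMALL_RFM)

    def test_missing_marker_is_an_error(self, blob_events):
        model = rfm_train(blob_events, blob_events.obs["true_label"], SMALL_RFM)
        narrow = EventTable(
            blob_events.intensities[:, :1], ["mx"], blob_events.sample_id
        )
        with pytest.raises(ValueError, match="my"):
            rfm_predict(model, narrow)


class TestTransfer:
    def test_self_query_recovers_labels(self, blob_events):
        y = blob_events.obs["true_label"]
        out = transfer_labels(blob_events, y, blob_events, k=5)
        assert (out["transfer_label"] == y).mean() >= 0.99

    def test_duplicated_cell_k1_exact(self, blob_events):
        y = blob_events.obs["true_label"]
        q = blob_events.select(np.array([17]))
        out = transfer_labels(blob_events, y, q, k=1)
        assert out["transfer_label"].iloc[0] == y.iloc[17]
        assert out["transfer_score"].iloc[0] == pytest.approx(1.0)

    def test_fresh_draw_recovery(self, four_type_reference):
        ref_ev = simulate(
            SimSpec.single_sample(four_type_reference, [0.25] * 4, 2000, seed=6)
        )
        query = simulate(
            SimSpec.single_sample(four_type_reference, [0.25] * 4, 1000, seed=7)
        )
        out = transfer_labels(ref_ev, ref_ev.obs["true_label"], query, k=15)
        assert (out["transfer_label"] == query.obs["true_label"]).mean() >= 0.95

    def test_k_exceeding_reference_is_error(self, blob_events):
        with pytest.raises(ValueError, match="k exceeds"):
            transfer_labels(
                blob_events, blob_events.obs["true_label"], blob_events, k=10**6
            )


class TestClusterAnnotation:
    def test_top_label_frequency(self):
        labels = ["neurons"] * 80 + ["NPC"] * 20
        out = get_annotation(labels, np.zeros(100, dtype=int))
        assert out.loc[0, "top_label"] == "neurons"
        assert out.loc[0, "frequency"] == pytest.approx(0.8)

    def test_unassigned_excluded_by_default(self):
        labels = ["neurons"] * 30 + [UNASSIGNED] * 70
        out = get_annotation(labels, np.zeros(100, dtype=int))
        assert out.loc[0, "top_label"] == "neurons"
        assert out.loc[0, "frequency"] == pytest.approx(1.0)

    def test_exact_tie_breaks_alphabetically_and_flags(self):
        labels = ["zeta"] * 50 + ["alpha"] * 50
        out = get_annotation(labels, np.zeros(100, dtype=int))
        assert out.loc[0, "top_label"] == "alpha"
        assert bool(out.loc[0, "tie"])

    def test_consensus_of_agreeing_methods(self):
        clusters = np.zeros(10, dtype=int)
        tables = {m: ["astro"] * 10 for m in ("cam", "rfm", "transfer")}
        out = annotate_df(tables, clusters)
        assert out.loc[0, "consensus"] == "astro"
        assert not out.loc[0, "review"]

    def test_three_way_disagreement_flagged(self):
        clusters = np.zeros(9, dtype=int)
        tables = {"cam": ["a"] * 9, "rfm": ["b"] * 9, "transfer": ["c"] * 9}
        out = annotate_df(tables, clusters)
        assert out.loc[0, "consensus"] == "a"  # alphabetical tie-break
        assert bool(out.loc[0, "review"])

    def test_annotate_applies_mapping_and_rejects_gaps(self, blob_events):
        clusters = np.repeat([0, 1, 2], 200)
        out = annotate(blob_events, clusters, {0: "x", 1: "y", 2: "z"})
        assert list(pd.unique(out.obs["final_label"])) == ["x", "y", "z"]
        with pytest.raises(KeyError, match="2"):
            annotate(blob_events, clusters, {0: "x", 1: "y"})


def test_consensus_at_least_as_good_as_best_method(four_type_reference):
    """With well-separated clusters, the per-cluster consensus annotation
    is at least as accurate as the best single per-cell method."""
    from cytotype.clustering import ClusterParams, get_clusters

    ev = simulate(
        SimSpec.single_sample(four_type_reference, [0.25] * 4, 2000, seed=8)
    )
    truth = ev.obs["true_label"].to_numpy()
    clusters = get_clusters(ev, ClusterParams(k_neighbors=30, resolution=0.1, seed=0)).labels

    cam = find_correlation(ev, four_type_reference, CamParams(min_corr=0.1))[
        "cam_label"
    ].to_numpy()
    model = rfm_train(ev, truth, SMALL_RFM)
    rfm = rfm_predict(model, ev)["rfm_label"].to_numpy()
    trans = transfer_labels(ev, truth, ev, k=10)["transfer_label"].to_numpy()

    cons = annotate_df({"cam": cam, "rfm": rfm, "transfer": trans}, clusters)
    mapping = dict(zip(cons["cluster"], cons["consensus"]))
    final = annotate(ev, clusters, mapping).obs["final_label"].to_numpy()

    accs = {
        "cam": np.mean([t in l for t, l in zip(truth, cam)]),
        "rfm": np.mean(rfm == truth),
        "transfer": np.mean(trans == truth),
    }
    consensus_acc = np.mean([t in l for t, l in zip(truth, final)])
    assert all(a >= 0.9 for a in accs.values())
    assert consensus_acc >= max(accs.values()) - 1e-9
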