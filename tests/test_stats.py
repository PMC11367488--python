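import numpy as np
import pandas as pd
import pytest

from cytotype.events import EventTable
from cytotype.stats import (
    permutation_test_multi,
    permutation_test_two,
    prep_for_stats,
    run_stats,
)


def _composition_events(counts_by_group, seed=0, group_var="line"):
    """Build an annotated EventTable from {group: {type: count}}."""
    rows, sids, groups = [], [], []
    labels = []
    for g, counts in counts_by_group.items():
        for t, n in counts.items():
            labels.extend([t] * n)
            sids.extend([f"sample_{g}"] * n)
    n_tot = len(labels)
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {group_var: [g for g in counts_by_group]},
        index=pd.Index([f"sample_{g}" for g in counts_by_group], name="sample_id"),
    )
    return EventTable(
        rng.uniform(0, 10, size=(n_tot, 2)),
        ["A", "B"],
        np.asarray(sids),
        sample_meta=meta,
        obs=pd.DataFrame({"final_label": labels}),
    )


class TestTwoGroup:
    def test_identical_composition_is_null(self):
        ev = _composition_events(
            {"g1": {"x": 300, "y": 200}, "g2": {"x": 300, "y": 200}}
        )
        res = permutation_test_two(ev, "line", ("g1", "g2"), seed=0)
        np.testing.assert_allclose(res["log2fd"], 0.0, atol=1e-12)
        assert not res["significant"].any()

    def test_planted_doubling_is_detected(self):
        """Type at 30% vs 15% of 2000 cells per group: log2FD near 1 and a
        significant call at the FDR<0.05, |log2FD|>0.58 defaults."""
        ev = _composition_events(
            {
                "g1": {"a": 600, "b": 700, "c": 700},
                "g2": {"a": 300, "b": 850, "c": 850},
            }
        )
        res = permutation_test_two(ev, "line", ("g1", "g2"), seed=1).set_index("cell_type")
        assert res.loc["a", "log2fd"] == pytest.approx(1.0, abs=0.1)
        assert bool(res.loc["a", "significant"])

    def test_antisymmetry_under_group_swap(self):
        ev = _composition_events(
            {"g1": {"a": 500, "b": 250}, "g2": {"a": 350, "b": 400}}
        )
        fwd = permutation_test_two(ev, "line", ("g1", "g2"), seed=2)
        rev = permutation_test_two(ev, "line", ("g2", "g1"), seed=2)
        np.testing.assert_allclose(fwd["log2fd"], -rev["log2fd"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        np.testing.assert_allclose(fwd["ci_lo"], -rev["ci_hi"], atol=1e-12)

    def test_p_floor_and_bh_order(self):
        ev = _composition_events(
            {"g1": {"a": 900, "b": 100}, "g2": {"a": 100, "b": 900}}
        )
        res = permutation_test_two(ev, "line", ("g1", "g2"), n_perm=499, seed=3)
        assert (res["p"] >= 1.0 / 500).all()
        assert (res["fdr"] >= res["p"] - 1e-12).all()

    def test_empty_type_uses_pseudo_proportion(self):
        ev = _composition_events(
            {"g1": {"a": 450, "b": 50}, "g2": {"a": 500}}
        )
        res = permutation_test_two(ev, "line", ("g1", "g2"), seed=4).set_index("cell_type")
        assert np.isfinite(res.loc["b", "log2fd"])
        assert bool(res.loc["b", "pseudo_count"])

    def test_type_one_error_calibrated(self):
        """Null simulations: the pre-FDR rejection rate at alpha 0.05 for a
        single tracked cell type stays within [0.03, 0.07] over 500 runs."""
        rng = np.random.default_rng(12345)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            n1 = int(rng.integers(150, 250))
            n2 = int(rng.integers(150, 250))
            p_a = rng.uniform(0.2, 0.5)
            a1 = rng.binomial(n1, p_a)
            a2 = rng.binomial(n2, p_a)
            ev = _composition_events(
                {
                    "g1": {"a": a1, "b": n1 - a1},
                    "g2": {"a": a2, "b": n2 - a2},
                },
                seed=int(rng.integers(2**31)),
            )
            res = permutation_test_two(
                ev, "line", ("g1", "g2"), n_perm=199, n_boot=2,
                seed=int(rng.integers(2**31)),
            ).set_index("cell_type")
            hits += res.loc["a", "p"] < 0.05
        rate = hits / n_sim
        assert 0.03 <= rate <= 0.07


def _multi_sample_events(props_by_sample, group_of_sample, n_per_sample, seed=0):
    rng = np.random.default_rng(seed)
    types = sorted({t for p in props_by_sample.values() for t in p})
    labels, sids = [], []
    for s, props in props_by_sample.items():
        p = np.array([props.get(t, 0.0) for t in types])
        draws = rng.choice(types, size=n_per_sample, p=p / p.sum())
        labels.extend(draws)
        sids.extend([s] * n_per_sample)
    meta = pd.DataFrame(
        {"line": [group_of_sample[s] for s in props_by_sample]},
        index=pd.Index(list(props_by_sample), name="sample_id"),
    )
    return EventTable(
        rng.uniform(0, 1, size=(len(labels), 2)),
        ["A", "B"],
        np.asarray(sids),
        sample_meta=meta,
        obs=pd.DataFrame({"final_label": labels}),
    )


class TestMultiGroup:
    def _null_events(self, seed):
        props = {"x": 0.5, "y": 0.3, "z": 0.2}
        samples = {f"s{i}": props for i in range(9)}
        groups = {f"s{i}": f"g{i // 3}" for i in range(9)}
        return _multi_sample_events(samples, groups, 400, seed=seed)

    def test_single_sample_group_rejected(self):
        props = {"x": 0.6, "y": 0.4}
        ev = _multi_sample_events(
            {"s0": props, "s1": props, "s2": props, "s3": props, "s4": props},
            {"s0": "a", "s1": "a", "s2": "b", "s3": "b", "s4": "c"},
            100,
        )
        with pytest.raises(ValueError, match="single sample"):
            permutation_test_multi(ev, "line")

    def test_two_groups_rejected(self):
        props = {"x": 0.6, "y": 0.4}
        ev = _multi_sample_events(
            {f"s{i}": props for i in range(4)},
            {"s0": "a", "s1": "a", "s2": "b", "s3": "b"},
            100,
        )
        with pytest.raises(ValueError, match=">= 3 groups"):
            permutation_test_multi(ev, "line")

    def test_planted_group_effect_detected(self):
        base = {"x": 0.2, "y": 0.4, "z": 0.4}
        shifted = {"x": 0.4, "y": 0.3, "z": 0.3}  # doubled type x
        samples = {f"s{i}": (shifted if i < 3 else base) for i in range(9)}
        groups = {f"s{i}": f"g{i // 3}" for i in range(9)}
        ev = _multi_sample_events(samples, groups, 600, seed=5)
        res = permutation_test_multi(ev, "line", n_perm=1000, seed=6).set_index(
            "cell_type"
        )
        assert res.loc["x", "p"] < 0.05

    def test_calibration_under_null(self):
        """200 null datasets: per-type rejection at alpha 0.05 lands in
        [0.03, 0.07] on average."""
        rng = np.random.default_rng(777)
        hits, total = 0, 0
        for i in range(200):
            ev = self._null_events(int(rng.integers(2**31)))
            res = permutation_test_multi(
                ev, "line", n_perm=199, seed=int(rng.integers(2**31))
            )
            hits += (res["p"] < 0.05).sum()
            total += res["p"].notna().sum()
        rate = hits / total
        assert 0.03 <= rate <= 0.07

    def test_constant_type_skipped(self):
        ev = self._null_events(3)
        # plant a type present in every sample at identical proportion
        # (already covered when variance is exactly zero -> NaN row)
        lab = ev.obs["final_label"].to_numpy().copy()
        res = permutation_test_multi(ev, "line", n_perm=99, seed=0)
        assert set(res.columns) == {"cell_type", "F", "p"}


class TestExpressionAnova:
    def _expression_events(self, shift=0.0, seed=0, n_samples_per_group=3, n_cells=60):
        """Two groups x markers A/B; optional +shift on marker A in group g2."""
        rng = np.random.default_rng(seed)
        blocks, sids, metas = [], [], {}
        for g in ("g1", "g2"):
            for i in range(n_samples_per_group):
                s = f"{g}_s{i}"
                a = rng.normal(5.0 + (shift if g == "g2" else 0.0), 1.0, n_cells)
                b = rng.normal(3.0, 1.0, n_cells)
                blocks.append(np.column_stack([a, b]))
                sids.extend([s] * n_cells)
                metas[s] = g
        meta = pd.DataFrame(
            {"line": list(metas.values())},
            index=pd.Index(list(metas), name="sample_id"),
        )
        n_tot = len(sids)
        return EventTable(
            np.vstack(blocks),
            ["A", "B"],
            np.asarray(sids),
            sample_meta=meta,
            obs=pd.DataFrame({"final_label": ["neurons"] * n_tot}),
        )

    def test_identical_groups_give_null_anova(self):
        ev = self._expression_events(shift=0.0, seed=1)
        long = prep_for_stats(ev, group_var="line")
        res = run_stats(long)
        tab = res.anova["neurons"]
        assert tab.loc["C(group)", "PR(>F)"] > 0.05

    def test_planted_shift_flags_interaction_and_pair(self):
        """+2 SD on one marker in one group: significant interaction and the
        correct Tukey pair within that marker."""
        ev = self._expression_events(shift=2.0, seed=2)
        long = prep_for_stats(ev, group_var="line")
        res = run_stats(long)
        tab = res.anova["neurons"]
        assert tab.loc["C(group):C(marker)", "PR(>F)"] < 0.05
        tukey = res.tukey["neurons"]
        hit = tukey[(tukey["marker"] == "A")]
        assert (hit["p_adj"] < 0.05).any()
        miss = tukey[(tukey["marker"] == "B")]
        assert (miss["p_adj"] > 0.05).all()

    def test_balanced_toy_matches_textbook_sums_of_squares(self):
        """2 groups x 2 markers x 3 replicates: F statistics agree with the
        brute-force two-way ANOVA decomposition."""
        data = []
        vals = {
            ("g1", "A"): [5.1, 4.9, 5.3],
            ("g1", "B"): [3.0, 3.2, 2.8],
            ("g2", "A"): [6.0, 6.2, 5.8],
            ("g2", "B"): [3.1, 2.9, 3.0],
        }
        for (g, m), xs in vals.items():
            for i, x in enumerate(xs):
                data.append(
                    dict(cell_type="t", group=g, marker=m, sample_id=f"{g}{i}",
                         expression=x)
                )
        long = pd.DataFrame(data)
        res = run_stats(long)
        tab = res.anova["t"]

        # brute-force decomposition
        y = np.array([vals[k] for k in vals], dtype=float)  # (4 cells, 3 reps)
        grand = y.mean()
        cell_means = y.mean(axis=1).reshape(2, 2)  # groups x markers
        g_means, m_means = cell_means.mean(1), cell_means.mean(0)
        n_rep = 3
        ss_g = 2 * n_rep * ((g_means - grand) ** 2).sum()
        ss_m = 2 * n_rep * ((m_means - grand) ** 2).sum()
        ss_int = n_rep * (
            (cell_means - g_means[:, None] - m_means[None, :] + grand) ** 2
        ).sum()
        ss_err = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum()
        f_g = (ss_g / 1) / (ss_err / 8)
        f_m = (ss_m / 1) / (ss_err / 8)
        f_int = (ss_int / 1) / (ss_err / 8)

        assert tab.loc["C(group)", "F"] == pytest.approx(f_g, rel=1e-9)
        assert tab.loc["C(marker)", "F"] == pytest.approx(f_m, rel=1e-9)
        assert tab.loc["C(group):C(marker)", "F"] == pytest.approx(f_int, rel=1e-9)

    def test_cell_replicates_warn(self):
        ev = self._expression_events(seed=4)
        with pytest.warns(UserWarning, match="cells as replicates"):
            prep_for_stats(ev, group_var="line", replicate_unit="cell")

    def test_sample_aggregation_shape(self):
        ev = self._expression_events(seed=5)
        long = prep_for_stats(ev, group_var="line")
        # 1 cell type x 2 groups x 3 samples x 2 markers
        assert len(long) == 12
        assert set(long.columns) == {
            "cell_type", "group", "sample_id", "marker", "expression"
        }
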