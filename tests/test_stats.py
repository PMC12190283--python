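import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegmfe.entropy import MFEMatrix, MFEParams
from eegmfe.stats import (
    accuracy_condition_test,
    channel_mean_long,
    cohens_d,
    correlation_preservation,
    mixed_anova,
    subject_mean_mfe,
    ttest_grid_fdr,
)

from conftest import make_recording


def make_matrices(values_by_subject, scales=(1, 2, 3)):
    """values_by_subject: list of (group, dataset, epoch x ch x scale array)."""
    params = MFEParams(scales=tuple(scales), feature_scales=(scales[-1],))
    out = []
    for i, (group, ds, vals) in enumerate(values_by_subject):
        out.append(
            MFEMatrix(
                subject_id=f"s{i}", group=group, dataset_id=ds,
                channel_names=[f"c{k}" for k in range(vals.shape[1])],
                params=params, values=np.asarray(vals, dtype=float),
            )
        )
    return out


def gaussian_grid(rng, n_subj, n_ch=3, n_scales=3, shift=0.0):
    return rng.standard_normal((n_subj, n_ch, n_scales)) + shift


class TestSubjectAggregation:
    def test_epoch_mean_first(self):
        vals = np.stack([np.zeros((2, 2)), np.full((2, 2), 4.0)])  # 2 epochs
        mats = make_matrices([("HS", "A", vals)], scales=(1, 2))
        meta, values = subject_mean_mfe(mats)
        assert values.shape == (1, 2, 2)
        assert np.all(values == 2.0)
        assert meta.loc[0, "group"] == "HS"

    def test_channel_mean_long_shape(self):
        rng = np.random.default_rng(0)
        mats = make_matrices(
            [("HS", "A", rng.uniform(0.5, 2.0, (4, 3, 3))) for _ in range(2)]
        )
        long = channel_mean_long(mats)
        assert len(long) == 2 * 3
        assert set(long["scale"]) == {1, 2, 3}
        sub0 = mats[0].values.mean(axis=0).mean(axis=0)  # epoch then channel mean
        got = long[long["subject_id"] == "s0"].sort_values("scale")["value"]
        assert np.allclose(got.to_numpy(), sub0)


class TestCohensD:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == pytest.approx(0.0)

    def test_hand_value(self):
        # means 3 and 1, pooled var = (2+2)/2 = 2 -> d = 2/sqrt(2)
        assert cohens_d([2.0, 4.0], [0.0, 2.0]) == pytest.approx(np.sqrt(2.0))

    def test_zero_variance_nan(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))

    def test_too_few(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


class TestTtestGridFdr:
    def test_cells_match_scipy_and_bh_definition(self):
        rng = np.random.default_rng(5)
        a = gaussian_grid(rng, 12, shift=0.4)
        b = gaussian_grid(rng, 10)
        res = ttest_grid_fdr(a, b)
        # single-cell oracle
        cell = sps.ttest_ind(a[:, 1, 2], b[:, 1, 2], equal_var=False)
        assert res.p_raw[1, 2] == pytest.approx(cell.pvalue, rel=1e-12)
        # BH from first principles over the flattened grid
        p = res.p_raw.ravel()
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        assert np.allclose(res.p_adj.ravel(), adj, atol=1e-12)
        assert np.array_equal(res.significant, res.p_adj < 0.05)

    def test_toy_bh_all_rejected(self):
        # p = {.01,.02,.03,.04}, m=4: adjusted all 0.04 -> all rejected at .05
        rng = np.random.default_rng(0)
        base = rng.standard_normal(6)
        a = np.empty((6, 2, 2))
        shifts = [3.05, 2.55, 2.35, 2.2]
        # construct 4 cells whose Welch p-values we then feed through BH;
        # exact p targets are unnecessary: check consistency instead
        for k in range(4):
            a[:, k // 2, k % 2] = base + shifts[k]
        b = np.tile(rng.standard_normal(6)[:, None, None], (1, 2, 2))
        res = ttest_grid_fdr(a, b)
        p = res.p_raw.ravel()
        expected = np.minimum.accumulate((np.sort(p) * 4 / np.arange(1, 5))[::-1])[::-1]
        assert np.allclose(np.sort(res.p_adj.ravel()), np.sort(expected))

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(2)
        a = gaussian_grid(rng, 15)
        res = ttest_grid_fdr(a, a.copy())
        assert np.allclose(res.p_raw, 1.0)
        assert not res.significant.any()

    def test_constant_cells_nan(self):
        rng = np.random.default_rng(3)
        a = gaussian_grid(rng, 8)
        b = gaussian_grid(rng, 8)
        a[:, 0, 0] = 1.0
        b[:, 0, 0] = 1.0
        res = ttest_grid_fdr(a, b)
        assert np.isnan(res.p_raw[0, 0])
        assert np.isnan(res.p_adj[0, 0])
        assert np.isnan(res.d[0, 0])
        assert np.isfinite(res.p_adj[1:, :]).all()

    def test_effect_direction(self):
        rng = np.random.default_rng(4)
        a = gaussian_grid(rng, 20, shift=1.0)
        b = gaussian_grid(rng, 20)
        res = ttest_grid_fdr(a, b)
        assert (res.d > 0).all()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            ttest_grid_fdr(np.zeros((1, 2, 2)), np.zeros((5, 2, 2)))


def anova_long(rng, n_per_cell=6, group_effect=0.0, scale_effect=0.0,
               datasets=("A", "B"), n_scales=5, noise=1.0, subj_sd=0.5):
    rows = []
    i = 0
    for g in ("AD", "HS"):
        for d in datasets:
            for _ in range(n_per_cell):
                sid = f"s{i}"
                i += 1
                intercept = subj_sd * rng.standard_normal()
                if g == "AD":
                    intercept += group_effect
                for s in range(1, n_scales + 1):
                    val = intercept + scale_effect * s + noise * rng.standard_normal()
                    rows.append({"subject_id": sid, "group": g, "dataset_id": d,
                                 "scale": s, "value": val})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin_single_between(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        long = anova_long(rng, n_per_cell=12, group_effect=0.8,
                          scale_effect=0.15, datasets=("A",))
        ours = mixed_anova(long)
        theirs = pingouin.mixed_anova(
            data=long, dv="value", within="scale", subject="subject_id",
            between="group", correction=True,
        ).set_index("Source")
        assert ours.loc["Group", "F"] == pytest.approx(
            theirs.loc["group", "F"], rel=1e-9
        )
        assert ours.loc["Scale", "F"] == pytest.approx(
            theirs.loc["scale", "F"], rel=1e-9
        )
        assert ours.loc["Scale x Group", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9
        )
        assert ours.loc["Group", ["df1", "df2"]].tolist() == [
            theirs.loc["group", "DF1"], theirs.loc["group", "DF2"],
        ]
        assert ours.loc["Scale", ["df1", "df2"]].tolist() == [
            theirs.loc["scale", "DF1"], theirs.loc["scale", "DF2"],
        ]

    def test_duplicated_dataset_gives_null_dataset_effect(self):
        """Cloning every subject into a second identical dataset must
        leave the Dataset main effect with F ~ 0."""
        rng = np.random.default_rng(18)
        base = anova_long(rng, n_per_cell=8, group_effect=0.7, datasets=("A",))
        clone = base.copy()
        clone["dataset_id"] = "B"
        clone["subject_id"] = clone["subject_id"] + "_b"
        table = mixed_anova(pd.concat([base, clone], ignore_index=True))
        assert table.loc["Dataset", "F"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["Dataset", "p"] == pytest.approx(1.0, abs=1e-9)
        assert table.loc["Group", "p"] < 0.01

    def test_group_p_calibrated_by_permutation(self):
        """The analytic Group p-value must sit near the rank of the
        observed F in a label-permutation null."""
        rng = np.random.default_rng(9)
        long = anova_long(rng, n_per_cell=6, group_effect=0.9)
        table = mixed_anova(long)
        f_obs = table.loc["Group", "F"]
        subj = long.drop_duplicates("subject_id")[
            ["subject_id", "group", "dataset_id"]
        ].reset_index(drop=True)
        count = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = subj.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            shuffled = long.drop(columns="group").merge(
                perm[["subject_id", "group"]], on="subject_id"
            )
            if mixed_anova(shuffled).loc["Group", "F"] >= f_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - table.loc["Group", "p"]) < 0.15

    def test_gg_epsilon_bounds_and_correction_direction(self):
        rng = np.random.default_rng(10)
        long = anova_long(rng, n_per_cell=6, scale_effect=0.3)
        table = mixed_anova(long)
        eps = table.loc["Scale", "eps"]
        n_scales = long["scale"].nunique()
        assert 1.0 / (n_scales - 1) <= eps <= 1.0
        assert table.loc["Scale", "p_gg"] >= table.loc["Scale", "p"] - 1e-15
        assert np.isnan(table.loc["Group", "eps"])

    def test_effect_rows_complete(self):
        rng = np.random.default_rng(11)
        table = mixed_anova(anova_long(rng))
        assert list(table.index) == [
            "Scale", "Group", "Dataset", "Scale x Group",
            "Group x Dataset", "Scale x Dataset", "Scale x Group x Dataset",
        ]
        assert (table["df2"] > 0).all()

    def test_unbalanced_panels_rejected(self):
        rng = np.random.default_rng(12)
        long = anova_long(rng)
        broken = long[~((long["subject_id"] == "s0") & (long["scale"] == 3))]
        with pytest.raises(ValueError):
            mixed_anova(broken)

    def test_singleton_cell_rejected(self):
        rng = np.random.default_rng(13)
        long = anova_long(rng, n_per_cell=4)
        keep = long[
            ~((long["group"] == "AD") & (long["dataset_id"] == "B")
              & (long["subject_id"] != "s4"))
        ]
        with pytest.raises(ValueError):
            mixed_anova(keep)


class TestAccuracyConditionTest:
    def test_matches_scipy_paired_one_tailed(self):
        rng = np.random.default_rng(14)
        ref = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0.4, 0.8, 12))}
        cond = {s: min(1.0, v + float(rng.uniform(0, 0.2))) for s, v in ref.items()}
        subjects = sorted(ref)
        expected = sps.ttest_rel(
            [cond[s] for s in subjects], [ref[s] for s in subjects],
            alternative="greater",
        ).pvalue
        assert accuracy_condition_test(ref, cond) == pytest.approx(expected)

    def test_identical_gives_half(self):
        ref = {"a": 0.7, "b": 0.8, "c": 0.6}
        assert accuracy_condition_test(ref, dict(ref)) == 0.5

    def test_constant_improvement_zero(self):
        ref = {"a": 0.5, "b": 0.6, "c": 0.7}
        cond = {s: v + 0.2 for s, v in ref.items()}
        assert accuracy_condition_test(ref, cond) == 0.0

    def test_constant_decline_one(self):
        ref = {"a": 0.5, "b": 0.6, "c": 0.7}
        cond = {s: v - 0.2 for s, v in ref.items()}
        assert accuracy_condition_test(ref, cond) == 1.0

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            accuracy_condition_test({"a": 0.5}, {"b": 0.5})


class TestCorrelationPreservation:
    def test_duplicated_channel_correlation_one(self):
        ch = np.random.default_rng(15).standard_normal(1200)
        rec = make_recording(np.vstack([ch, ch, -ch]))
        mats = correlation_preservation([rec], ["reference", "single_stand"])
        for cond in ("reference", "single_stand"):
            assert mats[cond][0, 1] == pytest.approx(1.0)
            assert mats[cond][0, 2] == pytest.approx(-1.0)

    def test_reference_matches_numpy_average(self):
        rng = np.random.default_rng(16)
        recs = [make_recording(rng.standard_normal((3, 900))) for _ in range(4)]
        mats = correlation_preservation(recs, ["reference"])
        expected = np.mean([np.corrcoef(r.data) for r in recs], axis=0)
        assert np.allclose(mats["reference"], expected, atol=1e-12)

    def test_all_conditions_coincide(self, preprocessed_cohort20):
        conds = ["reference", "single_norm", "global_norm",
                 "single_stand", "global_stand"]
        mats = correlation_preservation(preprocessed_cohort20, conds)
        ref = mats["reference"]
        for cond in conds[1:]:
            assert np.max(np.abs(mats[cond] - ref)) < 1e-9
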