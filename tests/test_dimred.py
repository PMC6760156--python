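"""PCA retention, per-component group tests, and LDA with loadings."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from toothrqa.dimred import (
    component_group_tests,
    lda_fit,
    lda_loadings,
    pca_fit,
    reclassify,
)
from toothrqa.errors import InestimableContrastError
from toothrqa.synthetic import Diagnosis, SubjectRecord, Zygosity


def make_subjects(labels):
    return [
        SubjectRecord(f"s{i:04d}", f"s{i:04d}", Zygosity.SINGLETON,
                      "M" if i % 2 else "F", 250.0, 2.5, Diagnosis(dx))
        for i, dx in enumerate(labels)
    ]


def gaussian_classes(rng, n_per_class=50, n_features=60, separation=5.0):
    """Four spherical Gaussian classes with distinct, well-separated means."""
    means = rng.normal(0, 1, (4, n_features))
    means = separation * means / np.linalg.norm(means, axis=1, keepdims=True)
    X, labels = [], []
    for cls, mu in zip(("TD", "ADHD", "ASD", "COMORBID"), means):
        X.append(mu + rng.normal(0, 1, (n_per_class, n_features)))
        labels += [cls] * n_per_class
    X = np.vstack(X)
    table = pd.DataFrame(
        X, index=[f"s{i:04d}" for i in range(len(X))],
        columns=[f"f{j}" for j in range(n_features)],
    )
    return table, make_subjects(labels)


class TestPCAFit:
    def test_iid_design_retention(self, rng):
        table = pd.DataFrame(
            rng.normal(size=(1000, 60)),
            columns=[f"f{j}" for j in range(60)],
        )
        res = pca_fit(table)
        # eigenvalues of a correlation-matrix PCA sum to the column count
        assert res.eigenvalues.sum() == pytest.approx(60.0, rel=1e-6)
        assert res.retained
        retained_eigs = res.eigenvalues[: len(res.retained)]
        assert np.all(retained_eigs > 1.0)
        # the 80% cumulative point falls strictly inside the spectrum
        cum = np.cumsum(res.variance_share)
        k80 = int(np.searchsorted(cum, 0.80) + 1)
        assert 1 < k80 < 60

    def test_rank_one_signal_retains_single_component(self, rng):
        latent = rng.normal(size=(300, 1))
        table = pd.DataFrame(
            latent @ rng.uniform(0.8, 1.2, (1, 30)) + 0.05 * rng.normal(size=(300, 30)),
            columns=[f"f{j}" for j in range(30)],
        )
        res = pca_fit(table)
        assert res.retained == [1]
        assert res.eigenvalues[0] > 1.0
        assert res.variance_share[0] > 0.80

    def test_duplicated_columns_preserve_score_geometry(self, rng):
        base = pd.DataFrame(
            rng.normal(size=(100, 6)), columns=[f"f{j}" for j in range(6)]
        )
        doubled = pd.concat(
            [base, base.add_suffix("_dup")], axis=1
        )
        s1 = pca_fit(base).scores.to_numpy()[:, :3]
        s2 = pca_fit(doubled).scores.to_numpy()[:, :3]
        # scores scale by sqrt(2) when every column is duplicated
        for k in range(3):
            r = np.corrcoef(s1[:, k], s2[:, k])[0, 1]
            assert abs(r) > 1 - 1e-9

    def test_scores_centered_and_constant_columns_dropped(self, rng):
        table = pd.DataFrame(
            rng.normal(size=(50, 5)), columns=list("abcde")
        )
        table["const"] = 1.0
        res = pca_fit(table)
        assert res.dropped_columns == ["const"]
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_missing_rows_excluded(self, rng):
        table = pd.DataFrame(
            rng.normal(size=(40, 5)), columns=list("abcde"),
            index=[f"s{i}" for i in range(40)],
        )
        table.iloc[3, 2] = np.nan
        res = pca_fit(table)
        assert res.excluded_subjects == ["s3"]
        assert res.scores.shape[0] == 39


class TestComponentGroupTests:
    def test_no_signal_gives_zero_betas(self):
        labels = ["TD", "ADHD", "ASD", "COMORBID"] * 10
        subjects = make_subjects(labels)
        scores = pd.DataFrame(
            {"PC1": np.tile([1.0, 2.0, 3.0, 4.0], 10)},
            index=[s.subject_id for s in subjects],
        )
        # identical score distribution across classes: shift-free design
        scores["PC1"] = 1.0 + 0 * scores["PC1"]
        out = component_group_tests(scores + np.linspace(0, 1e-9, 40)[:, None],
                                    subjects)
        assert np.allclose(out["beta"], 0.0, atol=1e-8)

    def test_recovers_injected_class_shift(self, rng):
        betas = []
        for rep in range(20):
            r = np.random.default_rng(rep)
            labels = ["TD"] * 40 + ["ADHD"] * 40 + ["ASD"] * 40 + ["COMORBID"] * 40
            subjects = make_subjects(labels)
            shift = {"TD": 0.0, "ADHD": -2.4, "ASD": 0.0, "COMORBID": 0.0}
            scores = pd.DataFrame(
                {
                    "PC1": [
                        shift[s.diagnosis.value] + r.normal() for s in subjects
                    ]
                },
                index=[s.subject_id for s in subjects],
            )
            out = component_group_tests(scores, subjects)
            row = out[out["contrast"] == "ADHD"].iloc[0]
            betas.append(row["beta"])
            assert row["p"] < 0.01
        assert abs(np.mean(betas) - (-2.4)) < 0.5

    def test_label_permutation_null_is_uniform(self, rng):
        labels = ["TD"] * 30 + ["ADHD"] * 30 + ["ASD"] * 30 + ["COMORBID"] * 30
        scores_vals = rng.normal(size=120)
        pvals = []
        for _ in range(500):
            perm = rng.permutation(labels)
            subjects = make_subjects(perm)
            scores = pd.DataFrame(
                {"PC1": scores_vals}, index=[s.subject_id for s in subjects]
            )
            out = component_group_tests(scores, subjects)
            pvals.append(float(out[out["contrast"] == "ADHD"]["p"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_class_is_inestimable(self):
        subjects = make_subjects(["TD", "TD", "ADHD", "ADHD"])
        scores = pd.DataFrame(
            {"PC1": [0.0, 1.0, 2.0, 3.0]}, index=[s.subject_id for s in subjects]
        )
        with pytest.raises(InestimableContrastError):
            component_group_tests(scores, subjects)


class TestLDAFit:
    def test_well_separated_classes_reclassify_accurately(self, rng):
        table, subjects = gaussian_classes(rng)
        res = lda_fit(table, subjects)
        assert res.axis_count == 3
        truth = pd.Series(
            {s.subject_id: s.diagnosis.value for s in subjects}
        ).loc[res.scores.index]
        acc = float((reclassify(res) == truth).mean())
        assert acc > 0.95

    def test_axis_scores_uncorrelated(self, rng):
        table, subjects = gaussian_classes(rng, separation=3.0)
        res = lda_fit(table, subjects)
        Z = res.scores.to_numpy()
        c = np.corrcoef(Z.T)
        assert np.allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-6)

    def test_identical_classes_have_negligible_separation(self, rng):
        # well-conditioned regime (many samples per feature) so the
        # degenerate axis is not inflated by overfitting
        table, subjects = gaussian_classes(rng, n_per_class=100, n_features=10,
                                           separation=4.0)
        # collapse ASD onto COMORBID's distribution: resample both from
        # the same mean
        labels = [s.diagnosis.value for s in subjects]
        mask = [l in ("ASD", "COMORBID") for l in labels]
        shared = rng.normal(0, 1, (sum(mask), table.shape[1]))
        table.iloc[np.where(mask)[0]] = shared
        res = lda_fit(table, subjects)
        # between-class variance on the weakest axis is tiny relative to
        # the strongest
        bv = res.class_means.to_numpy().var(axis=0)
        assert bv[-1] < 0.05 * bv[0]

    def test_affine_transform_invariance(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=40, n_features=20)
        A = rng.normal(size=(20, 20)) + 5 * np.eye(20)
        b = rng.normal(size=20)
        transformed = pd.DataFrame(
            table.to_numpy() @ A + b, index=table.index, columns=table.columns
        )
        truth = pd.Series({s.subject_id: s.diagnosis.value for s in subjects})
        acc1 = float((reclassify(lda_fit(table, subjects)) == truth).mean())
        acc2 = float((reclassify(lda_fit(transformed, subjects)) == truth).mean())
        assert acc1 == pytest.approx(acc2, abs=0.02)

    def test_matches_sklearn_subspace(self, rng):
        """Independent cross-check: class separation achieved in our LD
        space matches sklearn's LDA on the same data."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        table, subjects = gaussian_classes(rng, n_per_class=40, n_features=12,
                                           separation=3.0)
        y = np.array([s.diagnosis.value for s in subjects])
        res = lda_fit(table, subjects)
        acc_ours = float(
            (reclassify(res).to_numpy() == y).mean()
        )
        sk = LinearDiscriminantAnalysis()
        acc_sk = float(sk.fit(table.to_numpy(), y).score(table.to_numpy(), y))
        assert acc_ours == pytest.approx(acc_sk, abs=0.05)

    def test_emptied_class_names_the_class(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=5, n_features=4)
        # knock out all ASD rows with a missing value
        for s in subjects:
            if s.diagnosis is Diagnosis.ASD:
                table.loc[s.subject_id, "f0"] = np.nan
        with pytest.raises(InestimableContrastError, match="ASD"):
            lda_fit(table, subjects)

    def test_complete_case_exclusion_recorded(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=10, n_features=4)
        table.iloc[0, 0] = np.nan
        res = lda_fit(table, subjects)
        assert res.excluded_subjects == [table.index[0]]


class TestLDALoadings:
    def test_feature_equal_to_axis_scores_loads_one(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=30, n_features=10)
        res = lda_fit(table, subjects)
        table2 = table.copy()
        table2["echo"] = res.scores["LD1"]
        loadings = lda_loadings(res, table2)
        assert loadings.loc["echo", "LD1"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_has_small_loading(self, rng):
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            scores = pd.DataFrame(
                {"LD1": r.normal(size=200)},
                index=[f"s{i}" for i in range(200)],
            )
            feature = pd.DataFrame(
                {"f": r.normal(size=200)}, index=scores.index
            )
            from toothrqa.dimred import lda_loadings_frame

            val = float(lda_loadings_frame(scores, feature).loc["f", "LD1"])
            hits += abs(val) < 0.2
        assert hits >= 95

    def test_axis_sign_flip_flips_loadings(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=20, n_features=8)
        res = lda_fit(table, subjects)
        flipped = res.scores.copy()
        flipped["LD2"] *= -1.0
        from toothrqa.dimred import lda_loadings_frame

        l1 = lda_loadings_frame(res.scores, table)
        l2 = lda_loadings_frame(flipped, table)
        assert np.allclose(l1["LD2"], -l2["LD2"])
        assert np.allclose(l1["LD1"], l2["LD1"])

    def test_loadings_bounded_by_one(self, rng):
        table, subjects = gaussian_classes(rng, n_per_class=25, n_features=15)
        res = lda_fit(table, subjects)
        vals = res.standardized_loadings.to_numpy()
        assert np.all(np.abs(vals[np.isfinite(vals)]) <= 1.0 + 1e-12)
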