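import itertools

import numpy as np
import pytest
from scipy import stats as sps

from petref.errors import ValidationError
from petref.stats import (
    ancova,
    cohens_d,
    delong_compare,
    roc,
    severity_regression,
    voxelwise_cluster_test,
)


# ---------------------------------------------------------------------------
# ancova
# ---------------------------------------------------------------------------


def test_ancova_exact_null():
    values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    groups = ["A", "A", "A", "B", "B", "B"]
    age = [60.0, 70.0, 80.0, 60.0, 70.0, 80.0]
    sex = ["m", "f", "m", "m", "f", "m"]
    res = ancova(values, groups, age=age, sex=sex)
    assert res.group_t == pytest.approx(0.0, abs=1e-12)
    assert res.cohens_d.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)


def test_ancova_matches_normal_equations_oracle(rng):
    """Coefficients vs an explicit (X'X)^-1 X'y solve on a 12-row fixture."""
    n = 12
    groups = np.array(["P"] * 6 + ["C"] * 6)
    age = rng.normal(70, 8, n)
    sex = rng.choice(["m", "f"], n)
    values = rng.normal(2, 0.5, n) + (groups == "P") * 0.8 + 0.01 * age
    res = ancova(values, groups, age=age, sex=sex, reference="C")

    sx = (sex == "f").astype(float)
    X = np.column_stack([np.ones(n), (groups == "P").astype(float), age, sx])
    beta = np.linalg.solve(X.T @ X, X.T @ values)
    assert res.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-8)
    assert res.coefficients["group[P]"] == pytest.approx(beta[1], abs=1e-8)
    assert res.coefficients["age"] == pytest.approx(beta[2], abs=1e-8)
    assert res.coefficients["sex"] == pytest.approx(beta[3], abs=1e-8)


def test_cohens_d_hand_computed():
    # means 2 vs 4, both variances 1 -> pooled SD 1, d = 2
    assert cohens_d([3.0, 4.0, 5.0], [1.0, 2.0, 3.0]) == pytest.approx(2.0)
    res = ancova([1.0, 2.0, 3.0, 3.0, 4.0, 5.0], ["A"] * 3 + ["B"] * 3)
    assert res.cohens_d.loc["B", "A"] == pytest.approx(2.0)
    assert res.cohens_d.loc["A", "B"] == pytest.approx(-2.0)  # antisymmetric


def test_ancova_zero_variance_covariate_reduces_to_plain_model(rng):
    values = rng.normal(size=10)
    groups = ["A"] * 5 + ["B"] * 5
    with_cov = ancova(values, groups, age=None, sex=["m"] * 10)
    without = ancova(values, groups)
    assert with_cov.group_t == pytest.approx(without.group_t, rel=1e-12)


def test_ancova_rank_deficiency_raises():
    values = [1.0, 2, 3, 4, 5, 6]
    groups = ["A", "A", "A", "B", "B", "B"]
    age = [1.0, 1, 1, 2, 2, 2]  # identical to the group dummy
    with pytest.raises(ValidationError, match="rank"):
        ancova(values, groups, age=age)


def test_ancova_group_size_guard():
    with pytest.raises(ValidationError):
        ancova([1.0, 2, 3, 4], ["A", "A", "B", "B"])


def test_ancova_tukey_symmetric_three_groups(rng):
    values = rng.normal(size=15)
    groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
    res = ancova(values, groups)
    t = res.tukey_p
    assert np.allclose(t.values, t.values.T)
    assert ((t.values >= 0) & (t.values <= 1)).all()


def test_ancova_tukey_matches_statsmodels(rng):
    """Covariate-free Tukey HSD against the statsmodels implementation."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = rng.normal(size=18) + np.repeat([0.0, 0.8, 0.2], 6)
    groups = np.repeat(["A", "B", "C"], 6)
    res = ancova(values, groups)
    sm = pairwise_tukeyhsd(values, groups)
    for (g1, g2), p in zip(itertools.combinations(["A", "B", "C"], 2), sm.pvalues):
        assert res.tukey_p.loc[g1, g2] == pytest.approx(p, abs=1e-6)


# ---------------------------------------------------------------------------
# roc / delong
# ---------------------------------------------------------------------------


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: ties contribute 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    res = roc([1.0, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_roc_pair_counting_oracle():
    scores = np.array([1.0, 2.0, 3.0, 2.5, 3.5, 4.0])
    labels = np.array([False, False, False, True, True, True])
    res = roc(scores, labels)
    assert res.auc == pytest.approx(8.0 / 9.0)
    assert res.auc == pytest.approx(brute_force_auc(scores, labels))


def test_roc_pair_counting_oracle_with_ties(rng):
    scores = rng.integers(0, 5, 30).astype(float)
    labels = rng.random(30) > 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert roc(scores, labels).auc == pytest.approx(brute_force_auc(scores, labels))


def test_roc_label_flip_symmetry(rng):
    scores = rng.normal(size=40)
    labels = rng.random(40) > 0.5
    a = roc(scores, labels).auc
    b = roc(scores, ~labels).auc
    assert a + b == pytest.approx(1.0)


def test_roc_auc_matches_trapezoidal_curve_area(rng):
    """Dual route: Mann-Whitney estimator vs trapezoidal area under the
    empirical ROC curve (sklearn's independent implementation)."""
    from sklearn.metrics import roc_auc_score

    for _ in range(5):
        scores = np.round(rng.normal(size=50), 1)  # force ties
        labels = rng.random(50) > 0.4
        if labels.all() or not labels.any():
            continue
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_roc_youden_cutoff_matches_brute_force(rng):
    scores = rng.normal(size=30)
    labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
    scores[labels] += 1.0
    res = roc(scores, labels)
    best_j, best_th = -np.inf, None
    for th in sorted(set(scores)):
        sens = np.mean(scores[labels] >= th)
        spec = np.mean(scores[~labels] < th)
        if sens + spec - 1 > best_j + 1e-12:
            best_j, best_th = sens + spec - 1, th
    assert res.cutoff == best_th
    assert res.sensitivity + res.specificity - 1 == pytest.approx(best_j)


def test_roc_single_class_raises():
    with pytest.raises(ValidationError):
        roc([1.0, 2.0], [True, True])


def test_delong_self_comparison():
    scores = np.array([1.0, 2, 3, 4, 5, 6])
    labels = np.array([False, False, False, True, True, True])
    z, p = delong_compare(scores, scores, labels)
    assert z == 0.0 and p == 1.0


def test_delong_monotone_transform_invariance(rng):
    a = rng.normal(size=30)
    b = rng.normal(size=30)
    labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
    a[labels] += 1.0
    z1, p1 = delong_compare(a, b, labels)
    z2, p2 = delong_compare(np.exp(a), b, labels)  # rank-preserving transform
    assert z1 == pytest.approx(z2, rel=1e-12)
    assert roc(a, labels).auc == roc(np.exp(a), labels).auc


def test_delong_variance_matches_bootstrap_oracle(rng):
    """Subject-level bootstrap of the AUC difference on a 30-subject fixture."""
    n = 30
    labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
    a = rng.normal(size=n) + labels * 1.2
    b = rng.normal(size=n) + labels * 0.6

    v10a = np.array([np.mean(a[~labels] < s) + 0.5 * np.mean(a[~labels] == s) for s in a[labels]])
    v10b = np.array([np.mean(b[~labels] < s) + 0.5 * np.mean(b[~labels] == s) for s in b[labels]])
    var_a = v10a.var(ddof=1)  # noqa: F841 (sanity only)

    # analytic variance of the difference, back-derived from the z statistic
    z, _ = delong_compare(a, b, labels)
    auc_diff = roc(a, labels).auc - roc(b, labels).auc
    analytic_var = (auc_diff / z) ** 2

    boot = np.empty(10_000)
    idx_pos = np.nonzero(labels)[0]
    idx_neg = np.nonzero(~labels)[0]
    for i in range(10_000):
        rs = np.concatenate([rng.choice(idx_pos, idx_pos.size), rng.choice(idx_neg, idx_neg.size)])
        lab = labels[rs]
        boot[i] = brute_force_auc(a[rs], lab) - brute_force_auc(b[rs], lab)
    assert analytic_var == pytest.approx(boot.var(ddof=1), rel=0.15)


# ---------------------------------------------------------------------------
# severity regression
# ---------------------------------------------------------------------------


def test_severity_constant_severity_gives_zero_beta():
    out = severity_regression([5.0] * 8, np.arange(8.0))
    assert out.beta_std == 0.0


def test_severity_simple_regression_equals_pearson(rng):
    x = rng.normal(size=25)
    y = 0.5 * x + rng.normal(size=25)
    out = severity_regression(y, x)
    r = np.corrcoef(x, y)[0, 1]
    assert out.beta_std == pytest.approx(r, abs=1e-10)


def test_severity_missing_rows_dropped():
    sev = [1.0, 2.0, None, 3.0, 4.0, None, 5.0]
    x = np.arange(7.0)
    out = severity_regression(sev, x)
    assert out.n == 5 and out.n_dropped == 2


def test_severity_constant_readout_raises():
    with pytest.raises(ValidationError):
        severity_regression([1.0, 2, 3, 4], [2.0, 2, 2, 2])


def test_severity_planted_slope_recovery():
    """Generative recovery: mean fitted beta across 50 seeds within MC CI."""
    b, sx, se = 5.0, 0.4, 1.0
    expected = b * sx / np.sqrt((b * sx) ** 2 + se**2)
    betas = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        x = r.normal(0, sx, 40)
        sev = 20 + b * x + r.normal(0, se, 40)
        betas.append(severity_regression(sev, x).beta_std)
    mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
    assert abs(np.mean(betas) - expected) < 4 * mc_se + 0.02


# ---------------------------------------------------------------------------
# voxel-wise cluster test
# ---------------------------------------------------------------------------


def _null_maps(rng, n_per_group=5, shape=(10, 10, 6)):
    maps = rng.normal(size=(2 * n_per_group,) + shape)
    groups = ["P"] * n_per_group + ["C"] * n_per_group
    return maps, groups


def test_cluster_identical_groups_no_suprathreshold():
    rng = np.random.default_rng(0)
    half = rng.normal(size=(5, 8, 8, 4))
    maps = np.concatenate([half, half])  # identical images across groups
    groups = ["P"] * 5 + ["C"] * 5
    res = voxelwise_cluster_test(maps, groups, n_perm=100, seed=0)
    assert np.abs(res.t_map).max() <= res.forming_threshold
    assert res.cluster_labels.max() == 0


def test_cluster_planted_effect_recovered():
    dice_ok = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        maps, groups = _null_maps(rng, n_per_group=6, shape=(12, 12, 6))
        planted = np.zeros((12, 12, 6), dtype=bool)
        planted[4:8, 4:8, 2:4] = True
        maps[:6][:, planted] += 4.0  # strong effect in the patient group
        res = voxelwise_cluster_test(maps, groups, n_perm=200, seed=seed)
        surv = res.cluster_labels > 0
        dice = 2 * (surv & planted).sum() / (surv.sum() + planted.sum()) if surv.any() else 0.0
        dice_ok += dice > 0.5
    assert dice_ok >= 9


def test_cluster_reproducible_and_order_invariant():
    rng = np.random.default_rng(3)
    maps, groups = _null_maps(rng, n_per_group=5)
    maps[:5, 2:5, 2:5, 2:4] += 2.0
    age = rng.normal(70, 5, 10)
    sex = rng.choice(["m", "f"], 10)
    r1 = voxelwise_cluster_test(maps, groups, age=age, sex=sex, n_perm=150, seed=9)
    r2 = voxelwise_cluster_test(maps, groups, age=age, sex=sex, n_perm=150, seed=9)
    assert r1.cluster_p_fwe == r2.cluster_p_fwe
    perm = np.random.default_rng(0).permutation(10)
    r3 = voxelwise_cluster_test(
        maps[perm], np.asarray(groups)[perm], age=age[perm], sex=sex[perm], n_perm=150, seed=9
    )
    assert sorted(r1.cluster_p_fwe) == sorted(r3.cluster_p_fwe)
    assert sorted(r1.cluster_extents) == sorted(r3.cluster_extents)


def test_cluster_requires_two_groups_and_min_n():
    rng = np.random.default_rng(0)
    maps = rng.normal(size=(4, 6, 6, 4))
    with pytest.raises(ValidationError):
        voxelwise_cluster_test(maps, ["P", "P", "C", "C"], n_perm=100)
    with pytest.raises(ValidationError):
        voxelwise_cluster_test(maps[:3], ["P", "P", "C"], n_perm=100)
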