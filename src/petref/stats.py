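"""Validation statistics: ANCOVA with Tukey pairwise tests and Cohen's d,
ROC with Youden cut-offs and paired DeLong AUC comparison, covariate-adjusted
severity regression, and permutation-based voxel-wise cluster inference.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .errors import ValidationError

__all__ = [
    "AncovaResult",
    "ROCOutput",
    "RegressionOutput",
    "ClusterResult",
    "ancova",
    "cohens_d",
    "roc",
    "delong_compare",
    "severity_regression",
    "voxelwise_cluster_test",
]


def _encode_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "UO":
        return np.asarray([{"m": 0.0, "f": 1.0}[s] for s in arr])
    return arr.astype(float)


# ---------------------------------------------------------------------------
# ANCOVA / effect sizes
# ---------------------------------------------------------------------------


@dataclass
class AncovaResult:
    group_levels: list
    group_f: float
    group_p: float
    group_t: float | None  # two-group designs only; sign: second level minus reference
    group_t_p: float | None
    coefficients: dict  # name -> estimate (dummies + covariates + intercept)
    adjusted_means: dict  # group -> mean at covariate means
    tukey_p: pd.DataFrame
    cohens_d: pd.DataFrame  # raw pooled-SD d, antisymmetric
    cohens_d_adjusted: pd.DataFrame  # on covariate-residualized values
    residual_df: int


def _design(groups, covars: dict, reference: str):
    levels = sorted(set(groups))
    if reference not in levels:
        raise ValidationError(f"reference group {reference!r} not present")
    levels = [reference] + [g for g in levels if g != reference]
    g = np.asarray(groups)
    cols, names = [np.ones(g.size)], ["intercept"]
    for lev in levels[1:]:
        cols.append((g == lev).astype(float))
        names.append(f"group[{lev}]")
    for cname, cvals in covars.items():
        cols.append(np.asarray(cvals, dtype=float))
        names.append(cname)
    X = np.column_stack(cols)
    return X, names, levels


def _ols(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError("design matrix is rank deficient (collinear columns)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, resid, sigma2, xtx_inv, df


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def ancova(values, groups, age=None, sex=None, reference: str | None = None) -> AncovaResult:
    """Linear model ``value ~ group + age + sex`` with Tukey HSD and Cohen's d.

    The overall group effect is an F test (full vs covariate-only model);
    for two-group designs the dummy coefficient's t (second level minus
    ``reference``) is also reported.  Adjusted means are model predictions at
    the covariate means; Tukey-adjusted p-values use the model residual
    variance and the studentized range distribution.  Cohen's d is computed
    from raw group values with pooled SD (and, additionally, from
    covariate-residualized values).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValidationError("values and groups must have equal length")
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    counts = {lev: int((g == lev).sum()) for lev in levels}
    if min(counts.values()) < 3:
        raise ValidationError(f"every group needs n >= 3, got {counts}")
    covars = {}
    if age is not None:
        covars["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        sx = _encode_sex(sex)
        if np.ptp(sx) > 0:  # constant covariate would be collinear with intercept
            covars["sex"] = sx
    if reference is None:
        reference = levels[0]

    X, names, levels = _design(g, covars, reference)
    beta, resid, sigma2, xtx_inv, df = _ols(X, y)
    coefficients = dict(zip(names, beta.tolist()))

    # overall group F: compare against covariate-only model
    Xr = np.column_stack([np.ones(y.size)] + [covars[c] for c in covars])
    beta_r, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    rss_full = float(resid @ resid)
    rss_red = float(np.sum((y - Xr @ beta_r) ** 2))
    # residual variance at machine-noise level (e.g. exactly self-cancelling
    # ratios) is treated as an exact degenerate fit
    noise_floor = (max(float(np.abs(y).max()), 1.0) ** 2) * y.size * 1e-24
    if rss_full <= noise_floor:
        rss_full = 0.0
        sigma2 = 0.0
    q = len(levels) - 1
    if rss_full == 0:  # degenerate perfect fit
        f_stat = 0.0 if rss_red <= noise_floor else np.inf
    else:
        f_stat = ((rss_red - rss_full) / q) / (rss_full / df)
    f_p = float(sps.f.sf(f_stat, q, df))

    group_t = group_t_p = None
    if len(levels) == 2:
        j = names.index(f"group[{levels[1]}]")
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        if se == 0:  # zero residual variance: identical fit, exact null
            group_t = 0.0 if abs(beta[j]) < 1e-12 else float(np.inf * np.sign(beta[j]))
            group_t_p = 1.0 if group_t == 0.0 else 0.0
        else:
            group_t = float(beta[j] / se)
            group_t_p = float(2 * sps.t.sf(abs(group_t), df))

    # adjusted means: prediction at covariate means per group
    cov_means = {c: float(np.mean(covars[c])) for c in covars}
    adj = {}
    for lev in levels:
        pred = coefficients["intercept"]
        if lev != reference:
            pred += coefficients[f"group[{lev}]"]
        for c in covars:
            pred += coefficients[c] * cov_means[c]
        adj[lev] = float(pred)

    # Tukey HSD on adjusted means with model residual variance
    k = len(levels)
    tukey = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    d_raw = pd.DataFrame(np.zeros((k, k)), index=levels, columns=levels)
    d_adj = pd.DataFrame(np.zeros((k, k)), index=levels, columns=levels)
    # residualize on covariates for adjusted d
    y_res = y - Xr @ beta_r + y.mean()
    for i, gi in enumerate(levels):
        for j2, gj in enumerate(levels):
            if i == j2:
                continue
            diff = adj[gi] - adj[gj]
            se = np.sqrt(sigma2 * (1.0 / counts[gi] + 1.0 / counts[gj]))
            if se == 0:
                tukey.iloc[i, j2] = 1.0 if abs(diff) < 1e-10 else 0.0
                d_raw.iloc[i, j2] = cohens_d(y[g == gi], y[g == gj])
                d_adj.iloc[i, j2] = cohens_d(y_res[g == gi], y_res[g == gj])
                continue
            qval = abs(diff) / (se / np.sqrt(2.0))
            tukey.iloc[i, j2] = float(sps.studentized_range.sf(qval, k, df))
            d_raw.iloc[i, j2] = cohens_d(y[g == gi], y[g == gj])
            d_adj.iloc[i, j2] = cohens_d(y_res[g == gi], y_res[g == gj])
    return AncovaResult(
        group_levels=levels,
        group_f=float(f_stat),
        group_p=f_p,
        group_t=group_t,
        group_t_p=group_t_p,
        coefficients=coefficients,
        adjusted_means=adj,
        tukey_p=tukey,
        cohens_d=d_raw,
        cohens_d_adjusted=d_adj,
        residual_df=df,
    )


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class ROCOutput:
    auc: float
    delong_variance: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str = "patient-high"


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per patient) and V01 (per control)."""
    pos = scores[labels]
    neg = scores[~labels]
    # fraction of controls below each patient score (ties count 1/2)
    v10 = np.array([(np.sum(neg < s) + 0.5 * np.sum(neg == s)) / neg.size for s in pos])
    v01 = np.array([(np.sum(pos > s) + 0.5 * np.sum(pos == s)) / pos.size for s in neg])
    return v10, v01


def roc(scores, labels) -> ROCOutput:
    """AUC via the Mann-Whitney estimator plus Youden-J optimal cut-off.

    ``labels`` is boolean with True = patient; the decision rule calls
    ``score >= cutoff`` patient.  Ties in Youden J resolve to the lower
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise ValidationError("scores and labels must have equal length")
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = (v10.var(ddof=1) / n1 if n1 > 1 else 0.0) + (v01.var(ddof=1) / n0 if n0 > 1 else 0.0)

    best_j, best = -np.inf, None
    for th in np.unique(scores):
        call = scores >= th
        sens = float((call & labels).sum() / n1)
        spec = float((~call & ~labels).sum() / n0)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, (th, sens, spec)
    cutoff, sens, spec = best
    return ROCOutput(auc, float(var), float(cutoff), sens, spec)


def delong_compare(scores_a, scores_b, labels):
    """Paired DeLong test for two AUCs on the same subjects.

    Returns ``(z, p)`` with ``z = (AUC_A - AUC_B) / sqrt(vA + vB - 2 cov)``
    from placement-value covariances; zero variance of the difference is a
    degenerate-case error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("score sets and labels must be aligned")
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError("need >= 2 subjects per class")
    v10a, v01a = _placements(a, labels)
    v10b, v01b = _placements(b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    var_a = v10a.var(ddof=1) / n1 + v01a.var(ddof=1) / n0
    var_b = v10b.var(ddof=1) / n1 + v01b.var(ddof=1) / n0
    cov = (
        np.cov(v10a, v10b, ddof=1)[0, 1] / n1
        + np.cov(v01a, v01b, ddof=1)[0, 1] / n0
    )
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):  # e.g. comparing a score set with itself
            return 0.0, 1.0
        raise ValidationError("degenerate DeLong comparison: zero variance of the AUC difference")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# severity regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionOutput:
    beta_std: float
    p: float
    n: int
    n_dropped: int
    coefficients: dict


def severity_regression(severity, readout, age=None, sex=None) -> RegressionOutput:
    """``severity ~ readout + age + sex`` with a standardized readout slope.

    Severity and readout are z-scored before fitting, so the readout
    coefficient is a standardized beta.  Rows with missing severity are
    dropped (count reported).
    """
    sev = np.asarray([np.nan if s is None else s for s in severity], dtype=float)
    x = np.asarray(readout, dtype=float)
    keep = np.isfinite(sev)
    n_drop = int((~keep).sum())
    sev, x = sev[keep], x[keep]
    covars = {}
    if age is not None:
        covars["age"] = np.asarray(age, dtype=float)[keep]
    if sex is not None:
        sx = _encode_sex(sex)[keep]
        if np.ptp(sx) > 0:
            covars["sex"] = sx
    n = sev.size
    if n < 4:
        raise ValidationError(f"need >= 4 complete cases, got {n}")
    if x.std() == 0:
        raise ValidationError("readout is constant")
    if sev.std() == 0:
        # degenerate but well-defined: no association
        return RegressionOutput(0.0, 1.0, n, n_drop, {})
    yz = (sev - sev.mean()) / sev.std(ddof=1)
    xz = (x - x.mean()) / x.std(ddof=1)
    X = np.column_stack([np.ones(n), xz] + [covars[c] for c in covars])
    names = ["intercept", "readout"] + list(covars)
    beta, resid, sigma2, xtx_inv, df = _ols(X, yz)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = float(2 * sps.t.sf(abs(t), df))
    return RegressionOutput(float(beta[1]), p, n, n_drop, dict(zip(names, beta.tolist())))


# ---------------------------------------------------------------------------
# voxel-wise permutation cluster test
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    t_map: np.ndarray
    forming_threshold: float
    cluster_labels: np.ndarray  # surviving clusters only, labelled 1..k
    cluster_extents: list
    cluster_p_fwe: list
    n_permutations: int


def _group_t_maps(Y: np.ndarray, gvec: np.ndarray, Z: np.ndarray):
    """t of the group indicator in ``y ~ g + Z`` for every column of Y."""
    X = np.column_stack([gvec, Z])
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    gg = np.linalg.inv(X.T @ X)[0, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / np.sqrt(sigma2 * gg)
    return np.nan_to_num(t), df


def _max_cluster_extent(t: np.ndarray, thr: float, shape, mask_idx, structure) -> int:
    vol = np.zeros(shape, dtype=bool)
    best = 0
    for signed in (t > thr, t < -thr):
        vol[...] = False
        vol[mask_idx] = signed
        lab, k = ndimage.label(vol, structure=structure)
        if k:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def voxelwise_cluster_test(
    maps: np.ndarray,
    groups,
    age=None,
    sex=None,
    mask: np.ndarray | None = None,
    p_form: float = 0.001,
    alpha_cluster: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> ClusterResult:
    """Two-group voxel-wise ANCOVA with permutation cluster-extent FWE control.

    ``maps`` is (n_subjects, x, y, z).  Clusters are 26-connected components
    of |t| above the two-sided forming threshold; the null distribution of
    the maximum cluster extent comes from Freedman-Lane permutations
    (covariate-residualized data re-permuted under the reduced model).
    """
    maps = np.asarray(maps, dtype=float)
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValidationError("cluster test requires exactly two groups")
    if min(int((g == lev).sum()) for lev in levels) < 3:
        raise ValidationError("need >= 3 subjects per group")
    if n_perm < 100:
        raise ValidationError("need n_perm >= 100")
    if mask is None:
        mask = np.all(np.isfinite(maps), axis=0)
    mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(maps), axis=0)
    shape = maps.shape[1:]
    mask_idx = np.nonzero(mask)
    Y = maps[:, mask_idx[0], mask_idx[1], mask_idx[2]]
    gvec = (g == levels[1]).astype(float)
    zcols = [np.ones(g.size)]
    if age is not None:
        zcols.append(np.asarray(age, dtype=float))
    if sex is not None:
        sx = _encode_sex(sex)
        if np.ptp(sx) > 0:
            zcols.append(sx)
    Z = np.column_stack(zcols)

    # canonical subject order: permutations (and hence p-values) become
    # exactly invariant to the order rows are passed in
    digests = [
        hashlib.sha256(
            Y[i].tobytes() + gvec[i].tobytes() + Z[i].tobytes()
        ).hexdigest()
        for i in range(Y.shape[0])
    ]
    order = np.argsort(digests, kind="stable")
    Y, gvec, Z = Y[order], gvec[order], Z[order]

    t_obs, df = _group_t_maps(Y, gvec, Z)
    thr = float(sps.t.isf(p_form / 2.0, df))
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity

    # observed clusters (positive and negative separately)
    clusters = []
    vol = np.zeros(shape, dtype=bool)
    for sign in (1.0, -1.0):
        vol[...] = False
        vol[mask_idx] = sign * t_obs > thr
        lab, k = ndimage.label(vol, structure=structure)
        for ci in range(1, k + 1):
            clusters.append(lab == ci)

    # Freedman-Lane permutation of the maximum cluster extent
    hz = Z @ np.linalg.pinv(Z)
    fitted_red = hz @ Y
    resid_red = Y - fitted_red
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm, dtype=int)
    n_sub = Y.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n_sub)
        y_star = fitted_red + resid_red[perm]
        t_star, _ = _group_t_maps(y_star, gvec, Z)
        max_null[i] = _max_cluster_extent(t_star, thr, shape, mask_idx, structure)

    extents, pvals, surviving = [], [], []
    for cmask in clusters:
        ext = int(cmask.sum())
        p = float((1 + np.sum(max_null >= ext)) / (1 + n_perm))
        extents.append(ext)
        pvals.append(p)
        if p < alpha_cluster:
            surviving.append(cmask)
    t_map = np.zeros(shape)
    t_map[mask_idx] = t_obs
    labels_out = np.zeros(shape, dtype=np.int32)
    for i, cmask in enumerate(surviving, start=1):
        labels_out[cmask] = i
    return ClusterResult(t_map, thr, labels_out, extents, pvals, n_perm)
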