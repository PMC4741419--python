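"""Two-arm group comparison of the partial-volume features.

Arm 1 (partial volume): per region, a multivariate test (Pillai's trace on
the triple mu_gm, mu_wm, C_GM/C_WM) asks whether the tissue-specific
profile differs between patients and controls, and two-tailed
permutation-based two-sample t-tests attribute a multivariate difference to
individual components.  Arm 2 (global averaging): the classical region-mean
T1 compared with a two-sample t-test.  Age and sex enter every test as
covariates; multiplicity is controlled by Bonferroni or a max-statistic
permutation family-wise error procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .features import PV_FEATURES

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
EXHAUSTIVE_LIMIT = 20_000
DEFAULT_COVARIATES = ("age", "sex")


class RankDeficientDesignError(ValueError):
    """The design matrix (intercept, group, covariates) is rank-deficient."""


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _as_group_indicator(groups) -> np.ndarray:
    g = np.asarray(groups)
    if g.dtype.kind in "b":
        return g.astype(float)
    if g.dtype.kind in "iuf":
        vals = np.unique(g)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("numeric group vector must be 0/1")
        return g.astype(float)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {list(labels)}")
    # patients coded 1 when the canonical labels are present, else lexicographic
    one = "PATIENT" if "PATIENT" in labels else labels[1]
    return (g == one).astype(float)


def _design(groups, covariates) -> tuple[np.ndarray, np.ndarray]:
    g = _as_group_indicator(groups)
    n = g.size
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate matrix does not match the sample size")
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            "design matrix (intercept, group, covariates) is rank-deficient; "
            "a covariate is collinear with the group indicator")
    return X, g


def residualize(y, covariates) -> np.ndarray:
    """Residuals of a feature after regressing out intercept + covariates."""
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# MANOVA arm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManovaResult:
    pillai: float
    f_value: float
    df1: int
    df2: int
    p_raw: float
    n_per_group: tuple[int, int]


def manova_group_test(features, groups, covariates=None) -> ManovaResult:
    """Pillai's trace for the group effect in a multivariate linear model.

    Fits ``Y ~ 1 + group (+ covariates)`` for the feature matrix ``Y``
    (n subjects x p features) and tests the group coefficient row with
    Pillai's trace and its standard F approximation.  With a single feature
    and no covariates this reduces exactly to the pooled two-sample t-test.
    """
    Y = np.asarray(features, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    if np.isnan(Y).any():
        raise ValueError("feature matrix contains missing values; drop those "
                         "subjects first")
    X, g = _design(groups, covariates)
    n1 = int((g == 0).sum())
    n2 = int((g == 1).sum())
    if min(n1, n2) < 3:
        raise ValueError(f"need at least 3 subjects per group, got {n1}/{n2}")
    k = X.shape[1]
    if n - k < p:
        raise ValueError("fewer error degrees of freedom than features")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ X.T @ Y
    E = Y.T @ Y - B.T @ xtx @ B
    L = np.zeros((1, k))
    L[0, 1] = 1.0  # the group row
    LB = L @ B
    H = LB.T @ np.linalg.inv(L @ xtx_inv @ L.T) @ LB
    ve = n - k
    pillai = float(np.trace(H @ np.linalg.inv(H + E)))
    # hypothesis df = 1, so s = 1 and the F approximation is exact
    df1, df2 = p, ve - p + 1
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for the "
                         "Pillai F approximation")
    if pillai >= 1.0:
        f_value, p_raw = np.inf, 0.0
    else:
        f_value = (pillai / (1.0 - pillai)) * df2 / df1
        p_raw = float(sps.f.sf(f_value, df1, df2))
    return ManovaResult(pillai, float(f_value), df1, df2, min(max(p_raw, 0.0), 1.0),
                        (n1, n2))


# ---------------------------------------------------------------------------
# permutation component tests
# ---------------------------------------------------------------------------

def _pooled_t(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = x1.size, x2.size
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return 0.0
    return float((x2.mean() - x1.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def _pooled_t_matrix(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Row-wise pooled t statistics; rows are permutations (or features)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x2.mean(axis=1) - x1.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class PermutationResult:
    statistic: float
    p_raw: float
    p_fwe: float | None
    n_perm: int
    exhaustive: bool
    n_per_group: tuple[int, int]


def permutation_family_test(features, groups, covariates=None,
                            n_perm: int = DEFAULT_N_PERM,
                            rng: np.random.Generator | int | None = None,
                            exhaustive_limit: int = EXHAUSTIVE_LIMIT,
                            ) -> list[PermutationResult]:
    """Joint permutation t-tests for a family of features.

    Covariates are regressed out of each feature first; the observed pooled
    two-sample |t| on the residuals is then compared against its
    distribution under group-label permutations (residual-permutation
    scheme).  All features share the same permutations, which yields both
    per-feature raw p-values, ``p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm)``,
    and single-step max-statistic family-wise-error p-values,
    ``p_fwe = (1 + #{max_k |t*_k| >= |t_obs|}) / (1 + n_perm)``.
    When the number of distinct group splits is at most ``exhaustive_limit``
    the full enumeration is used and the p-values are exact fractions.
    """
    Y = np.asarray(features, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    _, g = _design(groups, covariates)  # validates the design
    idx1 = np.flatnonzero(g == 0)
    idx2 = np.flatnonzero(g == 1)
    n1, n2 = idx1.size, idx2.size
    if min(n1, n2) < 2:
        raise ValueError(f"need at least 2 subjects per group, got {n1}/{n2}")
    R = np.column_stack([residualize(Y[:, j], covariates) for j in range(p)])

    t_obs = np.array([_pooled_t(R[idx1, j], R[idx2, j]) for j in range(p)])
    constant = np.array([np.ptp(R[:, j]) < 1e-12 * max(1.0, np.abs(R[:, j]).max())
                         for j in range(p)])
    for j in np.flatnonzero(constant):
        log.warning("permutation test: feature %d is constant; p set to 1", j)

    total = comb(n, n1)
    eps = 1e-12
    if total <= exhaustive_limit:
        t_all = np.empty((total, p))
        order = np.arange(n)
        for i, subset in enumerate(combinations(order, n1)):
            sel = np.zeros(n, dtype=bool)
            sel[list(subset)] = True
            t_all[i] = [_pooled_t(R[sel, j], R[~sel, j]) for j in range(p)]
        abs_t = np.abs(t_all)
        max_t = abs_t.max(axis=1)
        results = []
        for j in range(p):
            if constant[j]:
                results.append(PermutationResult(0.0, 1.0, 1.0, total, True,
                                                 (n1, n2)))
                continue
            thr = abs(t_obs[j]) - eps
            p_raw = float(np.sum(abs_t[:, j] >= thr)) / total
            p_fwe = float(np.sum(max_t >= thr)) / total
            results.append(PermutationResult(float(t_obs[j]), p_raw, p_fwe,
                                             total, True, (n1, n2)))
        return results

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    perm = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    abs_t = np.empty((n_perm, p))
    for j in range(p):
        rp = R[:, j][perm]
        abs_t[:, j] = np.abs(_pooled_t_matrix(rp[:, :n1], rp[:, n1:]))
    max_t = abs_t.max(axis=1)
    results = []
    for j in range(p):
        if constant[j]:
            results.append(PermutationResult(0.0, 1.0, 1.0, n_perm, False,
                                             (n1, n2)))
            continue
        thr = abs(t_obs[j]) - eps
        p_raw = (1.0 + np.sum(abs_t[:, j] >= thr)) / (1.0 + n_perm)
        p_fwe = (1.0 + np.sum(max_t >= thr)) / (1.0 + n_perm)
        results.append(PermutationResult(float(t_obs[j]), float(p_raw),
                                         float(p_fwe), n_perm, False, (n1, n2)))
    return results


def permutation_component_test(feature, groups, covariates=None,
                               n_perm: int = DEFAULT_N_PERM,
                               rng: np.random.Generator | int | None = None,
                               exhaustive_limit: int = EXHAUSTIVE_LIMIT,
                               ) -> PermutationResult:
    """Two-tailed permutation two-sample t-test for a single feature."""
    return permutation_family_test(np.asarray(feature, float)[:, None], groups,
                                   covariates, n_perm, rng, exhaustive_limit)[0]


# ---------------------------------------------------------------------------
# global-averaging arm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalTestResult:
    statistic: float
    p_raw: float
    df: int
    n_per_group: tuple[int, int]


def global_mean_test(mean_t1, groups, covariates=None) -> GlobalTestResult:
    """Two-sample t-test on region-mean T1, optionally covariate-adjusted.

    Implemented as the t-test of the group coefficient in an ordinary
    linear model ``mean_t1 ~ 1 + group (+ covariates)``; with no covariates
    this is algebraically the classical pooled two-sample t-test.
    """
    y = np.asarray(mean_t1, dtype=np.float64)
    X, g = _design(groups, covariates)
    n1 = int((g == 0).sum())
    n2 = int((g == 1).sum())
    if min(n1, n2) < 3:
        raise ValueError(f"need at least 3 subjects per group, got {n1}/{n2}")
    fit = sm.OLS(y, X).fit()
    return GlobalTestResult(float(fit.tvalues[1]), float(fit.pvalues[1]),
                            int(fit.df_resid), (n1, n2))


# ---------------------------------------------------------------------------
# multiplicity correction
# ---------------------------------------------------------------------------

def correct_multiplicity(p_raw, method: str = "bonferroni",
                         family_size: int | None = None) -> np.ndarray:
    """Family-wise corrected p-values.

    ``bonferroni``: ``min(1, m * p)`` with ``m`` the family size (defaults
    to the number of p-values given).  The permutation-based max-statistic
    procedure is computed jointly with the component tests (see
    :func:`permutation_family_test`), since it needs the permutation draws,
    not just the raw p-values.
    """
    p = np.asarray(p_raw, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if method != "bonferroni":
        raise ValueError(f"unknown correction method {method!r}")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ComparisonConfig:
    regions: tuple[str, ...] = ("thalamus", "caudate", "putamen", "pallidum")
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    correction: str = "bonferroni"      # or "max_stat_fwe" (component tests)
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0


RESULT_COLUMNS = ["region", "arm", "feature", "statistic", "p_raw",
                  "p_corrected", "correction_method", "n_control", "n_patient"]


def _covariate_matrix(cohort: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray | None:
    if not names:
        return None
    cols = []
    for name in names:
        col = cohort[name]
        if name == "sex" or col.dtype == object:
            col = (col.astype(str).str.upper().str[0] == "M").astype(float)
        cols.append(np.asarray(col, dtype=np.float64))
    return np.column_stack(cols)


def run_comparison(feature_table: pd.DataFrame,
                   cohort: pd.DataFrame,
                   config: ComparisonConfig | None = None) -> pd.DataFrame:
    """Both analysis arms over all regions, with multiplicity correction.

    Returns one row per region for the MANOVA arm, one per component
    (mu_gm, mu_wm, ratio), and one for the global-mean arm.  Correction
    families: the regions form the family for the MANOVA and global arms;
    the three components within a region form the family for the component
    tests.  Subjects with missing features are dropped pairwise per region
    with a logged count.  Fully deterministic given ``config.seed``.
    """
    cfg = config or ComparisonConfig()
    feat_ids = set(feature_table["subject_id"].astype(str))
    coh_ids = set(cohort["subject_id"].astype(str))
    if feat_ids != coh_ids:
        only_f = sorted(feat_ids - coh_ids)
        only_c = sorted(coh_ids - feat_ids)
        raise ValueError(
            "feature table and cohort table cover different subjects: "
            f"only in features {only_f}; only in cohort {only_c}")
    merged = cohort.merge(feature_table, on="subject_id", validate="1:1")

    child_seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.regions))
    rows: list[dict] = []
    n_regions = len(cfg.regions)

    for region, seed_seq in zip(cfg.regions, child_seeds):
        pv_cols = [f"{region}_{f}" for f in PV_FEATURES]
        gm_col = f"{region}_mean_t1"
        missing_cols = [c for c in pv_cols + [gm_col] if c not in merged.columns]
        if missing_cols:
            raise ValueError(f"region {region!r} absent from the feature "
                             f"table (missing {missing_cols})")
        rng = np.random.default_rng(seed_seq)

        # --- partial-volume arm -------------------------------------------
        sub = merged.dropna(subset=pv_cols)
        n_drop = len(merged) - len(sub)
        if n_drop:
            log.info("region %s: dropped %d subjects with missing PV "
                     "features", region, n_drop)
        groups = sub["group"].to_numpy()
        covs = _covariate_matrix(sub, cfg.covariates)
        Y = sub[pv_cols].to_numpy(dtype=np.float64)
        man = manova_group_test(Y, groups, covs)
        rows.append(dict(region=region, arm="pv_manova", feature="all",
                         statistic=man.pillai, p_raw=man.p_raw,
                         p_corrected=float(correct_multiplicity(
                             [man.p_raw], family_size=n_regions)[0]),
                         correction_method="bonferroni",
                         n_control=man.n_per_group[0],
                         n_patient=man.n_per_group[1]))

        comp = permutation_family_test(Y, groups, covs, n_perm=cfg.n_perm,
                                       rng=rng)
        for fname, res in zip(PV_FEATURES, comp):
            if cfg.correction == "max_stat_fwe":
                p_corr, method = res.p_fwe, "max_stat_fwe"
            else:
                p_corr = float(correct_multiplicity(
                    [res.p_raw], family_size=len(PV_FEATURES))[0])
                method = "bonferroni"
            rows.append(dict(region=region, arm="pv_component", feature=fname,
                             statistic=res.statistic, p_raw=res.p_raw,
                             p_corrected=p_corr, correction_method=method,
                             n_control=res.n_per_group[0],
                             n_patient=res.n_per_group[1]))

        # --- global-averaging arm -----------------------------------------
        sub_g = merged.dropna(subset=[gm_col])
        groups_g = sub_g["group"].to_numpy()
        covs_g = _covariate_matrix(sub_g, cfg.covariates)
        glob = global_mean_test(sub_g[gm_col].to_numpy(dtype=np.float64),
                                groups_g, covs_g)
        rows.append(dict(region=region, arm="global_mean", feature="mean_t1",
                         statistic=glob.statistic, p_raw=glob.p_raw,
                         p_corrected=float(correct_multiplicity(
                             [glob.p_raw], family_size=n_regions)[0]),
                         correction_method="bonferroni",
                         n_control=glob.n_per_group[0],
                         n_patient=glob.n_per_group[1]))

    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def render_report(results: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable summary of a comparison results table."""
    lines = ["Group comparison report",
             "=======================", ""]
    for region, block in results.groupby("region", sort=False):
        lines.append(f"[{region}]")
        for _, row in block.iterrows():
            flag = " *" if row.p_corrected <= alpha else ""
            lines.append(
                f"  {row.arm:<13} {row.feature:<8} stat={row.statistic:+9.4f} "
                f"p={row.p_raw:8.5f} p_corr={row.p_corrected:8.5f} "
                f"({row.correction_method}){flag}")
        lines.append("")
    lines.append(f"* corrected p <= {alpha}; families: regions for the "
                 "MANOVA/global arms, the three components within a region "
                 "for the component tests.")
    return "\n".join(lines)
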