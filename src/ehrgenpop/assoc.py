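"""Association machinery: logistic scans of phecodes on ancestry, per-group
GWAS, fixed-effects meta-analysis, PheWAS, and the supporting statistics
(Bonferroni thresholds, genomic control, effective sample size).

Model conventions
-----------------
Every scan fits a logistic regression by maximum likelihood and reports the
coefficient of interest on the log-odds scale with its Wald standard error,
z, two-sided p, and OR with 95% CI (exp(beta +/- 1.96 SE)). Sex enters as a
0/1 covariate (female = 1) and is dropped automatically from sex-specific
strata where it is constant. Non-convergence and complete separation are
flagged and the p-value left missing, mirroring how biobank GWAS pipelines
report failed per-variant fits as NA rather than aborting the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

GENOME_WIDE_P = 5e-8
CHI2_1_MEDIAN = 0.4549  # median of the chi-square distribution with 1 df


# ----------------------------------------------------------------------
# single logistic fit
# ----------------------------------------------------------------------
@dataclass
class LogisticFit:
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    converged: bool
    separation: bool = False
    term: str = ""
    all_coefs: dict = field(default_factory=dict)


def fit_logistic(
    y: np.ndarray,
    X: pd.DataFrame,
    term: str,
    max_beta: float = 20.0,
) -> LogisticFit:
    """ML logistic fit of y on X (no implicit intercept: include ``const``).

    ``term`` names the covariate whose Wald test is reported. Degenerate
    outcomes and rank-deficient designs raise; separation (any |beta| >
    ``max_beta`` or a statsmodels separation error) is flagged with p
    missing.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: y is constant")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            return LogisticFit(
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                n_cases, n_controls, converged=False, separation=True, term=term,
            )
    beta = float(res.params[term])
    separation = bool(np.abs(res.params).max() > max_beta)
    converged = bool(res.mle_retvals.get("converged", False)) and not separation
    se = float(res.bse[term])
    if separation or not converged or not np.isfinite(se):
        return LogisticFit(
            beta, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_cases, n_controls, converged=False, separation=separation, term=term,
        )
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticFit(
        beta=beta,
        se=se,
        z=z,
        p=max(p, np.finfo(float).tiny),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        n_cases=n_cases,
        n_controls=n_controls,
        converged=True,
        term=term,
        all_coefs=dict(res.params),
    )


def _fit_row(fit: LogisticFit, **extra) -> dict:
    row = {
        "beta": fit.beta,
        "se": fit.se,
        "or": fit.odds_ratio,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "p": fit.p,
        "n_cases": fit.n_cases,
        "n_controls": fit.n_controls,
        "flag": "separation" if fit.separation else ("" if fit.converged else "no_convergence"),
    }
    row.update(extra)
    return row


def _error_row(err: Exception, **extra) -> dict:
    row = {
        "beta": np.nan, "se": np.nan, "or": np.nan, "ci_low": np.nan,
        "ci_high": np.nan, "p": np.nan, "n_cases": 0, "n_controls": 0,
        "flag": f"error:{err}",
    }
    row.update(extra)
    return row


# ----------------------------------------------------------------------
# scans
# ----------------------------------------------------------------------
@dataclass
class ScanResult:
    table: pd.DataFrame
    n_tests: int
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni(self.alpha, self.n_tests)


def _base_design(age: np.ndarray, female: np.ndarray, drop_sex: bool) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "age": age})
    if not drop_sex:
        X["sex"] = female
    return X


def phecode_gia_scan(
    case_status: pd.DataFrame,
    gia: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    sire: pd.Series | None = None,
    testable: dict[str, list[str]] | None = None,
    sex_specific: dict[str, str] | None = None,
    groups: list[str] | None = None,
    alpha: float = 0.05,
) -> ScanResult:
    """One-vs-rest GIA-phecode scan: logit(phecode) ~ group + sex + age
    (+ SIRE factor when ``sire`` is given).

    ``case_status`` is a person x phecode frame of 1/0/NaN. Ambiguous GIA
    samples are excluded from the "rest"; sex-specific phecodes are fit
    within the matching sex with the sex covariate dropped. The Bonferroni
    threshold spans all (phecode, group) cells attempted.
    """
    sex_specific = sex_specific or {}
    assigned = gia[gia != "Ambiguous"]
    if groups is None:
        groups = sorted(assigned.unique())
    persons = case_status.index.intersection(assigned.index)
    rows = []
    for group in groups:
        phecodes = (
            testable[group] if testable is not None else list(case_status.columns)
        )
        for ph in phecodes:
            y_all = case_status.loc[persons, ph]
            stratum = persons
            drop_sex = False
            ss = sex_specific.get(ph, "none")
            if ss in ("male", "female"):
                want = "F" if ss == "female" else "M"
                stratum = persons[sex.loc[persons] == want]
                drop_sex = True
            y = y_all.loc[stratum].dropna()
            idx = y.index
            X = _base_design(
                age.loc[idx].to_numpy(float),
                (sex.loc[idx] == "F").to_numpy(float),
                drop_sex,
            )
            X["gia_group"] = (assigned.loc[idx] == group).to_numpy(float)
            if sire is not None:
                sire_idx = sire.loc[idx]
                ref = sire_idx.value_counts().idxmax()  # largest SIRE as reference
                for level in sorted(sire_idx.unique()):
                    if level != ref:
                        X[f"sire_{level}"] = (sire_idx == level).to_numpy(float)
            X.index = idx
            try:
                fit = fit_logistic(y.to_numpy(), X, term="gia_group")
                rows.append(_fit_row(fit, test_id=ph, group=group))
            except ValueError as err:
                rows.append(_error_row(err, test_id=ph, group=group))
    table = pd.DataFrame(rows)
    return ScanResult(table=table, n_tests=len(rows), alpha=alpha)


def admixture_phecode_scan(
    case_status: pd.DataFrame,
    Q: pd.DataFrame,
    sire: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    min_cases: int = 10,
    alpha: float = 0.05,
) -> ScanResult:
    """Admixture-proportion scans within each SIRE group.

    For every SIRE, phecode with case count strictly > ``min_cases`` in that
    SIRE, and ancestry component, fits logit(phecode) ~ q_k + sex + age over
    that SIRE's members only. Bonferroni spans all attempted cells.
    """
    rows = []
    components = list(Q.columns)
    for sire_group in sorted(sire.unique()):
        members = sire[sire == sire_group].index
        members = case_status.index.intersection(members).intersection(Q.index)
        if len(members) == 0:
            continue
        for ph in case_status.columns:
            y_all = case_status.loc[members, ph].dropna()
            if (y_all == 1).sum() <= min_cases:
                continue
            idx = y_all.index
            for comp in components:
                X = _base_design(
                    age.loc[idx].to_numpy(float),
                    (sex.loc[idx] == "F").to_numpy(float),
                    drop_sex=False,
                )
                X["admix_q"] = Q.loc[idx, comp].to_numpy(float)
                X.index = idx
                try:
                    fit = fit_logistic(y_all.to_numpy(), X, term="admix_q")
                    rows.append(
                        _fit_row(fit, test_id=ph, group=sire_group, component=comp)
                    )
                except ValueError as err:
                    rows.append(
                        _error_row(err, test_id=ph, group=sire_group, component=comp)
                    )
    table = pd.DataFrame(rows)
    return ScanResult(table=table, n_tests=len(rows), alpha=alpha)


def gwas_scan(
    dosages: np.ndarray,
    variant_ids: list[str],
    y: np.ndarray,
    age: np.ndarray,
    sex_female: np.ndarray,
    pcs: np.ndarray | None = None,
    alpha: float = GENOME_WIDE_P,
) -> ScanResult:
    """Per-variant additive-dosage logistic GWAS within one GIA group.

    Inputs are expected to be post per-group QC (het outliers, HWE, in-group
    MAF); covariates are age, sex and the group's own PCs 1-10. Failed fits
    yield missing p. The result table carries a ``lambda_gc`` attribute.
    """
    X0 = pd.DataFrame({"const": 1.0, "age": np.asarray(age, float), "sex": np.asarray(sex_female, float)})
    if pcs is not None:
        for c in range(pcs.shape[1]):
            X0[f"pc{c + 1}"] = pcs[:, c]
    rows = []
    for j, vid in enumerate(variant_ids):
        d = dosages[:, j].astype(float)
        obs = d >= 0
        if not obs.all():
            d = np.where(obs, d, d[obs].mean() if obs.any() else np.nan)
        X = X0.copy()
        X["dosage"] = d
        try:
            fit = fit_logistic(np.asarray(y, float), X, term="dosage")
            rows.append(_fit_row(fit, test_id=vid))
        except ValueError as err:
            rows.append(_error_row(err, test_id=vid))
    table = pd.DataFrame(rows)
    result = ScanResult(table=table, n_tests=len(rows), alpha=0.05)
    result.lambda_gc = lambda_gc(table["p"].dropna().to_numpy()) if table["p"].notna().any() else np.nan
    result.genome_wide_threshold = alpha
    return result


def meta_fixed_effects(group_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis across GIA groups.

    Input frames need columns ``test_id, beta, se`` on a shared allele
    orientation. Combined beta = sum(w_g beta_g)/sum(w_g) with w = 1/SE^2,
    SE = sum(w)^(-1/2); only variants contributed by >= 2 groups (finite
    beta and SE) are reported. Zero SEs are rejected.
    """
    frames = []
    for grp, df in group_results.items():
        sub = df[["test_id", "beta", "se"]].copy()
        sub["group"] = grp
        frames.append(sub)
    allrows = pd.concat(frames, ignore_index=True)
    allrows = allrows[np.isfinite(allrows["beta"]) & np.isfinite(allrows["se"])]
    if (allrows["se"] <= 0).any():
        raise ValueError("zero or negative SE in meta-analysis input")
    out = []
    for vid, sub in allrows.groupby("test_id"):
        if len(sub) < 2:
            continue
        w = 1.0 / sub["se"] ** 2
        beta = float((w * sub["beta"]).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se
        out.append(
            {
                "test_id": vid,
                "beta": beta,
                "se": se,
                "p": float(2.0 * stats.norm.sf(abs(z))),
                "n_groups": int(len(sub)),
            }
        )
    return pd.DataFrame(out, columns=["test_id", "beta", "se", "p", "n_groups"])


def phewas(
    dosage: np.ndarray,
    case_status: pd.DataFrame,
    age: pd.Series,
    sex: pd.Series,
    pcs: pd.DataFrame | None = None,
    sex_specific: dict[str, str] | None = None,
    phecodes: list[str] | None = None,
    alpha: float = 0.05,
) -> ScanResult:
    """One variant against many phecodes within one GIA group.

    ``dosage`` is indexed like ``case_status``; ``pcs`` are the group's own
    PCs 1-10. Sex-specific phecodes are fit within the matching sex.
    Two thresholds are exposed: alpha/#phecodes and 5e-8/#phecodes.
    """
    sex_specific = sex_specific or {}
    if phecodes is None:
        phecodes = list(case_status.columns)
    dosage = pd.Series(np.asarray(dosage, float), index=case_status.index)
    rows = []
    for ph in phecodes:
        y_all = case_status[ph]
        stratum = case_status.index
        drop_sex = False
        ss = sex_specific.get(ph, "none")
        if ss in ("male", "female"):
            want = "F" if ss == "female" else "M"
            stratum = stratum[sex.loc[stratum] == want]
            drop_sex = True
        y = y_all.loc[stratum].dropna()
        idx = y.index
        X = _base_design(
            age.loc[idx].to_numpy(float), (sex.loc[idx] == "F").to_numpy(float), drop_sex
        )
        if pcs is not None:
            for c in pcs.columns:
                X[c] = pcs.loc[idx, c].to_numpy(float)
        X["dosage"] = dosage.loc[idx].to_numpy()
        X.index = idx
        try:
            fit = fit_logistic(y.to_numpy(), X, term="dosage")
            rows.append(_fit_row(fit, test_id=ph))
        except ValueError as err:
            rows.append(_error_row(err, test_id=ph))
    table = pd.DataFrame(rows)
    result = ScanResult(table=table, n_tests=len(phecodes), alpha=alpha)
    result.stringent_threshold = GENOME_WIDE_P / len(phecodes)
    return result


# ----------------------------------------------------------------------
# supporting statistics
# ----------------------------------------------------------------------
def bonferroni(alpha: float, n_tests: int) -> float:
    """alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2_1 quantile of the
    p-values over the null chi2_1 median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def n_effective(n_cases: int, n_controls: int) -> float:
    """Effective sample size 2 / (1/N_cases + 1/N_controls)."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("case and control counts must be >= 1")
    return 2.0 / (1.0 / n_cases + 1.0 / n_controls)
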