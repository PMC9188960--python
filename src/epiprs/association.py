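"""Case-control PRS association by covariate-adjusted logistic regression.

Organised as a model/results pair in the statsmodels idiom: build a
:class:`PRSLogit` from an outcome, a standardised polygenic score and
covariates (sex plus the top four ancestry PCs by convention), call
``fit()`` and read estimates off :class:`PRSLogitResults`.  The reported
effect is the log-odds of case status per 1 SD of PRS, with Wald
standard errors and Nagelkerke's pseudo-R2 as the variance-explained
summary.  A three-group screen-stratified comparison (controls vs
screen-positive vs screen-negative cases) is provided as three pairwise
fits with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PRSLogit", "PRSLogitResults", "AssocResult", "PairwiseComparison",
           "SeparationError", "fit_logistic", "nagelkerke_r2",
           "pairwise_group_comparison"]


class SeparationError(RuntimeError):
    """Raised when quasi-complete separation makes the MLE diverge."""


@dataclass
class AssocResult:
    """Log-odds of case status per SD of PRS, with uncertainty and fit summaries."""

    beta: float
    se: float
    z: float
    p: float
    r2_nagelkerke: float
    n_cases: int
    n_controls: int
    covariates: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class PairwiseComparison:
    """One contrast of the three-group screen-stratified comparison."""

    contrast: str  # control_vs_pos | control_vs_neg | pos_vs_neg
    result: AssocResult | None
    p_adjusted: float | None
    error: str | None = None


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R2.

    R2_CS = 1 - exp(2 (ll_null - ll_full) / n), divided by its maximum
    1 - exp(2 ll_null / n), clipped into [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-10:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    if loglik_null == 0:
        raise ValueError("null log-likelihood of 0 leaves Nagelkerke undefined")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal does not reduce rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear column(s): {bad}")


def _check_separation(fitted: np.ndarray, params: np.ndarray) -> None:
    pinned = (fitted < 1e-8) | (fitted > 1 - 1e-8)
    if pinned.any() and np.abs(params).max() > 20:
        raise SeparationError(
            "quasi-complete separation: fitted probabilities pinned at 0/1 "
            "with diverging coefficients")


class PRSLogit:
    """Logistic model of a binary outcome on a PRS plus covariates.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Outcome per sample (1 = case, or membership in the later-coded
        group for pairwise contrasts).
    prs : array-like
        Standardised polygenic score per sample.
    covariates : DataFrame or 2-D array, optional
        Additional columns (e.g. sex and the top four PCs).  Unknown sex
        (code 0) is mean-imputed with a warning.
    """

    def __init__(self, endog, prs, covariates=None, covariate_names=None):
        y = np.asarray(endog, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(set(y)) < 2:
            raise ValueError("both outcome classes must be present")
        prs = np.asarray(prs, dtype=float)
        if covariates is None:
            cov = np.empty((len(y), 0))
            names: list[str] = []
        elif isinstance(covariates, pd.DataFrame):
            cov = covariates.to_numpy(dtype=float)
            names = list(covariates.columns)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            names = covariate_names or [f"x{j + 1}" for j in range(cov.shape[1])]
        if "sex" in names:
            j = names.index("sex")
            sex = cov[:, j]
            unknown = ~np.isin(sex, (1.0, 2.0))
            if unknown.any():
                warnings.warn(f"{int(unknown.sum())} sample(s) with unknown sex "
                              "mean-coded")
                sex = sex.copy()
                sex[unknown] = sex[~unknown].mean() if (~unknown).any() else 1.5
                cov[:, j] = sex
        self.endog = y
        self.prs = prs
        self.cov = cov
        self.exog_names = ["const", "prs"] + names
        self.exog = np.column_stack([np.ones(len(y)), prs, cov])

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, prs_z,
                     covariates: tuple[str, ...] = ("sex", "pc1", "pc2", "pc3", "pc4")
                     ) -> "PRSLogit":
        """Build from a sample table (id, phenotype, covariate columns).

        ``prs_z`` may be a :class:`~epiprs.prs_scoring.PRSVector` or a
        Series indexed by sample id.
        """
        z = prs_z.z_series() if hasattr(prs_z, "z_series") else pd.Series(prs_z)
        df = samples.set_index("id")
        z = z.reindex(df.index)
        if z.isna().any():
            missing = list(df.index[z.isna()][:5])
            raise ValueError(f"samples without a PRS: {missing}")
        y = (df["phenotype"] == "case").astype(float)
        use = [c for c in covariates if c in df.columns]
        cov = df[use] if use else None
        return cls(y.to_numpy(), z.to_numpy(), covariates=cov)

    def fit(self, maxiter: int = 100) -> "PRSLogitResults":
        """Maximum-likelihood fit (IRLS) with rank and separation guards."""
        _check_rank(self.exog, self.exog_names)
        model = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, tol=1e-10)
        _check_separation(res.fittedvalues, res.params)
        # null model: covariates only (PRS column removed), for the
        # variance explained by the PRS term itself
        null_exog = np.delete(self.exog, 1, axis=1)
        null = sm.GLM(self.endog, null_exog, family=sm.families.Binomial()
                      ).fit(maxiter=maxiter, tol=1e-10)
        return PRSLogitResults(self, res, float(null.llf))


class PRSLogitResults:
    """Estimates, uncertainties and diagnostics of a fitted :class:`PRSLogit`."""

    def __init__(self, model: PRSLogit, glm_results, llf_null: float):
        self.model = model
        self._res = glm_results
        self.params = pd.Series(glm_results.params, index=model.exog_names)
        self.bse = pd.Series(glm_results.bse, index=model.exog_names)
        self.llf = float(glm_results.llf)
        self.llf_null = llf_null
        self.nobs = int(len(model.endog))
        self.n_cases = int(model.endog.sum())
        self.n_controls = self.nobs - self.n_cases
        self.beta = float(self.params["prs"])
        self.se = float(self.bse["prs"])
        self.zvalue = self.beta / self.se
        from scipy import stats as _st
        self.pvalue = float(np.clip(2 * _st.norm.sf(abs(self.zvalue)),
                                    np.finfo(float).tiny, 1.0))
        self.r2_nagelkerke = nagelkerke_r2(self.llf, self.llf_null, self.nobs)

    def to_assoc_result(self, cohort: str = "") -> AssocResult:
        cov_names = ",".join(self.model.exog_names[2:])
        return AssocResult(beta=self.beta, se=self.se, z=self.zvalue,
                           p=self.pvalue, r2_nagelkerke=self.r2_nagelkerke,
                           n_cases=self.n_cases, n_controls=self.n_controls,
                           covariates=cov_names)

    def summary(self) -> str:
        lines = [
            "PRS logistic regression",
            f"  observations: {self.nobs} ({self.n_cases} cases, "
            f"{self.n_controls} controls)",
            f"  log-likelihood: {self.llf:.4f} (covariates-only: {self.llf_null:.4f})",
            f"  Nagelkerke R2 (PRS term): {self.r2_nagelkerke:.4%}",
            "",
            f"  {'term':<10}{'coef':>10}{'se':>10}{'z':>9}{'p':>12}",
        ]
        from scipy import stats as _st
        for name in self.model.exog_names:
            b, s = self.params[name], self.bse[name]
            z = b / s
            p = 2 * _st.norm.sf(abs(z))
            lines.append(f"  {name:<10}{b:>10.4f}{s:>10.4f}{z:>9.3f}{p:>12.3g}")
        return "\n".join(lines)


def fit_logistic(y, prs_z, covariates=None) -> AssocResult:
    """One-call covariate-adjusted PRS association (see :class:`PRSLogit`)."""
    return PRSLogit(y, prs_z, covariates=covariates).fit().to_assoc_result()


_CONTRASTS = (
    # (label, group coded 0, group coded 1); positive beta = PRS elevated
    # in cases vs controls and in screen-positive vs screen-negative
    ("control_vs_pos", "control", "screen_pos"),
    ("control_vs_neg", "control", "screen_neg"),
    ("pos_vs_neg", "screen_neg", "screen_pos"),
)


def pairwise_group_comparison(prs_z, groups, covariates=None
                              ) -> list[PairwiseComparison]:
    """Three pairwise PRS contrasts between controls and the two case strata.

    ``groups`` holds values in {'control', 'screen_pos', 'screen_neg'}.
    Each unordered pair is compared by a covariate-adjusted logistic fit
    on the subset; p-values are Bonferroni-adjusted across the three
    contrasts.  A failing contrast is reported with its error and does
    not abort the others.
    """
    groups = np.asarray(groups)
    known = {"control", "screen_pos", "screen_neg"}
    bad = set(groups) - known
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    prs_z = np.asarray(prs_z, dtype=float)
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
    out = []
    for label, g0, g1 in _CONTRASTS:
        mask = np.isin(groups, (g0, g1))
        try:
            if not (groups == g0).any() or not (groups == g1).any():
                raise ValueError(f"empty group in contrast {label}")
            y = (groups[mask] == g1).astype(float)
            cov = covariates[mask].reset_index(drop=True) if covariates is not None else None
            res = fit_logistic(y, prs_z[mask], covariates=cov)
            out.append(PairwiseComparison(
                contrast=label, result=res,
                p_adjusted=float(min(1.0, 3.0 * res.p))))
        except (ValueError, SeparationError, np.linalg.LinAlgError) as e:
            out.append(PairwiseComparison(contrast=label, result=None,
                                          p_adjusted=None, error=str(e)))
    return out
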