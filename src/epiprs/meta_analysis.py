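"""Inverse-variance meta-analysis of per-cohort PRS effects.

Fixed-effects pooling with Cochran's Q and I-squared heterogeneity, and
a DerSimonian-Laird random-effects comparison.  Shaped as a model/results
pair: :class:`MetaAnalysis` holds the per-study log-odds and standard
errors; ``fit(method=...)`` returns a :class:`MetaAnalysisResults` with
the pooled estimate, heterogeneity statistics and a forest-plot table.

Closed forms: with w_i = 1/se_i^2, pooled = sum(w b)/sum(w),
pooled_se = sqrt(1/sum w), Q = sum w (b - pooled)^2,
I2 = max(0, (Q - df)/Q) * 100 with df = k - 1, and the DL estimate
tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) re-weights with
w*_i = 1/(se_i^2 + tau2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaAnalysis", "MetaAnalysisResults", "MetaResult",
           "fixed_effects", "random_effects_dl", "forest_table"]


@dataclass
class MetaResult:
    """Pooled log-odds per SD of PRS with heterogeneity summaries."""

    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    q_stat: float
    df: int
    i2: float  # percentage in [0, 100]
    tau2: float
    model: str  # 'fixed' or 'random'
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.i2 <= 100):
            raise ValueError("I2 must be a percentage in [0, 100]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


class MetaAnalysis:
    """Inverse-variance pooling of k independent study estimates."""

    def __init__(self, betas, ses, labels=None):
        self.betas = np.asarray(betas, dtype=float)
        self.ses = np.asarray(ses, dtype=float)
        if self.betas.size == 0:
            raise ValueError("no studies to pool")
        if self.betas.shape != self.ses.shape:
            raise ValueError("betas and ses must have equal length")
        if (self.ses <= 0).any() or not np.isfinite(self.ses).all():
            raise ValueError("all standard errors must be positive and finite")
        self.labels = list(labels) if labels is not None else \
            [f"study_{i + 1}" for i in range(self.betas.size)]

    @classmethod
    def from_results(cls, results) -> "MetaAnalysis":
        """Build from a list of AssocResult (uses .beta/.se/.cohort)."""
        return cls([r.beta for r in results], [r.se for r in results],
                   labels=[r.cohort or f"study_{i + 1}" for i, r in enumerate(results)])

    @property
    def k(self) -> int:
        return self.betas.size

    def _pool(self, weights: np.ndarray, model: str, q: float, df: int,
              i2: float, tau2: float) -> "MetaAnalysisResults":
        wsum = weights.sum()
        pooled = float((weights * self.betas).sum() / wsum)
        se = float(np.sqrt(1.0 / wsum))
        z = pooled / se
        p = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
        res = MetaResult(pooled_beta=pooled, pooled_se=se, z=z, p=p,
                         q_stat=q, df=df, i2=i2, tau2=tau2, model=model,
                         k=self.k)
        return MetaAnalysisResults(self, res, weights)

    def fit(self, method: str = "fixed") -> "MetaAnalysisResults":
        """Pool the studies; ``method`` is 'fixed' or 'random' (DerSimonian-Laird)."""
        w = 1.0 / self.ses**2
        pooled_fe = (w * self.betas).sum() / w.sum()
        q = float((w * (self.betas - pooled_fe) ** 2).sum())
        df = self.k - 1
        i2 = 0.0 if (df < 1 or q <= 0) else max(0.0, (q - df) / q) * 100.0
        if method == "fixed":
            return self._pool(w, "fixed", q, df, i2, tau2=0.0)
        if method == "random":
            if self.k < 2:
                raise ValueError("random-effects pooling needs at least 2 studies")
            denom = w.sum() - (w**2).sum() / w.sum()
            tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
            w_star = 1.0 / (self.ses**2 + tau2)
            return self._pool(w_star, "random", q, df, i2, tau2=tau2)
        raise ValueError(f"unknown method {method!r}")


class MetaAnalysisResults:
    """Pooled estimate plus per-study weights and forest-plot table."""

    def __init__(self, model: MetaAnalysis, result: MetaResult,
                 weights: np.ndarray):
        self.model = model
        self.result = result
        self.weights = weights

    def __getattr__(self, name):
        return getattr(self.result, name)

    def forest_table(self) -> pd.DataFrame:
        """Per-study rows (beta, se, 95% CI, weight %) plus the pooled row."""
        r = self.result
        wpct = 100.0 * self.weights / self.weights.sum()
        rows = [
            {"cohort": lab, "beta": b, "se": s,
             "ci_low": b - 1.96 * s, "ci_high": b + 1.96 * s,
             "weight_pct": wp}
            for lab, b, s, wp in zip(self.model.labels, self.model.betas,
                                     self.model.ses, wpct)
        ]
        rows.append({"cohort": f"pooled_{r.model}", "beta": r.pooled_beta,
                     "se": r.pooled_se,
                     "ci_low": r.pooled_beta - 1.96 * r.pooled_se,
                     "ci_high": r.pooled_beta + 1.96 * r.pooled_se,
                     "weight_pct": 100.0})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.result
        lines = [
            f"{r.model}-effects meta-analysis of {r.k} studies",
            f"  pooled log-odds per SD: {r.pooled_beta:.4f} "
            f"(se {r.pooled_se:.4f}, z {r.z:.3f}, p {r.p:.3g})",
            f"  heterogeneity: Q = {r.q_stat:.3f} on {r.df} df, "
            f"I2 = {r.i2:.1f}%, tau2 = {r.tau2:.4f}",
        ]
        return "\n".join(lines)


def fixed_effects(betas, ses, labels=None) -> MetaResult:
    """Inverse-variance fixed-effects pooled estimate with Q and I2."""
    return MetaAnalysis(betas, ses, labels).fit("fixed").result


def random_effects_dl(betas, ses, labels=None) -> MetaResult:
    """DerSimonian-Laird random-effects pooled estimate."""
    return MetaAnalysis(betas, ses, labels).fit("random").result


def forest_table(results, meta: MetaResult) -> pd.DataFrame:
    """Forest-plot table from per-cohort AssocResults and a pooled MetaResult."""
    ma = MetaAnalysis.from_results(results)
    if meta.model == "random":
        return ma.fit("random").forest_table()
    return ma.fit("fixed").forest_table()
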