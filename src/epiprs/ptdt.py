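"""Polygenic transmission disequilibrium test (pTDT) on parent-offspring trios.

For each trio the child's polygenic score is compared with the
mid-parent score (the average of the two parental scores, the child's
expectation under null transmission).  The per-trio deviation is
standardised by the SD of the mid-parent distribution within the
analysed set, and a one-sample two-sided t-test asks whether the mean
standardised deviation differs from 0.  Because the deviation is within
family, the test is robust to population stratification.

Shaped as a model/results pair: :class:`PTDT` holds trios and scores;
``fit(stratum=...)`` returns :class:`PTDTResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PTDT", "PTDTResult", "midparent_prs", "ptdt_test", "ptdt_stratified"]


@dataclass
class PTDTResult:
    """One-sample t-test of the standardised child-minus-mid-parent deviation."""

    n_trios: int
    mean_deviation: float
    sd_deviation: float
    t_stat: float
    df: int
    p: float
    stratum: str = "all"

    def summary(self) -> str:
        return (f"pTDT [{self.stratum}]: n = {self.n_trios}, "
                f"mean deviation = {self.mean_deviation:.4f} "
                f"(sd {self.sd_deviation:.4f}), "
                f"t({self.df}) = {self.t_stat:.3f}, p = {self.p:.3g}")


def _prs_lookup(prs) -> pd.Series:
    if hasattr(prs, "z_series"):
        return prs.z_series()
    return pd.Series(prs)


def midparent_prs(trios: pd.DataFrame, prs) -> pd.Series:
    """Mid-parent score per trio: (father + mother) / 2, indexed by child id."""
    s = _prs_lookup(prs)
    for col in ("father_id", "mother_id", "child_id"):
        missing = trios.loc[~trios[col].isin(s.index), col]
        if len(missing):
            raise ValueError(
                f"trio member(s) without a score: {list(missing[:5])}")
    mp = (s.loc[trios["father_id"]].to_numpy()
          + s.loc[trios["mother_id"]].to_numpy()) / 2.0
    return pd.Series(mp, index=trios["child_id"].to_numpy(), name="midparent")


class PTDT:
    """pTDT model over a trio set and a scored sample collection."""

    def __init__(self, trios: pd.DataFrame, prs, samples: pd.DataFrame | None = None):
        self.trios = trios.reset_index(drop=True)
        self.prs = _prs_lookup(prs)
        self.samples = samples

    def _subset(self, stratum: str) -> pd.DataFrame:
        if stratum == "all":
            return self.trios
        if self.samples is None:
            raise ValueError("stratified pTDT needs a sample table with screen_status")
        status = self.samples.set_index("id")["screen_status"]
        want = {"screen_pos": "positive", "screen_neg": "negative"}[stratum]
        keep = self.trios["child_id"].map(status) == want
        return self.trios[keep]

    def fit(self, stratum: str = "all") -> PTDTResult:
        """One-sample two-sided t-test of the mean standardised deviation.

        The denominator is the SD (n-1) of mid-parent scores over the
        analysed trios; at least 2 trios and a non-degenerate mid-parent
        spread are required.
        """
        trios = self._subset(stratum)
        n = len(trios)
        if n < 2:
            raise ValueError(f"stratum {stratum!r}: need >= 2 trios, have {n}")
        mp = midparent_prs(trios, self.prs)
        child = self.prs.loc[trios["child_id"]].to_numpy()
        sd_mp = np.std(mp.to_numpy(), ddof=1)
        if sd_mp == 0:
            raise ValueError("degenerate mid-parent scores: zero standard deviation")
        dev = (child - mp.to_numpy()) / sd_mp
        mean, sd = dev.mean(), dev.std(ddof=1)
        if sd == 0:
            t, p = 0.0, 1.0
            if mean != 0:
                t, p = np.inf * np.sign(mean), np.finfo(float).tiny
        else:
            t, p = stats.ttest_1samp(dev, 0.0)
        return PTDTResult(n_trios=n, mean_deviation=float(mean),
                          sd_deviation=float(sd), t_stat=float(t),
                          df=n - 1, p=float(np.clip(p, np.finfo(float).tiny, 1.0)),
                          stratum=stratum)

    def fit_stratified(self) -> list[PTDTResult]:
        """Overall test plus per-screen-status strata (skipping strata < 2 trios)."""
        out = [self.fit("all")]
        for stratum in ("screen_pos", "screen_neg"):
            try:
                out.append(self.fit(stratum))
            except ValueError:
                out.append(PTDTResult(n_trios=len(self._subset(stratum)),
                                      mean_deviation=np.nan, sd_deviation=np.nan,
                                      t_stat=np.nan, df=0, p=np.nan,
                                      stratum=f"{stratum} (skipped)"))
        return out


def ptdt_test(trios: pd.DataFrame, prs, samples: pd.DataFrame | None = None,
              stratum: str = "all") -> PTDTResult:
    """Functional wrapper over :class:`PTDT` for a single stratum."""
    return PTDT(trios, prs, samples).fit(stratum)


def ptdt_stratified(trios: pd.DataFrame, prs, samples: pd.DataFrame
                    ) -> list[PTDTResult]:
    """Overall, screen-positive and screen-negative pTDT results."""
    return PTDT(trios, prs, samples).fit_stratified()
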