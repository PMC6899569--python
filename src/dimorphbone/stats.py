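"""Study statistics: sex x genotype ANOVA, paired littermate t-tests,
relative qPCR quantification, and significance heat-map binning.

Two-way ANOVA uses type-II sums of squares on the two-factor linear model,
which is well-defined for the mildly unbalanced group sizes typical of
littermate designs. Littermate comparisons are one-tailed paired t-tests on
WT/KO pairs sharing a litter; the direction must be declared per endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "two_way_anova",
    "paired_one_tailed_t",
    "ddct_fold",
    "significance_heatmap",
    "SIGNIFICANCE_BINS",
]

#: heat-map bins: upper p bound -> colour (checked in order)
SIGNIFICANCE_BINS = (
    (1e-4, "red"),
    (1e-2, "yellow"),
    (5e-2, "green"),
    (1.0, "blue"),
)


@dataclass
class ComparisonResult:
    effect: str
    statistic: float
    df: tuple[float, float] | float
    p_value: float

    @property
    def significance_bin(self) -> str:
        return significance_bin(self.p_value)


def significance_bin(p: float) -> str:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    for bound, colour in SIGNIFICANCE_BINS:
        if p <= bound:
            return colour
    return "blue"


def two_way_anova(values, sex, genotype) -> dict[str, ComparisonResult]:
    """Sex x genotype two-way ANOVA (type-II sums of squares).

    Returns results keyed "sex", "genotype", "interaction". Every sex x
    genotype cell must be populated, and at least two cells need >= 2
    observations for an error term. If the response has zero variance the
    F statistics are undefined and every p is reported as 1 (no evidence of
    any effect).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "sex": list(sex), "genotype": list(genotype)})
    counts = df.groupby(["sex", "genotype"]).size()
    levels_s, levels_g = df.sex.unique(), df.genotype.unique()
    for s in levels_s:
        for g in levels_g:
            if (s, g) not in counts.index:
                raise ValueError(f"empty design cell: sex={s}, genotype={g}")
    if np.var(df.value.to_numpy()) == 0:
        one = ComparisonResult("", float("nan"), (float("nan"),) * 2, 1.0)
        return {k: ComparisonResult(k, one.statistic, one.df, one.p_value)
                for k in ("sex", "genotype", "interaction")}
    model = smf.ols("value ~ C(sex) * C(genotype)", data=df).fit()
    table = anova_lm(model, typ=2)
    key_map = {"C(sex)": "sex", "C(genotype)": "genotype",
               "C(sex):C(genotype)": "interaction"}
    out = {}
    for row, name in key_map.items():
        out[name] = ComparisonResult(
            effect=name,
            statistic=float(table.loc[row, "F"]),
            df=(float(table.loc[row, "df"]), float(table.loc["Residual", "df"])),
            p_value=float(table.loc[row, "PR(>F)"]),
        )
    return out


def paired_one_tailed_t(wt, ko, direction: str = "ko_greater") -> ComparisonResult:
    """One-tailed paired t-test on littermate WT/KO differences.

    ``direction`` is the alternative hypothesis: "ko_greater" (KO > WT) or
    "ko_less". With all-zero differences t = 0 and the one-sided p is 0.5 by
    the usual convention.
    """
    wt = np.asarray(wt, dtype=float)
    ko = np.asarray(ko, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError("WT and KO vectors must be paired (equal length)")
    if len(wt) < 2:
        raise ValueError("need at least two littermate pairs")
    d = ko - wt
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    if direction == "ko_greater":
        p = float(sps.t.sf(t, n - 1))
    elif direction == "ko_less":
        p = float(sps.t.cdf(t, n - 1))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ComparisonResult(effect=f"paired ({direction})", statistic=float(t),
                            df=float(n - 1), p_value=p)


def ddct_fold(ct_target, ct_reference, calibrator_ct_target,
              calibrator_ct_reference) -> np.ndarray:
    """Relative expression 2^(-ddCt) against a reference gene and calibrator.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the calibrator
    group's mean dCt. Returns one fold value per sample.
    """
    for name, arr in (("ct_target", ct_target), ("ct_reference", ct_reference),
                      ("calibrator_ct_target", calibrator_ct_target),
                      ("calibrator_ct_reference", calibrator_ct_reference)):
        if arr is None or len(np.atleast_1d(arr)) == 0:
            raise ValueError(f"{name} is missing")
        if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
            raise ValueError(f"{name} contains non-finite Ct values")
    dct = np.asarray(ct_target, float) - np.asarray(ct_reference, float)
    cal_dct = float(np.mean(np.asarray(calibrator_ct_target, float)
                            - np.asarray(calibrator_ct_reference, float)))
    return 2.0 ** -(dct - cal_dct)


def significance_heatmap(p_values: pd.DataFrame,
                         fdr: bool = False) -> pd.DataFrame:
    """Bin per-position p-values into the heat-map colours.

    ``p_values`` is a position x endpoint table. Binning is per position with
    no multiple-testing correction by default; ``fdr=True`` applies
    Benjamini-Hochberg across positions within each endpoint first.
    """
    p = p_values.copy().astype(float)
    if ((p < 0) | (p > 1)).any().any():
        raise ValueError("p-values outside [0, 1]")
    if fdr:
        for col in p.columns:
            p[col] = multipletests(p[col].to_numpy(), method="fdr_bh")[1]
    return p.map(significance_bin)
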