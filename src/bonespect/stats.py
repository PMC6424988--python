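"""Paired agreement statistics between reconstruction conditions.

Each non-reference condition is compared with the CT-based gold standard
over matched lesions: Pearson correlation, Bland-Altman mean difference
with 1.96-SD limits of agreement, and a proportional-bias check (ordinary
least squares of the differences on the pair means).

Sign convention: differences are ``test - reference`` throughout, so a
positive mean difference means the test condition reads higher than the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import PairingError

SIGN_CONVENTION = "test - reference"


@dataclass(frozen=True)
class AgreementResult:
    reference: str
    test: str
    n: int
    pearson_r: float
    pearson_p: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_intercept: float
    bias_slope_p: float


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(reference, test, reference_label: str = "reference",
                 test_label: str = "test") -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Differences are test - reference; the limits of agreement are
    ``mean +/- 1.96 * SD`` (SD with n-1 denominator).  Proportional bias is
    the OLS slope of the differences on the pair means, with its two-sided
    p-value.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-D arrays")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = tst - ref
    means = (tst + ref) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))

    if np.ptp(means) > 0:
        fit = sps.linregress(means, diff)
        slope, intercept, slope_p = float(fit.slope), float(fit.intercept), \
            float(fit.pvalue)
    else:
        slope, intercept, slope_p = 0.0, mean_diff, float("nan")

    try:
        r, p = pearson(ref, tst)
    except ValueError:          # identical inputs etc.
        r, p = float("nan"), float("nan")

    return AgreementResult(
        reference=reference_label, test=test_label, n=n,
        pearson_r=r, pearson_p=p,
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        bias_slope=slope, bias_intercept=intercept, bias_slope_p=slope_p)


def compare_conditions(table: pd.DataFrame, reference_condition: str = "CTAC",
                       metric: str = "suv_peak") -> list[AgreementResult]:
    """One agreement result per non-reference condition over matched lesions.

    ``table`` is the long-format quantitation table (columns ``lesion_id``,
    ``condition`` and the metric).  Every lesion must be present under the
    reference and each test condition; missing pairs raise with the lesion
    ids listed.
    """
    if reference_condition not in set(table["condition"]):
        raise PairingError(f"reference condition {reference_condition!r} missing "
                           "from the table")
    ref = table[table["condition"] == reference_condition].set_index("lesion_id")
    results = []
    for cond in sorted(set(table["condition"]) - {reference_condition}):
        tst = table[table["condition"] == cond].set_index("lesion_id")
        missing = sorted(set(ref.index).symmetric_difference(tst.index))
        if missing:
            raise PairingError(
                f"conditions {reference_condition}/{cond} not paired for "
                f"lesions {missing}")
        ids = sorted(ref.index)
        results.append(bland_altman(ref.loc[ids, metric].to_numpy(),
                                    tst.loc[ids, metric].to_numpy(),
                                    reference_label=reference_condition,
                                    test_label=cond))
    return results
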