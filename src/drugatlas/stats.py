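"""Comparison statistics for distance, sensitivity and screen-enrichment
analyses: one-sided Welch t-tests on distance sets, 2x2 chi-square
enrichment of screen hits over a random background, and the stratified
sensitivity-vs-synergy report.  No multiple-testing correction is applied
to the primary p-values; a Benjamini-Hochberg column is attached to reports
for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    test_kind: str                # t_one_sided | chi2 | pearson
    groups: tuple
    sizes: tuple
    means: tuple
    sems: tuple
    statistic: float
    p_value: float
    extra: dict = field(default_factory=dict)


def _sem(x) -> float:
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_distance_sets(synergy_distances, reference_distances,
                          alternative: str = "greater",
                          n_bins: int = 20) -> ComparisonResult:
    """One-sided Welch t-test: do synergistic pairs sit farther apart?

    Also emits shared histogram bins over [min, max] of the pooled data for
    plotting the two distance distributions side by side.
    """
    a = np.asarray(synergy_distances, float)
    b = np.asarray(reference_distances, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each distance set needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    return ComparisonResult(
        test_kind="t_one_sided",
        groups=("synergy", "reference"),
        sizes=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sems=(_sem(a), _sem(b)),
        statistic=float(t), p_value=float(p),
        extra={"bin_edges": edges,
               "hist_synergy": np.histogram(a, edges)[0],
               "hist_reference": np.histogram(b, edges)[0],
               "alternative": alternative},
    )


def enrichment_chi2(hits_a: int, total_a: int, hits_b: int, total_b: int,
                    yates: bool = False) -> ComparisonResult:
    """2x2 chi-square: screen hit rate vs background hit rate.

    Uncorrected by default; expected counts are reported and an expected
    cell below 1 triggers a warning recommending an exact test.
    """
    if not (total_a >= hits_a >= 0 and total_b >= hits_b >= 0):
        raise ValueError("totals must be >= hits >= 0")
    table = np.array([[hits_a, total_a - hits_a],
                      [hits_b, total_b - hits_b]], float)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
    if expected.min() < 1:
        warnings.warn("expected cell count < 1: consider Fisher's exact test",
                      stacklevel=2)
    return ComparisonResult(
        test_kind="chi2",
        groups=("screen", "background"),
        sizes=(total_a, total_b),
        means=(hits_a / total_a, hits_b / total_b),
        sems=(float("nan"), float("nan")),
        statistic=float(chi2), p_value=float(p),
        extra={"expected": expected, "yates": yates},
    )


def sensitivity_synergy_report(sensitivity_records: pd.DataFrame,
                               synergy_table,
                               alternative: str = "less") -> pd.DataFrame:
    """Compare normalized sensitivity S of synergy cases against the overall
    distribution for the same drugs, stratified by the targeted flag.

    A (cell line, drug) case counts as a synergy case when it appears on
    either side of a positive synergy row.  Lower S = more sensitive, so
    the default alternative tests whether synergy cases are *more*
    sensitive (mean S smaller) than the background.  Strata with < 2 cases
    are skipped.  A Benjamini-Hochberg adjusted column is attached.
    """
    recs = sensitivity_records
    if "targeted" not in recs.columns:
        recs = recs.assign(targeted=False)
    pos = synergy_table.rows[synergy_table.rows["label"] == 1]
    case_keys = set()
    for _, r in pos.iterrows():
        case_keys.add((r["cell_line"], r["drug_a"]))
        case_keys.add((r["cell_line"], r["drug_b"]))
    keyed = list(zip(recs["cell_line"], recs["drug"]))
    is_case = np.array([k in case_keys for k in keyed])
    case_drugs = {d for _, d in case_keys}
    in_scope = recs["drug"].isin(case_drugs).to_numpy()

    rows = []
    for strat, mask in (("all", np.ones(len(recs), bool)),
                        ("targeted", recs["targeted"].to_numpy(bool)),
                        ("non-targeted", ~recs["targeted"].to_numpy(bool))):
        sel = mask & in_scope
        a = recs.loc[sel & is_case, "S"].to_numpy(float)
        b = recs.loc[sel, "S"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        rows.append({"stratum": strat, "n_synergy": len(a), "n_overall": len(b),
                     "mean_S_synergy": a.mean(), "mean_S_overall": b.mean(),
                     "t": float(t), "p_one_sided": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p_one_sided"], method="fdr_bh")[1]
    return df
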