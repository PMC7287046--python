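"""n-drug combination index (median-effect principle) and reference scores.

For n single-agent viabilities V_1..V_n and the combined viability V_comb,
all in percent of untreated control,

    CI = [ sum_k 1/V_k  -  (n - 1)/100 ] / (1 / V_comb).

CI < 0.8 is called synergy, CI in [0.8, 1] additive-band, CI > 1
antagonism.  The (n-1)/100 correction makes the formula unit-dependent:
viabilities must be percentages, and fractional input is rejected.

The secondary CI treats an existing (k-1)-drug combination as a single
agent and scores the k-th drug on top of it — used for multi-drug designs
where each added drug must itself contribute.

Bliss excess and HSA (highest-single-agent) excess are also provided as
external reference metrics; the interpolated thresholds mapping CI = 0.8
onto external Loewe/Bliss software scales (7.8 and 2.5 respectively) are
stored as constants for interoperability only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CheckerboardPlate

logger = logging.getLogger("drugatlas")

CI_SYNERGY_THRESHOLD = 0.8
CI_ADDITIVE = 1.0
LOEWE_SYNERGY_THRESHOLD = 7.8   # external Combenefit Loewe scale
BLISS_ADDITIVITY_THRESHOLD = 2.5  # external Combenefit Bliss scale

V_FLOOR = 1.0    # % viability floor: avoids 1/V blow-up near complete kill
V_CEILING = 99.0  # % ceiling for plate-cell eligibility


@dataclass
class CIResult:
    """Combination index for one dose combination."""

    n: int
    v_singles: tuple
    v_comb: float
    ci: float
    classification: str
    bliss_excess: float = float("nan")
    hsa_excess: float = float("nan")
    floored: bool = False


def classify(ci: float) -> str:
    if ci < CI_SYNERGY_THRESHOLD:
        return "synergy"
    if ci > CI_ADDITIVE:
        return "antagonism"
    return "additive-band"


def _check_percent_scale(values) -> None:
    vals = np.asarray(values, float)
    if np.all(vals <= 1.5):
        raise ValueError(
            "viabilities look fractional (all <= 1.5); the combination index "
            "requires percent-of-control input"
        )


def combination_index(v_singles, v_comb: float) -> CIResult:
    """Combination index for n >= 2 drugs (viabilities in percent).

    Non-positive viabilities are floored to 1% with a QC flag; the
    classification follows the 0.8 / 1.0 thresholds.
    """
    v_singles = list(map(float, v_singles))
    n = len(v_singles)
    if n < 2:
        raise ValueError("combination index requires >= 2 single agents")
    _check_percent_scale(v_singles + [v_comb])
    floored = False
    floored_singles = []
    for v in v_singles:
        if v < V_FLOOR:
            floored = True
            v = V_FLOOR
        floored_singles.append(v)
    vc = float(v_comb)
    if vc < V_FLOOR:
        floored = True
        vc = V_FLOOR
    if floored:
        logger.debug("viability floored to %.1f%% before CI", V_FLOOR)
    ci = (sum(1.0 / v for v in floored_singles) - (n - 1) / 100.0) / (1.0 / vc)
    bliss, hsa = bliss_hsa(floored_singles, vc)
    return CIResult(n=n, v_singles=tuple(v_singles), v_comb=float(v_comb),
                    ci=float(ci), classification=classify(ci),
                    bliss_excess=bliss, hsa_excess=hsa, floored=floored)


def secondary_ci(v_pair_comb: float, v_third: float, v_triple: float) -> CIResult:
    """Secondary combination index: the pair's combined effect is treated as
    one agent and the third drug is scored on top of it.

    Identical by construction to ``combination_index([V_AB, V_C], V_ABC)``;
    the three rotations ([AB]+C, [BC]+A, [AC]+B) are obtained by permuting
    the arguments.
    """
    return combination_index([v_pair_comb, v_third], v_triple)


def bliss_hsa(v_singles, v_comb: float):
    """Bliss-independence and highest-single-agent excess, percentage points.

    Positive excess = the combination kills more than the reference surface.
    """
    v = np.asarray(v_singles, float)
    bliss_ref = float(np.prod(v / 100.0) * 100.0)
    hsa_ref = float(np.min(v))
    return bliss_ref - float(v_comb), hsa_ref - float(v_comb)


@dataclass
class PlateSummary:
    """Per-cell CI grid plus a plate-level summary for a checkerboard."""

    plate: CheckerboardPlate
    ci_grid: np.ndarray         # NaN for ineligible cells
    eligible: np.ndarray        # boolean mask, same shape
    summary_ci: float
    classification: str
    results: dict = field(default_factory=dict)  # index tuple -> CIResult
    summary_stat: str = "mean"
    thresholds: dict = field(default_factory=lambda: {
        "ci_synergy": CI_SYNERGY_THRESHOLD,
        "loewe": LOEWE_SYNERGY_THRESHOLD,
        "bliss": BLISS_ADDITIVITY_THRESHOLD,
    })


def summarize_plate(plate: CheckerboardPlate, mode: str = "primary",
                    summary: str = "mean") -> PlateSummary:
    """Score every combination cell of a checkerboard and summarize.

    For each cell where every drug has a nonzero dose, the single-agent
    reference viabilities are read off the plate's single-agent edges at the
    matching doses.  ``mode="primary"`` applies the n-drug CI; for a 3-drug
    plate ``mode="secondary"`` scores the third drug on top of the measured
    first-pair combination.  Cells whose combined viability falls outside
    [1%, 99%] (complete kill / no effect: CI uninformative) are ineligible
    and excluded from the summary, as are cells missing a single-agent
    reference.
    """
    nd = len(plate.drugs)
    if mode == "secondary" and nd != 3:
        raise ValueError("secondary mode requires a 3-drug plate")
    viab = plate.viability
    shape = viab.shape
    ci_grid = np.full(shape, np.nan)
    eligible = np.zeros(shape, bool)
    results: dict = {}

    def single(axis, level):
        idx = [0] * nd
        idx[axis] = level
        return viab[tuple(idx)]

    it = np.ndindex(*shape)
    n_missing_ref = 0
    for idx in it:
        if any(i == 0 for i in idx):
            continue  # single-agent edge or control, not a full combination
        vc = viab[idx]
        if np.isnan(vc):
            continue
        singles = [single(ax, lv) for ax, lv in enumerate(idx)]
        if any(np.isnan(s) for s in singles):
            n_missing_ref += 1
            continue
        if mode == "primary":
            res = combination_index(singles, vc)
        else:
            pair_idx = (idx[0], idx[1]) + (0,) * (nd - 2)
            v_pair = viab[pair_idx]
            if np.isnan(v_pair):
                n_missing_ref += 1
                continue
            res = secondary_ci(v_pair, singles[2], vc)
        results[idx] = res
        ci_grid[idx] = res.ci
        eligible[idx] = V_FLOOR <= vc <= V_CEILING
    if n_missing_ref:
        logger.warning("%d combination cell(s) lacked a single-agent reference",
                       n_missing_ref)

    vals = ci_grid[eligible]
    if vals.size == 0:
        # no cell in the informative band (e.g. an all-100% plate): fall
        # back to every computed cell so a null plate still reads additive
        vals = ci_grid[~np.isnan(ci_grid)]
    if vals.size == 0:
        summary_ci = float("nan")
        cls = "undetermined"
    else:
        summary_ci = float(np.mean(vals) if summary == "mean" else np.median(vals))
        cls = classify(summary_ci)
    return PlateSummary(plate=plate, ci_grid=ci_grid, eligible=eligible,
                        summary_ci=summary_ci, classification=cls,
                        results=results, summary_stat=summary)
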