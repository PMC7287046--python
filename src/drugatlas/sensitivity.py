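"""Drug-sensitivity normalization and dose-response reduction.

Sensitivities are log2 IC50 values (log2 uM).  ``normalize_tissue`` centres
them per (tissue, drug) stratum so the stratum average reads exactly 1 and a
record's value is 1 plus its delta-log2-IC50 from the stratum mean (values
below 1 = more sensitive than the tissue average).  ``scale01`` min-max
scales a small analysis panel per drug so 0 is the most and 1 the least
sensitive cell line.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import Annotation

logger = logging.getLogger("drugatlas")

#: Numeric targeted-variable encoding: 1 when the drug targets a gene
#: affected (mutated/amplified) in the cell line, 0.01 otherwise.
T_TARGETED = 1.0
T_UNTARGETED = 0.01


def normalize_tissue(records: pd.DataFrame,
                     grouping=("tissue", "drug"),
                     value_col: str = "log2_ic50") -> pd.DataFrame:
    """Add a normalized sensitivity column ``S`` = 1 + (log2 IC50 - stratum mean).

    The stratum is (tissue, drug) by default; within each stratum the mean of
    S is exactly 1.  Records with a missing IC50 are dropped (count logged).
    """
    df = records.copy()
    n_missing = int(df[value_col].isna().sum())
    if n_missing:
        logger.warning("skipping %d record(s) with missing %s", n_missing, value_col)
        df = df.dropna(subset=[value_col])
    means = df.groupby(list(grouping))[value_col].transform("mean")
    df["S"] = 1.0 + (df[value_col] - means)
    return df.reset_index(drop=True)


def scale01(records: pd.DataFrame, panel=None,
            value_col: str = "log2_ic50") -> pd.DataFrame:
    """Add ``scaled01``: per-drug min-max scaling over an analysis panel.

    0 marks the most sensitive (lowest IC50) and 1 the least sensitive cell
    line of the panel.  A constant panel has no ordering; every record gets
    0.5 with a warning.
    """
    df = records.copy()
    if panel is not None:
        df = df[df["cell_line"].isin(panel)].copy()
    out = np.empty(len(df))
    for _, idx in df.groupby("drug").groups.items():
        v = df.loc[idx, value_col].to_numpy(float)
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            warnings.warn("constant sensitivity panel: scaled01 set to 0.5",
                          stacklevel=2)
            out[df.index.get_indexer(idx)] = 0.5
        else:
            out[df.index.get_indexer(idx)] = (v - lo) / (hi - lo)
    df["scaled01"] = out
    return df


def targeted_flag(cell_line, drug, ann: Annotation) -> float:
    """Targeted variable T for a (cell line, drug) case.

    T = 1 when the drug's annotated targets intersect the cell line's
    affected genes, else 0.01.  An unannotated drug cannot be matched and
    falls back to 0.01 with a warning.
    """
    if drug not in ann.targets_of:
        warnings.warn(f"drug {drug!r} has no target annotation; T = {T_UNTARGETED}",
                      stacklevel=2)
        return T_UNTARGETED
    targets = ann.targets_of[drug]
    affected = ann.mutated_in.get(cell_line, set())
    return T_TARGETED if targets & affected else T_UNTARGETED


def add_targeted_flags(records: pd.DataFrame, ann: Annotation) -> pd.DataFrame:
    """Vectorized :func:`targeted_flag` over a records table."""
    df = records.copy()
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for line, drug in zip(df["cell_line"], df["drug"]):
            flags.append(targeted_flag(line, drug, ann))
    df["T"] = flags
    df["targeted"] = df["T"] == T_TARGETED
    return df


def dose_response_reduce(doses, viability):
    """Reduce a single-agent titration to (absolute IC50, AUC).

    The absolute IC50 is the dose at which the log-linearly interpolated
    viability crosses 50% of control (missing when 50% is never reached, as
    happens for weakly active compounds).  AUC is the trapezoid of
    viability/100 over log2 dose, normalized by the log-dose span to [0, 1];
    0 = complete killing everywhere, 1 = no effect.

    Doses must be positive and increasing (>= 4 points).  A wildly
    non-monotone curve is still reduced but flagged via the returned
    ``qc_flag``.
    """
    doses = np.asarray(doses, float)
    viability = np.asarray(viability, float)
    if doses.size < 4:
        raise ValueError("dose-response reduction needs >= 4 dose points")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")

    logd = np.log2(doses)
    auc = float(np.trapezoid(viability / 100.0, logd) / (logd[-1] - logd[0]))
    auc = float(np.clip(auc, 0.0, 1.0))

    ic50 = None
    below = viability <= 50.0
    if below.any():
        k = int(np.argmax(below))  # first crossing
        if k == 0:
            ic50 = float(doses[0])
        else:
            v0, v1 = viability[k - 1], viability[k]
            frac = (v0 - 50.0) / (v0 - v1)
            ic50 = float(2.0 ** (logd[k - 1] + frac * (logd[k] - logd[k - 1])))

    rough = np.abs(np.diff(viability))
    qc_flag = bool(np.sum(rough) > 2.5 * (viability.max() - viability.min() + 1e-9))
    return ic50, auc, qc_flag
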