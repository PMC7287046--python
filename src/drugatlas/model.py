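"""Logistic synergy-prediction models over (cell line, drug pair) features.

Each feature row holds, for one cell line k and one unordered drug pair
(i, j): the normalized dendrogram distance d_ij between the drugs, the cell
line's normalized sensitivities S_i, S_j to each drug, the targeted
variables T_i, T_j in {0.01, 1} and their row-level max t = max(T_i, T_j)
("at least one drug targets a gene affected in the line"), and a binary
synergy label.

Four nested logistic models are compared:

    IA :  logit(theta) = alpha + beta t
    IB :  logit(theta) = alpha + beta t + delta d
    IIA:  logit(theta) = alpha + beta t + gamma (S_i + S_j)
    IIB:  logit(theta) = alpha + beta t + delta d + gamma (S_i + S_j)

A single gamma is shared by the two sensitivity covariates: the pair is
unordered, so exchangeability of (i, j) forces one coefficient.  Because
unlabelled pairs may be unknown rather than non-synergistic, fitting uses
balanced negative resampling: per tissue, all positive rows plus an equally
sized random draw of negative rows, repeated ``n_resamples`` times;
reported coefficients are means over resamples (case-control sampling
shifts only the intercept, so slope estimates are consistent).

``SynergyLogit`` is the model object; ``fit`` returns a
``SynergyLogitResults`` carrying coefficient means, their spread over
resamples, separation diagnostics and a ``summary()`` table, with
``predict`` / ``rank_predictions`` / ROC evaluation hanging off it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import ttest_rel

import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold

from .io import Annotation, SynergyTable
from .distance import DistanceMatrix
from .sensitivity import T_UNTARGETED, targeted_flag

logger = logging.getLogger("drugatlas")

#: Covariate sets per model id (S_sum = S_i + S_j, shared gamma).
MODEL_COVARIATES = {
    "IA": ["t"],
    "IB": ["t", "d"],
    "IIA": ["t", "S_sum"],
    "IIB": ["t", "d", "S_sum"],
}
#: Greek coefficient name per design column.
COEF_NAMES = {"const": "alpha", "t": "beta", "d": "delta", "S_sum": "gamma"}


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_features(distances: DistanceMatrix,
                      sensitivities: pd.DataFrame,
                      annotation: Annotation,
                      synergy_table: SynergyTable) -> pd.DataFrame:
    """One row per (cell line, canonical drug pair) with all covariates.

    ``sensitivities`` needs columns cell_line, tissue, drug, S.  Pairs
    without a distance entry are dropped (logged).  C = 1 when at least one
    of the two sensitivities is known; rows with C = 0 are kept but flagged
    (they are excluded from every fit).
    """
    import warnings as _w

    dmat = distances.matrix
    sens = sensitivities.set_index(["cell_line", "drug"])["S"]
    tissue_of = dict(zip(sensitivities["cell_line"], sensitivities["tissue"]))
    rows = []
    n_nodist = 0
    for _, r in synergy_table.rows.iterrows():
        k, a, b = r["cell_line"], r["drug_a"], r["drug_b"]
        if a not in dmat.index or b not in dmat.index or np.isnan(dmat.loc[a, b]):
            n_nodist += 1
            continue
        s_i = sens.get((k, a), np.nan)
        s_j = sens.get((k, b), np.nan)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            t_i = targeted_flag(k, a, annotation)
            t_j = targeted_flag(k, b, annotation)
        c = int(not (np.isnan(s_i) and np.isnan(s_j)))
        rows.append({
            "cell_line": k, "tissue": tissue_of.get(k, "unspecified"),
            "drug_i": a, "drug_j": b,
            "d": float(dmat.loc[a, b]),
            "S_i": s_i, "S_j": s_j,
            "T_i": t_i, "T_j": t_j, "t": max(t_i, t_j),
            "C": c, "label": int(r["label"]),
        })
    if n_nodist:
        logger.warning("dropped %d row(s) whose pair has no distance", n_nodist)
    df = pd.DataFrame(rows)
    if len(df):
        df["S_sum"] = df["S_i"].fillna(0) + df["S_j"].fillna(0)
    return df


# ---------------------------------------------------------------------------
# Closed-form scores
# ---------------------------------------------------------------------------

def eq2_objective(rows: pd.DataFrame, s: float, d: float, t: float):
    """Linear pair-scoring objective C * (-s*Sbar + d*D + t*(T_i + T_j)).

    Sbar is the mean of the two sensitivities; rows without sensitivity
    information (C = 0) contribute 0.  Returns (per-row values, sum).
    """
    sbar = (rows["S_i"].fillna(0) + rows["S_j"].fillna(0)) / 2.0
    vals = rows["C"] * (-s * sbar + d * rows["d"] + t * (rows["T_i"] + rows["T_j"]))
    return vals.to_numpy(float), float(vals.sum())


def eq2_minimize(rows: pd.DataFrame, bounds=((0, 10), (0, 10), (0, 10))):
    """Bounded search minimizing the summed objective — a diagnostic only
    (the quantity has no stated loss; it is not used for prediction)."""
    def f(p):
        return eq2_objective(rows, *p)[1]
    res = minimize(f, x0=np.ones(3), bounds=bounds, method="L-BFGS-B")
    return {"s": res.x[0], "d": res.x[1], "t": res.x[2], "objective": res.fun}


def eq3_simplistic(t, d):
    """Closed-form synergy score theta = t e^d / (1 + t e^d).

    Equals the logistic inverse-link of (d + log t): increasing in both the
    drug distance d and the targeted variable t, and close to zero when
    neither drug targets a lesion of the cell line (t = 0.01).
    """
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    z = t * np.exp(d)
    return z / (1.0 + z)


def eq3_pair_scores(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-pair average of the simplistic score over available cell lines."""
    df = rows.copy()
    df["theta"] = eq3_simplistic(df["t"], df["d"])
    return (df.groupby(["drug_i", "drug_j"])["theta"]
              .mean().reset_index().sort_values("theta", ascending=False)
              .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def _design(rows: pd.DataFrame, model_id: str) -> np.ndarray:
    cols = MODEL_COVARIATES[model_id]
    X = rows[cols].to_numpy(float)
    return np.c_[np.ones(len(rows)), X]


def _fit_single(X: np.ndarray, y: np.ndarray):
    """ML logistic fit; falls back to a tiny L2 ridge on separation."""
    import warnings as _w
    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        separated = (not np.all(np.isfinite(res.bse))) or np.max(np.abs(params)) > 50
    except Exception:
        separated = True
        params = None
    if separated:
        lr = LogisticRegression(C=1e6, solver="lbfgs",
                                fit_intercept=False, max_iter=500)
        lr.fit(X, y)
        params = lr.coef_.ravel()
    return np.asarray(params, float), separated


class SynergyLogit:
    """Logistic synergy model over assembled pair features.

    Parameters
    ----------
    features : DataFrame from :func:`assemble_features` (or the synthetic
        generator): columns t, d, S_i, S_j, S_sum, tissue, label, C.
    model : {"IA", "IB", "IIA", "IIB"}
    min_positives : int
        Tissue strata with fewer positive rows are skipped (logged).

    Models IIA/IIB require both sensitivities observed (strict filter);
    IA/IB require C = 1 (at least one observed).
    """

    def __init__(self, features: pd.DataFrame, model: str = "IIB",
                 min_positives: int = 5):
        if model not in MODEL_COVARIATES:
            raise ValueError(f"unknown model id {model!r}")
        self.model_id = model
        self.min_positives = min_positives
        df = features.copy()
        if "C" not in df.columns:
            df["C"] = 1
        if "tissue" not in df.columns:
            df["tissue"] = "all"
        if "S_sum" not in df.columns and {"S_i", "S_j"} <= set(df.columns):
            df["S_sum"] = df["S_i"].fillna(0) + df["S_j"].fillna(0)
        if model in ("IIA", "IIB") and {"S_i", "S_j"} <= set(df.columns):
            keep = df["S_i"].notna() & df["S_j"].notna()
        else:
            keep = df["C"] == 1
        self.features = df[keep].reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "IIB", **kw):
        return cls(df, model=model, **kw)

    def fit(self, n_resamples: int = 1000, seed: int = 0) -> "SynergyLogitResults":
        """Balanced-negative resampled maximum-likelihood fit.

        Per resample: within each tissue stratum take every positive row and
        an equal-size uniform draw of negative rows (so the class balance is
        exactly 1:1), pool strata, fit by ML.  Coefficients are averaged
        over resamples; each resample's fit is kept for spread diagnostics.
        """
        rng = np.random.default_rng(seed)
        df = self.features
        strata = []
        for tissue, sub in df.groupby("tissue"):
            pos = sub[sub["label"] == 1]
            neg = sub[sub["label"] == 0]
            if len(pos) < self.min_positives:
                logger.warning("tissue %r skipped: %d positives < %d",
                               tissue, len(pos), self.min_positives)
                continue
            if len(neg) == 0:
                logger.warning("tissue %r skipped: no negative rows", tissue)
                continue
            strata.append((pos, neg))
        if not strata:
            raise ValueError("no tissue stratum with enough positive rows")

        cols = ["const"] + MODEL_COVARIATES[self.model_id]
        draws = np.empty((n_resamples, len(cols)))
        n_separated = 0
        for r in range(n_resamples):
            parts = []
            for pos, neg in strata:
                take = rng.choice(len(neg), size=len(pos), replace=len(neg) < len(pos))
                parts.append(pos)
                parts.append(neg.iloc[take])
            samp = pd.concat(parts, ignore_index=True)
            X = _design(samp, self.model_id)
            y = samp["label"].to_numpy(int)
            params, sep = _fit_single(X, y)
            n_separated += int(sep)
            draws[r] = params
        names = [COEF_NAMES[c] for c in cols]
        return SynergyLogitResults(
            model=self,
            params=pd.Series(draws.mean(axis=0), index=names),
            params_std=pd.Series(draws.std(axis=0, ddof=1) if n_resamples > 1
                                 else np.zeros(len(names)), index=names),
            resample_params=pd.DataFrame(draws, columns=names),
            n_resamples=n_resamples,
            n_separated=n_separated,
            seed=seed,
        )


@dataclass
class SynergyLogitResults:
    """Fitted synergy model: aggregate coefficients and diagnostics.

    ``params`` are means over balanced resamples, ``params_std`` their
    spread (resampling variability, not asymptotic SEs).  ``sigma2`` is a
    placeholder for the specification's Gaussian error variance, which a
    standard logistic likelihood does not estimate.
    """

    model: SynergyLogit
    params: pd.Series
    params_std: pd.Series
    resample_params: pd.DataFrame
    n_resamples: int
    n_separated: int
    seed: int
    sigma2: float | None = None
    _auc_cache: dict = field(default_factory=dict, repr=False)

    @property
    def model_id(self) -> str:
        return self.model.model_id

    def linpred(self, rows: pd.DataFrame) -> np.ndarray:
        df = rows.copy()
        if "S_sum" not in df.columns and {"S_i", "S_j"} <= set(df.columns):
            df["S_sum"] = df["S_i"].fillna(0) + df["S_j"].fillna(0)
        X = _design(df, self.model_id)
        return X @ self.params.to_numpy()

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predicted synergy probability theta for each row."""
        return expit(self.linpred(rows))

    def rank_predictions(self, candidates: pd.DataFrame) -> pd.DataFrame:
        """Candidate pairs sorted by predicted theta (descending); ties are
        broken by larger distance, then lexicographic pair."""
        df = candidates.copy()
        df["theta"] = self.predict(df)
        pair_cols = [c for c in ("drug_i", "drug_j") if c in df.columns]
        sort_cols = ["theta", "d"] + pair_cols
        asc = [False, False] + [True] * len(pair_cols)
        return df.sort_values(sort_cols, ascending=asc, kind="mergesort").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Synergy logistic model {self.model_id}",
            f"  rows: {len(self.model.features)}   "
            f"positives: {int(self.model.features['label'].sum())}",
            f"  balanced resamples: {self.n_resamples}   "
            f"ridge fallbacks (separation): {self.n_separated}",
            "",
            f"  {'coef':<8}{'mean':>12}{'resample sd':>14}",
        ]
        for name in self.params.index:
            lines.append(f"  {name:<8}{self.params[name]:>12.4f}"
                         f"{self.params_std[name]:>14.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ROC / AUC evaluation
# ---------------------------------------------------------------------------

def roc_auc(labels, scores):
    """Rank-statistic ROC AUC plus the curve points."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(roc_auc_score(labels, scores)), fpr, tpr


def evaluate_auc(results: SynergyLogitResults, rows: pd.DataFrame,
                 scheme: str = "holdout", n_folds: int = 5,
                 n_resamples: int = 25, seed: int = 0):
    """ROC AUC of a fitted model under a chosen evaluation scheme.

    ``holdout`` / ``external``: score the frozen coefficients on ``rows``.
    ``cv_kfold``: refit per fold with folds grouped by drug pair so no pair
    spans the train/test boundary, pool the out-of-fold scores.
    """
    if scheme in ("holdout", "external"):
        scores = results.predict(rows)
        auc, fpr, tpr = roc_auc(rows["label"], scores)
        return {"auc": auc, "fpr": fpr, "tpr": tpr, "scheme": scheme}
    if scheme != "cv_kfold":
        raise ValueError(f"unknown scheme {scheme!r}")
    pairs = rows["drug_i"].astype(str) + "|" + rows["drug_j"].astype(str)
    gkf = GroupKFold(n_splits=n_folds)
    scores = np.full(len(rows), np.nan)
    for f, (tr, te) in enumerate(gkf.split(rows, groups=pairs)):
        sub = SynergyLogit(rows.iloc[tr], model=results.model_id,
                           min_positives=results.model.min_positives)
        fit = sub.fit(n_resamples=n_resamples, seed=seed + f)
        scores[te] = fit.predict(rows.iloc[te])
    auc, fpr, tpr = roc_auc(rows["label"], scores)
    return {"auc": auc, "fpr": fpr, "tpr": tpr, "scheme": "cv_kfold",
            "n_folds": n_folds}


def covariate_contribution(rows: pd.DataFrame, n_resamples: int = 50,
                           seed: int = 0) -> pd.DataFrame:
    """Paired AUC comparison: does the distance add predictive power?

    For each balanced resample the nested pairs (IA, IB) and (IIA, IIB) are
    fitted on the same draw and scored on the full table; the one-sided
    paired t-test asks whether the richer model's AUC exceeds the poorer
    one's across resamples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for poor, rich in (("IA", "IB"), ("IIA", "IIB")):
        aucs = {poor: [], rich: []}
        for r in range(n_resamples):
            s = int(rng.integers(2**31))
            for mid in (poor, rich):
                m = SynergyLogit(rows, model=mid)
                fit = m.fit(n_resamples=1, seed=s)
                auc, _, _ = roc_auc(m.features["label"], fit.predict(m.features))
                aucs[mid].append(auc)
        a_poor = np.array(aucs[poor])
        a_rich = np.array(aucs[rich])
        t, p = ttest_rel(a_rich, a_poor, alternative="greater")
        out.append({"comparison": f"{rich} - {poor}",
                    f"auc_poor": a_poor.mean(), "auc_rich": a_rich.mean(),
                    "delta_auc": float((a_rich - a_poor).mean()),
                    "t": float(t), "p_one_sided": float(p),
                    "n_resamples": n_resamples})
    return pd.DataFrame(out)
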