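"""Ground-truth synthetic data emulating every input of the pipeline.

The generator plants a process structure: each drug inhibits exactly one
biological process, each cell line is vulnerable to a subset of processes,
and a drug only works in lines vulnerable to its process.  Driver genes map
1:1 to processes — a mutated driver makes its process a likely
vulnerability, and the drug targeting that process is "targeted" in that
line.  Synergy labels are drawn from the same mechanism the prediction
model assumes: pairs hitting two distinct processes to which a line is
co-vulnerable (large effect distance, high sensitivity to both) are the
synergy substrate.

Checkerboard plates are simulated with Hill single-agent curves, a Bliss
independence combination surface, and a multiplicative synergy factor < 1
on co-vulnerable pairs; plates with factor 1 should score near-additive
under the combination index, which ties the generator to the CI module's
0.8 synergy threshold.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Annotation, CheckerboardPlate, ResponseMatrix, SynergyTable
from .sensitivity import normalize_tissue


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults (4 processes x 8 drugs, 60 cell lines, 3 tissues, response
    noise 0.08) keep the planted structure recoverable while the full test
    suite runs in minutes.
    """

    n_processes: int = 4
    drugs_per_process: int = 8
    n_cell_lines: int = 60
    tissues: tuple = ("brain", "breast", "lung")
    vulnerability_prob: float = 0.35   # baseline P(line vulnerable to process)
    mutation_rate: float = 0.25        # P(driver gene mutated in a line)
    mut_implies_vuln: float = 0.9      # P(vulnerable | driver mutated)
    auc_resistant: float = 0.9         # AUC when the drug does not work
    auc_effect: float = 0.55           # AUC drop in vulnerable lines
    noise_sigma: float = 0.08          # response noise (AUC units)
    ic50_base: float = 2.0             # log2 uM in resistant lines
    ic50_effect: float = 3.0           # log2 IC50 drop in vulnerable lines
    ic50_sigma: float = 0.5
    # label mechanism: logit(theta) = alpha + beta t + delta d + gamma (S_i + S_j)
    alpha: float = -2.0
    beta: float = 2.0
    delta: float = 3.0
    gamma: float = -1.0
    d_within: float = 0.15             # smoothed distance, same-process pair
    d_cross: float = 0.85              # smoothed distance, cross-process pair
    d_noise: float = 0.05
    # checkerboard generation
    hill_slope: float = 1.0
    n_dose_steps: int = 5              # twofold ladder from IC50 downward
    synergy_factor: float = 0.5        # viability multiplier, co-vulnerable pairs
    plate_noise: float = 0.01          # multiplicative viability noise
    seed: int = 0

    def __post_init__(self):
        for p in (self.vulnerability_prob, self.mutation_rate,
                  self.mut_implies_vuln):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class Panel:
    """Generated panel: response matrix plus all ground truth."""

    response: ResponseMatrix
    annotation: Annotation
    mutations: pd.DataFrame        # cell_line, gene
    sensitivities: pd.DataFrame    # cell_line, tissue, drug, log2_ic50, S
    process_of: dict               # drug -> process index
    vulnerable: pd.DataFrame       # lines x processes boolean
    config: SimConfig = None


def _rng(cfg: SimConfig, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(cfg.seed + offset)


def generate_panel(cfg: SimConfig) -> Panel:
    """Sample the drug x cell-line panel with planted process structure."""
    rng = _rng(cfg, 0)
    P, K = cfg.n_processes, cfg.drugs_per_process
    drugs = [f"D{p}{chr(ord('a') + k)}" for p in range(P) for k in range(K)]
    process_of = {d: p for p in range(P) for d in
                  [f"D{p}{chr(ord('a') + k)}" for k in range(K)]}
    genes = [f"G{p}" for p in range(P)]
    lines = [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]
    tissue_of = {c: cfg.tissues[i % len(cfg.tissues)] for i, c in enumerate(lines)}

    mutated = rng.random((len(lines), P)) < cfg.mutation_rate
    vuln = np.where(
        mutated,
        rng.random((len(lines), P)) < cfg.mut_implies_vuln,
        rng.random((len(lines), P)) < cfg.vulnerability_prob,
    )

    proc_idx = np.array([process_of[d] for d in drugs])
    works = vuln[:, proc_idx]                       # lines x drugs
    auc = (cfg.auc_resistant - cfg.auc_effect * works
           + rng.normal(0, cfg.noise_sigma, works.shape))
    clipped = (auc < 0) | (auc > 1)
    if clipped.mean() > 0.20:
        warnings.warn(f"{clipped.mean():.0%} of AUC values clipped to [0, 1]",
                      stacklevel=2)
    auc = np.clip(auc, 0, 1)
    response = ResponseMatrix(
        values=pd.DataFrame(auc.T, index=drugs, columns=lines),
        value_kind="auc", tissue_of=tissue_of,
    )

    annotation = Annotation(
        targets_of={d: {genes[process_of[d]]} for d in drugs},
        mutated_in={c: {genes[p] for p in range(P) if mutated[i, p]}
                    for i, c in enumerate(lines)},
        pathway_of={d: f"process{process_of[d]}" for d in drugs},
    )
    mut_rows = [{"cell_line": c, "gene": genes[p]}
                for i, c in enumerate(lines) for p in range(P) if mutated[i, p]]
    mutations = pd.DataFrame(mut_rows, columns=["cell_line", "gene"])

    ic50 = (cfg.ic50_base - cfg.ic50_effect * works
            + rng.normal(0, cfg.ic50_sigma, works.shape))
    sens = pd.DataFrame({
        "cell_line": np.repeat(lines, len(drugs)),
        "tissue": np.repeat([tissue_of[c] for c in lines], len(drugs)),
        "drug": np.tile(drugs, len(lines)),
        "log2_ic50": ic50.ravel(),
    })
    sens = normalize_tissue(sens)

    return Panel(response=response, annotation=annotation, mutations=mutations,
                 sensitivities=sens,
                 process_of=process_of,
                 vulnerable=pd.DataFrame(vuln, index=lines,
                                         columns=[f"process{p}" for p in range(P)]),
                 config=cfg)


def generate_labels(panel: Panel, cfg: SimConfig | None = None):
    """Draw synergy labels from the planted mechanism.

    Label ~ Bernoulli(theta) with logit(theta) = alpha + beta t + delta d +
    gamma (S_i + S_j), where d is the cross-process indicator smoothed into
    [0, 1] and t = 1 when either drug targets a mutated driver of the line.
    Returns (SynergyTable, features DataFrame incl. ground-truth columns).
    """
    cfg = cfg or panel.config
    rng = _rng(cfg, 1)
    drugs = panel.response.drugs
    lines = panel.response.cell_lines
    proc = np.array([panel.process_of[d] for d in drugs])
    S = panel.sensitivities.pivot(index="cell_line", columns="drug", values="S")
    S = S.loc[lines, drugs].to_numpy()

    gene_of = {d: next(iter(panel.annotation.targets_of[d])) for d in drugs}
    T = np.array([[1.0 if gene_of[d] in panel.annotation.mutated_in.get(c, set())
                   else 0.01 for d in drugs] for c in lines])

    ii, jj = np.triu_indices(len(drugs), k=1)
    cross = (proc[ii] != proc[jj]).astype(float)
    d_pair = np.clip(np.where(cross == 1, cfg.d_cross, cfg.d_within)
                     + rng.normal(0, cfg.d_noise, ii.shape), 0, 1)

    rows = []
    for li, c in enumerate(lines):
        t = np.maximum(T[li, ii], T[li, jj])
        s_sum = S[li, ii] + S[li, jj]
        logit = cfg.alpha + cfg.beta * t + cfg.delta * d_pair + cfg.gamma * s_sum
        theta = 1.0 / (1.0 + np.exp(-logit))
        lab = (rng.random(theta.shape) < theta).astype(int)
        for k in range(len(ii)):
            rows.append({
                "cell_line": c, "tissue": panel.response.tissue_of[c],
                "drug_a": drugs[ii[k]], "drug_b": drugs[jj[k]],
                "label": int(lab[k]),
                "d_true": float(d_pair[k]), "cross_process": bool(cross[k]),
                "t": float(t[k]),
                "S_i": float(S[li, ii[k]]), "S_j": float(S[li, jj[k]]),
                "theta_true": float(theta[k]),
            })
    features = pd.DataFrame(rows)
    features["S_sum"] = features["S_i"] + features["S_j"]
    features["d"] = features["d_true"]
    features["C"] = 1
    features["drug_i"] = features["drug_a"]
    features["drug_j"] = features["drug_b"]
    table = SynergyTable(features[["cell_line", "drug_a", "drug_b", "label"]]
                         .assign(source="simulated"))
    return table, features


def generate_feature_rows(n: int, coeffs=None, seed: int = 0) -> pd.DataFrame:
    """Direct feature-row generator for parameter-recovery studies.

    Rows are drawn i.i.d.: d ~ U(0,1), t in {0.01, 1} (P = 0.35),
    S_i, S_j ~ N(1, 0.6); labels follow the richest model with
    ``coeffs = (alpha, beta, delta, gamma)`` (default (-2, 2, 3, -1)).
    """
    alpha, beta, delta, gamma = coeffs if coeffs is not None else (-2.0, 2.0, 3.0, -1.0)
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 1, n)
    t = np.where(rng.random(n) < 0.35, 1.0, 0.01)
    s_i = rng.normal(1.0, 0.6, n)
    s_j = rng.normal(1.0, 0.6, n)
    logit = alpha + beta * t + delta * d + gamma * (s_i + s_j)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return pd.DataFrame({
        "d": d, "t": t, "S_i": s_i, "S_j": s_j, "S_sum": s_i + s_j,
        "label": y, "tissue": "all", "C": 1,
    })


# ---------------------------------------------------------------------------
# Checkerboard plates
# ---------------------------------------------------------------------------

def _hill_viability(dose: np.ndarray, ic50_lin: float, slope: float) -> np.ndarray:
    v = np.where(dose > 0, 100.0 / (1.0 + (dose / ic50_lin) ** slope), 100.0)
    return v


def co_vulnerable(panel: Panel, cell_line: str, drug_a: str, drug_b: str) -> bool:
    """True when the line is vulnerable to both drugs' (distinct) processes."""
    pa, pb = panel.process_of[drug_a], panel.process_of[drug_b]
    if pa == pb:
        return False
    row = panel.vulnerable.loc[cell_line]
    return bool(row[f"process{pa}"] and row[f"process{pb}"])


def generate_plates(panel: Panel, pairs, cell_lines=None,
                    cfg: SimConfig | None = None):
    """Simulate 6x6-style checkerboards for the given drug pairs.

    Single agents follow Hill curves; the combination surface is the Bliss
    product times a synergy factor (< 1 on co-vulnerable pairs, 1
    elsewhere), with multiplicative noise.  Dose ladders run twofold from
    the line's IC50 downward, the highest dose at the IC50 as in a
    titration capped there.  Returns a list of (cell_line, plate,
    truth_factor) tuples.
    """
    cfg = cfg or panel.config
    rng = _rng(cfg, 2)
    lines = cell_lines if cell_lines is not None else panel.response.cell_lines
    ic50_tab = panel.sensitivities.set_index(["cell_line", "drug"])["log2_ic50"]
    out = []
    for a, b in pairs:
        for c in lines:
            factor = cfg.synergy_factor if co_vulnerable(panel, c, a, b) else 1.0
            plates_doses = []
            singles = []
            for drug in (a, b):
                ic50_lin = float(2.0 ** ic50_tab.loc[(c, drug)])
                ladder = ic50_lin * 2.0 ** np.arange(-(cfg.n_dose_steps - 1), 1)
                plates_doses.append(np.concatenate([[0.0], ladder]))
                singles.append(_hill_viability(
                    np.concatenate([[0.0], ladder]), ic50_lin, cfg.hill_slope))
            va = singles[0][:, None]
            vb = singles[1][None, :]
            viab = va * vb / 100.0
            comb = (np.arange(viab.shape[0])[:, None] > 0) & \
                   (np.arange(viab.shape[1])[None, :] > 0)
            viab = np.where(comb, viab * factor, viab)
            viab = viab * rng.normal(1.0, cfg.plate_noise, viab.shape)
            viab = np.clip(viab, 0, None)
            plate = CheckerboardPlate([a, b], plates_doses, viab)
            out.append((c, plate, factor))
    return out


def generate_triple_cis(panel: Panel, triples, cell_lines=None,
                        cfg: SimConfig | None = None,
                        base_ci: float = 0.95, ci_noise: float = 0.05):
    """Per-cell-line dual and triple combination indices for drug triples.

    The dual CI of a pair is the near-additive baseline scaled by its
    synergy factor; the triple CI scales by the mean of the three pairwise
    factors, so triples whose pairs all synergize get low multi-drug CIs —
    the mechanism that makes dual synergies predictive of multi-drug
    synergy.  Returns a long DataFrame with one row per (triple, cell
    line): dual CIs for the three rotations plus the triple CI.
    """
    cfg = cfg or panel.config
    rng = _rng(cfg, 3)
    lines = cell_lines if cell_lines is not None else panel.response.cell_lines
    rows = []
    for triple in triples:
        a, b, c3 = triple
        for c in lines:
            f = {}
            for x, y in ((a, b), (b, c3), (a, c3)):
                f[(x, y)] = cfg.synergy_factor if co_vulnerable(panel, c, x, y) else 1.0
            duals = {k: max(base_ci * v + rng.normal(0, ci_noise), 0.05)
                     for k, v in f.items()}
            triple_ci = max(base_ci * float(np.mean(list(f.values()))) ** 1.5
                            + rng.normal(0, ci_noise), 0.05)
            rows.append({
                "drugs": triple, "cell_line": c,
                "ci_ab": duals[(a, b)], "ci_bc": duals[(b, c3)],
                "ci_ac": duals[(a, c3)], "ci_triple": triple_ci,
            })
    return pd.DataFrame(rows)
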