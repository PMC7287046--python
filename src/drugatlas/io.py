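"""Readers and writers for drug-response panels, annotations, synergy labels,
checkerboard plates, atlas geometry and dendrograms.

All tabular inputs are delimited text (TSV by default, CSV accepted).
Missing values are encoded as empty fields or ``NA`` and are preserved as
missing — no imputation happens at read time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("drugatlas")

#: Strings accepted as missing values in any input table.
NA_VALUES = ["", "NA", "NaN", "nan"]


def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing TSV vs CSV from the suffix."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Drug x cell-line response panel.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by drug, columns by cell line.  Entries are either
        dose-response AUC fractions in [0, 1] (low = sensitive) or
        log2 IC50 in log2(uM), per ``value_kind``.  Missing entries are NaN.
    value_kind : {"auc", "log2_ic50"}
    tissue_of : mapping cell line -> tissue label.
    """

    values: pd.DataFrame
    value_kind: str = "auc"
    tissue_of: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.value_kind not in ("auc", "log2_ic50"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("drug and cell-line identifiers must be unique")
        if self.value_kind == "auc":
            vals = self.values.to_numpy(float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                raise ValueError("AUC values must lie in [0, 1]")

    @property
    def drugs(self) -> list:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list:
        return list(self.values.columns)

    def one_minus_auc(self) -> pd.DataFrame:
        """Response effect vectors (1 - AUC): high = strong drug effect."""
        if self.value_kind != "auc":
            raise ValueError("one_minus_auc requires AUC values")
        return 1.0 - self.values


@dataclass
class Annotation:
    """Drug-target / mutation / pathway annotation.

    ``targets_of`` maps drug -> set of target gene symbols; ``mutated_in``
    maps cell line -> set of affected (mutated or amplified) gene symbols;
    ``pathway_of`` optionally maps drug -> ontology group; ``cross_reactive``
    flags drugs with known activity over multiple pathways (excluded from
    within-pathway distance analyses).
    """

    targets_of: dict = field(default_factory=dict)
    mutated_in: dict = field(default_factory=dict)
    pathway_of: dict = field(default_factory=dict)
    cross_reactive: set = field(default_factory=set)

    def __post_init__(self):
        extra = set(self.cross_reactive) - set(self.pathway_of)
        if extra:
            raise ValueError(
                f"cross-reactive drugs missing a pathway label: {sorted(extra)}"
            )


@dataclass
class SynergyTable:
    """Curated synergy labels: one row per (cell line, unordered drug pair).

    Pairs are stored canonically (lexicographic drug order).  ``label`` is 1
    where the pair displays synergy in the cell line and 0 otherwise; a 0 may
    mean "no synergy" or "unknown".
    """

    rows: pd.DataFrame  # columns: cell_line, drug_a, drug_b, label, source

    def __post_init__(self):
        df = self.rows.copy()
        required = {"cell_line", "drug_a", "drug_b", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"synergy table missing columns: {sorted(missing)}")
        if "source" not in df.columns:
            df["source"] = ""
        if (df["drug_a"] == df["drug_b"]).any():
            raise ValueError("self-pairs (drug_a == drug_b) are not allowed")
        a = df[["drug_a", "drug_b"]].min(axis=1)
        b = df[["drug_a", "drug_b"]].max(axis=1)
        df["drug_a"], df["drug_b"] = a, b
        dup = df.duplicated(subset=["cell_line", "drug_a", "drug_b"], keep=False)
        if dup.any():
            sub = df[dup]
            if sub.groupby(["cell_line", "drug_a", "drug_b"])["label"].nunique().gt(1).any():
                raise ValueError("conflicting labels for a (cell line, pair) row")
            df = df.drop_duplicates(subset=["cell_line", "drug_a", "drug_b"])
        self.rows = df.reset_index(drop=True)


@dataclass
class CheckerboardPlate:
    """Dose-combination viability matrix (% of untreated control).

    ``doses`` holds one strictly increasing ladder per drug, each starting at
    0 (the untreated level).  ``viability`` is an n-dimensional array over the
    dose grid, axis k indexing drug k's ladder; the all-zero-dose corner is
    the untreated control and should read ~100.
    """

    drugs: list
    doses: list            # list of 1-D arrays, one per drug, starting at 0
    viability: np.ndarray  # shape = tuple(len(d) for d in doses)
    replicate: object = 0  # replicate index or grouping tag (e.g. cell line)
    units: str = "uM"

    def __post_init__(self):
        if len(self.drugs) < 2:
            raise ValueError("a checkerboard needs at least two drugs")
        self.doses = [np.asarray(d, float) for d in self.doses]
        self.viability = np.asarray(self.viability, float)
        if self.viability.shape != tuple(len(d) for d in self.doses):
            raise ValueError("viability shape does not match dose ladders")
        for d in self.doses:
            if d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ValueError("dose ladders must start at 0 and increase strictly")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.viability) < 0:
                raise ValueError("viability must be non-negative")
        control = self.viability[(0,) * len(self.drugs)]
        if np.isfinite(control) and abs(control - 100.0) > 15.0:
            warnings.warn(
                f"untreated control reads {control:.1f}%, expected ~100%",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Response-table readers
# ---------------------------------------------------------------------------

def read_response_table(
    path,
    layout: str = "wide",
    value_kind: str = "auc",
    tissue_table=None,
    min_cell_lines: int = 10,
) -> ResponseMatrix:
    """Read a drug x cell-line response table.

    ``layout="wide"``: first column = drug, remaining columns = cell lines.
    ``layout="long"``: columns drug, cell_line, value (extra columns such as
    a screening-site/batch tag are tolerated and warned about; no batch
    correction is attempted).

    Drugs with fewer than ``min_cell_lines`` non-missing values are dropped
    with a logged warning.  Duplicated (drug, cell line) entries are allowed
    only when their values agree; conflicts raise a ``ValueError`` naming the
    pair.
    """
    if layout == "wide":
        df = _read_table(path)
        df = df.set_index(df.columns[0])
        df.index.name = "drug"
        values = df.astype(float)
    elif layout == "long":
        df = _read_table(path)
        needed = {"drug", "cell_line", "value"}
        if not needed <= set(df.columns):
            raise ValueError(f"long layout requires columns {sorted(needed)}")
        extra = set(df.columns) - needed
        for col in extra & {"site", "batch", "dataset"}:
            logger.warning(
                "response table carries a dataset/batch column %r; multi-site "
                "panels can cluster by site rather than by drug effect — no "
                "correction is applied", col,
            )
        grouped = df.groupby(["drug", "cell_line"])["value"]
        if grouped.nunique(dropna=True).gt(1).any():
            bad = grouped.nunique(dropna=True)
            pair = bad[bad > 1].index[0]
            raise ValueError(f"conflicting duplicate entries for {pair}")
        ndup = len(df) - len(grouped)
        if ndup > 0:
            logger.warning("deduplicated %d consistent duplicate entries", ndup)
        values = grouped.first().unstack("cell_line")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    n_ok = values.notna().sum(axis=1)
    drop = n_ok[n_ok < min_cell_lines].index
    if len(drop):
        logger.warning(
            "dropping %d drug(s) with < %d non-missing values: %s",
            len(drop), min_cell_lines, list(drop),
        )
        values = values.drop(index=drop)

    tissue_of = {}
    if tissue_table is not None:
        tt = _read_table(tissue_table) if not isinstance(tissue_table, pd.DataFrame) else tissue_table
        tissue_of = dict(zip(tt.iloc[:, 0], tt.iloc[:, 1]))
    else:
        tissue_of = {c: "unspecified" for c in values.columns}
    return ResponseMatrix(values=values, value_kind=value_kind, tissue_of=tissue_of)


def read_annotation(targets_path=None, mutations_path=None, pathways_path=None) -> Annotation:
    """Assemble an :class:`Annotation` from up to three two-column tables.

    targets: drug, target (one row per drug-target link);
    mutations: cell_line, gene; pathways: drug, pathway[, cross_reactive].
    """
    targets_of: dict = {}
    mutated_in: dict = {}
    pathway_of: dict = {}
    cross: set = set()
    if targets_path is not None:
        df = _read_table(targets_path)
        for drug, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if not isinstance(gene, str) or not gene:
                raise ValueError("gene symbols must be non-empty strings")
            targets_of.setdefault(drug, set()).add(gene)
    if mutations_path is not None:
        df = _read_table(mutations_path)
        for line, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if not isinstance(gene, str) or not gene:
                raise ValueError("gene symbols must be non-empty strings")
            mutated_in.setdefault(line, set()).add(gene)
    if pathways_path is not None:
        df = _read_table(pathways_path)
        pathway_of = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if "cross_reactive" in df.columns:
            cross = set(df.loc[df["cross_reactive"].astype(bool), df.columns[0]])
    return Annotation(targets_of, mutated_in, pathway_of, cross)


def read_synergy_table(path) -> SynergyTable:
    """Read a curated synergy-label table (cell_line, drug_a, drug_b, label[, source])."""
    return SynergyTable(_read_table(path))


def read_plate_long(path) -> list:
    """Read checkerboard plates from a long table.

    Columns: ``drug_a, drug_b[, drug_c], dose_a, dose_b[, dose_c], viability
    [, replicate]``.  One plate is emitted per (drug set, replicate).
    """
    df = _read_table(path)
    drug_cols = [c for c in ("drug_a", "drug_b", "drug_c") if c in df.columns]
    dose_cols = [c.replace("drug", "dose") for c in drug_cols]
    if "replicate" not in df.columns:
        df["replicate"] = 0
    plates = []
    for (names_rep), sub in df.groupby(drug_cols + ["replicate"]):
        drugs = list(names_rep[:-1])
        rep = names_rep[-1]
        ladders = [np.sort(sub[c].unique()) for c in dose_cols]
        shape = tuple(len(l) for l in ladders)
        viab = np.full(shape, np.nan)
        index = [{v: i for i, v in enumerate(l)} for l in ladders]
        for _, row in sub.iterrows():
            idx = tuple(index[k][row[c]] for k, c in enumerate(dose_cols))
            viab[idx] = row["viability"]
        plates.append(CheckerboardPlate(drugs, ladders, viab, replicate=rep))
    return plates


# ---------------------------------------------------------------------------
# Atlas geometry output
# ---------------------------------------------------------------------------

def write_atlas_geometry(layout, path, format: str = "json") -> None:
    """Serialize an atlas layout: one record per drug with polygon vertices,
    centroid and per-edge border weight.

    JSON round-trips bit-for-bit within 1e-9 vertex tolerance via
    :func:`read_atlas_geometry`.  SVG renders filled cells with stroke width
    proportional to border weight.
    """
    if not layout.cells:
        raise ValueError("cannot write an empty layout")
    if format == "json":
        records = []
        for drug, poly in layout.cells.items():
            xy = list(map(list, np.asarray(poly.exterior.coords)))
            c = poly.centroid
            records.append({
                "drug": str(drug),
                "vertices": xy,
                "centroid": [c.x, c.y],
                "site": list(map(float, layout.sites[drug])),
                "weight": float(layout.weights.get(drug, 1.0)),
                "borders": [
                    {"neighbor": str(b), "weight": float(w)}
                    for (a, b), w in layout.border_weight.items() if a == drug
                ] + [
                    {"neighbor": str(a), "weight": float(w)}
                    for (a, b), w in layout.border_weight.items() if b == drug
                ],
            })
        payload = {
            "container": list(map(list, np.asarray(layout.container.exterior.coords))),
            "threshold": layout.threshold,
            "cells": records,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
    elif format == "svg":
        Path(path).write_text(_layout_to_svg(layout))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_atlas_geometry(path):
    """Inverse of :func:`write_atlas_geometry` for the JSON format."""
    from shapely.geometry import Polygon
    from .atlas import AtlasLayout

    payload = json.loads(Path(path).read_text())
    cells, sites, weights = {}, {}, {}
    borders = {}
    for rec in payload["cells"]:
        cells[rec["drug"]] = Polygon(rec["vertices"])
        sites[rec["drug"]] = tuple(rec["site"])
        weights[rec["drug"]] = rec["weight"]
        for b in rec["borders"]:
            key = tuple(sorted((rec["drug"], b["neighbor"])))
            borders[key] = b["weight"]
    return AtlasLayout(
        container=Polygon(payload["container"]),
        cells=cells,
        sites=sites,
        weights=weights,
        border_weight=borders,
        threshold=payload.get("threshold"),
    )


def _layout_to_svg(layout, size: int = 640) -> str:
    """Render the layout as a standalone SVG (one <path> per drug cell)."""
    minx, miny, maxx, maxy = layout.container.bounds
    span = max(maxx - minx, maxy - miny)
    scale = (size - 20) / span

    def tx(x, y):
        return 10 + (x - minx) * scale, 10 + (maxy - y) * scale

    wmax = max(layout.border_weight.values(), default=1.0) or 1.0
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    palette = ["#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
               "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac"]
    for i, (drug, poly) in enumerate(sorted(layout.cells.items())):
        pts = " L".join(f"{x:.2f},{y:.2f}" for x, y in
                        (tx(px, py) for px, py in poly.exterior.coords))
        w = max((v for (a, b), v in layout.border_weight.items()
                 if drug in (a, b)), default=wmax)
        stroke = 0.5 + 3.5 * w / wmax
        parts.append(
            f'<path d="M{pts} Z" fill="{palette[i % len(palette)]}" '
            f'fill-opacity="0.75" stroke="#222" stroke-width="{stroke:.2f}">'
            f"<title>{drug}</title></path>"
        )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def export_tree_newick(tree, path=None) -> str:
    """Write a cluster tree as Newick, merge heights encoded as branch lengths.

    A node's branch length is its parent's merge height minus its own height
    (leaves have height 0), so root-to-leaf path length equals the root merge
    height for every leaf.
    """
    newick = tree.to_newick()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
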