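"""Readers/writers for every external format the pipeline touches.

TSV throughout (Xena-style matrices, edge lists, clinical and infiltration
tables); networks additionally as SIF and GraphML. Missing expression cells
may be encoded as ``NA`` or left empty.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    InfiltrationTable,
    InteractionCatalog,
    RegulatoryNetwork,
)

_NA_VALUES = ["NA", "NaN", "nan", ""]


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path,
    feature_class: str,
    condition_map: Mapping[str, str] | Callable[[str], str],
) -> ExpressionMatrix:
    """Read a features × samples TSV into an :class:`ExpressionMatrix`.

    The first column holds feature ids, the header row sample ids.
    ``condition_map`` assigns tumor/normal per sample id (mapping or callable).
    Duplicate ids and non-numeric cells raise ``ValueError``.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate feature ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
                )
            df[col] = coerced
    if callable(condition_map):
        condition = {s: condition_map(s) for s in df.columns}
    else:
        condition = {s: condition_map[s] for s in df.columns}
    return ExpressionMatrix(df.astype(float), feature_class, condition)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA")


def preprocess(
    m: ExpressionMatrix,
    already_log2: bool = True,
    missing_fraction_max: float = 0.30,
) -> ExpressionMatrix:
    """Drop heavily missing features, impute the rest, optionally log2-transform.

    Features missing in strictly more than ``missing_fraction_max`` of samples
    are deleted; surviving missing cells are imputed by the feature's
    per-condition mean (falling back to the overall feature mean when a whole
    condition is missing). When ``already_log2`` is false, ``log2(x + 1)`` is
    applied after imputation.
    """
    vals = m.values
    frac_missing = vals.isna().mean(axis=1)
    keep = frac_missing <= missing_fraction_max
    if not keep.any():
        raise ValueError("preprocess removed every feature")
    vals = vals.loc[keep].copy()
    classes = m.feature_class.loc[keep]

    if vals.isna().to_numpy().any():
        for cond in ("tumor", "normal"):
            cols = m.samples_in(cond)
            if len(cols) == 0:
                continue
            block = vals[cols]
            vals[cols] = block.apply(lambda r: r.fillna(r.mean()), axis=1)
        # whole-condition gaps: fall back to the feature's overall mean
        if vals.isna().to_numpy().any():
            vals = vals.apply(lambda r: r.fillna(r.mean()), axis=1)

    if not already_log2:
        if (vals.to_numpy() < 0).any():
            raise ValueError("negative values under log2(x+1) transform")
        vals = np.log2(vals + 1.0)

    return ExpressionMatrix(vals, classes, m.condition)


# ---------------------------------------------------------------------------
# clinical / catalog / infiltration tables


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical TSV needs a sample_id column")
    df = df.set_index("sample_id")
    return ClinicalTable(df[["OS_time", "OS_event"]].astype(float))


def write_clinical(c: ClinicalTable, path) -> None:
    out = c.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_catalog(path) -> InteractionCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "source" not in df.columns:
        df["source"] = "unknown"
    return InteractionCatalog(df[["regulator", "target", "source"]])


def write_catalog(cat: InteractionCatalog, path) -> None:
    cat.edges.to_csv(path, sep="\t", index=False)


def read_infiltration(path) -> InfiltrationTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    return InfiltrationTable(df.astype(float))


def write_infiltration(t: InfiltrationTable, path) -> None:
    out = t.scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# networks

NETWORK_FORMATS = ("sif", "graphml", "tsv")

_SIF_TYPES = {"negative": "represses", "positive": "cerna"}


def _mediators_to_str(meds) -> str:
    return ",".join(sorted(meds)) if meds else ""


def _str_to_mediators(s: str) -> frozenset:
    return frozenset(x for x in str(s).split(",") if x) if s and not _is_nan(s) else frozenset()


def _is_nan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def write_network(net: RegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write a network as SIF, GraphML or a typed edge TSV.

    SIF carries only topology (``source<TAB>type<TAB>target``); GraphML and
    TSV additionally carry node classes, edge PCCs and ceRNA mediators, and
    round-trip through :func:`read_network`.
    """
    fmt = format.lower()
    path = Path(path)
    if fmt == "sif":
        itype = _SIF_TYPES[net.polarity]
        with open(path, "w") as fh:
            for a, b in net.graph.edges:
                fh.write(f"{a}\t{itype}\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph(polarity=net.polarity)
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, cls=d.get("cls", ""))
        for a, b, d in net.graph.edges(data=True):
            g.add_edge(
                a,
                b,
                pcc=float(d.get("pcc", 0.0)),
                mediators=_mediators_to_str(d.get("mediators")),
            )
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = []
        for a, b, d in net.graph.edges(data=True):
            rows.append(
                {
                    "source": a,
                    "source_class": net.graph.nodes[a].get("cls", ""),
                    "target": b,
                    "target_class": net.graph.nodes[b].get("cls", ""),
                    "pcc": d.get("pcc", float("nan")),
                    "mediators": _mediators_to_str(d.get("mediators")),
                    "polarity": net.polarity,
                }
            )
        cols = ["source", "source_class", "target", "target_class", "pcc", "mediators", "polarity"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}; use one of {NETWORK_FORMATS}")


def read_network(path, format: str = "tsv") -> RegulatoryNetwork:
    fmt = format.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        polarity = g.graph.get("polarity", "negative")
        out = nx.Graph()
        for n, d in g.nodes(data=True):
            out.add_node(n, cls=d.get("cls", ""))
        for a, b, d in g.edges(data=True):
            out.add_edge(a, b, pcc=float(d.get("pcc", 0.0)),
                         mediators=_str_to_mediators(d.get("mediators", "")))
        return RegulatoryNetwork(out, polarity)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"mediators": str}, keep_default_na=False,
                         na_values=["NA"])
        g = nx.Graph()
        polarity = "negative"
        for _, row in df.iterrows():
            polarity = row["polarity"]
            g.add_node(row["source"], cls=row["source_class"])
            g.add_node(row["target"], cls=row["target_class"])
            g.add_edge(
                row["source"],
                row["target"],
                pcc=float(row["pcc"]),
                mediators=_str_to_mediators(row["mediators"]),
            )
        return RegulatoryNetwork(g, polarity)
    raise ValueError(f"cannot read network format {format!r}")
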