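"""Shared data containers for the ceRNA network-inference pipeline.

Expression matrices are features × samples on the log2 scale; sample
condition labels (tumor/normal) and per-feature RNA classes ride along with
the values so every downstream stage can subset without bookkeeping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

FEATURE_CLASSES = ("miRNA", "mRNA", "lncRNA")
CONDITIONS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Log2 expression values with feature-class and sample-condition labels.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples); index = feature ids,
        columns = sample ids.
    feature_class
        Per-feature RNA class, one of ``miRNA``, ``mRNA``, ``lncRNA``.
        A single string is broadcast to all features.
    condition
        Per-sample condition, one of ``tumor``, ``normal``. A mapping is
        reindexed to the sample ids.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    condition: pd.Series

    def __init__(self, values, feature_class, condition):
        values = pd.DataFrame(values)
        if isinstance(feature_class, str):
            feature_class = pd.Series(feature_class, index=values.index)
        else:
            feature_class = pd.Series(feature_class)
            feature_class = feature_class.reindex(values.index)
        if isinstance(condition, Mapping):
            condition = pd.Series(condition)
        condition = pd.Series(condition).reindex(values.columns)
        self.values = values
        self.feature_class = feature_class
        self.condition = condition
        self._validate()

    def _validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = set(self.feature_class.dropna()) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature class(es): {sorted(bad)}")
        if self.feature_class.isna().any():
            raise ValueError("feature_class missing for some features")
        bad = set(self.condition.dropna()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise ValueError(f"condition missing for samples: {missing[:5]}")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tumor_mask(self) -> np.ndarray:
        return (self.condition == "tumor").to_numpy()

    def samples_in(self, condition: str) -> pd.Index:
        return self.values.columns[self.condition == condition]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            self.values.loc[ids], self.feature_class.loc[ids], self.condition
        )

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            self.values[ids], self.feature_class, self.condition.loc[ids]
        )

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values.to_numpy()).all())


@dataclass
class ClinicalTable:
    """Right-censored survival records: one row per sample.

    ``table`` has index sample_id and columns ``OS_time`` (days, ≥0) and
    ``OS_event`` (1 = death observed, 0 = censored).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("OS_time", "OS_event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (t["OS_time"] < 0).any():
            raise ValueError("negative survival time")
        if not t["OS_event"].isin([0, 1]).all():
            raise ValueError("OS_event must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def times(self) -> np.ndarray:
        return self.table["OS_time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["OS_event"].to_numpy(dtype=int)

    def subset(self, ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(ids)])


@dataclass
class InteractionCatalog:
    """Candidate regulator→target edges from an external prediction source.

    The search space for the correlation filter: a pair absent from the
    catalog can never become a network edge. Regulators are always miRNAs;
    targets may be mRNAs or lncRNAs.
    """

    edges: pd.DataFrame  # columns: regulator, target, source

    def __post_init__(self):
        e = self.edges
        for col in ("regulator", "target", "source"):
            if col not in e.columns:
                raise ValueError(f"catalog missing column {col!r}")
        if e.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pairs in catalog")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def targets_of(self, regulator: str) -> set[str]:
        return set(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    def restrict(self, regulators: Iterable[str], targets: Iterable[str]) -> "InteractionCatalog":
        regs, tgts = set(regulators), set(targets)
        mask = self.edges["regulator"].isin(regs) & self.edges["target"].isin(tgts)
        return InteractionCatalog(self.edges.loc[mask].reset_index(drop=True))

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, str]], source: str = "catalog") -> "InteractionCatalog":
        df = pd.DataFrame(list(pairs), columns=["regulator", "target"])
        df["source"] = source
        return InteractionCatalog(df)

    def merged_with(self, other: "InteractionCatalog") -> "InteractionCatalog":
        df = pd.concat([self.edges, other.edges], ignore_index=True)
        df = df.drop_duplicates(subset=["regulator", "target"]).reset_index(drop=True)
        return InteractionCatalog(df)


@dataclass
class InfiltrationTable:
    """Per-sample immune-cell infiltration scores (samples × cell types)."""

    scores: pd.DataFrame

    def __post_init__(self):
        if self.scores.shape[1] == 0:
            raise ValueError("infiltration table has no cell types")
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample ids in infiltration table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.columns


@dataclass
class RegulatoryNetwork:
    """Typed-node correlation network.

    ``polarity='negative'`` networks are bipartite miRNA→target graphs whose
    edges all carry PCC < 0; ``polarity='positive'`` networks are the ceRNA
    (lncRNA–mRNA) graphs whose edges carry PCC > 0 plus the non-empty set of
    shared miRNA mediators that licensed the pair.
    """

    graph: nx.Graph
    polarity: str

    def __post_init__(self):
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.graph.graph["polarity"] = self.polarity

    def validate(self) -> None:
        """Assert the structural invariants of the polarity class."""
        g = self.graph
        if any(a == b for a, b in g.edges):
            raise ValueError("self-loop in network")
        for a, b, data in g.edges(data=True):
            ca, cb = g.nodes[a].get("cls"), g.nodes[b].get("cls")
            pcc = data.get("pcc")
            if self.polarity == "negative":
                if (ca == "miRNA") == (cb == "miRNA"):
                    raise ValueError(f"negative edge {a}-{b} not miRNA↔target")
                if pcc is not None and pcc >= 0:
                    raise ValueError(f"negative edge {a}-{b} has pcc {pcc} >= 0")
            else:
                if {ca, cb} != {"lncRNA", "mRNA"}:
                    raise ValueError(f"positive edge {a}-{b} not lncRNA↔mRNA")
                if pcc is not None and pcc <= 0:
                    raise ValueError(f"positive edge {a}-{b} has pcc {pcc} <= 0")
                if not data.get("mediators"):
                    raise ValueError(f"ceRNA edge {a}-{b} has no miRNA mediators")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, cls: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("cls") == cls]


@dataclass
class NetworkModule:
    """A dense subgraph found by MCODE."""

    members: frozenset
    seed: str
    score: float
    rank: int = 0

    def __post_init__(self):
        if self.seed not in self.members:
            raise ValueError("module seed not among members")
        if self.score < 0:
            raise ValueError("module score must be ≥ 0")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RiskModel:
    """Risk-score model: per-gene univariate Cox coefficients + mean cutoff.

    RiskScore(patient) = Σ_i r_i · Exp_i ; patients above the cohort-mean
    score form the high-risk group.
    """

    coefficients: pd.Series  # index = gene ids, values = univariate Cox r_i
    cutoff: float = field(default=float("nan"))

    @property
    def gene_ids(self) -> pd.Index:
        return self.coefficients.index


@dataclass
class SurvivalComparison:
    """Log-rank comparison between two survival groups."""

    chi_square: float
    degrees_of_freedom: int
    p_value: float
    n_high: int
    n_low: int

    def __post_init__(self):
        if self.chi_square < 0:
            raise ValueError("chi-square must be ≥ 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must be in (0, 1]")
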