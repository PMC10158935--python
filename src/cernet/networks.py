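"""Correlation-filtered regulatory network construction.

Two negative (bipartite) networks — miRNA–mRNA and miRNA–lncRNA — keep a
catalog pair only when both partners are differentially expressed and their
Pearson correlation over the full cohort is below −0.7 (strict). Candidate
ceRNA pairs are lncRNA–mRNA pairs sharing at least one miRNA across the two
negative networks; a candidate becomes a positive-network edge when its
lncRNA–mRNA correlation exceeds +0.7 (strict), carrying the shared miRNAs
as edge mediators.

A simplified seed-match scanner stands in for a full target-prediction
algorithm for miRNA–lncRNA candidates: a hit is an exact occurrence of the
reverse complement of the miRNA 7-mer seed (positions 2–8) in the lncRNA.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import ExpressionMatrix, InteractionCatalog, RegulatoryNetwork

NEGATIVE_PCC_MAX = -0.7
POSITIVE_PCC_MIN = 0.7


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation; errors on constant vectors or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return float(np.clip(r, -1.0, 1.0))


def stack_expression(*matrices: ExpressionMatrix) -> pd.DataFrame:
    """Stack matrices feature-wise over their common samples (order of the first)."""
    common = matrices[0].sample_ids
    for m in matrices[1:]:
        common = common.intersection(m.sample_ids)
    if len(common) == 0:
        raise ValueError("matrices share no samples")
    return pd.concat([m.values[common] for m in matrices])


def build_negative_network(
    de_regulators: Iterable[str],
    de_targets: Iterable[str],
    catalog: InteractionCatalog,
    expr: pd.DataFrame,
    pcc_max: float = NEGATIVE_PCC_MAX,
    target_class: str = "mRNA",
) -> RegulatoryNetwork:
    """miRNA→target network: catalog ∩ DE sets ∩ {PCC < pcc_max}.

    ``expr`` holds one row per feature over a common sample set (see
    :func:`stack_expression`); correlation is computed over all of its
    samples (tumor + normal). Nodes are restricted to edge endpoints.
    """
    regs, tgts = set(de_regulators), set(de_targets)
    g = nx.Graph()
    for _, row in catalog.edges.iterrows():
        m, t = row["regulator"], row["target"]
        if m not in regs or t not in tgts:
            continue
        if m not in expr.index or t not in expr.index:
            raise KeyError(f"no expression for catalog pair ({m}, {t})")
        pcc = pearson_correlation(expr.loc[m], expr.loc[t])
        if pcc < pcc_max:
            g.add_node(m, cls="miRNA")
            g.add_node(t, cls=target_class)
            g.add_edge(m, t, pcc=pcc)
    net = RegulatoryNetwork(g, "negative")
    net.validate()
    return net


def candidate_cerna_pairs(
    net_mirna_mrna: RegulatoryNetwork,
    net_mirna_lncrna: RegulatoryNetwork,
) -> list[tuple[str, str, frozenset]]:
    """All (lncRNA, mRNA, shared-miRNA set) pairs with ≥1 common miRNA."""
    for net in (net_mirna_mrna, net_mirna_lncrna):
        if net.polarity != "negative":
            raise ValueError("candidate ceRNA pairs need negative-polarity inputs")
    shared: dict[tuple[str, str], set] = {}
    g1, g2 = net_mirna_mrna.graph, net_mirna_lncrna.graph
    mirnas = set(net_mirna_mrna.nodes_of_class("miRNA")) & set(
        net_mirna_lncrna.nodes_of_class("miRNA")
    )
    for m in mirnas:
        for g in g1.neighbors(m):
            for l in g2.neighbors(m):
                shared.setdefault((l, g), set()).add(m)
    return sorted(
        (l, g, frozenset(ms)) for (l, g), ms in shared.items()
    )


def build_cerna_network(
    pairs: Sequence[tuple[str, str, frozenset]],
    expr: pd.DataFrame,
    pcc_min: float = POSITIVE_PCC_MIN,
) -> RegulatoryNetwork:
    """Positive lncRNA–mRNA network: candidates with PCC > pcc_min."""
    g = nx.Graph()
    for l, m, mediators in pairs:
        pcc = pearson_correlation(expr.loc[l], expr.loc[m])
        if pcc > pcc_min:
            g.add_node(l, cls="lncRNA")
            g.add_node(m, cls="mRNA")
            g.add_edge(l, m, pcc=pcc, mediators=frozenset(mediators))
    net = RegulatoryNetwork(g, "positive")
    net.validate()
    return net


def check_mediator_integrity(
    cerna: RegulatoryNetwork,
    net_mirna_mrna: RegulatoryNetwork,
    net_mirna_lncrna: RegulatoryNetwork,
) -> None:
    """Every ceRNA mediator must link to both endpoints in the negative nets."""
    g1, g2 = net_mirna_mrna.graph, net_mirna_lncrna.graph
    for a, b, data in cerna.graph.edges(data=True):
        l, m = (a, b) if cerna.graph.nodes[a]["cls"] == "lncRNA" else (b, a)
        meds = data.get("mediators") or frozenset()
        if not meds:
            raise ValueError(f"ceRNA edge {l}-{m} has no mediators")
        for mi in meds:
            if not g1.has_edge(mi, m) or not g2.has_edge(mi, l):
                raise ValueError(
                    f"mediator {mi} of ceRNA edge {l}-{m} missing from a negative network"
                )


# ---------------------------------------------------------------------------
# simplified seed-match target scanner

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = set("ACGT")


def _normalize(seq: str, name: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise ValueError(f"empty sequence for record {name!r}")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"record {name!r} has non-nucleotide characters {sorted(bad)}")
    return s


def seed_match_scan(mirna_fasta, lncrna_fasta) -> InteractionCatalog:
    """Emit (miRNA, lncRNA) when the reverse complement of the miRNA seed
    (positions 2–8, a 7-mer) occurs as an exact substring of the lncRNA.

    This is a deliberately simplified target scanner: no alignment scoring
    or hybridisation energetics, just canonical 7-mer seed pairing.
    """
    mirnas = list(SeqIO.parse(str(mirna_fasta), "fasta"))
    lncs = list(SeqIO.parse(str(lncrna_fasta), "fasta"))
    if not mirnas:
        raise ValueError(f"no FASTA records in {mirna_fasta}")
    if not lncs:
        raise ValueError(f"no FASTA records in {lncrna_fasta}")
    rows = []
    for mrec in mirnas:
        mseq = _normalize(mrec.seq, mrec.id)
        if len(mseq) < 8:
            raise ValueError(f"miRNA {mrec.id!r} shorter than 8 nt")
        seed = mseq[1:8]
        site = seed.translate(_COMPLEMENT)[::-1]
        for lrec in lncs:
            lseq = _normalize(lrec.seq, lrec.id)
            if site in lseq:
                rows.append((mrec.id, lrec.id, "seed-match"))
    df = pd.DataFrame(rows, columns=["regulator", "target", "source"])
    return InteractionCatalog(df)
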