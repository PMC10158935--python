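"""End-to-end orchestration of the ceRNA analysis.

Stages mirror the analysis order: cohort preparation → differential
expression (three RNA classes) → negative miRNA–mRNA / miRNA–lncRNA
networks → shared-miRNA ceRNA network → MCODE modules → topology nulls →
survival models (top single genes, per-module and per-ceRNA-component risk
scores) → infiltration correlation. Every stage reads its inputs from and
writes its artifacts to the run directory, so a run is resumable stage by
stage; a manifest records each artifact with a checksum and the seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import networks as cnet
from .datatypes import RegulatoryNetwork
from .diffexpr import call_differential
from .immune import correlate_infiltration, correlation_matrix
from .mcode import find_modules
from .survival import (
    fit_risk_model,
    km_estimator,
    risk_group_survival,
    single_gene_survival,
)
from .synthetic import CohortConfig, PlantedDE, PlantedInfiltration, PlantedTriplet, SurvivalConfig, generate_cohort
from .topology import apl_null_test

log = logging.getLogger("cernet")

DEFAULT_FC_THRESHOLDS = {"miRNA": 1.0, "mRNA": 1.0, "lncRNA": 0.58}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class MCODEParams:
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    min_size: int = 3


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` drives all randomness."""

    outdir: Path = Path("cernet_run")
    seed: int = 0
    synthetic: CohortConfig | None = None
    mirna_path: str | None = None
    mrna_path: str | None = None
    lncrna_path: str | None = None
    condition_path: str | None = None
    clinical_path: str | None = None
    catalog_path: str | None = None
    infiltration_path: str | None = None
    already_log2: bool = True
    fc_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_FC_THRESHOLDS))
    p_threshold: float = 0.01
    combine: str = "or"
    n_perm: int = 1000
    pcc_negative: float = -0.7
    pcc_positive: float = 0.7
    n_random: int = 1000
    n_swaps_factor: int = 10
    mcode: MCODEParams = field(default_factory=MCODEParams)
    survival_split: str = "median"
    corr_method: str = "pearson"
    top_single_genes: int = 20

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.synthetic is None and self.mirna_path is None:
            raise ValueError("config needs either a synthetic cohort or input paths")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            syn["planted_de"] = [PlantedDE(**d) for d in syn.get("planted_de", [])]
            syn["planted_triplets"] = [
                PlantedTriplet(**d) for d in syn.get("planted_triplets", [])
            ]
            syn["infiltration"] = [
                PlantedInfiltration(**d) for d in syn.get("infiltration", [])
            ]
            if "survival" in syn:
                syn["survival"] = SurvivalConfig(**syn["survival"])
            syn = CohortConfig(**syn)
        mc = raw.pop("mcode", None)
        cfg = PipelineConfig(synthetic=syn, **raw)
        if mc is not None:
            cfg.mcode = MCODEParams(**mc)
        return cfg


# ---------------------------------------------------------------------------
# per-stage helpers (each reads what it needs from the run directory)


def _p(cfg: PipelineConfig, name: str) -> Path:
    return cfg.outdir / name


def _load_condition(cfg: PipelineConfig) -> dict:
    df = pd.read_csv(_p(cfg, "conditions.tsv"), sep="\t")
    return dict(zip(df["sample_id"], df["condition"]))


def _load_matrix(cfg: PipelineConfig, cls: str):
    return cio.read_expression(_p(cfg, f"{cls.lower()}.tsv"), cls, _load_condition(cfg))


def stage_prepare(cfg: PipelineConfig) -> dict:
    """Simulate (or load) the cohort, preprocess, and persist everything."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.synthetic.seed + cfg.seed)
        cohort = generate_cohort(syn)
        mats = {"miRNA": cohort.mirna, "mRNA": cohort.mrna, "lncRNA": cohort.lncrna}
        clinical, catalog, infil = cohort.clinical, cohort.catalog, cohort.infiltration
    else:
        cond = dict(
            pd.read_csv(cfg.condition_path, sep="\t")[["sample_id", "condition"]].values
        )
        mats = {
            "miRNA": cio.read_expression(cfg.mirna_path, "miRNA", cond),
            "mRNA": cio.read_expression(cfg.mrna_path, "mRNA", cond),
            "lncRNA": cio.read_expression(cfg.lncrna_path, "lncRNA", cond),
        }
        clinical = cio.read_clinical(cfg.clinical_path) if cfg.clinical_path else None
        catalog = cio.read_catalog(cfg.catalog_path) if cfg.catalog_path else None
        infil = (
            cio.read_infiltration(cfg.infiltration_path)
            if cfg.infiltration_path
            else None
        )
    counts = {}
    for cls, m in mats.items():
        m = cio.preprocess(m, already_log2=cfg.already_log2)
        cio.write_expression(m, _p(cfg, f"{cls.lower()}.tsv"))
        counts[cls] = m.n_features
    cond_df = pd.DataFrame(
        {"sample_id": mats["miRNA"].sample_ids, "condition": mats["miRNA"].condition.values}
    )
    cond_df.to_csv(_p(cfg, "conditions.tsv"), sep="\t", index=False)
    if clinical is not None:
        cio.write_clinical(clinical, _p(cfg, "clinical.tsv"))
    if catalog is not None:
        cio.write_catalog(catalog, _p(cfg, "catalog.tsv"))
    if infil is not None:
        cio.write_infiltration(infil, _p(cfg, "infiltration.tsv"))
    log.info("prepare: %s features, %d samples", counts, mats["miRNA"].n_samples)
    return {"features": counts, "n_samples": int(mats["miRNA"].n_samples)}


def stage_de(cfg: PipelineConfig) -> dict:
    counts = {}
    for cls in ("miRNA", "mRNA", "lncRNA"):
        m = _load_matrix(cfg, cls)
        res = call_differential(
            m,
            fc_threshold=cfg.fc_thresholds[cls],
            p_threshold=cfg.p_threshold,
            combine=cfg.combine,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        res.to_csv(_p(cfg, f"de_{cls.lower()}.tsv"), sep="\t", index=False)
        counts[cls] = int(res["called"].sum())
    log.info("differential expression: %s", counts)
    return {"de_counts": counts}


def _de_set(cfg: PipelineConfig, cls: str) -> set:
    df = pd.read_csv(_p(cfg, f"de_{cls.lower()}.tsv"), sep="\t")
    return set(df.loc[df["called"], "feature_id"])


def _write_net(cfg: PipelineConfig, net: RegulatoryNetwork, stem: str) -> None:
    for fmt in ("tsv", "sif", "graphml"):
        cio.write_network(net, _p(cfg, f"{stem}.{fmt}"), fmt)


def stage_network(cfg: PipelineConfig) -> dict:
    catalog = cio.read_catalog(_p(cfg, "catalog.tsv"))
    mir = _load_matrix(cfg, "miRNA")
    mrna = _load_matrix(cfg, "mRNA")
    lnc = _load_matrix(cfg, "lncRNA")
    expr = cnet.stack_expression(mir, mrna, lnc)
    de_mir = _de_set(cfg, "miRNA")
    net_mm = cnet.build_negative_network(
        de_mir, _de_set(cfg, "mRNA"), catalog, expr, cfg.pcc_negative, "mRNA"
    )
    net_ml = cnet.build_negative_network(
        de_mir, _de_set(cfg, "lncRNA"), catalog, expr, cfg.pcc_negative, "lncRNA"
    )
    pairs = cnet.candidate_cerna_pairs(net_mm, net_ml)
    cerna = cnet.build_cerna_network(pairs, expr, cfg.pcc_positive)
    cnet.check_mediator_integrity(cerna, net_mm, net_ml)
    _write_net(cfg, net_mm, "net_mirna_mrna")
    _write_net(cfg, net_ml, "net_mirna_lncrna")
    _write_net(cfg, cerna, "net_cerna")
    counts = {
        "mirna_mrna": [net_mm.n_nodes, net_mm.n_edges],
        "mirna_lncrna": [net_ml.n_nodes, net_ml.n_edges],
        "cerna": [cerna.n_nodes, cerna.n_edges],
        "candidate_pairs": len(pairs),
    }
    for name, (nn, ne) in ((k, v) for k, v in counts.items() if k != "candidate_pairs"):
        if ne == 0:
            log.warning("network %s is empty", name)
        else:
            log.info("network %s: %d nodes, %d edges", name, nn, ne)
    return counts


def stage_modules(cfg: PipelineConfig) -> dict:
    net = cio.read_network(_p(cfg, "net_mirna_mrna.tsv"))
    mods = find_modules(
        net,
        vwp=cfg.mcode.vwp,
        haircut=cfg.mcode.haircut,
        fluff=cfg.mcode.fluff,
        min_size=cfg.mcode.min_size,
    )
    rows = [
        {
            "module_id": f"M{m.rank}",
            "rank": m.rank,
            "seed": m.seed,
            "score": m.score,
            "size": m.size,
            "members": ",".join(sorted(m.members)),
        }
        for m in mods
    ]
    pd.DataFrame(
        rows, columns=["module_id", "rank", "seed", "score", "size", "members"]
    ).to_csv(_p(cfg, "modules.tsv"), sep="\t", index=False)
    for m in mods:
        sub = RegulatoryNetwork(net.graph.subgraph(m.members).copy(), net.polarity)
        cio.write_network(sub, _p(cfg, f"module_M{m.rank}.sif"), "sif")
    log.info("MCODE: %d modules", len(mods))
    return {"n_modules": len(mods), "module_sizes": [m.size for m in mods]}


def stage_topology(cfg: PipelineConfig) -> dict:
    net = cio.read_network(_p(cfg, "net_mirna_mrna.tsv"))
    if net.n_edges < 2:
        log.warning("topology skipped: miRNA-mRNA network has <2 edges")
        return {"skipped": True}
    summary = apl_null_test(
        net, n_random=cfg.n_random, n_swaps_factor=cfg.n_swaps_factor, seed=cfg.seed
    )
    with open(_p(cfg, "topology.json"), "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    pd.DataFrame({"apl_null": summary.apl_null}).to_csv(
        _p(cfg, "apl_null.tsv"), sep="\t", index=False
    )
    log.info(
        "topology: APL %.3f vs null %.3f (p=%.4g, %s)",
        summary.apl_real,
        float(np.mean(summary.apl_null)),
        summary.empirical_p,
        summary.direction,
    )
    return summary.to_dict()


def _gene_sets_for_survival(cfg: PipelineConfig) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    mods_path = _p(cfg, "modules.tsv")
    if mods_path.exists():
        mods = pd.read_csv(mods_path, sep="\t")
        for _, row in mods.iterrows():
            sets[f"module_{row['module_id']}"] = row["members"].split(",")
    cerna_path = _p(cfg, "net_cerna.tsv")
    if cerna_path.exists():
        cerna = cio.read_network(cerna_path)
        import networkx as nx

        for i, comp in enumerate(
            sorted(nx.connected_components(cerna.graph), key=lambda c: (-len(c), sorted(c)[0])),
            start=1,
        ):
            sets[f"cerna_component_{i}"] = sorted(comp)
    return sets


def stage_survival(cfg: PipelineConfig) -> dict:
    clin_path = _p(cfg, "clinical.tsv")
    if not clin_path.exists():
        log.warning("survival skipped: no clinical table")
        return {"skipped": True}
    clinical = cio.read_clinical(clin_path)
    mir = _load_matrix(cfg, "miRNA")
    mrna = _load_matrix(cfg, "mRNA")
    lnc = _load_matrix(cfg, "lncRNA")
    expr = cnet.stack_expression(mir, mrna, lnc)

    results: dict = {"single_gene": {}, "gene_set": {}}
    de_mir = pd.read_csv(_p(cfg, "de_mirna.tsv"), sep="\t")
    top = (
        de_mir.loc[de_mir["called"]]
        .reindex(de_mir.loc[de_mir["called"], "d_stat"].abs().sort_values(ascending=False).index)
        .head(cfg.top_single_genes)
    )
    for fid in top["feature_id"]:
        try:
            comp = single_gene_survival(expr.loc[fid], clinical, split=cfg.survival_split)
            results["single_gene"][fid] = {
                "chi_square": comp.chi_square,
                "p_value": comp.p_value,
            }
        except ValueError as exc:
            log.warning("single-gene survival skipped for %s: %s", fid, exc)

    for name, genes in _gene_sets_for_survival(cfg).items():
        genes = [g for g in genes if g in expr.index]
        if len(genes) == 0:
            continue
        try:
            model = fit_risk_model(expr.loc[genes], clinical)
            comp, high, low = risk_group_survival(model, expr, clinical)
        except (ValueError, KeyError) as exc:
            log.warning("risk model skipped for %s: %s", name, exc)
            continue
        results["gene_set"][name] = {
            "genes": genes,
            "coefficients": {g: float(r) for g, r in model.coefficients.items()},
            "cutoff": model.cutoff,
            "chi_square": comp.chi_square,
            "p_value": comp.p_value,
            "n_high": comp.n_high,
            "n_low": comp.n_low,
        }
        ch, clo = clinical.subset(high), clinical.subset(low)
        for label, tab in (("high", ch), ("low", clo)):
            km = km_estimator(tab.times, tab.events)
            km.as_frame().to_csv(
                _p(cfg, f"km_{name}_{label}.tsv"), sep="\t", index=False
            )
    with open(_p(cfg, "survival.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    log.info(
        "survival: %d single-gene, %d gene-set models",
        len(results["single_gene"]),
        len(results["gene_set"]),
    )
    return {
        "n_single_gene": len(results["single_gene"]),
        "n_gene_set": len(results["gene_set"]),
    }


def stage_immune(cfg: PipelineConfig) -> dict:
    infil_path = _p(cfg, "infiltration.tsv")
    if not infil_path.exists():
        log.warning("immune stage skipped: no infiltration table")
        return {"skipped": True}
    infil = cio.read_infiltration(infil_path)
    lnc = _load_matrix(cfg, "lncRNA")
    long = correlate_infiltration(lnc, infil, method=cfg.corr_method)
    long.to_csv(_p(cfg, "immune_corr.tsv"), sep="\t", index=False)
    correlation_matrix(long).to_csv(_p(cfg, "immune_corr_matrix.tsv"), sep="\t")
    log.info("immune: %d correlations", len(long))
    return {"n_correlations": int(len(long))}


STAGES = [
    ("prepare", stage_prepare),
    ("de", stage_de),
    ("network", stage_network),
    ("modules", stage_modules),
    ("topology", stage_topology),
    ("survival", stage_survival),
    ("immune", stage_immune),
]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}
    for name, fn in STAGES:
        try:
            manifest["stages"][name] = fn(cfg)
        except Exception as exc:  # partial artifacts stay on disk
            _write_manifest(cfg, manifest)
            raise PipelineStageError(name, exc) from exc
        _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: PipelineConfig, manifest: dict) -> None:
    manifest["artifacts"] = {
        f.name: _checksum(f)
        for f in sorted(cfg.outdir.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    with open(_p(cfg, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
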