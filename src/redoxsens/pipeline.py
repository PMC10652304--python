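"""End-to-end orchestration: simulate -> quantify -> network -> stability -> score.

The pipeline can run entirely from a synthetic dataset (``simulate`` +
``run_all``) or from user-supplied FASTA / edge-list / evidence files.
Every run writes a manifest with the seed, the parameter hash and the
package version so identical configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml

from . import __version__
from .io import read_evidence, read_fasta, read_lfq, write_evidence, write_fasta, write_lfq
from .network import (
    calibrated_subnetwork,
    community_centrality_profile,
    eigenvector_centrality,
    load_network,
    louvain_partition,
    membership_upset,
    write_network,
)
from .ptm import correlate, grand_sum, lfq_log2_table, overlay_lfq, ptm_change_table, sign_census
from .scoring import community_summary, compute_scores, summary_table, top_percentile
from .stability import ModelConstants, proteome_map
from .synthetic import (
    SyntheticConfig,
    condition_pairs,
    generate_lfq,
    generate_network,
    generate_proteome,
    generate_ptm_evidence,
)

logger = logging.getLogger("redoxsens")


class StageError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run parameters for the full analysis.

    Input paths may be omitted when ``simulate`` is true, in which case a
    synthetic dataset is generated into the output directory first.
    """

    fasta: str | None = None
    edge_list: str | None = None
    evidence: str | None = None
    lfq: str | None = None
    out_dir: str = "redoxsens_out"
    simulate: bool = True
    synthetic: dict[str, Any] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)
    min_score: float = 400.0
    tol: float = 1e-10
    max_iter: int = 1000
    resolution: float = 1.0
    zero_tolerance: float = 1e-9
    pseudocount: float = 0.0
    n_boot: int = 1000
    p_set: Literal["ptm-mapped", "network"] = "ptm-mapped"
    percentile: float = 50.0
    top_k: int = 20
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(config: PipelineConfig) -> dict[str, str]:
    """Generate the synthetic dataset bundle into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    proteome, proteome_truth = generate_proteome(syn)
    graph, net_truth = generate_network(syn)
    detected = [r for r in proteome if r.protein_id in set(syn.detected_ids())]
    evidence, ptm_truth = generate_ptm_evidence(syn, detected)
    lfq, lfq_truth = generate_lfq(syn, detected)

    paths = {
        "fasta": str(out / "proteome.fasta"),
        "edge_list": str(out / "network.tsv"),
        "evidence": str(out / "evidence.csv"),
        "lfq": str(out / "lfq.csv"),
        "truth": str(out / "truth.json"),
    }
    write_fasta(proteome, paths["fasta"])
    write_network(graph, paths["edge_list"])
    write_evidence(evidence, paths["evidence"])
    write_lfq(lfq, paths["lfq"])
    truth = ptm_truth
    truth.hubs = net_truth.hubs
    truth.charge_compositions = proteome_truth.charge_compositions
    truth.lfq_fold_changes = lfq_truth.lfq_fold_changes
    truth.to_json(paths["truth"])
    logger.info("simulated %d proteins, %d detected, %d edges",
                syn.n_proteins_total, syn.n_detected, graph.number_of_edges())
    return paths


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle.

    Returns a dict with the in-memory results (score table, summaries,
    correlations) and the paths of everything written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate and not (config.fasta and config.edge_list and config.evidence):
        paths = simulate(config)
        config = dataclasses.replace(config, **{k: v for k, v in paths.items()
                                                if k != "truth"})
    for name in ("fasta", "edge_list", "evidence"):
        value = getattr(config, name)
        if not value or not Path(value).exists():
            raise StageError("inputs" if name != "edge_list" else "network",
                             f"missing required input: {name}")

    syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    pairs = condition_pairs(syn.conditions)

    # --- PTM quantification -------------------------------------------------
    try:
        evidence = read_evidence(config.evidence)
        ptm_tables = {
            stem: ptm_change_table(evidence, pair, zero_tolerance=config.zero_tolerance,
                                   pseudocount=config.pseudocount)
            for stem, pair in pairs.items()
        }
        mod_tables = {
            stem: ptm_change_table(evidence, pair, by="modification",
                                   zero_tolerance=config.zero_tolerance,
                                   pseudocount=config.pseudocount)
            for stem, pair in pairs.items()
        }
        summaries = {
            stem: {
                "grand_sum_protein": grand_sum(tbl),
                "grand_sum_modification": grand_sum(mod_tables[stem]),
                "census": dict(zip(("decreasing", "increasing", "unchanged"),
                                   sign_census(tbl, config.zero_tolerance))),
            }
            for stem, tbl in ptm_tables.items()
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ptm", str(exc)) from exc

    # --- network ------------------------------------------------------------
    try:
        graph = load_network(config.edge_list, min_score=config.min_score)
        centrality = eigenvector_centrality(graph, tol=config.tol,
                                            max_iter=config.max_iter)
        detected_ids = sorted(evidence["protein_id"].unique())
        subnet, sub_centrality = calibrated_subnetwork(graph, centrality, detected_ids)
        partition = louvain_partition(subnet, seed=config.seed,
                                      resolution=config.resolution)
        profile = community_centrality_profile(partition, sub_centrality)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    # --- stability ----------------------------------------------------------
    try:
        constants = ModelConstants(**config.constants) if config.constants else ModelConstants()
        stability = proteome_map(config.fasta, constants)
    except Exception as exc:
        raise StageError("stability", str(exc)) from exc

    # --- correlations and LFQ overlay ----------------------------------------
    correlations: dict[str, Any] = {}
    overlays: dict[str, pd.DataFrame] = {}
    try:
        stems = sorted(pairs)
        if {"young", "old"} <= set(stems):
            correlations["young_vs_old_pct_change"] = dataclasses.asdict(
                correlate(ptm_tables["young"]["pct_change_per_site"],
                          ptm_tables["old"]["pct_change_per_site"],
                          n_boot=config.n_boot, seed=config.seed)
            )
        for stem in stems:
            correlations[f"centrality_vs_pct_change_{stem}"] = dataclasses.asdict(
                correlate(sub_centrality.as_series(),
                          ptm_tables[stem]["pct_change_per_site"],
                          n_boot=config.n_boot, seed=config.seed)
            )
        if config.lfq and Path(config.lfq).exists():
            lfq = read_lfq(config.lfq)
            for stem, pair in pairs.items():
                overlays[stem] = overlay_lfq(ptm_tables[stem], lfq_log2_table(lfq, pair))
    except Exception as exc:
        raise StageError("correlation", str(exc)) from exc

    # --- scoring ------------------------------------------------------------
    try:
        signs = {stem: tbl["net_sign"].to_dict() for stem, tbl in ptm_tables.items()}
        if config.p_set == "ptm-mapped":
            scored_set = [p for p in detected_ids
                          if p in stability.index and p in sub_centrality.values]
        else:
            scored_set = [p for p in sub_centrality.values if p in stability.index]
        scores = compute_scores(
            stability, sub_centrality,
            partition=partition.labels,
            old_signs=signs.get("old", {}), young_signs=signs.get("young", {}),
            scored_set=scored_set,
        )
        top = top_percentile(scores, config.percentile)
        communities = community_summary(scores)
        table = summary_table(scores, config.top_k)
    except Exception as exc:
        raise StageError("scoring", str(exc)) from exc

    # --- outputs ------------------------------------------------------------
    written: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        written[name] = str(path)

    for stem, tbl in ptm_tables.items():
        _write(f"ptm_change_by_protein_{stem}.tsv", tbl)
        _write(f"ptm_change_by_modification_{stem}.tsv", mod_tables[stem])
    for stem, ov in overlays.items():
        _write(f"lfq_overlay_{stem}.tsv", ov)
    _write("centrality_full.tsv", centrality.as_series().rename_axis("protein_id").to_frame())
    _write("centrality_subnetwork.tsv",
           sub_centrality.as_series().rename_axis("protein_id").to_frame())
    _write("communities.tsv",
           pd.Series(partition.labels, name="community").rename_axis("protein_id").to_frame())
    _write("community_centrality_profile.tsv", profile)
    _write("stability.tsv", stability)
    _write("scores.tsv", scores)
    _write("scores_top_percentile.tsv", top)
    _write("community_css_summary.tsv", communities)
    _write("summary_table.tsv", table)

    report = {
        "ptm_summaries": summaries,
        "correlations": correlations,
        "modularity": partition.modularity,
        "n_communities": len(set(partition.labels.values())),
        "network": {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges(),
                    "subnetwork_nodes": subnet.number_of_nodes(),
                    "subnetwork_edges": subnet.number_of_edges()},
        "scored_set_size": int(scores.shape[0]),
        "top_css_protein": scores.index[0],
        "top_css": float(scores["css"].iloc[0]),
    }
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)
    written["report.json"] = str(out / "report.json")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "outputs": sorted(written),
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)

    return {
        "scores": scores,
        "top": top,
        "communities": communities,
        "summary_table": table,
        "report": report,
        "manifest": manifest,
        "written": written,
    }
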