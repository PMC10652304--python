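"""Synthetic proteomes, interaction networks and MS evidence with known truth.

Every downstream stage of the pipeline — PTM change quantification,
centrality calibration, community detection, stability modelling, scoring
— is testable against planted ground truth without any external download:

* proteomes with controlled length and charge-class composition (the only
  sequence properties the stability model consumes),
* scale-free-like interaction networks, optionally with planted hubs whose
  degree dominates the median,
* site-level PTM evidence in which each protein carries a planted signed
  percent effect of treatment, under Poisson or lognormal count noise,
* LFQ-style abundance tables with planted fold changes.

The default study design mirrors a two-age, two-arm senolytic experiment:
conditions young-vehicle / young-treated / old-vehicle / old-treated with
a handful of technical replicates, predominantly negative PTM effects in
the old arm and mixed, mostly positive effects in the young arm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ProteinRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "MODIFICATION_VOCABULARY",
    "condition_pairs",
    "generate_proteome",
    "generate_network",
    "generate_ptm_evidence",
    "generate_lfq",
]

# oxidative adduct vocabulary used to label synthetic sites
MODIFICATION_VOCABULARY = (
    "4-ONE",
    "HNE",
    "carboxymethyl",
    "carboxyethyl",
    "G-H1",
    "GlyGly",
    "mono-oxidation",
    "di-oxidation",
)

NON_CHARGED_RESIDUES = tuple("ACFGILMNPQSTVWY")  # 15 standard AAs outside R/K/D/E/H
DEFAULT_CONDITIONS = ("young-vehicle", "young-treated", "old-vehicle", "old-treated")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    ``charge_fraction_ranges`` gives, per charge class, the [low, high]
    interval from which each protein's residue-class fraction is drawn;
    counts are the rounded fraction of the sampled length.
    ``effect_table`` plants per-protein treatment effects in percent; a
    value may be a scalar (every condition pair) or a mapping from pair
    stem (e.g. ``"old"``) to percent.  ``None`` lets the generator draw
    effects itself: mostly negative in old, mostly positive in young.
    """

    n_proteins_total: int = 2000
    n_detected: int = 500
    length_range: tuple[int, int] = (60, 1200)
    charge_fraction_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "positive": (0.08, 0.16),
            "negative": (0.08, 0.16),
            "variable": (0.01, 0.04),
        }
    )
    network_model: Literal["preferential_attachment", "planted_hub"] = "preferential_attachment"
    n_planted_hubs: int = 0
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    effect_table: Mapping[str, float | Mapping[str, float]] | None = None
    noise_model: Literal["poisson", "lognormal"] = "poisson"
    noise_scale: float = 1.0
    baseline_quantity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_detected > self.n_proteins_total:
            raise ValueError("n_detected cannot exceed n_proteins_total")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.baseline_quantity < 0:
            raise ValueError("baseline quantity must be non-negative")
        hi_sum = sum(hi for _, hi in self.charge_fraction_ranges.values())
        if hi_sum > 1.0:
            raise ValueError(f"charge fractions can sum to {hi_sum} > 1; infeasible")
        if self.n_planted_hubs >= self.n_proteins_total:
            raise ValueError("n_planted_hubs must be smaller than n_proteins_total")

    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins_total - 1))
        return [f"P{i:0{width}d}" for i in range(self.n_proteins_total)]

    def detected_ids(self) -> list[str]:
        return self.protein_ids()[: self.n_detected]


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic dataset."""

    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    lfq_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)
    charge_compositions: dict[str, dict[str, int]] = field(default_factory=dict)
    detected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


def condition_pairs(conditions: Sequence[str]) -> dict[str, tuple[str, str]]:
    """Pair (vehicle, treated) condition labels sharing a stem.

    ``young-vehicle``/``young-treated`` pair under stem ``young``.
    """
    stems: dict[str, dict[str, str]] = {}
    for label in conditions:
        stem, _, arm = label.rpartition("-")
        if arm in ("vehicle", "treated") and stem:
            stems.setdefault(stem, {})[arm] = label
    return {
        stem: (arms["vehicle"], arms["treated"])
        for stem, arms in stems.items()
        if set(arms) == {"vehicle", "treated"}
    }


def _sample_sequence(rng: np.random.Generator, length: int,
                     fractions: Mapping[str, float]) -> str:
    n_pos = round(length * fractions["positive"])
    n_neg = round(length * fractions["negative"])
    n_var = round(length * fractions["variable"])
    if n_pos + n_neg + n_var > length:
        raise ValueError("sampled charge counts exceed sequence length")
    residues = list(rng.choice(["R", "K"], n_pos))
    residues += list(rng.choice(["D", "E"], n_neg))
    residues += ["H"] * n_var
    residues += list(rng.choice(NON_CHARGED_RESIDUES, length - len(residues)))
    rng.shuffle(residues)
    return "".join(residues)


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate the full synthetic proteome and its charge-composition truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    truth = SyntheticTruth(detected=config.detected_ids())
    for pid in config.protein_ids():
        length = int(rng.integers(lo, hi + 1))
        fractions = {
            cls: float(rng.uniform(flo, fhi))
            for cls, (flo, fhi) in config.charge_fraction_ranges.items()
        }
        seq = _sample_sequence(rng, length, fractions)
        records.append(ProteinRecord(pid, seq))
        truth.charge_compositions[pid] = {
            "positive": seq.count("R") + seq.count("K"),
            "negative": seq.count("D") + seq.count("E"),
            "variable": seq.count("H"),
            "length": length,
        }
    return records, truth


def generate_network(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Generate a scale-free-like interaction network, optionally with hubs.

    The ``planted_hub`` model grows a preferential-attachment base graph
    and then wires each hub (drawn from the detected set) to random
    partners until its degree is at least 10x the median degree.  Edge
    confidence scores are uniform on the upper STRING range [400, 1000).
    """
    if config.n_proteins_total < 3:
        raise ValueError("need at least 3 proteins for a network")
    rng = np.random.default_rng(config.seed + 1)
    ids = config.protein_ids()
    n = config.n_proteins_total
    m = min(3, n - 1)
    base = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(base, dict(enumerate(ids)))
    truth = SyntheticTruth(detected=config.detected_ids())

    if config.network_model == "planted_hub" and config.n_planted_hubs > 0:
        hub_pool = config.detected_ids()
        hubs = [hub_pool[i] for i in rng.choice(len(hub_pool), config.n_planted_hubs,
                                                replace=False)]
        for hub in hubs:
            while True:
                degrees = np.array([d for _, d in graph.degree()])
                target = int(np.ceil(10 * np.median(degrees)))
                if graph.degree(hub) >= target or graph.degree(hub) >= n - 1:
                    break
                candidates = [v for v in ids if v != hub and not graph.has_edge(hub, v)]
                need = min(target - graph.degree(hub), len(candidates))
                for v in rng.choice(len(candidates), need, replace=False):
                    graph.add_edge(hub, candidates[v])
        truth.hubs = sorted(hubs)

    for a, b in graph.edges():
        graph[a][b]["score"] = int(rng.integers(400, 1000))
    return graph, truth


def _noisy(rng: np.random.Generator, mean: float, model: str, scale: float) -> float:
    if scale == 0:
        return float(mean)
    if model == "poisson":
        return float(rng.poisson(mean))
    if model == "lognormal":
        # sigma = scale; divide by exp(sigma^2/2) so the expectation is `mean`
        return float(mean * rng.lognormal(0.0, scale) / np.exp(scale**2 / 2))
    raise ValueError(f"unknown noise model {model!r}")


def _planted_effect(
    config: SyntheticConfig, rng: np.random.Generator, pid: str, stem: str
) -> float:
    if config.effect_table is not None:
        entry = config.effect_table.get(pid, 0.0)
        if isinstance(entry, Mapping):
            return float(entry.get(stem, 0.0))
        return float(entry)
    # default study design: oxidative PTM loss dominates in old, gain in young
    if stem == "old":
        return float(np.clip(rng.normal(-25.0, 15.0), -95.0, 200.0))
    return float(np.clip(rng.normal(10.0, 15.0), -95.0, 200.0))


def generate_ptm_evidence(
    config: SyntheticConfig, proteome: Sequence[ProteinRecord]
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate site-level PTM evidence with planted per-protein effects.

    For every protein, 1-3 modification sites are placed uniformly without
    replacement along the sequence.  The vehicle-condition expectation at
    every site is ``baseline_quantity``; the treated expectation is scaled
    by (1 + effect/100) for the planted effect of that condition pair.
    """
    if config.effect_table is not None:
        known = {r.protein_id for r in proteome}
        unknown = set(config.effect_table) - known
        if unknown:
            raise ValueError(f"effect_table refers to unknown proteins: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(config.seed + 2)
    pairs = condition_pairs(config.conditions)
    rows = []
    truth = SyntheticTruth(detected=[r.protein_id for r in proteome])
    for rec in proteome:
        n_sites = int(rng.integers(1, min(3, len(rec.sequence)) + 1))
        sites = sorted(rng.choice(len(rec.sequence), n_sites, replace=False) + 1)
        mods = rng.choice(MODIFICATION_VOCABULARY, n_sites)
        truth.effects[rec.protein_id] = {}
        for stem, (vehicle, treated) in pairs.items():
            effect = _planted_effect(config, rng, rec.protein_id, stem)
            truth.effects[rec.protein_id][stem] = effect
            for site, mod in zip(sites, mods):
                for condition, mean in (
                    (vehicle, config.baseline_quantity),
                    (treated, config.baseline_quantity * (1 + effect / 100.0)),
                ):
                    for rep in range(1, config.n_replicates + 1):
                        rows.append(
                            {
                                "protein_id": rec.protein_id,
                                "site": int(site),
                                "modification": str(mod),
                                "condition": condition,
                                "replicate": rep,
                                "quantity": _noisy(rng, mean, config.noise_model,
                                                   config.noise_scale),
                            }
                        )
    return pd.DataFrame(rows), truth


def generate_lfq(
    config: SyntheticConfig, proteome: Sequence[ProteinRecord]
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate LFQ-style intensities with planted per-protein fold changes.

    Vehicle expectation is a protein-specific baseline intensity; the
    treated expectation is baseline x fold change.  Noise is multiplicative
    lognormal with sigma = ``noise_scale`` (Poisson makes little sense for
    intensities and is mapped to lognormal here).
    """
    rng = np.random.default_rng(config.seed + 3)
    pairs = condition_pairs(config.conditions)
    rows = []
    truth = SyntheticTruth(detected=[r.protein_id for r in proteome])
    for rec in proteome:
        baseline = float(rng.lognormal(np.log(1e6), 0.5))
        truth.lfq_fold_changes[rec.protein_id] = {}
        for stem, (vehicle, treated) in pairs.items():
            fold = float(rng.lognormal(0.0, 0.4))
            truth.lfq_fold_changes[rec.protein_id][stem] = fold
            for condition, mean in ((vehicle, baseline), (treated, baseline * fold)):
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "protein_id": rec.protein_id,
                            "condition": condition,
                            "replicate": rep,
                            "intensity": _noisy(rng, mean, "lognormal",
                                                config.noise_scale),
                        }
                    )
    return pd.DataFrame(rows), truth
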