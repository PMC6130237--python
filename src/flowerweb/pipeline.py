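"""End-to-end analysis of a set of habitat webs.

Reproduces the full workflow on any collection of habitat matrices or
long-format census records: optional merging of under-sampled habitats,
per-habitat and pooled network metrics, NODF nestedness tests against the
Ce null model, per-habitat richness and Shannon diversity, Jaccard/UPGMA
similarity with bootstrap support, and a pooled species-role table.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import PresenceTable, bootstrap_support, jaccard_distance_matrix, shannon_diversity
from .matrix import InteractionMatrix, from_records, merge_networks, read_matrix, read_records
from .nestedness import NestednessResult, nestedness_test
from .netmetrics import network_metrics
from .species import species_table

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "summarize_significance"]

SMALL_WEB_SPECIES = 15  # warn below this: tiny webs give unstable metrics


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Inputs and knobs of one analysis run."""

    matrix_paths: dict[str, str] = field(default_factory=dict)  # habitat -> wide file
    records_path: str | None = None  # long-format file (alternative input)
    merge: dict[str, tuple[str, ...]] = field(default_factory=dict)  # new -> parts
    n_null: int = 1000
    bootstrap: int = 9999
    seed: int = 0
    alpha: float = 0.01
    out_dir: str = "results"
    rounding: int = 3

    def __post_init__(self) -> None:
        if self.n_null < 100:
            raise ConfigError("n_null must be >= 100 for significance claims")


@dataclass
class AnalysisResult:
    webs: dict[str, InteractionMatrix]
    pooled: InteractionMatrix
    network_table: pd.DataFrame
    nestedness_table: pd.DataFrame
    nestedness_results: list[NestednessResult]
    richness_table: pd.DataFrame
    species: pd.DataFrame
    newick: str
    jaccard: pd.DataFrame


def _load_webs(cfg: AnalysisConfig) -> dict[str, InteractionMatrix]:
    if cfg.records_path:
        return from_records(read_records(cfg.records_path))
    if not cfg.matrix_paths:
        raise ConfigError("no inputs: provide matrix paths or a records file")
    return {
        hab: read_matrix(path, habitat=hab) for hab, path in sorted(cfg.matrix_paths.items())
    }


def _apply_merges(
    webs: dict[str, InteractionMatrix], merge: Mapping[str, Sequence[str]]
) -> dict[str, InteractionMatrix]:
    out = dict(webs)
    for new, parts in merge.items():
        missing = [p for p in parts if p not in out]
        if missing:
            raise ConfigError(f"merge {new!r}: habitats not in inputs: {missing}")
        out[new] = merge_networks([out.pop(p) for p in parts], new_habitat=new)
    return out


def summarize_significance(
    results: Sequence[NestednessResult], alpha: float = 0.01
) -> pd.DataFrame:
    """Nestedness verdict per habitat: nested iff p < alpha."""
    return pd.DataFrame(
        {
            "habitat": [r.habitat for r in results],
            "NODF_total": [r.NODF_total for r in results],
            "NODF_null_mean": [r.null_mean for r in results],
            "p_value": [r.p_value for r in results],
            "nested": [r.p_value < alpha for r in results],
        }
    )


def run_analysis(cfg: AnalysisConfig, write: bool = True) -> AnalysisResult:
    """Run the whole pipeline; optionally write the report bundle to
    ``cfg.out_dir`` (delimited tables, a Newick dendrogram and a run log)."""
    webs = _apply_merges(_load_webs(cfg), cfg.merge)
    warnings = [
        f"habitat {h!r} has only {w.size} species; metrics may be unstable"
        for h, w in webs.items()
        if w.size < SMALL_WEB_SPECIES
    ]
    for msg in warnings:
        print(f"warning: {msg}", file=sys.stderr)

    pooled = merge_networks(list(webs.values()), new_habitat="pooled")
    ordered = [pooled] + [webs[h] for h in sorted(webs)]

    net_rows = [network_metrics(M).to_row() for M in ordered]
    network_table = pd.DataFrame(net_rows)

    rng = np.random.default_rng(cfg.seed)
    nest_results = [
        nestedness_test(M, n_null=cfg.n_null, seed=int(rng.integers(2**31)))
        for M in ordered
    ]
    nestedness_table = summarize_significance(nest_results, alpha=cfg.alpha)
    nestedness_table.insert(3, "NODF_null_sd", [r.null_sd for r in nest_results])

    presence = PresenceTable.from_matrices(webs, guild="higher")
    richness_table = pd.DataFrame(
        {
            "habitat": presence.habitat_labels,
            "richness": presence.richness().values,
            "H_shannon": [
                shannon_diversity(np.ones(int(s))) for s in presence.richness().values
            ],
        }
    )
    jaccard = jaccard_distance_matrix(presence)
    tree = bootstrap_support(presence, n_rep=cfg.bootstrap, seed=cfg.seed + 1)
    newick = tree.to_newick()

    species = species_table(pooled)

    result = AnalysisResult(
        webs=webs,
        pooled=pooled,
        network_table=network_table,
        nestedness_table=nestedness_table,
        nestedness_results=nest_results,
        richness_table=richness_table,
        species=species,
        newick=newick,
        jaccard=jaccard,
    )
    if write:
        _write_bundle(cfg, result)
    return result


def _write_bundle(cfg: AnalysisConfig, res: AnalysisResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = cfg.rounding
    res.network_table.round(r).to_csv(out / "network_metrics.tsv", sep="\t", index=False)
    res.nestedness_table.round(r).to_csv(out / "nestedness.tsv", sep="\t", index=False)
    res.richness_table.round(r).to_csv(out / "richness.tsv", sep="\t", index=False)
    res.species.round(r).to_csv(out / "species_metrics.tsv", sep="\t", index=False)
    res.jaccard.round(r).to_csv(out / "jaccard_distance.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(res.newick + "\n")
    (out / "run_log.txt").write_text(
        "flowerweb analysis run\n"
        f"version: {__version__}\n"
        f"seed: {cfg.seed}\n"
        f"n_null: {cfg.n_null}\n"
        f"bootstrap replicates: {cfg.bootstrap}\n"
        f"alpha: {cfg.alpha}\n"
        f"habitats: {', '.join(sorted(res.webs))}\n"
    )
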