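"""End-to-end convenience: raw tables -> standardized -> final -> networks."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ingest import (
    AdapterConfig, BUILTIN_ADAPTERS, filter_prediction_types, normalize_raw,
    standardize,
)
from .phosphofilter import FilterAudit, filter_predictions
from .reference import KinaseMap, Phosphoproteome, ReferenceProteome
from .stringency import LEVELS, StringencyScheme, ThresholdedNetwork, threshold


@dataclass
class AlgorithmResult:
    algorithm_id: str
    standardized: pd.DataFrame
    removed_types: pd.DataFrame
    quarantined: pd.DataFrame
    final: pd.DataFrame
    unmatched: pd.DataFrame
    incoherent: pd.DataFrame
    audit: FilterAudit
    networks: dict[str, ThresholdedNetwork] = field(default_factory=dict)


def run_algorithm(
    raw: pd.DataFrame,
    adapter: AdapterConfig,
    proteome: ReferenceProteome,
    phospho: Phosphoproteome,
    kinase_map: KinaseMap,
    scheme: StringencyScheme | None = None,
    levels=LEVELS,
) -> AlgorithmResult:
    """Unify, filter and (optionally) threshold one algorithm's raw table."""
    if "algorithm_id" not in raw.columns:
        raw = normalize_raw(raw, adapter)
    kept, removed = filter_prediction_types(raw, kinase_map)
    std, quarantined = standardize(kept, kinase_map, proteome)
    final, unmatched, incoherent, audit = filter_predictions(
        std, phospho, proteome, kinase_map, adapter.window
    )
    result = AlgorithmResult(
        adapter.algorithm_id, std, removed, quarantined,
        final, unmatched, incoherent, audit,
    )
    if scheme is not None:
        for level in levels:
            net, _ = threshold(final, scheme, level)
            result.networks[level] = net
    return result


def run_all(
    raw_tables: dict[str, pd.DataFrame],
    proteome: ReferenceProteome,
    phospho: Phosphoproteome,
    kinase_map: KinaseMap,
    schemes: dict[str, StringencyScheme],
    adapters: dict[str, AdapterConfig] | None = None,
) -> dict[str, AlgorithmResult]:
    adapters = adapters or BUILTIN_ADAPTERS
    return {
        algo: run_algorithm(
            raw, adapters[algo], proteome, phospho, kinase_map,
            scheme=schemes.get(algo),
        )
        for algo, raw in raw_tables.items()
    }
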