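"""Restrict standardized edges to the known phosphoproteome.

Two matching modes implement the site-placement logic:

* **position** — the edge's (accession, position) is a recorded phosphosite
  and the reference residue at that position equals the edge residue;
* **peptide** — otherwise, every exact occurrence of the edge's
  (padding-stripped) flanking peptide in the reference sequence is located,
  and each occurrence whose implied center is a recorded phosphosite with an
  agreeing residue becomes a match. Repetitive sequence can yield several
  centers; all are retained, each producing one output row.

Edges matching nowhere are *unmatched* — an outcome, not an error — and are
written to a sidecar so "filtered out" is never confused with "not tested".
After placement, the kinase-type coherence filter removes edges pairing a
tyrosine kinase with an S/T site or a serine/threonine kinase with a Y site;
dual-specificity kinases keep all three residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ingest import STANDARD_COLUMNS, parse_site, strip_padding
from .reference import KinaseMap, Phosphoproteome, ReferenceProteome, SubstrateID

FINAL_COLUMNS = STANDARD_COLUMNS + ["match_mode"]


@dataclass
class MatchOutcome:
    edge: dict
    matched_positions: list[int]
    match_mode: str  # position | peptide | unmatched


@dataclass
class FilterAudit:
    """Conservation accounting for one filtering run."""

    n_input: int = 0
    n_position: int = 0
    n_peptide: int = 0
    n_unmatched: int = 0
    n_peptide_rows: int = 0  # rows emitted by peptide matches (multiplicity)
    n_incoherent: int = 0
    n_final: int = 0
    rejected_centers: int = 0  # peptide occurrences at non-site/disagreeing centers
    extra: dict = field(default_factory=dict)


def find_peptide_centers(
    sequence: str, peptide: str, window: int
) -> list[int]:
    """1-based center positions of every exact occurrence of ``peptide``.

    ``peptide`` may carry terminal padding; the center is the residue that
    sat at index ``window // 2`` of the padded form.
    """
    stripped, left = strip_padding(peptide)
    if not stripped:
        return []
    center_offset = window // 2 - left  # 0-based index of center in stripped form
    positions = []
    start = 0
    while True:
        i = sequence.find(stripped, start)
        if i < 0:
            break
        center = i + center_offset + 1  # back to 1-based coordinates
        if 1 <= center <= len(sequence):
            positions.append(center)
        start = i + 1  # overlapping occurrences count
    return positions


def match_to_phosphoproteome(
    edge, phospho: Phosphoproteome, proteome: ReferenceProteome, window: int
) -> MatchOutcome:
    """Place one standardized edge onto the known phosphoproteome.

    Position mode wins whenever it applies, even if the peptide would also
    match elsewhere — the fallback is strictly conditional.
    """
    d = edge if isinstance(edge, dict) else edge._asdict()
    residue, position = parse_site(d["site"])
    acc = d["accession"]
    if (
        phospho.is_known_site(acc, position)
        and proteome.residue_at(acc, position) == residue
    ):
        return MatchOutcome(d, [position], "position")
    seq = proteome.sequence(acc) if acc in proteome else ""
    centers = find_peptide_centers(seq, d["peptide"], window)
    # a center counts only if it is a known site whose residue agrees
    good = [
        c for c in centers
        if phospho.is_known_site(acc, c) and proteome.residue_at(acc, c) == residue
    ]
    if good:
        return MatchOutcome(d, good, "peptide")
    return MatchOutcome(d, [], "unmatched")


def coherence_filter(
    edges: pd.DataFrame, kinase_map: KinaseMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only residue-coherent kinase-site pairings.

    TK kinases keep Y sites only, STK keep S/T only, DUAL keep all. A kinase
    missing from the map is an upstream contract violation and raises.
    """
    if edges.empty:
        removed = edges.copy()
        removed["reason"] = pd.Series(dtype=str)
        return edges.copy(), removed
    ok = []
    for kin, site in zip(edges["kinase"], edges["site"]):
        if kin not in kinase_map:
            raise KeyError(f"kinase {kin!r} missing from the kinase map")
        ok.append(site[0] in kinase_map.allowed_residues(kin))
    mask = pd.Series(ok, index=edges.index)
    kept = edges[mask].copy()
    removed = edges[~mask].copy()
    removed["reason"] = "incoherent"
    return kept, removed


def finalize(outcomes: list[MatchOutcome]) -> tuple[pd.DataFrame, FilterAudit]:
    """One output row per (edge, matched position); substrate ids rewritten.

    Unmatched edges are excluded but counted in the audit.
    """
    audit = FilterAudit(n_input=len(outcomes))
    rows = []
    for oc in outcomes:
        if oc.match_mode == "unmatched":
            audit.n_unmatched += 1
            continue
        if oc.match_mode == "position":
            audit.n_position += 1
        else:
            audit.n_peptide += 1
            audit.n_peptide_rows += len(oc.matched_positions)
        residue = oc.edge["site"][0]
        for pos in oc.matched_positions:
            row = dict(oc.edge)
            row["substrate_id"] = SubstrateID(row["accession"], pos).render()
            row["site"] = f"{residue}{pos}"
            row["match_mode"] = oc.match_mode
            rows.append(row)
    final = pd.DataFrame(rows, columns=FINAL_COLUMNS)
    audit.n_final = len(final)
    assert audit.n_final == audit.n_position + audit.n_peptide_rows
    return final, audit


def filter_predictions(
    edges: pd.DataFrame,
    phospho: Phosphoproteome,
    proteome: ReferenceProteome,
    kinase_map: KinaseMap,
    window: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, FilterAudit]:
    """Full filtering pipeline for one algorithm's standardized edge table.

    Returns (final, unmatched_sidecar, incoherent_sidecar, audit). The final
    table keeps the standardized schema plus a ``match_mode`` column.
    """
    outcomes = [
        match_to_phosphoproteome(row, phospho, proteome, window)
        for row in edges.to_dict("records")
    ]
    placed, audit = finalize(outcomes)
    unmatched = pd.DataFrame(
        [oc.edge for oc in outcomes if oc.match_mode == "unmatched"],
        columns=STANDARD_COLUMNS,
    )
    final, incoherent = coherence_filter(placed, kinase_map)
    audit.n_incoherent = len(incoherent)
    audit.n_final = len(final)
    return final.reset_index(drop=True), unmatched, incoherent, audit
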