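"""Release-to-release update planning.

Reference proteomes and phosphoproteomes change over time. Rather than
re-running every external predictor on every release, the update engine
diffs two proteome releases, emits a worklist of sequences that genuinely
need fresh predictions (added or changed records), flags final edges that
have gone stale, and re-filters the retained whole-proteome edge set against
the new phosphoproteome — surfacing edges that were previously filtered out
only because their site was not yet known to be phosphorylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .phosphofilter import filter_predictions
from .reference import KinaseMap, Phosphoproteome, ReferenceProteome


@dataclass
class ProteomeDiff:
    added: set[str] = field(default_factory=set)
    removed: set[str] = field(default_factory=set)
    changed: set[str] = field(default_factory=set)
    unchanged: set[str] = field(default_factory=set)

    def all_accessions(self) -> set[str]:
        return self.added | self.removed | self.changed | self.unchanged

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, status)
                for status, accs in (("added", self.added),
                                     ("removed", self.removed),
                                     ("changed", self.changed),
                                     ("unchanged", self.unchanged))
                for a in sorted(accs)]
        return pd.DataFrame(rows, columns=["accession", "status"])


def diff_proteomes(old: ReferenceProteome, new: ReferenceProteome) -> ProteomeDiff:
    """Exact partition of the union of accessions by presence and sequence."""
    old_accs, new_accs = set(old.records), set(new.records)
    diff = ProteomeDiff(
        added=new_accs - old_accs,
        removed=old_accs - new_accs,
    )
    for acc in old_accs & new_accs:
        if old.sequence(acc) == new.sequence(acc):
            diff.unchanged.add(acc)
        else:
            diff.changed.add(acc)
    return diff


def _windows_differ(
    old_seq: str, new_seq: str, positions: list[int], window: int
) -> bool:
    half = window // 2
    for pos in positions:
        a = old_seq[max(0, pos - 1 - half): pos + half]
        b = new_seq[max(0, pos - 1 - half): pos + half]
        if a != b:
            return True
    return False


@dataclass
class UpdatePlan:
    worklist: set[str]
    stale_edges: pd.DataFrame


def plan_update(
    diff: ProteomeDiff,
    final_edges: pd.DataFrame,
    old: ReferenceProteome | None = None,
    new: ReferenceProteome | None = None,
    window: int | None = None,
) -> UpdatePlan:
    """Minimal recomputation plan for a proteome release change.

    The worklist is the set of added plus changed accessions — those need
    fresh external predictions. Final edges on removed or changed accessions
    are stale pending replacement. With ``window`` (and both proteomes)
    given, a changed accession enters the worklist only when some final
    edge's flanking window actually differs between releases — a strictly
    smaller, still-safe worklist.
    """
    changed = set(diff.changed)
    if window is not None and old is not None and new is not None:
        refined = set()
        by_acc = final_edges.groupby("accession") if len(final_edges) else []
        positions = {acc: [int(s[1:]) for s in grp["site"]]
                     for acc, grp in by_acc}
        for acc in changed:
            pos = positions.get(acc)
            if pos is None or _windows_differ(
                old.sequence(acc), new.sequence(acc), pos, window
            ):
                refined.add(acc)
        changed = refined
    worklist = set(diff.added) | changed
    stale_accs = set(diff.removed) | set(diff.changed)
    if len(final_edges):
        stale = final_edges[final_edges["accession"].isin(stale_accs)].copy()
    else:
        stale = final_edges.copy()
    return UpdatePlan(worklist=worklist, stale_edges=stale)


def refilter(
    whole_proteome_edges: pd.DataFrame,
    new_phospho: Phosphoproteome,
    proteome: ReferenceProteome,
    kinase_map: KinaseMap,
    window: int,
):
    """Re-run the phosphoproteome filter against a new reference release.

    Identical, row for row, to filtering the retained whole-proteome edge
    set from scratch: newly known sites surface previously filtered edges,
    removed sites drop theirs.
    """
    return filter_predictions(
        whole_proteome_edges, new_phospho, proteome, kinase_map, window
    )


def worklist_fasta(worklist: set[str], proteome: ReferenceProteome, handle) -> None:
    """Write worklist records as FASTA for submission to external predictors."""
    sub = ReferenceProteome(
        {a: proteome.records[a] for a in sorted(worklist) if a in proteome}
    )
    sub.to_fasta(handle)
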