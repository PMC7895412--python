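"""Convert raw per-algorithm prediction output into the standardized edge table.

Each prediction algorithm publishes a different dialect (column names, score
semantics, flanking-window length). An :class:`AdapterConfig` describes one
dialect; three built-ins cover the NetworKIN-like (likelihood ratio, 11-mer),
GPS-like (score with per-kinase cutoffs, 15-mer) and PhosphoPICK-like
(p-value, 15-mer) families. Ingest maps raw kinase names onto the global
kinase ontology, builds ``ACC_POS`` substrate identifiers and attaches gene
names from the reference proteome. No stringency filtering happens here:
every tested edge is preserved so downstream users control thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from io import StringIO

import pandas as pd
import yaml

from .reference import KinaseMap, ReferenceProteome, SubstrateID

PAD_CHAR = "-"

STANDARD_COLUMNS = [
    "substrate_id", "accession", "gene_name", "site",
    "peptide", "kinase", "score", "algorithm",
]

RAW_COLUMNS = [
    "algorithm_id", "raw_kinase_name", "accession", "position",
    "residue", "score", "peptide", "prediction_type",
]


@dataclass(frozen=True)
class AdapterConfig:
    """Describes one raw prediction dialect.

    ``columns`` maps the canonical field names (kinase, accession, position,
    residue, score, peptide, prediction_type) onto the dialect's column
    headers; ``window`` is the flanking-peptide length; ``score_semantics``
    records what the score means (documentation only — thresholds live in
    the stringency schemes).
    """

    algorithm_id: str
    window: int
    score_semantics: str
    columns: dict[str, str] = field(default_factory=dict)
    sep: str = ","

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "AdapterConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**data)


BUILTIN_ADAPTERS = {
    "networkin_like": AdapterConfig(
        algorithm_id="networkin_like", window=11,
        score_semantics="likelihood_ratio",
    ),
    "gps_like": AdapterConfig(
        algorithm_id="gps_like", window=15,
        score_semantics="score_with_per_kinase_cutoff",
    ),
    "phosphopick_like": AdapterConfig(
        algorithm_id="phosphopick_like", window=15,
        score_semantics="p_value",
    ),
}


def read_raw(source, adapter: AdapterConfig) -> pd.DataFrame:
    """Read a raw prediction table into the canonical raw-row schema.

    Peptides are validated against the adapter's window length and their
    center character against the recorded residue (padding-aware).
    """
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    return normalize_raw(pd.read_csv(source, sep=adapter.sep), adapter)


def normalize_raw(df: pd.DataFrame, adapter: AdapterConfig) -> pd.DataFrame:
    """Validate an in-memory raw table against the adapter's dialect."""
    rename = {adapter.column(c): c for c in
              ("raw_kinase_name", "accession", "position", "residue",
               "score", "peptide", "prediction_type")}
    df = df.rename(columns=rename)
    missing = {"raw_kinase_name", "accession", "position", "residue",
               "score", "peptide"} - set(df.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")
    if "prediction_type" not in df.columns:
        df["prediction_type"] = "kinase"
    df["algorithm_id"] = adapter.algorithm_id
    df["position"] = df["position"].astype(int)
    bad_len = df["peptide"].str.len() != adapter.window
    if bad_len.any():
        raise ValueError(
            f"{int(bad_len.sum())} peptides violate the declared "
            f"{adapter.window}-mer window for {adapter.algorithm_id}"
        )
    center = adapter.window // 2
    bad_center = df["peptide"].str[center] != df["residue"]
    if bad_center.any():
        raise ValueError(
            f"{int(bad_center.sum())} peptides whose center character "
            f"disagrees with the recorded residue"
        )
    return df[RAW_COLUMNS]


def strip_padding(peptide: str) -> tuple[str, int]:
    """Remove terminal pad characters; returns (stripped, n_left_stripped)."""
    left = len(peptide) - len(peptide.lstrip(PAD_CHAR))
    return peptide.strip(PAD_CHAR), left


def split_fasta(proteome: ReferenceProteome, n_parts: int) -> list[list[str]]:
    """Partition accessions into ``n_parts`` balanced, order-preserving parts.

    Part sizes differ by at most one; empty parts are allowed (and logged)
    when more parts than records are requested. Mirrors the batching used to
    submit a whole proteome to prediction services in manageable pieces.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    accs = proteome.accessions()
    n = len(accs)
    base, extra = divmod(n, n_parts)
    parts, start = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        parts.append(accs[start:start + size])
        start += size
    return parts


def write_fasta_parts(proteome: ReferenceProteome, n_parts: int, out_dir) -> list[str]:
    """Write the balanced parts as FASTA files; returns the paths."""
    import os

    paths = []
    for i, accs in enumerate(split_fasta(proteome, n_parts), start=1):
        path = os.path.join(out_dir, f"part_{i:02d}.fasta")
        sub = ReferenceProteome({a: proteome.records[a] for a in accs})
        with open(path, "w") as fh:
            sub.to_fasta(fh)
        paths.append(path)
    return paths


def filter_prediction_types(
    rows: pd.DataFrame, kinase_map: KinaseMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition raw rows into kinase predictions vs everything else.

    A row is kept iff its raw kinase name resolves through the kinase map's
    alias index for that algorithm; rows naming non-kinase prediction types
    (phospho-binding domains, unmapped names) are returned separately with a
    reason tag. ``len(kept) + len(removed) == len(rows)`` always.
    """
    if rows.empty:
        removed = rows.copy()
        removed["reason"] = pd.Series(dtype=str)
        return rows.copy(), removed
    resolved = [
        kinase_map.resolve_alias(r, a)
        for r, a in zip(rows["raw_kinase_name"], rows["algorithm_id"])
    ]
    mask = pd.Series([r is not None for r in resolved], index=rows.index)
    kept = rows[mask].copy()
    removed = rows[~mask].copy()
    removed["reason"] = "non-kinase-or-unmapped"
    return kept, removed


def standardize(
    rows: pd.DataFrame, kinase_map: KinaseMap, proteome: ReferenceProteome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map type-filtered raw rows onto the standardized edge schema.

    Returns (standardized, quarantine): rows whose accession is absent from
    the reference proteome are quarantined with a reason instead of being
    dropped. Duplicate raw rows are preserved verbatim; deduplication is a
    separate, explicit step (:func:`dedup_edges`).
    """
    known = rows["accession"].isin(proteome.records)
    quarantine = rows[~known].copy()
    quarantine["reason"] = "accession-not-in-proteome"
    rows = rows[known]
    if rows.empty:
        return pd.DataFrame(columns=STANDARD_COLUMNS), quarantine
    kinase = [
        kinase_map.resolve_alias(r, a)
        for r, a in zip(rows["raw_kinase_name"], rows["algorithm_id"])
    ]
    if any(k is None for k in kinase):
        raise ValueError("standardize() requires type-filtered rows "
                         "(unmapped kinase name encountered)")
    out = pd.DataFrame({
        "substrate_id": [
            SubstrateID(a, p).render()
            for a, p in zip(rows["accession"], rows["position"])
        ],
        "accession": rows["accession"].to_numpy(),
        "gene_name": [proteome.gene_name(a) for a in rows["accession"]],
        "site": [f"{r}{p}" for r, p in zip(rows["residue"], rows["position"])],
        "peptide": rows["peptide"].to_numpy(),
        "kinase": kinase,
        "score": rows["score"].to_numpy(),
        "algorithm": rows["algorithm_id"].to_numpy(),
    })
    return out, quarantine


def dedup_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Explicitly drop rows identical on every standardized column."""
    return edges.drop_duplicates(subset=STANDARD_COLUMNS).reset_index(drop=True)


def parse_site(site: str) -> tuple[str, int]:
    """Split a site string like ``"Y1197"`` into (residue, position)."""
    return site[0], int(site[1:])
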