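"""Reference proteome, reference phosphoproteome and global kinase ontology.

These three inputs define the coordinate system for everything downstream:
the proteome is the authority for sequences and residue positions (1-based,
matching UniProt site nomenclature such as "Y1197"), the phosphoproteome is
the catalogue of experimentally observed phosphosites each carrying the
number of annotation compendia it appears in, and the kinase map translates
algorithm-specific kinase names onto one common vocabulary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"U", "X"}
PHOSPHO_RESIDUES = ("S", "T", "Y")

#: Accepted kinase-type tokens and the free-text synonyms normalized onto them.
KINASE_TYPE_SYNONYMS = {
    "TK": "TK",
    "STK": "STK",
    "DUAL": "DUAL",
    "Y": "TK",
    "TYROSINE": "TK",
    "S/T": "STK",
    "ST": "STK",
    "SER/THR": "STK",
    "SERINE/THREONINE": "STK",
    "DUAL-SPECIFICITY": "DUAL",
    "DUAL SPECIFICITY": "DUAL",
}

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|")


class ValidationError(ValueError):
    """Raised when a reference input violates its schema or invariants."""


@dataclass(frozen=True)
class SubstrateID:
    """Site-specific substrate identifier: accession plus 1-based position.

    The rendered form ``"ACC_POS"`` (e.g. ``"P00533_1197"``) is the unique
    substrate key used across all unified prediction tables.
    """

    accession: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    def render(self) -> str:
        return f"{self.accession}_{self.position}"

    @classmethod
    def parse(cls, text: str) -> "SubstrateID":
        acc, _, pos = text.rpartition("_")
        if not acc or not pos.isdigit():
            raise ValidationError(f"not a substrate id: {text!r}")
        return cls(acc, int(pos))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class ProteinRecord:
    sequence: str
    gene_name: str = ""
    description: str = ""


def normalize_accession(accession: str) -> str:
    """Strip an isoform suffix (``P00533-2`` -> ``P00533``), warning if present."""
    if "-" in accession:
        base = accession.split("-", 1)[0]
        logger.warning("isoform accession %s normalized to %s", accession, base)
        return base
    return accession


def _parse_fasta_header(header: str) -> tuple[str, str, str]:
    """Return (accession, gene_name, description) from a FASTA header line.

    Accepts the UniProt ``sp|ACC|NAME desc GN=GENE`` dialect and a bare
    leading accession token.
    """
    m = _UNIPROT_HEADER.match(header)
    accession = m.group("acc") if m else header.split()[0] if header.split() else ""
    if not accession:
        raise ValidationError(f"cannot extract an accession from header {header!r}")
    gm = re.search(r"\bGN=(\S+)", header)
    gene = gm.group(1) if gm else ""
    desc = header.split(None, 1)[1] if len(header.split(None, 1)) > 1 else ""
    return normalize_accession(accession), gene, desc


class ReferenceProteome:
    """Canonical, non-redundant proteome indexed by UniProt accession."""

    def __init__(self, records: Mapping[str, ProteinRecord]):
        for acc, rec in records.items():
            if not rec.sequence:
                raise ValidationError(f"empty sequence for {acc}")
            bad = set(rec.sequence) - AMINO_ACIDS
            if bad:
                raise ValidationError(
                    f"sequence for {acc} contains non-amino-acid characters {sorted(bad)}"
                )
        self.records = dict(records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def accessions(self) -> list[str]:
        return list(self.records)

    def sequence(self, accession: str) -> str:
        return self.records[accession].sequence

    def gene_name(self, accession: str) -> str:
        return self.records[accession].gene_name

    def residue_at(self, accession: str, position: int) -> str | None:
        """Residue at a 1-based position, or None when out of range/unknown."""
        rec = self.records.get(accession)
        if rec is None or position < 1 or position > len(rec.sequence):
            return None
        return rec.sequence[position - 1]

    @classmethod
    def from_fasta(cls, source) -> "ReferenceProteome":
        """Load from a FASTA path or handle; duplicate accessions are rejected."""
        records: dict[str, ProteinRecord] = {}
        for rec in SeqIO.parse(source, "fasta"):
            acc, gene, desc = _parse_fasta_header(rec.description)
            if acc in records:
                raise ValidationError(f"duplicate accession {acc} in FASTA input")
            records[acc] = ProteinRecord(str(rec.seq).upper(), gene, desc)
        return cls(records)

    def to_fasta(self, handle) -> None:
        for acc, rec in self.records.items():
            header = f">sp|{acc}|{rec.gene_name or acc}"
            if rec.gene_name:
                header += f" GN={rec.gene_name}"
            handle.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


def load_proteome(fasta_source) -> ReferenceProteome:
    return ReferenceProteome.from_fasta(fasta_source)


# ---------------------------------------------------------------------------
# Global kinase ontology map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinaseMapEntry:
    accession: str
    common_name: str
    preferred_name: str
    description: str
    kinase_type: str  # TK | STK | DUAL
    aliases: Mapping[str, str] = field(default_factory=dict)


class KinaseMap:
    """Global kinase ontology: common names, types and per-algorithm aliases.

    Dual-specificity kinases belong to both the tyrosine and the
    serine/threonine category.
    """

    def __init__(self, entries: Iterable[KinaseMapEntry]):
        self.entries: dict[str, KinaseMapEntry] = {}
        self._alias_index: dict[str, dict[str, str]] = {}
        for e in entries:
            if e.common_name in self.entries:
                raise ValidationError(f"duplicate common_name {e.common_name}")
            if e.kinase_type not in ("TK", "STK", "DUAL"):
                raise ValidationError(f"unknown kinase_type {e.kinase_type!r}")
            self.entries[e.common_name] = e
            for algo, raw in e.aliases.items():
                idx = self._alias_index.setdefault(algo, {})
                if raw in idx and idx[raw] != e.common_name:
                    raise ValidationError(
                        f"alias {raw!r} maps to both {idx[raw]} and {e.common_name} "
                        f"for algorithm {algo}"
                    )
                idx[raw] = e.common_name

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, common_name: str) -> bool:
        return common_name in self.entries

    def kinase_type(self, common_name: str) -> str:
        return self.entries[common_name].kinase_type

    def resolve_alias(self, raw_name: str, algorithm_id: str) -> str | None:
        """Common name for an algorithm-specific raw name, or None if unmapped."""
        return self._alias_index.get(algorithm_id, {}).get(raw_name)

    def category(self, which: str) -> set[str]:
        """Kinase common names in the ``"tyrosine"`` or ``"ser_thr"`` category."""
        if which == "tyrosine":
            types = ("TK", "DUAL")
        elif which == "ser_thr":
            types = ("STK", "DUAL")
        else:
            raise ValueError(f"unknown category {which!r}")
        return {n for n, e in self.entries.items() if e.kinase_type in types}

    def allowed_residues(self, common_name: str) -> tuple[str, ...]:
        """Residues a kinase may coherently phosphorylate."""
        t = self.kinase_type(common_name)
        return {"TK": ("Y",), "STK": ("S", "T"), "DUAL": ("S", "T", "Y")}[t]


def load_kinase_map(table_source) -> KinaseMap:
    """Read the kinase map CSV.

    Required columns: accession, common_name, preferred_name, description,
    kinase_type; alias columns are named ``alias:<algorithm_id>``.
    kinase_type accepts the declared free-text synonyms.
    """
    df = pd.read_csv(table_source, dtype=str).fillna("")
    required = {"accession", "common_name", "kinase_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"kinase map missing columns: {sorted(missing)}")
    alias_cols = [c for c in df.columns if c.startswith("alias:")]
    entries = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        token = str(d["kinase_type"]).strip().upper()
        if token not in KINASE_TYPE_SYNONYMS:
            raise ValidationError(f"unknown kinase_type token {d['kinase_type']!r}")
        aliases = {
            c.split(":", 1)[1]: d[c] for c in alias_cols if str(d[c]).strip()
        }
        entries.append(
            KinaseMapEntry(
                accession=d["accession"],
                common_name=d["common_name"],
                preferred_name=d.get("preferred_name", "") or d["common_name"],
                description=d.get("description", ""),
                kinase_type=KINASE_TYPE_SYNONYMS[token],
                aliases=aliases,
            )
        )
    return KinaseMap(entries)


# ---------------------------------------------------------------------------
# Reference phosphoproteome
# ---------------------------------------------------------------------------

PHOSPHO_COLUMNS = ["accession", "position", "residue", "n_compendia"]


class Phosphoproteome:
    """Experimentally known phosphosites with compendia counts.

    ``sites`` is a DataFrame with columns accession, position, residue,
    n_compendia and a boolean ``stale`` flag marking sites whose recorded
    residue disagrees with the reference sequence (kept so the peptide
    fallback matcher can still place their edges).
    """

    def __init__(self, sites: pd.DataFrame, n_dropped: int = 0):
        self.sites = sites.reset_index(drop=True)
        self.n_dropped = n_dropped
        # stale records stay in the catalogue: their edges are the ones the
        # peptide-fallback matcher recovers
        self._known = set(zip(self.sites["accession"], self.sites["position"]))
        self._compendia = dict(
            zip(zip(self.sites["accession"], self.sites["position"]),
                self.sites["n_compendia"])
        )

    def __len__(self) -> int:
        return len(self.sites)

    def is_known_site(self, accession: str, position: int) -> bool:
        """True when (accession, position) is a recorded phosphosite."""
        return (accession, position) in self._known

    def n_compendia(self, accession: str, position: int) -> int | None:
        return self._compendia.get((accession, position))

    def counts_by_residue(self) -> dict[str, int]:
        return self.sites["residue"].value_counts().to_dict()


def load_phosphoproteome(table_source, proteome: ReferenceProteome) -> Phosphoproteome:
    """Load a phosphoproteome CSV and validate it against the proteome.

    Rows on accessions absent from the proteome are dropped (counted);
    rows whose reference residue disagrees with the recorded residue are
    retained but flagged stale.
    """
    df = pd.read_csv(table_source)
    missing = set(PHOSPHO_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"phosphoproteome missing columns: {sorted(missing)}")
    bad_res = ~df["residue"].isin(PHOSPHO_RESIDUES)
    if bad_res.any():
        raise ValidationError(
            f"phosphoproteome residues outside S/T/Y: "
            f"{sorted(df.loc[bad_res, 'residue'].unique())}"
        )
    if df.duplicated(subset=["accession", "position"]).any():
        raise ValidationError("duplicate (accession, position) in phosphoproteome")
    known_mask = df["accession"].isin(proteome.records)
    n_dropped = int((~known_mask).sum())
    if n_dropped:
        logger.info("dropped %d phosphosites on unknown accessions", n_dropped)
    df = df[known_mask].copy()
    df["position"] = df["position"].astype(int)
    df["n_compendia"] = df["n_compendia"].astype(int)
    ref = [
        proteome.residue_at(a, p) for a, p in zip(df["accession"], df["position"])
    ]
    df["stale"] = [r != rec for r, rec in zip(ref, df["residue"])]
    return Phosphoproteome(df[PHOSPHO_COLUMNS + ["stale"]], n_dropped=n_dropped)
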