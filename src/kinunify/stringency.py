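"""Stringency schemes and thresholded bipartite networks.

Every prediction algorithm weighs its edges on a different scale, so each
gets its own stringency scheme: a direction (keep scores at-or-above for
likelihoods, at-or-below for p-values) and low/medium/high cutoffs. The
built-in schemes are:

* ``networkin_like`` — unified likelihood ratio; keep >= 0.3 / 0.5 / 1.
* ``phosphopick_like`` — p-value; keep <= 0.1 / 0.06 / 0.02. A native
  four-level scheme (0.25 / 0.1 / 0.05 / 0.005) is available as
  ``phosphopick_native``.
* ``gps_like`` — score compared against per-kinase cutoffs extracted at
  false-positive-rate levels of 10/6/2% (S/T kinases) and 15/9/4%
  (Y kinases); a per-kinase cutoff table is mandatory.

All comparisons are inclusive: an edge exactly at the cutoff survives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

LEVELS = ("low", "medium", "high")
NATIVE_PP_LEVELS = ("low", "medium", "high", "very_high")


class ConfigurationError(ValueError):
    pass


@dataclass
class StringencyScheme:
    algorithm_id: str
    direction: str  # keep_geq | keep_leq
    cutoffs: dict[str, float] = field(default_factory=dict)
    per_kinase_cutoffs: dict[tuple, float] | None = None
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if self.direction not in ("keep_geq", "keep_leq"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        vals = [self.cutoffs[l] for l in self.levels if l in self.cutoffs]
        if len(vals) > 1:
            diffs = [b - a for a, b in zip(vals, vals[1:])]
            if self.direction == "keep_geq" and not all(d > 0 for d in diffs):
                raise ConfigurationError(
                    "keep_geq cutoffs must strictly increase with level")
            if self.direction == "keep_leq" and not all(d < 0 for d in diffs):
                raise ConfigurationError(
                    "keep_leq cutoffs must strictly decrease with level")

    def cutoff_for(self, level: str, kinase: str | None = None,
                   residue_class: str | None = None) -> float:
        """Resolve the cutoff, preferring a per-kinase entry when present."""
        if level not in self.levels:
            raise ConfigurationError(f"unknown level {level!r}")
        if self.per_kinase_cutoffs is not None:
            if residue_class is not None:
                v = self.per_kinase_cutoffs.get((kinase, residue_class, level))
                if v is not None:
                    return v
            v = self.per_kinase_cutoffs.get((kinase, level))
            if v is not None:
                return v
        if level in self.cutoffs:
            return self.cutoffs[level]
        if self.per_kinase_cutoffs is not None:
            raise KeyError(f"no cutoff for kinase {kinase!r} at level {level!r}")
        raise ConfigurationError(
            f"scheme {self.algorithm_id} has no cutoff for level {level!r}")

    def keeps(self, score: float, cutoff: float) -> bool:
        # inclusive on both directions: an edge exactly at cutoff survives
        return score >= cutoff if self.direction == "keep_geq" else score <= cutoff


def load_gps_cutoff_table(source) -> dict[tuple, float]:
    """Read a per-kinase cutoff CSV (kinase, residue_class, level, cutoff).

    ``residue_class`` ("Y" or "ST") may be empty, in which case the cutoff
    applies to the kinase at that level regardless of residue class.
    """
    df = pd.read_csv(source)
    missing = {"kinase", "level", "cutoff"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"cutoff table missing columns {sorted(missing)}")
    table: dict[tuple, float] = {}
    has_rc = "residue_class" in df.columns
    for row in df.itertuples(index=False):
        rc = getattr(row, "residue_class", None) if has_rc else None
        if rc is None or (isinstance(rc, float) and pd.isna(rc)) or rc == "":
            key = (row.kinase, row.level)
        else:
            key = (row.kinase, str(rc), row.level)
        table[key] = float(row.cutoff)
    return table


def builtin_schemes(
    gps_cutoffs: dict[tuple, float] | None = None,
) -> dict[str, StringencyScheme]:
    """The three harmonized stringency schemes plus the native PhosphoPICK one.

    ``gps_like`` is only usable when a per-kinase cutoff table is supplied;
    requesting a GPS cutoff without one is a configuration error.
    """
    schemes = {
        "networkin_like": StringencyScheme(
            "networkin_like", "keep_geq",
            {"low": 0.3, "medium": 0.5, "high": 1.0},
        ),
        "phosphopick_like": StringencyScheme(
            "phosphopick_like", "keep_leq",
            {"low": 0.1, "medium": 0.06, "high": 0.02},
        ),
        "phosphopick_native": StringencyScheme(
            "phosphopick_like", "keep_leq",
            {"low": 0.25, "medium": 0.1, "high": 0.05, "very_high": 0.005},
            levels=NATIVE_PP_LEVELS,
        ),
        "gps_like": StringencyScheme(
            "gps_like", "keep_geq", {}, per_kinase_cutoffs=gps_cutoffs or None,
        ),
    }
    return schemes


class ThresholdedNetwork:
    """Bipartite kinase -> substrate-set mapping surviving one stringency level."""

    def __init__(self, algorithm_id: str, level: str,
                 kinase_sets: dict[str, set[str]]):
        self.algorithm_id = algorithm_id
        self.level = level
        self.kinase_sets = {k: set(v) for k, v in kinase_sets.items()}

    @property
    def kinases(self) -> list[str]:
        return list(self.kinase_sets)

    @property
    def substrates(self) -> set[str]:
        out: set[str] = set()
        for s in self.kinase_sets.values():
            out |= s
        return out

    @property
    def edge_count(self) -> int:
        return sum(len(s) for s in self.kinase_sets.values())

    def kinase_degree(self) -> dict[str, int]:
        return {k: len(s) for k, s in self.kinase_sets.items()}

    def substrate_degree(self) -> dict[str, int]:
        c: Counter = Counter()
        for s in self.kinase_sets.values():
            c.update(s)
        return dict(c)

    def edges(self) -> set[tuple[str, str]]:
        return {(k, s) for k, subs in self.kinase_sets.items() for s in subs}

    def is_subnetwork_of(self, other: "ThresholdedNetwork") -> bool:
        return all(
            self.kinase_sets[k] <= other.kinase_sets.get(k, set())
            for k in self.kinase_sets
        )


def threshold(
    final_edges: pd.DataFrame, scheme: StringencyScheme, level: str
) -> tuple[ThresholdedNetwork, pd.DataFrame]:
    """Build the bipartite network of edges surviving ``level``.

    Edges whose kinase has no resolvable cutoff are diverted to an audit
    table rather than silently kept or dropped. A substrate's residue class
    ("Y" vs "ST") is derived from its site string to pick the right
    per-kinase cutoff row for dual-specificity kinases.
    """
    kinase_sets: dict[str, set[str]] = {}
    diverted = []
    for row in final_edges.itertuples(index=False):
        rc = "Y" if row.site[0] == "Y" else "ST"
        try:
            cut = scheme.cutoff_for(level, kinase=row.kinase, residue_class=rc)
        except KeyError:
            diverted.append(row._asdict())
            continue
        kinase_sets.setdefault(row.kinase, set())
        if scheme.keeps(float(row.score), cut):
            kinase_sets[row.kinase].add(row.substrate_id)
    # kinases whose every edge fell below cutoff keep an (empty) set only if
    # they appeared in the input; drop empties for a clean bipartite view
    kinase_sets = {k: v for k, v in kinase_sets.items() if v}
    net = ThresholdedNetwork(scheme.algorithm_id, level, kinase_sets)
    audit = pd.DataFrame(diverted, columns=list(final_edges.columns))
    return net, audit


def coverage_and_edges(networks: dict[str, ThresholdedNetwork]) -> pd.DataFrame:
    """Per-level substrate and edge counts normalized to the low network.

    ``networks`` maps level name -> network for one algorithm. The low-level
    network must be non-empty; otherwise the ratios are undefined.
    """
    if "low" not in networks:
        raise ValueError("a 'low' network is required for normalization")
    low = networks["low"]
    n_sub_low = len(low.substrates)
    n_edge_low = low.edge_count
    if n_sub_low == 0 or n_edge_low == 0:
        raise ValueError("empty low-stringency network: ratios undefined")
    rows = []
    for level, net in networks.items():
        rows.append({
            "algorithm": net.algorithm_id,
            "level": level,
            "n_substrates": len(net.substrates),
            "n_edges": net.edge_count,
            "substrate_ratio": len(net.substrates) / n_sub_low,
            "edge_ratio": net.edge_count / n_edge_low,
        })
    return pd.DataFrame(rows)
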