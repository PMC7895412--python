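"""Synthetic reference and prediction fixtures.

Running the real external predictors over a proteome takes weeks and
multi-GB downloads; every pipeline stage here is instead exercised on
generated data that emulates the four real input kinds: a reference proteome
FASTA, a phosphoproteome table with compendia counts, a global kinase map
with per-algorithm aliases, and three raw prediction tables (plus the
per-kinase cutoff table the GPS-like scheme requires).

The generator plants known structure so analyses can be checked against
ground truth:

* **overlap** — for each planted (kinase_i, kinase_j, J*) pair, substrate
  sets are built by inclusion-exclusion on a fixed union size:
  |A ∩ B| = round(J* · |A ∪ B|). Edges on shared substrates of a planted
  pair share one confidence tier, so the planted Jaccard survives
  thresholding at every stringency level (similar kinases score shared
  substrates similarly);
* **study bias** — substrates annotated in many compendia both attract
  more edges (selection weight ``(1 + bias_strength) ** n_compendia``, a
  constant degree ratio between adjacent compendia groups) and receive
  more confident scores (``tier = u^(1 + bias_strength * n_compendia)``,
  smaller tier = more confident),
  reproducing how training-set membership inflates both the degree and the
  score of well-studied sites;
* **staleness** — a configurable fraction of raw rows has its recorded
  position shifted by +1 while the flanking peptide stays centered on the
  true site, forcing the peptide-fallback matching path.

Scores are drawn per algorithm inside bands that straddle the built-in
stringency cutoffs, so an edge's tier determines exactly which levels it
survives and nesting holds by construction. One seed fully determines every
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import BUILTIN_ADAPTERS, PAD_CHAR
from .reference import (
    KinaseMap, Phosphoproteome, ProteinRecord, ReferenceProteome,
    load_kinase_map, PHOSPHO_COLUMNS,
)

ALGORITHMS = ("networkin_like", "gps_like", "phosphopick_like")

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_KINASES = (
    ("SRC", "TK"), ("LCK", "TK"), ("EGFR", "TK"), ("ABL1", "TK"),
    ("CDK1", "STK"), ("CK2A1", "STK"), ("PKACA", "STK"), ("AKT1", "STK"),
    ("DYRK1A", "DUAL"),
)

#: fraction of substrates surviving each stringency level in expectation
DEFAULT_SURVIVAL = {"low": 0.9, "medium": 0.6, "high": 0.3}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; the seed fixes every output."""

    seed: int = 0
    n_proteins: int = 50
    mean_length: int = 300
    phospho_rate: dict[str, float] = field(
        default_factory=lambda: {"S": 0.20, "T": 0.15, "Y": 0.30})
    compendia_probs: tuple[float, ...] = (0.08, 0.55, 0.17, 0.12, 0.05, 0.03)
    kinases: tuple[tuple[str, str], ...] = DEFAULT_KINASES
    n_substrates_per_kinase: int = 120
    planted_jaccard: tuple[tuple[str, str, float], ...] = ()
    planted_union: int = 200
    bias_strength: float = 0.0
    stale_fraction: float = 0.0
    unknown_site_fraction: float = 0.10
    non_kinase_fraction: float = 0.05
    survival: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL))

    def validate(self) -> None:
        for r, v in self.phospho_rate.items():
            if not 0 <= v <= 1:
                raise ValueError(f"phospho_rate[{r}]={v} outside [0, 1]")
        for _, _, j in self.planted_jaccard:
            if not 0 <= j <= 1:
                raise ValueError(f"planted Jaccard {j} outside [0, 1]")
        for frac in (self.stale_fraction, self.unknown_site_fraction,
                     self.non_kinase_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticReference:
    proteome: ReferenceProteome
    phospho: Phosphoproteome
    kinase_map: KinaseMap
    phospho_frame: pd.DataFrame
    kinase_map_frame: pd.DataFrame


def _alias(name: str, algorithm: str) -> str:
    return f"{name}_{algorithm.split('_')[0]}"


def generate_reference(spec: FixtureSpec) -> SyntheticReference:
    """Generate the proteome, phosphoproteome and kinase map for one spec."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 11])
    records: dict[str, ProteinRecord] = {}
    for i in range(spec.n_proteins):
        acc = f"SYN{i:04d}"
        length = max(50, int(rng.poisson(spec.mean_length)))
        seq = "".join(rng.choice(AA, size=length))
        records[acc] = ProteinRecord(seq, gene_name=f"GENE{i:04d}",
                                     description=f"synthetic protein {i}")
    proteome = ReferenceProteome(records)

    rows = []
    probs = np.asarray(spec.compendia_probs, dtype=float)
    probs = probs / probs.sum()
    for acc, rec in records.items():
        for pos0, res in enumerate(rec.sequence):
            if res in spec.phospho_rate and rng.random() < spec.phospho_rate[res]:
                nc = int(rng.choice(len(probs), p=probs))
                rows.append((acc, pos0 + 1, res, nc))
    phospho_frame = pd.DataFrame(rows, columns=PHOSPHO_COLUMNS)
    phospho_frame["stale"] = False
    phospho = Phosphoproteome(phospho_frame.copy())

    km_rows = []
    for j, (name, ktype) in enumerate(spec.kinases):
        km_rows.append({
            "accession": f"K{j:05d}",
            "common_name": name,
            "preferred_name": name,
            "description": f"synthetic {ktype} kinase",
            "kinase_type": ktype,
            **{f"alias:{a}": _alias(name, a) for a in ALGORITHMS},
        })
    kinase_map_frame = pd.DataFrame(km_rows)
    import io

    kinase_map = load_kinase_map(
        io.StringIO(kinase_map_frame.to_csv(index=False)))
    return SyntheticReference(proteome, phospho, kinase_map,
                              phospho_frame[PHOSPHO_COLUMNS], kinase_map_frame)


def _site_pools(ref: SyntheticReference) -> dict[str, list[tuple[str, int, str, int]]]:
    """Known phosphosites split by residue class ('Y' vs 'ST')."""
    pools: dict[str, list] = {"Y": [], "ST": []}
    for row in ref.phospho_frame.itertuples(index=False):
        cls = "Y" if row.residue == "Y" else "ST"
        pools[cls].append((row.accession, int(row.position), row.residue,
                           int(row.n_compendia)))
    return pools


def _unknown_pool(ref: SyntheticReference) -> dict[str, list[tuple[str, int, str, int]]]:
    """S/T/Y positions *not* in the phosphoproteome (whole-proteome edges)."""
    known = {(a, p) for a, p in
             zip(ref.phospho_frame["accession"], ref.phospho_frame["position"])}
    pools: dict[str, list] = {"Y": [], "ST": []}
    for acc, rec in ref.proteome.records.items():
        for pos0, res in enumerate(rec.sequence):
            if res in "STY" and (acc, pos0 + 1) not in known:
                cls = "Y" if res == "Y" else "ST"
                pools[cls].append((acc, pos0 + 1, res, 0))
    return pools


def _peptide(sequence: str, position: int, window: int) -> str:
    half = window // 2
    lo, hi = position - 1 - half, position + half
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    return (PAD_CHAR * left_pad
            + sequence[max(0, lo):min(len(sequence), hi)]
            + PAD_CHAR * right_pad)


def _assign_substrates(
    spec: FixtureSpec, pools: dict[str, list], rng: np.random.Generator,
    kinase_types: dict[str, str],
) -> tuple[dict[str, list], dict[str, set]]:
    """Choose each kinase's true substrate list, honoring planted overlaps.

    Returns (kinase -> substrate tuples, kinase -> planted-shared substrate
    keys). Planted pairs are carved out of one sampled union per pair.
    """
    sets: dict[str, list] = {}
    shared: dict[str, set] = {k: set() for k, _ in spec.kinases}
    planted_members = {k for pair in spec.planted_jaccard for k in pair[:2]}
    for ki, kj, jstar in spec.planted_jaccard:
        cls_i = "Y" if kinase_types[ki] == "TK" else "ST"
        cls_j = "Y" if kinase_types[kj] == "TK" else "ST"
        if cls_i != cls_j:
            raise ValueError(
                f"planted pair ({ki}, {kj}) spans residue classes")
        pool = pools[cls_i]
        union = spec.planted_union
        if union > len(pool):
            raise ValueError(
                f"planted union {union} exceeds available phosphosites "
                f"({len(pool)}) in class {cls_i}")
        n_inter = round(jstar * union)
        n_excl = union - n_inter
        n_a = n_excl // 2 + n_excl % 2
        idx = rng.choice(len(pool), size=union, replace=False)
        sites = [pool[i] for i in idx]
        inter, rest = sites[:n_inter], sites[n_inter:]
        sets[ki] = inter + rest[:n_a]
        sets[kj] = inter + rest[n_a:]
        keys = {(a, p) for a, p, _, _ in inter}
        shared[ki] |= keys
        shared[kj] |= keys
    for name, ktype in spec.kinases:
        if name in planted_members:
            continue
        cls = "Y" if ktype == "TK" else "ST"
        if ktype == "DUAL":
            pool = pools["Y"] + pools["ST"]
        else:
            pool = pools[cls]
        n = min(spec.n_substrates_per_kinase, len(pool))
        # study bias: each extra compendium multiplies a site's attraction,
        # so adjacent compendia groups differ by a constant degree ratio
        w = np.array([(1.0 + spec.bias_strength) ** nc for _, _, _, nc in pool])
        idx = rng.choice(len(pool), size=n, replace=False, p=w / w.sum())
        sets[name] = [pool[i] for i in idx]
    return sets, shared


def _score_from_tier(
    tier: float, survival: dict[str, float], bands: list[tuple[float, float]],
    rng: np.random.Generator,
) -> float:
    """Map a confidence tier onto a score inside the matching cutoff band.

    ``bands`` lists (lo, hi) score intervals ordered best-to-worst:
    index 0 survives the high level, 1 only medium, 2 only low, 3 none.
    """
    if tier <= survival["high"]:
        lo, hi = bands[0]
    elif tier <= survival["medium"]:
        lo, hi = bands[1]
    elif tier <= survival["low"]:
        lo, hi = bands[2]
    else:
        lo, hi = bands[3]
    return float(rng.uniform(lo, hi))


@dataclass
class SyntheticPredictions:
    raw: dict[str, pd.DataFrame]
    gps_cutoffs: dict[tuple, float]
    gps_cutoff_frame: pd.DataFrame
    truth: dict[str, set]  # kinase -> true substrate keys (acc, pos)


def generate_predictions(
    spec: FixtureSpec, ref: SyntheticReference
) -> SyntheticPredictions:
    """Emit three raw prediction tables plus the GPS-like cutoff table."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 23])
    pools = _site_pools(ref)
    unknown = _unknown_pool(ref)
    kinase_types = {n: t for n, t in spec.kinases}
    sets, shared = _assign_substrates(spec, pools, rng, kinase_types)
    truth = {k: {(a, p) for a, p, _, _ in v} for k, v in sets.items()}

    # per-kinase GPS cutoffs; Y rows sit on a different base than S/T rows,
    # mirroring the separate FPR calibration of tyrosine kinases
    gps_cutoffs: dict[tuple, float] = {}
    cut_rows = []
    for name, ktype in spec.kinases:
        classes = ("Y", "ST") if ktype == "DUAL" else (
            ("Y",) if ktype == "TK" else ("ST",))
        for rc in classes:
            base = float(rng.uniform(4.0, 8.0)) + (2.0 if rc == "Y" else 0.0)
            cuts = {"low": base, "medium": base + 1.5, "high": base + 3.0}
            for level, cut in cuts.items():
                gps_cutoffs[(name, rc, level)] = cut
                cut_rows.append({"kinase": name, "residue_class": rc,
                                 "level": level, "cutoff": cut})
    gps_cutoff_frame = pd.DataFrame(cut_rows)

    score_bands = {
        "networkin_like": [(1.0, 3.0), (0.5, 0.999), (0.3, 0.499), (0.01, 0.299)],
        "phosphopick_like": [(0.0005, 0.02), (0.0201, 0.06),
                             (0.0601, 0.1), (0.1001, 0.25)],
    }

    raw: dict[str, pd.DataFrame] = {}
    for algo in ALGORITHMS:
        arng = np.random.default_rng([spec.seed, 37, ALGORITHMS.index(algo)])
        window = BUILTIN_ADAPTERS[algo].window
        # one tier per substrate for planted-shared sites, per algorithm
        site_tier: dict[tuple, float] = {}
        rows = []
        for name, _ in spec.kinases:
            for acc, pos, res, nc in sets[name]:
                key = (acc, pos)
                exponent = 1.0 + spec.bias_strength * nc
                if key in shared[name]:
                    if key not in site_tier:
                        site_tier[key] = float(arng.random() ** exponent)
                    tier = site_tier[key]
                else:
                    tier = float(arng.random() ** exponent)
                if algo == "gps_like":
                    rc = "Y" if res == "Y" else "ST"
                    base = gps_cutoffs[(name, rc, "low")]
                    bands = [
                        (base + 3.0, base + 6.0),
                        (base + 1.5, base + 2.999),
                        (base, base + 1.499),
                        (base - 3.0, base - 0.001),
                    ]
                else:
                    bands = score_bands[algo]
                score = _score_from_tier(tier, spec.survival, bands, arng)
                seq = ref.proteome.sequence(acc)
                recorded = pos
                if spec.stale_fraction and arng.random() < spec.stale_fraction:
                    recorded = pos + 1
                rows.append({
                    "raw_kinase_name": _alias(name, algo),
                    "accession": acc,
                    "position": recorded,
                    "residue": res,
                    "score": round(score, 6),
                    "peptide": _peptide(seq, pos, window),
                    "prediction_type": "kinase",
                })
        # whole-proteome edges at sites not (yet) known to be phosphorylated
        if spec.unknown_site_fraction > 0:
            n_extra = int(len(rows) * spec.unknown_site_fraction)
            names = [n for n, _ in spec.kinases]
            for _ in range(n_extra):
                name = names[int(arng.integers(len(names)))]
                ktype = kinase_types[name]
                cls = "Y" if ktype == "TK" else "ST"
                pool = unknown[cls]
                if not pool:
                    continue
                acc, pos, res, _ = pool[int(arng.integers(len(pool)))]
                bands = (score_bands.get(algo)
                         or None)
                if algo == "gps_like":
                    rc = "Y" if res == "Y" else "ST"
                    base = gps_cutoffs[(name, rc, "low")]
                    bands = [
                        (base + 3.0, base + 6.0),
                        (base + 1.5, base + 2.999),
                        (base, base + 1.499),
                        (base - 3.0, base - 0.001),
                    ]
                score = _score_from_tier(float(arng.random()),
                                         spec.survival, bands, arng)
                rows.append({
                    "raw_kinase_name": _alias(name, algo),
                    "accession": acc,
                    "position": pos,
                    "residue": res,
                    "score": round(score, 6),
                    "peptide": _peptide(ref.proteome.sequence(acc), pos, window),
                    "prediction_type": "kinase",
                })
        # non-kinase prediction types the type filter must remove
        if spec.non_kinase_fraction > 0:
            n_junk = int(len(rows) * spec.non_kinase_fraction)
            pool = pools["ST"] + pools["Y"]
            for _ in range(n_junk):
                acc, pos, res, _ = pool[int(arng.integers(len(pool)))]
                rows.append({
                    "raw_kinase_name": "SH2_binding_model",
                    "accession": acc,
                    "position": pos,
                    "residue": res,
                    "score": round(float(arng.uniform(0, 1)), 6),
                    "peptide": _peptide(ref.proteome.sequence(acc), pos, window),
                    "prediction_type": "binding_domain",
                })
        df = pd.DataFrame(rows)
        raw[algo] = df
    return SyntheticPredictions(raw, gps_cutoffs, gps_cutoff_frame, truth)


def write_fixture(spec: FixtureSpec, out_dir) -> dict[str, str]:
    """Write every fixture artifact to ``out_dir``; returns name -> path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    ref = generate_reference(spec)
    preds = generate_predictions(spec, ref)
    paths = {}
    p = os.path.join(out_dir, "proteome.fasta")
    with open(p, "w") as fh:
        ref.proteome.to_fasta(fh)
    paths["proteome"] = p
    p = os.path.join(out_dir, "phosphoproteome.csv")
    ref.phospho_frame.to_csv(p, index=False)
    paths["phosphoproteome"] = p
    p = os.path.join(out_dir, "kinase_map.csv")
    ref.kinase_map_frame.to_csv(p, index=False)
    paths["kinase_map"] = p
    p = os.path.join(out_dir, "gps_cutoffs.csv")
    preds.gps_cutoff_frame.to_csv(p, index=False)
    paths["gps_cutoffs"] = p
    for algo, df in preds.raw.items():
        p = os.path.join(out_dir, f"raw_{algo}.csv")
        df.to_csv(p, index=False)
        paths[f"raw_{algo}"] = p
        p = os.path.join(out_dir, f"adapter_{algo}.yaml")
        with open(p, "w") as fh:
            fh.write(BUILTIN_ADAPTERS[algo].to_yaml())
        paths[f"adapter_{algo}"] = p
    return paths
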