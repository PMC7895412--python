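"""Degree statistics, outliers, study-bias tests and cross-algorithm correlations.

Study bias is probed through the number of annotation compendia a phosphosite
appears in: a site present in many independent PTM databases was far more
likely to be part of an algorithm's training data. If predictions were free
of this bias, substrate degree (how many kinases connect to a site at a given
stringency) would be independent of compendia count; a two-sample
Kolmogorov-Smirnov test between each adjacent compendia group says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import Phosphoproteome, SubstrateID
from .stringency import ThresholdedNetwork

SIGNIFICANCE_P = 1e-3


def degree_table(network: ThresholdedNetwork, side: str) -> pd.Series:
    """Degrees of one side of the bipartite network as an id -> degree series."""
    if side == "substrate":
        d = network.substrate_degree()
    elif side == "kinase":
        d = network.kinase_degree()
    else:
        raise ValueError(f"side must be 'substrate' or 'kinase', got {side!r}")
    return pd.Series(d, dtype=int).sort_index()


def degree_outliers(degrees: pd.Series) -> set[str]:
    """Entities whose degree strictly exceeds mean + 2 population SD.

    With constant degrees the SD is zero and nothing is an outlier.
    """
    if len(degrees) < 2:
        raise ValueError("need at least two entities to call outliers")
    vals = degrees.to_numpy(dtype=float)
    mu, sd = vals.mean(), vals.std(ddof=0)
    if sd == 0:
        return set()
    return set(degrees.index[vals > mu + 2 * sd])


@dataclass(frozen=True)
class KSResult:
    group_pair: tuple[int, int]
    n_lower: int
    n_upper: int
    D: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_P


def ks_adjacent_groups(groups: dict[int, np.ndarray]) -> tuple[list[KSResult], list[tuple[int, int]]]:
    """Two-sample KS between each adjacent compendia group's degree sample.

    Groups are compared in increasing compendia order: (g, g+1) for every
    consecutive pair of *observed* group labels. Pairs where either sample is
    empty are untestable and reported separately. Asymptotic p-values.
    """
    if not groups:
        return [], []
    lo, hi = min(groups), max(groups)
    results, untestable = [], []
    for g_lo in range(lo, hi):
        g_hi = g_lo + 1
        a = np.asarray(groups.get(g_lo, ()))
        b = np.asarray(groups.get(g_hi, ()))
        if len(a) == 0 or len(b) == 0:
            untestable.append((g_lo, g_hi))
            continue
        ks = stats.ks_2samp(a, b, method="asymp")
        results.append(KSResult((g_lo, g_hi), len(a), len(b),
                                float(ks.statistic), float(ks.pvalue)))
    return results, untestable


def study_bias_ks(
    network: ThresholdedNetwork, phospho: Phosphoproteome
) -> tuple[list[KSResult], list[tuple[int, int]]]:
    """KS tests of substrate-degree distributions across compendia groups.

    Substrates are grouped by the number of compendia annotating them
    (sites never annotated form their own 0 group). Substrates in the
    network but absent from the phosphoproteome are ignored — they cannot
    occur after filtering.
    """
    degrees = network.substrate_degree()
    groups: dict[int, list[int]] = {}
    for sid, deg in degrees.items():
        sub = SubstrateID.parse(sid)
        nc = phospho.n_compendia(sub.accession, sub.position)
        if nc is None:
            continue
        groups.setdefault(int(nc), []).append(deg)
    arrays = {g: np.asarray(v) for g, v in groups.items()}
    return ks_adjacent_groups(arrays)


def bias_results_frame(results: list[KSResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"group_low": r.group_pair[0], "group_high": r.group_pair[1],
         "n_low": r.n_lower, "n_high": r.n_upper,
         "D": r.D, "p": r.p, "significant": r.significant}
        for r in results
    ])


def degree_correlation(
    net_a: ThresholdedNetwork, net_b: ThresholdedNetwork, side: str
) -> tuple[float, float, int]:
    """Pearson correlation of degrees over entities shared by both networks.

    Returns (r, p, n). Fewer than three shared entities or a zero-variance
    degree vector leaves the correlation undefined and raises.
    """
    da, db = degree_table(net_a, side), degree_table(net_b, side)
    shared = sorted(set(da.index) & set(db.index))
    n = len(shared)
    if n < 3:
        raise ValueError(f"correlation undefined with n={n} shared entities")
    x = da.loc[shared].to_numpy(dtype=float)
    y = db.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: a degree vector is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
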