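import io

import pandas as pd
import pytest

from kinunify.reference import (
    KinaseMap, KinaseMapEntry, Phosphoproteome, ProteinRecord,
    ReferenceProteome, load_phosphoproteome,
)
from kinunify.simulate import (
    FixtureSpec, generate_predictions, generate_reference,
)


@pytest.fixture
def toy_proteome() -> ReferenceProteome:
    # AXXXXXYXXXS... sequences built so specific sites are easy to reason about
    return ReferenceProteome({
        "A1": ProteinRecord("MSAAAAYAAAASTYAAAAAA", gene_name="G1"),
        "A2": ProteinRecord("MYYYYYSSSSSTTTTTAAAA", gene_name="G2"),
        "A3": ProteinRecord("MAAAAAAAAAAAAAAAAAAY", gene_name="G3"),
    })


@pytest.fixture
def toy_kinase_map() -> KinaseMap:
    return KinaseMap([
        KinaseMapEntry("K1", "SRC", "SRC", "", "TK",
                       {"networkin_like": "SRC_nk", "gps_like": "SRC_gps"}),
        KinaseMapEntry("K2", "CDK1", "CDK1", "", "STK",
                       {"networkin_like": "CDK1_nk"}),
        KinaseMapEntry("K3", "DYRK1A", "DYRK1A", "", "DUAL",
                       {"networkin_like": "DYRK1A_nk", "gps_like": "DYRK1A_gps"}),
    ])


@pytest.fixture
def toy_phospho(toy_proteome) -> Phosphoproteome:
    csv = io.StringIO(
        "accession,position,residue,n_compendia\n"
        "A1,7,Y,2\n"        # matches sequence
        "A1,12,S,1\n"
        "A1,13,T,0\n"
        "A1,14,Y,3\n"
        "A2,7,S,1\n"
        "A2,12,T,5\n"
        "A3,20,Y,1\n"
    )
    return load_phosphoproteome(csv, toy_proteome)


def small_fixture(seed: int = 1, **overrides) -> tuple:
    defaults = dict(
        seed=seed,
        n_proteins=40,
        planted_jaccard=(("CDK1", "CK2A1", 0.5),),
        planted_union=150,
        stale_fraction=0.05,
    )
    defaults.update(overrides)
    spec = FixtureSpec(**defaults)
    ref = generate_reference(spec)
    preds = generate_predictions(spec, ref)
    return spec, ref, preds


@pytest.fixture(scope="session")
def pipeline_fixture():
    """One generated study run end-to-end; shared across tests (read-only)."""
    from kinunify.pipeline import run_all
    from kinunify.stringency import builtin_schemes

    spec = FixtureSpec(
        seed=7,
        n_proteins=60,
        planted_jaccard=(("CDK1", "CK2A1", 0.5), ("SRC", "LCK", 0.8)),
        planted_union=200,
        stale_fraction=0.05,
    )
    ref = generate_reference(spec)
    preds = generate_predictions(spec, ref)
    schemes = builtin_schemes(preds.gps_cutoffs)
    results = run_all(preds.raw, ref.proteome, ref.phospho,
                      ref.kinase_map, schemes)
    return spec, ref, preds, results
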