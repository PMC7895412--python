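# kinunify

Unify proteome-scale kinase–substrate prediction datasets onto a common
substrate/kinase reference, filter them against the known human
phosphoproteome, and compare the resulting bipartite networks.

## Who this is for

Phosphoproteomics and network-biology researchers who want to use — or
compare — predictions from several kinase–substrate predictors (e.g.
likelihood-ratio scorers like NetworKIN, FPR-calibrated scorers like GPS,
p-value scorers like PhosphoPICK) without fighting three different kinase
vocabularies, flanking-window conventions, score semantics and proteome
releases. A *substrate* here is always a site: an S/T/Y residue at a
1-based position, identified as `ACC_POS`.

## What it computes

- **Unification**: adapter-driven ingest of raw per-algorithm tables into
  one standardized edge schema (`substrate_id, accession, gene_name, site,
  peptide, kinase, score, algorithm`), with kinase names resolved through a
  global kinase ontology map (TK / STK / dual-specificity, the latter
  counted in both categories).
- **Phosphoproteome filtering**: position match against the reference
  phosphoproteome with an exact peptide-window fallback for stale
  coordinates (all repeat matches retained), then a residue-coherence
  filter (tyrosine kinases keep Y sites, Ser/Thr kinases keep S/T,
  dual-specificity keep all).
- **Stringency thresholding**: per-algorithm low/medium/high cutoff
  schemes, inclusive comparisons, per-kinase cutoff tables for
  FPR-calibrated scores; thresholded networks nest (high ⊆ medium ⊆ low).
- **Network analyses**: coverage/edge ratios, degree distributions and
  outliers (> mean + 2 SD), study-bias Kolmogorov–Smirnov tests across
  annotation-compendia groups, cross-algorithm degree correlations,
  within- and between-algorithm Jaccard similarity
  (J(A,B) = |A∩B| / |A∪B|, significant at J ≥ 0.49 for sets of ≥ 100
  sites at p = 0.001), top-1% match flags, self-match rank CDFs against
  the k/N random-expectation line, and degree-preserving randomization
  nulls.
- **Updates**: proteome release diffing, minimal re-prediction worklists,
  and re-filtering of retained whole-proteome edges against a new
  phosphoproteome.
- **Synthetic studies**: a seeded generator emits every input file kind
  (FASTA, phosphoproteome, kinase map, three raw prediction dialects,
  cutoff tables) with planted overlap, planted study bias and planted
  stale sites, so the whole pipeline is testable offline.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from kinunify import FixtureSpec, generate_reference, generate_predictions
from kinunify import builtin_schemes, run_all, within_matrix, significant_pairs, jaccard

spec = FixtureSpec(seed=1, planted_jaccard=(("CDK1", "CK2A1", 0.5),),
                   bias_strength=0.5, stale_fraction=0.05)
ref = generate_reference(spec)
preds = generate_predictions(spec, ref)
results = run_all(preds.raw, ref.proteome, ref.phospho, ref.kinase_map,
                  builtin_schemes(preds.gps_cutoffs))

res = results["networkin_like"]
print(len(res.standardized), res.audit.n_position, res.audit.n_peptide,
      res.audit.n_unmatched)
# 1254 1073 67 114

low = res.networks["low"]
print({lvl: net.edge_count for lvl, net in res.networks.items()})
# {'low': 1061, 'medium': 815, 'high': 530}

print(round(jaccard(low.kinase_sets["CDK1"], low.kinase_sets["CK2A1"]), 3))
# 0.489
```

Of 1254 standardized edges, 1073 match a known phosphosite at their
recorded position, 67 are recovered through the peptide fallback (the
fixture planted 5% stale coordinates) and 114 sit on sites not in the
phosphoproteome, so they are set aside rather than dropped. Thresholded
edge counts shrink with stringency (nesting), and the planted Jaccard
overlap of 0.5 between CDK1 and CK2A1 is recovered as 0.489 on the
low-stringency network.

The same pipeline is available from the shell:

```sh
kinunify simulate --seed 1 --out fixture/
kinunify refs validate --proteome fixture/proteome.fasta \
    --phospho fixture/phosphoproteome.csv --kinmap fixture/kinase_map.csv
kinunify ingest --algorithm networkin_like --raw fixture/raw_networkin_like.csv \
    --proteome fixture/proteome.fasta --kinmap fixture/kinase_map.csv --out std.csv
kinunify filter --pred std.csv --phospho fixture/phosphoproteome.csv \
    --proteome fixture/proteome.fasta --kinmap fixture/kinase_map.csv \
    --window 11 --out final.csv
kinunify threshold --final final.csv --scheme networkin_like --level high --out net.csv
kinunify compare within --network net.csv --out jaccard.csv
```

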