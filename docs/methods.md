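# Methods

## The problem

Proteome-scale kinase–substrate predictors (likelihood-ratio scorers,
FPR-calibrated sequence scorers, Bayesian p-value scorers) each publish
edges between kinases and site-specific substrates in their own dialect:
their own kinase names, their own flanking-window conventions, their own
score semantics, and coordinates tied to whatever proteome release they
were run against. `kinunify` puts such datasets onto one reference frame so
they can be filtered against the known phosphoproteome and compared.

A *substrate* throughout is a single phosphorylatable residue — an S, T or
Y at a 1-based position in a protein — identified as `ACC_POS` (e.g.
`P00533_1197`), never a whole protein. A *kinase set* at a stringency level
is the set of substrates connected to that kinase by an edge surviving the
level's cutoff.

## Pipeline

1. **Reference loading.** The proteome (UniProt-dialect FASTA) is the
   coordinate authority. The phosphoproteome table carries, per site, the
   number of annotation compendia it appears in (0–5), used later as a
   study-bias proxy; sites whose recorded residue disagrees with the
   reference sequence are kept but flagged stale, because the peptide
   fallback can still place their edges. The global kinase map assigns each
   kinase a common name, a type (`TK`, `STK`, `DUAL`) and per-algorithm
   aliases; dual-specificity kinases count in both the tyrosine and
   serine/threonine categories.
2. **Ingest.** Adapter configs (column names, window length, score
   semantics) describe each raw dialect; rows whose name does not resolve
   through the kinase map's alias index (non-kinase prediction types,
   unmapped names) are partitioned out, the rest are rewritten to the
   standardized schema. No stringency filtering happens here — every tested
   edge is preserved. Counts are conserved at every partition
   (`kept + removed == input`).
3. **Phosphoproteome filter.** An edge is placed by *position* when its
   (accession, position) is a recorded phosphosite and the reference
   residue agrees with the edge residue; otherwise every exact occurrence
   of its padding-stripped flanking peptide is located and each occurrence
   whose center is a recorded site with an agreeing residue becomes a match
   (*peptide* mode; repetitive sequence can produce several rows, all
   retained). Position mode always wins when it applies. Unmatched and
   residue-incoherent edges (TK with S/T, STK with Y) go to sidecar tables,
   never silently away.
4. **Thresholding.** Each algorithm gets a stringency scheme: direction
   (`keep_geq` for likelihoods/scores, `keep_leq` for p-values) and
   low/medium/high cutoffs — 0.3/0.5/1 for the likelihood-ratio scheme,
   0.1/0.06/0.02 for the p-value scheme, and per-kinase cutoff tables
   (extracted at FPR 10/6/2% for S/T kinases, 15/9/4% for Y kinases) for
   the FPR-calibrated scheme, which refuses to run without such a table.
   Comparisons are inclusive, so networks nest: high ⊆ medium ⊆ low.
5. **Analyses.** Coverage and edge counts normalized to the low network;
   substrate/kinase degree tables with outliers called above
   mean + 2 population SD (strict inequality); study-bias two-sample KS
   tests between adjacent compendia groups (asymptotic p-values,
   two-sided, significance at p < 1e-3, the 0-compendia group included);
   Pearson degree correlations over shared entities; Jaccard matrices
   within (symmetric, hierarchically ordered by average linkage on 1 − J)
   and between algorithms (non-symmetric, rows/columns restricted to
   shared kinases); significance at J ≥ 0.49 for sets of ≥ 100 substrates
   (the tabulated p = 0.001 critical value — taken as a constant, not
   recomputed); top-1% cell flags per matrix with boundary ties all
   flagged; self-match rank CDFs with the k/N_B random-expectation line;
   and randomization nulls.

## Update engine

Diffing two proteome releases partitions accessions into
added/removed/changed/unchanged. The worklist (records needing fresh
external predictions) is added ∪ changed; "changed" means any sequence
inequality, which is a safe superset — an optional window-aware refinement
keeps a changed record out of the worklist when no retained edge's flanking
window actually differs. Re-filtering the retained whole-proteome edge set
against a new phosphoproteome is row-for-row identical to rerunning the
filter from scratch, so newly discovered sites surface their pre-computed
edges without touching any predictor.

## Numerical and design choices

- **Positions are 1-based** everywhere a user sees them, matching site
  nomenclature like `Y1197`; conversion to string indices happens only
  inside sequence operations.
- **Peptide search is exact**; terminal windows are padded with `-`, a
  non-amino-acid sentinel, and the pad is stripped before searching with
  the center offset adjusted. A peptide-mode center must carry the same
  residue type as the edge; centers with a different residue are rejected.
- **Inclusive cutoffs** in both directions: an edge exactly at a cutoff
  survives.
- **Outliers use the population SD**; at network scale the sample/population
  distinction is immaterial.
- **Rank ties take the worst rank.** This never inflates apparent
  agreement between algorithms; a kinase whose row is constant ranks last.
- **Randomization null** (`resample`) replaces each kinase's set by a
  uniform same-size sample from the network's substrate universe: kinase
  degrees are preserved exactly, substrate degrees are not. A slower
  double-edge-swap variant (`swap`) preserves both degree sequences.
- **Empty-set Jaccard** is defined as 0 with a warning.
- The self-match rank CDF of randomized network pairs follows the k/N_B
  line only when the two kinase degree sequences are unrelated (candidate
  columns are then exchangeable). With degrees matched kinase-for-kinase
  across the two networks, degree-preserving randomization deviates
  systematically from k/N_B — consistent with the observation that real
  algorithm pairs show no cross-algorithm degree correlation, the null
  fixtures use independent degree sequences.

## The synthetic generator

Real prediction runs take weeks of compute and multi-gigabyte transfers, so
all tests run against generated studies (`kinunify.simulate`). One seed
fully determines every output file. The generator emulates:

- i.i.d.-composition protein sequences (default 50 proteins, mean length
  300) with phosphosites sampled per residue class (defaults S 0.20,
  T 0.15, Y 0.30 of residues) and compendia counts drawn from a categorical
  distribution whose defaults (8% unannotated, 55% in one compendium, ~20%
  in three or more) mirror the composition of real phosphoproteome
  compendia;
- a kinase panel with TK, STK and dual-specificity members and
  per-algorithm aliases, plus decoy non-kinase prediction rows;
- three raw prediction tables whose scores are drawn inside bands that
  straddle each scheme's cutoffs, so an edge's latent confidence tier
  determines exactly which levels it survives (expected survival defaults:
  0.9 / 0.6 / 0.3 at low/medium/high) and nesting holds by construction;
- **planted overlap**: for each planted (kinase, kinase, J*) pair,
  substrate sets are built by inclusion–exclusion on a fixed union
  (|A ∩ B| = round(J*·|A ∪ B|), default union 200). Edges on shared
  substrates of a planted pair share one confidence tier within an
  algorithm — similar kinases score their common substrates similarly — so
  the planted Jaccard survives thresholding instead of being diluted by
  independent thinning;
- **planted study bias**: a site's attraction for edges scales as
  (1 + bias)^n_compendia (constant degree ratio between adjacent compendia
  groups) and its confidence tier is skewed as u^(1 + bias·n_compendia);
- **staleness**: a configurable fraction of raw rows has its recorded
  position shifted by +1 while the peptide stays centered on the true
  site, forcing the peptide-fallback path.

What the generator does *not* emulate: realistic amino-acid composition or
sequence repeats, the true score distributions of any published predictor,
kinase-family structure, or correlated errors between algorithms. Passing
tests therefore demonstrate that the machinery is correct under controlled
conditions, not that any particular predictor is accurate on real data.

## Problem sizes

Tests and the acceptance script run studies of 40–150 proteins with 9
kinases, 150–500 substrates per kinase, planted-pair unions of 200, 100
replicates for Monte-Carlo nulls, and 200–1000 probes for the exactness
oracles. These sizes were chosen so sampling error sits comfortably inside
the asserted tolerances (planted Jaccard ±0.05 at union 200; rank-CDF
deviation ≤ 0.05 over 100 replicates; ≤ 1% false-significant under the
permutation null), as verified by simulation before the tolerances were
frozen.

## Known limitations

- Coordinate lifting is not isoform-aware; suffixed accessions are
  truncated to their canonical record with a warning.
- Peptide placement is exact-match only — no mismatch tolerance, no
  alignment — so heavily diverged sequence between releases is handled by
  the update worklist, not the matcher.
- The 0.49 Jaccard critical value is a constant valid for sets of at least
  100 substrates; pairs below that size are reported as untested rather
  than extrapolated.
- Whether the top-1% flagging of between-algorithm matrices should pool
  cells across matrices is ambiguous in the source analyses; flags here
  are per-matrix.
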