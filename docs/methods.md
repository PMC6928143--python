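# Methods

## Study design being modeled

The pipeline re-implements a meta-analysis workflow in which nine
previously published omics datasets from non-functional pituitary
adenoma (NFPA) research are analyzed one by one against a curated
pathway/interaction knowledge base, and the per-dataset results are
then intersected. The nine datasets fall into three groups: NFPA vs
control (serials 1–4: quantitative transcriptomics, quantitative
proteomics, mapping proteins, nitroproteins), invasive vs non-invasive
NFPA (serials 5–6: quantitative transcriptomics and proteomics), and
control-tissue inventories (serials 7–9: mapping proteins,
nitroproteins, phosphoproteins). Quantitative datasets carry signed
fold-changes; mapping datasets are presence-only.

Fold-changes use the signed convention throughout: a ratio t/c ≥ 1 is
reported as-is and a ratio below 1 as −(c/t), so magnitudes are
symmetric about ±1 and the open interval (−1, 1) is not a valid value.
Values inside that interval are rejected at load time rather than
silently normalized, on the grounds that they indicate a
convention mismatch in the input rather than a small effect.

## Identifier hygiene

Identifiers are canonicalized to uppercase; no alias expansion is
attempted (alias tables are an input concern, not built in). Duplicate
identifiers collapse to one record: for quantitative data the survivor
is the record of largest |fold-change| with its sign retained —
"largest fold-change" read as largest magnitude, since with the signed
convention a raw maximum would systematically discard down-regulation —
and for presence-only data the first occurrence. A dataset identifier
is *mapped* when the knowledge base knows it (graph node or pathway
member); the mapped set after de-duplication is the *network-eligible*
set admitted to enrichment and network construction. The
pathway-eligible set is modeled as identical to the network-eligible
set.

## Over-representation model

For one dataset, let N be the size of the knowledge-base universe
(default: the union of all pathway annotations plus graph nodes), n the
number of eligible molecules inside the universe, K a pathway's size
and k the observed overlap. The enrichment p-value is the one-sided
hypergeometric upper tail P(X ≥ k), computed with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; k = 0 gives p = 1 exactly.
Benjamini–Hochberg adjustment (statsmodels `fdr_bh`) is applied across
the pathways of one dataset — per dataset, not globally, matching the
per-dataset significant-pathway counts the workflow reports — and
significance is adjusted p < 0.05 (strict). Pathways significant in at
least `min_datasets` (default 2) datasets form the shared-pathway
table; cancer-related and panel annotations are input labels (in the
original study these were assigned by literature review, which is not
reproduced here).

## Network construction and scoring

The reference platform's network algorithm is undisclosed; the
implementation is a documented, deterministic stand-in with the same
observable properties (≤ 35 nodes, mixed dataset/filler membership,
connectivity, a −log₁₀ p score, sparse hub structure):

* **Seed**: the not-yet-assigned eligible node of highest full-graph
  degree; lexicographic tie-break.
* **Extend**: repeatedly add the neighboring candidate maximizing
  (number of unassigned eligible molecules newly brought within reach,
  then full-graph degree, then lexicographically smallest name), until
  the network holds `max_size` nodes (default 35) or no connected
  candidate remains. Candidates that are eligible molecules already
  assigned to an earlier network are excluded.
* Eligible molecules are partitioned across networks (each belongs to
  at most one); non-eligible filler molecules may recur.

The network score is −log₁₀ P(X ≥ k) for the overlap of the network's
K nodes with the dataset's n eligible molecules in the N-molecule
universe, 0 when the probability is 1; it is rounded to one decimal
only in reports. A *hub* is a node with ≥ `min_links` (default 5)
neighbors inside the induced subgraph of its network, counting direct-
and indirect-relationship edges alike. Adjacency — not reachability —
is deliberate: within a connected 35-node network reachability would
make nearly every node a hub. Node coverage percentages round half away
from zero (23/35 → 66, 18/35 → 51).

## Cross-dataset hub meta-analysis

Hub occurrences are pooled over all networks. A molecule's *frequency*
is the number of distinct tumor-group datasets (serials 1–6) in which
it is a hub; multiple networks within one dataset count once. Control
serials 7–9 are never counted, matching the serial lists of the
published high-frequency table, every row of which draws only on 1–6.
Records with frequency ≥ 3 are *high-frequency*. The PTM cross-tab
marks a record detected when its identifier appears in the
phosphopeptide quantification with any ratio, and large-change when
the maximum |signed ratio| ≥ 2.5 (threshold inclusive). The
percent-detected summary is truncated toward zero at one decimal —
the convention under which 25/57 prints as 43.8%.

The packaged fixture `data/table1_hubs.tsv` transcribes the published
57-row high-frequency hub table (identifier, frequency, serial list,
detection flag, magnitude-class flag). For the cross-tab the printed
detection classes are encoded as representative maximum magnitudes
(2.5 for the ≥ 2.5-fold class, 1.8 for the reported 1–2.5-fold class);
the counts are then recomputed by the same code path that serves
pipeline output, not copied.

## Phosphopeptide quantification

Inputs are post-search tables; spectral processing and database
searching are out of scope (the original search parameters — ±5 ppm
precursor, ±0.02 Da product tolerance, ≤ 4 missed cleavages — would be
provenance metadata of such tables). Group peak areas are summed over
the two injections per group; the signed ratio is invariant to sum vs
mean because both groups use the same rule. Rows without a positive
area in each group are dropped into a rejects report. Peptide strings
mark methionine oxidation with a trailing `#`; a mark after any other
residue is a format error. Site tokens (`S236`, `S236?`) carry a
confidence flag; ambiguous localizations keep all candidate sites,
flagged non-confident.

The target–decoy FDR threshold scans observed scores from the highest
down; at a cutoff, FDR = (#decoys ≥ cutoff)/(#targets ≥ cutoff),
undefined (skipped) with zero targets. The returned cutoff maximizes
accepted targets subject to FDR ≤ α (default 0.05), taking the lowest
qualifying score on ties so that tied scores at the cutoff are all
included; `None` when no cutoff qualifies.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline is exercised.

* **Universe**: 2000 molecule identifiers (10 reserved hub names +
  generic symbols).
* **Graph**: Barabási–Albert preferential attachment with m = 3 (planted
  hubs occupy the earliest, highest-degree positions), each edge
  labeled direct (60%) or indirect (40%). Around each planted hub an
  extra star-plus-clique is wired: the hub connects to 8 companions and
  the companions to each other, so the hub's induced degree is ≥ 5
  whenever it lands in a network with 5 of them.
* **Pathways**: 300 gene sets of 10–60 members sampled uniformly;
  planted pathways are tagged cancer-related.
* **Datasets**: sizes default to the published inventories
  (280 = 114↑ + 166↓, 50 = 21↑ + 29↓, 218, 12, 346 = 233↑ + 113↓,
  57 = 30↑ + 27↓, 1469, 8, 28). Target datasets of a planted hub always
  contain the hub and 6 companions; target datasets of a planted pathway
  oversample its members at the configured overlap fraction (defaults
  0.4–0.5); remaining quota is drawn uniformly. Fold-change magnitudes
  are log-uniform on [1.5, 10], a typical dynamic range for reported
  differential expression, with signs filling the up/down quotas.
* **Planting targets**: default planted pathways go only into serials
  1, 3 and 5. Over-representation requires the query to be a small
  minority of the background: the control inventory (serial 7) covers
  1469/2000 = 73% of the universe, so its expected pathway overlap is
  already 0.73·K and no planted fraction below that can make it
  enriched — planting "enrichment" there would be statistically
  incoherent. The small datasets (2, 4, 6, 8, 9) have no quota to
  spare beyond their planted hub groups.
* **PTM table**: per planted (gene, peptide, sites, ratio), control
  areas are log-normal around a base intensity and tumor areas equal
  control × ratio (÷|ratio| for negative), each injection perturbed by
  multiplicative exp(N(0, σ²)) noise with σ = 0.1 by default. At σ = 0
  every planted ratio is recovered exactly (up to the 2-decimal area
  formatting). An independent Monte-Carlo oracle for σ = 0.1 put the
  median |log ratio error| at ≈ 0.068 (never above 0.087 in 2000
  replicates of 200 peptides); the test bound is frozen at 0.10.
* Everything is deterministic given the seed; a self-audit at
  generation time verifies every planted hub's wiring guarantee, and a
  `truth.json` ledger records all planted structure.

**What the generator does not emulate**: real gene-symbol vocabularies,
probe-level microarray structure, correlated expression between related
molecules, knowledge-base curation bias, or mass-spectral noise beyond
log-normal peak-area jitter. Passing recovery tests therefore show
that the pipeline's machinery detects the structure it is pointed at
under realistic sizes — not that it would reproduce the original
study's specific networks, which depend on a proprietary knowledge
base.

## Numerical and design choices

* Hypergeometric tails come from scipy's survival function and are
  clipped to (0, 1]; BH from statsmodels. Both are cross-checked in the
  test suite against independent oracles (exhaustive draw enumeration
  for N ≤ 12; a hand-written step-up with cumulative minimum).
* Ties everywhere break lexicographically, making every stage
  deterministic; pipeline reruns are byte-identical.
* Enrichment query identifiers outside the universe are dropped with a
  warning rather than failing the run.
* `aggregate_summary` tolerates missing serials with a warning, so
  partial studies remain summarizable.
* The pipeline config hash in the run manifest covers analytic inputs
  and thresholds but not the output directory.

## Problem sizes

The default synthetic study (2000-molecule universe, 300 pathways,
nine datasets up to 1469 records) runs the full pipeline in roughly
half a minute on one CPU; the acceptance script regenerates the bundle
and repeats the complete analysis at that scale. Unit and property
tests use reduced universes (300–400 molecules) chosen to keep each
oracle exhaustive or near-exhaustive.

## Known limitations

* The seed-and-extend greedy with a 35-node cap can split a planted
  hub's star across two networks when part of the group is chain-pulled
  into an earlier network that fills up mid-group; with the default
  configuration this costs at most one hub-dataset occurrence in ten
  and recovery of planted hubs as high-frequency is ≥ 90% at the
  default seed, not 100%.
* Frequency counting is fixed to distinct datasets; the alternative
  reading (counting panel appearances) is not implemented, as every
  row of the published table equals the dataset count.
* Cancer-related and panel labels are pass-through inputs; no
  literature mining or label inference is attempted.
* Biofunction/tox-function enrichment and pathway activity z-scores are
  out of scope; only canonical-pathway over-representation is modeled.
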