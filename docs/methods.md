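# Methods

## Data model and identity conventions

A catalog bundles five record collections: herbs, compounds,
compound–target interactions, target proteins, and target–pathway
memberships.  Identity keys follow the conventions that make the
counting results well defined:

* **Compounds** are identified by PubChem CID when known, otherwise by
  their normalized name (casefolded, whitespace-collapsed).  Name
  normalization is deterministic and idempotent; it merges
  capitalization variants of one compound but deliberately does *not*
  merge synonyms — the packaged catalog keeps "riboflavin" and
  "vitamin b2" as distinct records because the source tables list
  both, and the published totals are reproduced only under
  transcription-as-printed.
* **Target proteins** are identified by their numeric KEGG `hsa` gene
  id, never by printed protein name: the 5'-nucleotidase appears under
  two distinct ids (4907 and 22978) and must count as two targets.
* **Pathways** are identified by one canonical KEGG name each;
  spelling variants of the same pathway were merged during fixture
  curation, since per-pathway frequencies require one name per
  pathway.

The packaged fixture is a post-screening snapshot: compounds are
flagged `prescreened` (OB/DL not on record) and interactions carry no
prediction scores.  Counting analyses work on it; score-weighted
centrality refuses it with a data error rather than imputing scores.
One transcription discrepancy is preserved deliberately: the source
lists seven compounds for LPCAT1 where its prose says six; the fixture
transcribes the table as printed, so LPCAT1 counts 7.  Three of the
20 herbs have no post-screening compounds and stay in the catalog with
empty compound sets.

## Screening

ADME screening keeps compounds with OB ≥ 30 (percent scale) and
DL ≥ 0.18, both boundaries inclusive; interaction screening keeps
compound–target edges with prediction score strictly greater than 55.
All three thresholds are configurable.  Prescreened compounds (and the
score-absent interactions of prescreened compounds) bypass their
stage.  The score scale is database-dependent; the default cutoff is
meaningful for scores on a 0–100 scale, which is also the scale the
synthetic generator uses.  Screening is idempotent, and raising any
threshold can only shrink the kept sets — both are enforced by tests.

## Tripartite network

The network has three analytic layers — screened compounds (n₂),
target proteins (n₁), pathways — plus the originating herbs as an
annotation layer.  Compounds with no surviving interaction remain as
isolated compound nodes: the centrality sums only over existing edges,
so they cannot influence any score, but they belong to the compound
total and to exports.  Ranked tables break ties deterministically
(count descending, then id/name ascending, numeric ids compared
numerically) so outputs are byte-reproducible.  Pathway frequency
counts *targets* per pathway (the number of target-table rows listing
the pathway), which is what reproduces the published 15/11/10/6 head
of the frequency table.

## Weighted degree centrality

Each target gene j gets

    w_j = ( Σ_k √(p_jk) · e_jk ) / ln( Σ_k e_jk ),

and each pathway i the score S_i = Σ_j w_j · e_ij.  The weight rises
with the number and strength of a gene's compound interactions, with
the square root damping large scores and the ln(·) denominator
discounting promiscuous genes.  The formula is undefined for a gene
hit by exactly one compound (ln 1 = 0).  Two policies are offered:

* `singleton_one` (default): denominator 1 for single-compound genes,
  so w_j = √(p_j1).  The null model applies the identical rule, so
  observed-vs-null comparisons stay internally consistent.
* `strict`: raise an error naming the gene.

A gene with no compound edges has weight 0 (empty sum), and a pathway
with no target edges has S = 0.  Natural logarithm throughout.  The
implementation is verified against an independent brute-force triple
loop over (pathway, gene, compound) applying the indicator definitions
literally, at relative tolerance 1e-9 on 120 random small networks
(observed agreement is at machine precision).

## Null model and significance

Herbs are binned by their catalog compound count.  The published bin
labels leave the counts 10 and 41 unassigned; the bins are closed as
≤10 / 11–20 / 21–40 / ≥41 so that they partition all counts (the
closure is configurable).  Each replicate draws, per bin, the observed
number of herbs uniformly without replacement, applies the same
screening, builds the network and computes all pathway centralities;
R = 10,000 replicates by default.  Replicates use independent
substreams spawned from the master seed (parallel-safe, reproducible).
The observed herbs remain eligible for null draws by default.

Pathways absent from a replicate score 0 there (empty sum), stored
sparsely.  The empirical p-value is the add-one upper-tail estimator
p = (1 + #{S_null ≥ S_obs}) / (R + 1), ties counting against the
observation, so p ∈ [1/(R+1), 1] and is never 0.  Raw exceedance
counts are used rather than a smoothed density estimate.
Benjamini–Hochberg step-up adjustment is applied across the pathways
of the observed network (the hypotheses actually under test), with
significance declared at q < α = 0.05.  The BH step itself is
delegated to `statsmodels.stats.multitest.multipletests` and checked
in the tests against an independently coded step-up.

**A granularity constraint worth knowing:** with m tested pathways the
smallest achievable adjusted value is q_min = m/(R+1).  Whenever
R < m/α − 1, *no* pathway can be declared significant regardless of
effect size.  With m = 54 pathways and α = 0.05 this requires
R > 1079 — comfortably satisfied by the default R = 10,000, but easily
violated in casually scaled-down runs.  The desk-scale studies below
therefore use R = 1000 for power and R = 600 for calibration, the
latter being the smallest R at which a false discovery is even
possible at desk scale (making the calibration bound informative
rather than vacuous).

## Synthetic data

The generator emulates the statistical shape the analysis assumes,
and nothing else (no chemistry, no real database records):

* **Herb→compound catalog**: 8159 herbs drawing from a shared pool of
  43,413 compounds with popularity weights ∝ rank^(−0.8), so a few
  compounds are shared by many herbs (as choline-like compounds are in
  real catalogs) — compound sharing is what couples null replicates,
  so the generator must produce it.  Per-herb compound counts follow
  configurable bin proportions, default (0.40, 0.30, 0.20, 0.10),
  uniform within bin (the top bin spans 41–60).
* **OB/DL**: drawn uniformly on the pass or fail side of the 30 / 0.18
  thresholds with configurable marginal pass probabilities (default
  0.5 each).
* **Scores**: 0–100 scale with configurable mass above 55 (default
  0.35); targets per compound Poisson with mean 3.
* **Target–pathway map**: uniformly random distinct pairs at KEGG
  scale — 325 pathways, 7373 proteins, 29,039 memberships.

The documented desk preset (300 herbs, 800-compound pool, 400
targets, 40 pathways, 194 memberships) scales the membership count
with the product of the two axis reductions, preserving the full
map's bipartite density: each pathway covers ~1.2% of the proteins
and any two pathways overlap in ~1.2% of their members, exactly as at
full scale.  This is the property that keeps the dependence between
pathway centralities realistic; preserving instead the per-protein
membership count (~4 pathways per protein) would give each desk
pathway 10% occupancy and induce a strong common factor across all
pathway scores that the full-scale map does not have.  A scaled
bipartite map cannot preserve both marginals; occupancy is the one
that matters for pathway-level null statistics.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: real catalogs have heavy-tailed,
correlated interaction structure (chemically similar compounds hit
the same targets), curated non-random pathway membership, and OB/DL
values correlated with each other and with target promiscuity.
Conclusions from synthetic runs concern the statistical machinery,
not any biological system.

### Enrichment planting (power probe)

`plant_enrichment` multiplies the *mean* screened compound-degree of a
pathway's member targets by a boost factor, adding high-score (80–100)
interactions round-robin across the members.  Two design points:

* The multiplication applies to the members' mean degree, not to each
  target's own degree — otherwise zero-degree members never receive
  edges and a weakly connected pathway is unboostable in principle.
* New edges attach to the *least herb-shared* eligible compounds of
  the observed herb set.  Planting on popularity-shared compounds
  injects the same signal into the null replicates (which draw herbs
  carrying those compounds), so the planted effect largely cancels
  and the probe measures nothing.

For the same reason, the power study draws its null with the observed
herbs excluded: the probe measures recovery of enrichment specific to
the observed set, and with the observed herbs eligible, ~75% of
matched 20-herb draws contain at least one of them and inherit the
planted edges.

## Study sizes and measured behavior

The statistical test studies run on the desk preset (catalog seed 11,
observed profile (8, 6, 4, 2), i.e. 20 herbs matched to the generator
bins):

* *p-value uniformity*: 20 global-null runs at R = 500; the KS
  distance of the observed-network p-values to Uniform(0,1) falls
  below the exact 1% critical value in 19–20 of 20 runs.
* *FDR calibration*: 200 global-null runs at R = 600; runs with ≥ 1 BH
  discovery stay within 0.05 + 3σ (measured ~1%).
* *Power*: 10 runs, boost 8 applied to the highest-baseline pathway of
  the observed network, R = 1000, observed herbs excluded from the
  null; detection (q < 0.05) in ≥ 9 of 10 runs.
* *Oracle agreement*: 120 random small networks (≤ 8 pathways, ≤ 10
  genes, ≤ 15 compounds); max relative deviation ~3e-16.

All studies, and every pipeline output, are pure functions of their
seeds; the full test suite runs in about half a minute on one CPU.

## Known limitations

* The fixture supports counting analyses only; the study's own
  centrality values are not reproducible without the undeposited
  source extracts, so no fixture-level centrality reference exists.
* The prediction-score scale is treated as given; no rescaling or
  calibration across databases is attempted.
* The null model is purely empirical; no analytic approximation to
  the null density is provided, so p-value resolution is 1/(R+1).
* `w_ij` in the defining sums depends only on the gene j; it is
  implemented as a per-gene weight.  If pathway-dependent gene weights
  were ever intended, this implementation does not capture them.
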