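# Methods

This note documents the models, conventions and numerical choices behind
`ppiconserve`, what the synthetic generators do and do not emulate, and
the known limitations.

## Interaction identity and harmonization

A PPI is an unordered accession pair within one species.  The comparison
key everywhere is `(canonical pair, taxid)` with the pair in lexicographic
order: the same accession pair reported in two species counts as two PPIs,
which is what per-species partitions of shared interactions require.
Self-pairs (homo-oligomers) are legal throughout and count their protein
once in per-species protein tallies.

MITAB ingestion takes the first `db:acc` token of columns 1–2, taxids
from columns 10–11 and the PSI-MI interaction-type identifier from column
12.  Records whose two interactor taxids differ are dropped (and counted):
a single species per PPI is a structural assumption of the downstream
conservation analysis.  The default interaction-type allow-list is
{MI:0915 physical association, MI:0407 direct interaction} — a surrogate
for "physical-only" release variants; real databases do not agree on
which evidence classes are "physical", so the list is configurable and an
empty list disables filtering.

Normalization strips isoform suffixes (`-N`) from UniProt-shaped
accessions only (a conservative regex guard avoids corrupting
non-UniProt identifiers) and then applies a secondary→primary map.
Normalization is idempotent and can only shrink a snapshot.  Readers
accept gzip-compressed files; reader statistics (lines, malformed,
filtered, cross-species, deduplicated) are kept on the snapshot and
logged, since they are part of the analysis record.

## Overlap quantification

Exclusive intersections partition the union of all snapshots by exact
membership signature (the UpSet bar quantity); counts provably sum to the
union size.  The overlap coefficient |A∩B| / min(|A|, |B|) is 1 whenever
one release contains the other, making containment relations visible
(e.g. a curated subset inside a larger aggregator).  A coefficient
involving an empty release is reported as missing, never 0 — a zero would
fabricate disagreement.  The summary median is taken over the strict
upper triangle (each unordered database pair once, midpoint convention on
ties), and databases are displayed in descending-size order.  "Shared by
two databases" supports both at-least-2 (default) and exactly-2 modes,
since the informal phrase is ambiguous.

## Homology clustering

Pairwise identity comes from a Needleman–Wunsch global alignment with
match +1, mismatch 0 and linear gap −1, counting matched positions and
dividing by the shorter sequence length (the CD-HIT denominator; robust
to fragment database entries).  Among co-optimal alignments the match
count can differ under this scoring, so the traceback deterministically
prefers diagonal over up over left.  The row recurrence is vectorized via
a prefix-max identity that is exact for a linear gap penalty.

Clustering is greedy centroid assignment: sequences in decreasing length
(ties by accession), each joining the first representative at identity ≥
threshold, else founding a new cluster.  This is deterministic,
order-stable, and at threshold 1.0 merges exact duplicates only.  An
import path for external member→representative TSVs allows MMseqs2-style
output to replace the internal clusterer; reproducing MMseqs2's
bit-score/coverage semantics is explicitly out of scope.  Snapshots are
remapped onto representatives and the overlap matrix recomputed; the
headline diagnostic is the maximum absolute off-diagonal shift in
percentage points.

## Conservation spans

Proteins map to ortholog-group IDs through an explicit input table; an
accession listed with multiple groups is rejected (and counted) because
the analysis assumes one group per protein at a chosen taxonomic level.
A group-pair's span is the number of *distinct* taxids in which it was
observed — within-species paralog pairs collapsing to the same group pair
do not inflate span.  Sources are provenance only and never affect
group-pair identity.  Whether each species' observation must be
experimental is not resolvable from the inputs; any observation per
species counts.

## Structure-coverage enrichment

A group pair is "solved" if the structure index lists any PDB complex ID
for it; the index is an explicit input and its contents are not
validated, because the mapping from ortholog pairs to PDB chains is a
curation decision upstream of this package.  Per span level (1…cap−1
plus an open `>=cap` bin, cap 6 by default) the solved odds are compared
with the span-1 baseline: OR = (a/b)/(c/d), Haldane–Anscombe +0.5 on all
four cells when any cell is zero (top levels routinely have near-empty
unsolved cells), 95% CI by exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) on the
corrected cells, and a two-sided Fisher exact p-value on the uncorrected
table for reference.  The unsolved listing (span ≥ 2, no evidence) is
sorted by span descending then lexicographically.

## Conserved networks

Edges are group pairs with span ≥ a threshold (default 5), collapsed
across databases, attributed with span, solved flag and sorted PDB IDs.
Self-loops are kept (homo-oligomer group pairs) but never merge
components and count as one edge in tie-breaks.  Components are ranked by
node count, then edge count, then smallest node ID — "largest" is not
otherwise defined, so the tie-break chain is documented and deterministic
under relabeling.  Edge-list TSV export is round-trip safe including
attributes; GraphML is provided for graph tooling.

## Ensemble analysis

All structural analysis is Cα-only.  Superposition is the closed-form
Kabsch SVD fit with proper-rotation enforcement by flipping the smallest
singular vector; inputs of fewer than 3 or collinear points are rejected.
RMSF is computed about an iteratively refined mean structure (initial fit
to the first model, then 2 mean-refinement passes) over a configurable
fit selection (default all residues); the fitting protocol is a
documented surrogate since none is canonical.  Contact frequency uses an
8 Å Cα–Cα cutoff by default — likewise a documented surrogate.

TM-score normalizes by the reference length L_t with
d0 = 1.24·(L_t−15)^⅓ − 1.8 and maximizes over rigid fits using the
standard iterative scheme: seeds on the full correspondence and on
sliding fragments of length L, L/2 and L/4; per seed, residues within a
distance threshold (starting at max(d0+1, 1.5) Å, shrinking by 0.5 Å to a
floor of 1.5 Å) are refit until the retained set repeats; a thread whose
retained set falls below 3 residues stops.  The residue correspondence is
an explicit input — structural alignment search is out of scope.  For
references of 16–18 residues d0 ≤ 0 and scores are not meaningful;
shorter references are rejected outright.  One subtlety worth recording:
the per-residue score term is convex at d = d0, so for configurations
with balanced single-residue displacements of exactly d0 some rigid
motion scores strictly above 0.5; the textbook "all residues at d0 ⇒
TM = 0.5" statement holds for constructions (used in the tests) where
every least-squares fit of the scheme is the identity, such as paired
coincident reference points displaced ±d0.

## Synthetic data: what it emulates

The generators define the study conditions and produce exact truth
records sufficient to compute every downstream statistic independently.

* **Snapshots** — eight releases drawn from a 3,000-pair universe over
  400 proteins in 10 species with 1/rank model-organism skew; sizes
  66/40/30/26/20/8/5% of the universe plus MINT as a strict subset of
  IntAct at 11% of its entries, reproducing a containment pair whose
  overlap coefficient is exactly 1.  The sampled median overlap
  coefficient lands near 0.33.
* **Orthology** — 1,500 group pairs with span distribution
  0.55/0.20/0.10/0.07/0.05/0.03 over spans 1–6, 25% hub reuse of existing
  groups and 2% homodimer pairs; accessions are reused per (group, taxon)
  so hubs share proteins.  Span recovery by the pipeline is exact by
  construction.
* **Structure index** — solved status is Bernoulli with odds =
  baseline odds × planted OR per span level; defaults 1/6/22/80/200/700
  on a 5% baseline, putting the top bin's solved share near 97%.
* **Sequences** — families are stars around i.i.d. uniform centroids: the
  centroid itself is the first (canonical) member and the others carry
  i.i.d. per-site substitutions at the divergence rate.  At 10%
  divergence members sit at ≈0.90 identity to their centroid, so a 0.8
  threshold recovers the planted partition exactly; had every member been
  mutated independently with no canonical entry present, member–member
  identities would straddle 0.8 and greedy clustering would fragment.
* **Ensembles** — two ideal α-helices 30 Å apart; flexible residues get
  isotropic Normal(0, amplitude²) displacement per axis (expected RMSF =
  amplitude·√3), the core is rigid, planted interface contacts are placed
  within 4 Å in an exact fraction of models (those residues carry no
  Gaussian noise, so occupancy is exact), and each model receives a
  random global rigid motion that downstream superposition must undo.

Each generator draws from its own stream (seed + fixed offset), so output
is byte-reproducible and generators do not perturb one another.

What the generators do **not** emulate: literature-curation biases,
evidence-class heterogeneity between databases, real orthology ambiguity
(one-to-many group assignments appear only as rejected rows), sequence
evolution beyond i.i.d. substitution, realistic protein geometry beyond
Cα helices, and correlated (non-isotropic) conformational motion.
Passing recovery tests therefore demonstrates correctness of the
computations under controlled conditions, not robustness to every real
data pathology.

## Problem sizes

Defaults were chosen as compact desk-scale conditions: 3,000-pair
universes, 1,500 group pairs, 180-sequence families, 40–200-model
ensembles of ~110 residues, and 20,000 group pairs per level for
odds-ratio recovery.  At these sizes the full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* PSI-MI XML, mmCIF and live REST/ID-mapping services are not supported;
  all mappings are file inputs.
* The BioGRID-style "physical multi-validated" evidence class has no
  exact PSI-MI equivalent; the allow-list is an approximation.
* Odds-ratio CIs use the normal approximation on the log scale; exact
  conditional intervals are not implemented (Fisher p-values are
  reported).
* TM-score requires a supplied correspondence; insertions/deletions must
  be resolved by the caller.
* The greedy clusterer is quadratic in cluster count × sequences and is
  intended for desk-scale inputs; large-scale clustering should use an
  external tool and the cluster-TSV import path.
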