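# Methods

## Standardization

Library molecules are standardized once, at build time.

**Counter-ion removal.** Multi-fragment inputs keep the fragment with the
most heavy atoms; ties go to the fragment with more carbons, then to the
lexicographically smallest canonical SMILES. This is a deterministic proxy
for "remove the counter ion" that never needs a salt dictionary.

**pH 7.4 ionization.** Full pKa prediction is out of scope. A fixed SMARTS
rule table covers the groups that dominate drug-like chemistry at
physiological pH: carboxylic, sulfonic and phosphonic acids are
deprotonated (every matching acidic O–H, so a phosphonic acid becomes a
dianion); aliphatic primary/secondary/tertiary amines, amidines and
guanidines are protonated; anilines, amides, alcohols, phenols and
aromatic ring nitrogens stay neutral. Each rule is written so an already
transformed site no longer matches, making the whole pipeline idempotent,
and symmetric matches (the two =N positions of a guanidine) are
deduplicated so a site is modified at most once. No claim is made that
these structures match any particular commercial pKa engine.

**Annotation.** Formula (Hill order, charge suffix on ions), HBA = number
of N + O atoms, HBD = number of hydrogens on N or O (the Lipinski
conventions — the counts back the query-time lock filters and only need to
be self-consistent within the tool), plus raw O and N atom counts and a
9-bit vendor mask (default 511 = all vendors).

Query molecules are annotated *as drawn* (counter-ion strip and
canonicalization only): a user sketching neutral adrenaline expects
formula-locked hits to be C9H13NO3 isomers, not isomers of the ammonium
species. The library side is fully standardized.

## Fingerprints

- **MQN** (42 counts) via RDKit's implementation of the canonical
  molecular-quantum-numbers definition: 12 atom counts, 7 bond counts
  (aromatic systems kekulized, since MQN has no aromatic bond class;
  rotatable bonds per the standard acyclic-single-bond definition), 6
  polarity counts and 17 topology counts.
- **SMIfp** (34 counts): literal symbol counts on the canonical SMILES.
  The symbol table is 14 element symbols (Cl and Br count as single
  symbols), `= #`, `( )`, `[ ]`, `+ -`, `@`, `H`, ring-closure digits 1–9
  and `.`. Symbols outside the table (stereo-bond slashes, `%nn` ring
  closures) are ignored. The table is this package's own documented
  choice of 34 symbols; counts on unusual SMILES dialects are therefore
  implementation-defined.
- **sFP** (1024 bits): every linear atom-bond path of 0–7 bonds is
  enumerated (length 0 = a single atom, so methane sets exactly one bit);
  a path token concatenates atom symbols (lowercase if aromatic, with
  formal charge) and bond-order symbols, read in the lexicographically
  smaller direction; SHA-1 of the token modulo 1024 gives the bit. SHA-1
  is used purely as a documented, platform-stable hash. Bit-exact parity
  with other toolkits' path fingerprints is explicitly not a goal — only
  dimensionality, canonicalization invariance and retrieval behavior are
  contracted.
- **ECFP4** (1024 bits): RDKit Morgan generator, radius 2 (bond diameter
  4), folded to 1024 bits, duplicate environment identifiers emitted once.

All four encoders are pure functions of the canonical structure. The
cached `total_sum` always equals the sum of the vector.

## Exact sum-keyed search

One hash table per space, keyed by fingerprint total sum. The pruning
bound |ΣA − ΣB| ≤ CBD(A,B) makes bucket pruning lossless: a query with
total sum s and bound d scans keys [max(0, s−d), s+d] only.

*Max Distance* collects everything within the bound. *Max Count k*
expands rings of buckets at |Δ total sum| = 0, 1, 2, … and stops once the
running k-th smallest CBD is **strictly** below the next ring's lower
bound. The strict comparison matters: hits are ordered by (CBD, id), and
an unexplored ring can still contain an equal-CBD molecule with a smaller
id; stopping at ≤ would return a correct distance profile but not the
deterministic tie-broken hit set a linear scan produces. Both modes cap
output at 1000 hits (Max Distance truncates to the 1000 nearest with a
logged warning).

Vendor matching is a nonzero bitwise AND between the record's and the
query's 9-bit masks. Property filters compare against the query molecule's
own annotation (formula string equality for the formula lock).

## Clustering

Lloyd's algorithm on raw fingerprint vectors, Euclidean distance (means
must be well-defined, which rules out clustering directly on CBD;
"clustering in a fingerprint space" is the operative reading), k-means++
initialization with an explicit seed, iteration cap 100, convergence when
assignments stop changing. An empty cluster is re-seeded with the point
farthest from its current center. The within-cluster sum of squares is
recorded per iteration and is non-increasing. Search and clustering are
independent steps and may use different spaces.

Clusters are renumbered 1..k by decreasing size (ties by smallest member
id) so the labels themselves carry the display order; each cluster's
representative is the member nearest the cluster mean, ties broken by
smaller CBD to the original query, then id. Saved cluster files list each
cluster's representative first.

## Benchmarking

Decks of actives and decoys are ranked by ascending CBD or descending
Tanimoto, ties by id. AUC is the rank-sum (Mann–Whitney) estimator with
midrank tie correction, equal to the trapezoidal area under the tie-grouped
ROC curve. EF_f selects the top ⌈f·N⌉ molecules and divides the recalled
active fraction by f (so EF₁ ≡ 1); boundary ties are resolved by the
deterministic rank order, not fractional counting. Published full-database
enrichment figures depend on external compound collections and are out of
scope; the machinery is validated against exhaustive pair-counting and
closed-form oracles instead.

## Synthetic libraries

The generator crosses ~14 drug-like scaffold templates (benzenes,
pyridines, indoles, piperidines, thiophenes, pyrimidines, benzamides,
sulfonamides) with ~30 substituents in a seeded random order,
standardizes each product and deduplicates on canonical SMILES — chemical
validity is guaranteed by construction, and the grammar yields well over
5000 unique molecules. Vendor masks are drawn uniformly from [1, 511].
What it does *not* emulate: any real catalog's property or scaffold
distributions, stereochemical diversity, or realistic vendor overlap
structure — so passing tests demonstrate correctness of the machinery,
not retrieval quality on commercial chemistry space. Fixture sizes used
by the test suite (5000 molecules for the exactness and dimensionality
suites, 2000 for the retrieval-ceiling check, 300–400 for unit tests) are
the package's choice of desk-scale problem sizes.

`make_blobs` plants k integer-vector clusters in a count space with
inter-center CBD ≥ 200 against intra-blob spread ≤ 12 (margin > 10×), so
exact partition recovery by K-means is a construction guarantee, not a
statistical hope.

## Numerical and degenerate-input choices

- Tanimoto of two all-zero vectors is defined as 0 with a logged warning
  (all-zero fingerprints signal degenerate molecules).
- A Max Distance bound of 0 is legal (identity search); Max Count must be
  ≥ 1 and is clamped at 1000.
- Duplicate library structures under distinct ids are retained.
- Malformed library lines are skipped with a warning carrying the line
  number; an input with zero valid records is an error.

## Known limitations

- The ionization table is rule-based; microspecies, tautomers and
  zwitterion energetics are out of scope.
- SMIfp's authoritative published symbol table could not be consulted;
  the table above is equivalent in spirit but not certified identical.
- sFP/ECFP4 bit positions are stable within this package only.
- K-means with k close to n on data containing duplicate fingerprints may
  produce fewer than k non-empty clusters' worth of distinct content;
  re-seeding keeps k clusters but singleton guarantees need distinct
  vectors.
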