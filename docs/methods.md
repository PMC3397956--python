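# Methods

## The model

`cpinet` treats curated bioactivity data as a bipartite graph G(C, P, E):
chemicals C, proteins P, and an edge (c_i, p_j) whenever a binding constant
(Ki) or inhibitory concentration (IC50) below 10 µM has been measured. All
affinities are stored in µM; nanomolar input is divided by 1000 on ingest.
Each edge carries a potency weight

    w_ij = -log10(affinity_ij / 100 µM)

so the curation window (affinity < 10 µM) maps to w > 1, and 1 nM maps to
w = 5. The 100 µM reference makes every curated weight positive, which the
weighted diffusion requires.

### Diffusion scorers

All three network scorers are two-step mass diffusion. For a query chemical
the initial resource is its row of the adjacency matrix (its link profile);
step one moves resource from proteins to their chemical neighbours, step two
moves it back to proteins. Scores for the query are the final resource on
its unlinked proteins. With row-stochastic allocation matrices M1 (protein →
chemical) and M2 (chemical → protein), the full score matrix is
F = R0 · M1 · M2 where R0 is the matrix of initial resources.

* **NBI**: equal split. R0 = A, M1 = D_p^-1 A^T, M2 = D_c^-1 A, giving
  F = A D_p^-1 A^T D_c^-1 A.
* **EWNBI(λ)**: edge values v_ij = w_ij^λ on edges, zero elsewhere; R0 = V
  and both allocations proportional to v. λ = 0 is coded as an exact
  reduction to NBI (V := A), so the identity holds to the last bit; λ = 1 is
  the fully potency-weighted method. Intermediate λ damps strong edges
  relative to weak ones; negative λ inverts the preference. Any non-positive
  weight on an existing edge is an error when λ ≠ 0.
* **NWNBI(β)**: binary initial resource, allocation to a neighbour
  proportional to (neighbour degree)^β, normalized per sender. The original
  description of the node-weighted variant does not say whether the
  preferential allocation acts at the first step, the second, or both, so
  the step is configurable (`apply_at` in {"step1", "step2", "both"});
  "both" is the default because it treats the two node classes
  symmetrically. β = 0 reproduces NBI exactly for every choice.

Resource is conserved by construction: each chemical's final resource row
sums to its degree (NBI, NWNBI) or weighted strength (EWNBI) whenever no
node it touches is isolated. The test suite checks this, plus exact
equivalence against a deliberately naive per-edge resource-passing
simulator, on every small fixture.

Zero-degree nodes (possible in cross-validation-masked copies) contribute
and receive nothing; scorers emit a warning and the evaluation protocol
excludes the affected links explicitly rather than letting them score zero
silently.

### Similarity scorers

DBSI scores pair (i, j) as the S_c-weighted mean of the other chemicals'
links to j, excluding i itself from the sums — without the self-exclusion a
known link would predict itself. TBSI mirrors this over protein similarity.
Both are convex combinations of 0/1 entries, hence bounded by [0, 1]; a
query with zero similarity to every other node scores 0.

Chemical similarity operates on fixed-length binary fingerprints (166-bit
MACCS keys computed via RDKit, or any precomputed binary matrix) with four
metrics defined from shared-bit counts: Tanimoto a/(a+b+c), Cosine
a/√((a+b)(a+c)), Forbes a·n/((a+b)(a+c)) and Russell–Rao a/n. Pairs sharing
no on-bit score 0 under every metric ("no evidence of similarity"), which
also covers all-zero vectors. Forbes may exceed 1; the other three cannot.

Protein similarity is local Smith–Waterman alignment (Biopython
PairwiseAligner) normalized as SW(i,j)/√(SW(i,i)·SW(j,j)); the diagonal is
exactly 1. Defaults are BLOSUM62 with gap open 10 and extend 0.5 — the
standard choice in drug–target prediction work; the parameters are
configurable and recorded in the matrix metadata, since the normalization
convention affects absolute similarity ranges.

The SAR statistic — Tanimoto overlap of two nodes' interaction-partner sets,
N_ij/(k_i + k_j − N_ij) — quantifies the assumption behind DBSI/TBSI and is
cross-checked in tests against `binary_similarity` applied to partner
indicator vectors.

## Curation

Record-level filters run first, in a fixed order: species (human by
default; optional), affinity strictly below 10 µM, protein sequence present
with ≥ 100 standard residues, chemical organic (contains carbon) with
average molecular weight in [100, 600] Da. Molecular weights come from an
explicit mapping or from SMILES via RDKit; chemicals whose weight cannot be
determined pass that filter unexamined rather than being silently dropped.
Duplicate (chemical, protein) measurements then collapse to the most potent
(lowest affinity) record — the "best evidence" convention; the source
protocol does not state a rule. Finally proteins with fewer than three
distinct active chemicals are removed, once, after all other filters —
not iterated to a fixed point, so the retained counts are reproducible and
the operation is idempotent. The report partitions the input exactly:
removed-per-criterion counts plus retained equals the input count.

## Evaluation protocol

Cross-validation splits the *interaction pairs* (not nodes) uniformly into
k = 10 folds differing in size by at most one; each repetition (default 10)
draws a fresh split from a seed derived deterministically from the master
seed, and reports carry mean ± sd across repetitions plus the seeds used.
Within a fold the test pairs are masked (adjacency and weight zeroed), the
method scores the masked network, and each query's candidate queue is all
opposite-side nodes minus its remaining training links. A test link is
unassessable when either endpoint lost all its training links in the split —
such links cannot be predicted by construction and are counted in
`n_excluded_links` instead of being scored as misses.

Metrics:

* **recall@L** — fraction of assessable test links ranked within the top L
  of their query's queue. Ranking ties break by ascending candidate id, so
  results are deterministic.
* **ER** = R·N/L with N the size of the full opposite node set. This is
  recall relative to the expected recall of a random top-L list among N
  candidates. Using the total N (not N minus the query's known links)
  reproduces the enhancement values published for the reference benchmark
  exactly, so it is the adopted definition; the identity ER = R·N/L holds on
  every report by construction.
* **AUC** — per query, (wins + 0.5·ties)/comparisons over all (test link,
  non-link candidate) score pairs, averaged over assessable queries.
  A pooled variant (comparisons aggregated across queries before dividing)
  is available via `auc_mode="pooled"` for sensitivity analysis; on the
  synthetic benchmark the two differ by < 0.002.

External validation scores compounds absent from the network: each adopts
the link row of its most Tanimoto-similar training compound (ties by
lexicographically smallest id) as a virtual profile — the initial resource
for diffusion methods, the link profile for TBSI — while DBSI uses the
novel fingerprint directly. The compound is ranked against **all** proteins;
its adopted links are not masked, because the inherited neighbourhood is
exactly where its true targets are expected. The similarity-pruned stress
test removes the round(fraction·n) external compounds with the highest
maximum Tanimoto to the training set (ties by id) and re-evaluates.

Parameter sweeps run one cross-validation per grid value with the same
master seed, so splits are paired and differences along the β or λ curve are
attributable to the parameter alone.

## Synthetic data generator

`random_bipartite` plants the structure the methods assume in real
bioactivity data, with all sources of randomness drawn from one seed:

* chemicals and proteins partitioned into contiguous co-binding blocks
  (default 4 blocks over 100 chemicals × 20 proteins, i.e. 25 × 5 per
  block); links Bernoulli with probability 0.4 within a block and 0.01
  between — a strong but noisy community signal;
* potencies log-uniform over 0.001–10 µM (the curation window), so edge
  weights span (1, 5];
* fingerprints with block-owned bits on at 0.9 and noise bits at 0.02, so
  Tanimoto similarity correlates with co-binding (the DBSI signal);
* protein sequences of 160 residues containing a 70-residue block-conserved
  segment (the TBSI signal);
* isolated nodes re-linked inside their block (bounded retries), so
  generated training networks always satisfy the degree ≥ 1 invariant;
* optionally a fraction of whole chemicals (default 0.1) held out with all
  their links, chosen greedily so no protein is stranded — the external
  validation set. Whole compounds are held out, rather than individual
  links, because the external protocol requires compounds absent from
  training.

What the generator does *not* emulate: skewed (scale-free-like) degree
distributions, assay noise, activity cliffs, shared scaffolds across
communities, or correlations between potency and topology. Passing tests on
this generator therefore demonstrates correctness of the algorithms and
recoverability of clean community structure, not performance on real
bioactivity data.

The null configuration used in tests sets within = between = 0.4 (same
density, contrast removed). The density is kept at the within-block value
deliberately: diffusion scores scale with candidate degree and held-out
links are degree-biased, so a sparse null would show a visible
degree-driven AUC offset above 0.5, whereas at p = 0.4 the binomial degree
fluctuations are small relative to the mean and the measured CV AUC is
0.48–0.50.

Under the structured condition (0.4/0.01) the measured 10×10-fold NBI AUC
is 0.86–0.89 across seeds. This is essentially the ceiling of the condition
itself: about 7 % of planted links are between-block noise that no scorer
can recover, and a masked within-block link is statistically exchangeable
with the non-linked proteins of its block; feeding the true generating
probabilities through the same harness as a scorer yields AUC 0.905.

## Numerical and design choices

* Internal affinity unit is µM everywhere; the potency formula is defined
  against 100 µM.
* Node ids are ordered lexicographically at network construction and every
  ranking tie breaks by ascending id, so all outputs are deterministic for
  identical inputs; CV derives per-repetition seeds from one master seed
  below 2^31.
* Scores of known training pairs are computed but masked only at ranking
  time (never zeroed in the matrix), keeping conservation checks valid.
* Division-by-zero situations (isolated nodes, zero similarity rows,
  all-zero fingerprints) yield score 0 rather than NaN, except where the
  input is unusable (all-zero novel fingerprint, empty network), which is
  an error.
* Delimiters of tabular inputs are auto-detected between tab and comma and
  can be overridden; similarity/fingerprint matrices carry an id header row
  and column plus a `# key=value` metadata line.
* Problem sizes in the test suite (networks of 20–100 chemicals, 10-fold CV
  with up to 10 repetitions) are chosen so the full suite runs in seconds
  while still exercising the complete 10×10 protocol; the algorithms are
  dense-matrix based and handle benchmark-scale networks (thousands of
  chemicals, hundreds of proteins) in minutes.

## Known limitations

* Dense numpy matrices throughout: memory grows as N_c × N_p, fine for
  ChEMBL-family-scale networks, wasteful for very large sparse corpora.
* No structure standardization (salts, tautomers) before fingerprinting;
  SMILES are used as given.
* Smith–Waterman similarity is O(n²) pairwise alignments; for hundreds of
  long sequences a precomputed matrix (supported) is the practical route.
* Only the two-hop diffusion of the original methods is implemented — no
  heat spreading, longer walks or matrix factorization baselines.
* The evaluation protocol assumes one network per assay type; mixing Ki and
  IC50 records triggers a warning, not an error.
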