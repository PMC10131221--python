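# Methods

## Scope and model

`ctidp` analyses the *circuit topology* (CT) of residue–residue contact
trajectories, aimed at intrinsically disordered proteins and regions
(IDPs/IDRs) whose conformational ensembles defeat single-structure
descriptions.  The unit of analysis is the unordered contact `(i, j)`,
`1 ≤ i < j`, on a single chain.  Every pair of contacts stands in exactly
one of three relations determined by the order of the four contact sites
along the sequence:

* **series (S)** — the chain intervals are disjoint;
* **parallel (P)** — one interval is strictly nested inside the other
  (directional: the nested contact is in P with its envelope, the envelope
  in P⁻¹ with the nested one; both describe the same arrangement);
* **cross (X)** — the intervals overlap without containment.

When the two contacts share exactly one residue, the relation is
*concerted*: CS for a shared meeting point of serial intervals, CP/CP⁻¹
for a shared endpoint with nesting.  The classifier
(`topology.classify_pair`) is a closed case analysis over the site
ordering; the test suite locks it against an independent set-theoretic
oracle (interval intersection cardinality and containment) exhaustively on
all contact pairs of chains up to 10 residues.

Assumptions: unknotted single chains, 1-based sequential residue
numbering, and a binary notion of contact.  Inter-molecular contacts and
higher-order (3-contact) motifs are out of scope.

## Contact detection and lifetimes

Contacts are called geometrically: at least `min_atom_pairs` (default 1)
heavy-atom pairs within `distance_cutoff` (default 4.5 Å — the common
heavy-atom contact-map convention) and sequence separation
`|j − i| ≥ min_seq_separation` (default 3, excluding trivially adjacent
pairs; configurable down to 1).  Hydrogens are excluded by default.
Frames with a missing residue are rejected rather than imputed.

A contact may form and break repeatedly; its **lifetime** is the length of
its *longest contiguous run* of frames times the frame interval (default
5 ns).  Maximum run — not total occupancy — is used because a contact
contributes most to structure while it persists uninterrupted.

## Lifetime regimes

The lifetime distribution of disordered chains is dominated by a power-law
bulk of short-lived contacts.  `LifetimeRegimeModel.fit()`:

1. estimates the lifetime density with a naive Gaussian KDE on the grid of
   frame-interval multiples, renormalised to unit trapezoidal integral;
2. fits `log density = a·log t + b` by least squares over growing prefixes
   of the grid (first three points, then one point per step) and records
   each prefix's R²;
3. sets the **short-regime** boundary at the first prefix with R² < t₁
   (default 0.8) and the **middle-regime** boundary at the first prefix
   after the R² curve's global minimum with R² > t₂ (default 0.3).
   Contacts beyond the second boundary are **long**-lived: comparable to
   the trajectory duration, their dynamics cannot be observed in full.

Numerical conventions: grid points with zero density are dropped before
the log transform; the R² of a zero-variance fit is defined as 0; if R²
never drops below t₁ the distribution is single-regime and both boundaries
collapse to the maximum lifetime with a warning (likewise when R² never
recovers above t₂).  Boundary assignment is closed on the left:
`lifetime ≤ short_end → short`, `short_end < lifetime ≤ middle_end →
middle`.  An optional mode requires two consecutive sub-t₁ prefixes to
resist single-point noise.

**KDE bandwidth.**  The default bandwidth is one fifth of the frame
interval (1 ns at 5 ns resolution), matching the absolute default of the
naive-KDE implementations commonly used for this analysis.  A bandwidth as
wide as the grid step is a poor choice here: a 5 ns Gaussian kernel on a
5 ns grid bleeds ≈ 61% relative weight into neighbouring grid points and
flattens the steep head of the discrete distribution, which biases the
fitted slope by far more than the sampling error (the slope-recovery
property test quantifies this: with the 1 ns default, the short-window
slope recovers generating exponents in [1.5, 3] within ±0.3 at n = 2000).

**What boundary recovery can and cannot do.**  The prefix-R² drop marks
where the power law stops describing the data — which, at realistic sample
sizes, is where the tail statistics die rather than the true end of the
power-law range.  With 2000 samples of an exponent-2 law on a 5 ns grid,
expected counts per grid point fall below one near 200 ns, so the detected
short-regime boundary lands well before a 1 µs truncation and should be
read as "the range over which the power law is statistically supported".
The suite pins the attainable direction (the boundary never overshoots the
planted break); pinpoint recovery of a distant planted break is not
achievable at that sample size and the corresponding strict check is
expected to fail.

## Topology landscape and evolution score

Each frame maps to counts `(nS, nP, nX)` over unordered contact pairs,
with concerted subclasses folded into their parents (CS→S; CP/CP⁻¹/P⁻¹→P).
Frames with fewer than two contacts are kept at (0, 0, 0) and flagged.
After per-axis min–max scaling to [0, 1] (constant axes map to 0), the
point cloud is segmented with a Gaussian mixture model for each candidate
k in 1..10 (a 0-component mixture is undefined) with 100 initialisations,
convergence tolerance 1e-4, at most 10 000 EM iterations and covariance
regularisation 1e-6.  The winning k optimises the Bayesian Information
Criterion; because sign conventions differ between implementations, the
selector defaults to the standard lower-is-better form and exposes
`bic_direction`.  Cluster centroids are member means; the spread is the
mean Euclidean member–centroid distance.  Clusters are temporally ordered
by the median frame index of their members (median rather than first visit
to resist stray early assignments; ties break by cluster id).

The **evolution score** over the temporally ordered states is

    E = Σ_consecutive pairs  d_ij / (s_i + s_j),

centroid distance over combined spread, summed along the state sequence;
one state gives E = 0, and a transition between two coincident point
states (zero combined spread) contributes 0 with a warning.  This ratio is
the minimal form with the intended qualitative behaviour — translation
invariant, scale invariant under joint rescaling of distances and spreads,
strictly increasing as clusters narrow at fixed centroids — i.e. wide
overlapping states score low, narrow well-separated states visited in
sequence score high.  The per-transition functional is injectable
(`pair_score=`) so alternative empirical definitions can be swapped in.

## Topology strings and similarity

The topology matrix (contacts in canonical order: ascending first site,
ties by second; diagonal excluded) is linearized row by row into a string
over {S, CS, P, CP, X}, inverse labels folded.  Row-wise linearization of
a symmetric matrix accounts for the locality of relations along both rows
and columns.  Strings are coarse-grained by the code S=0, CS=1, P=2, CP=3,
X=4 — entangled relations weigh more than non-interacting ones — averaging
non-overlapping windows of five and rounding half away from zero; a
trailing partial window is averaged too (flag to drop it instead).

Similarity is scored two ways, both symmetric, in [0, 1], and 1 for
identical strings:

* **global** — dynamic-programming global alignment with match 1,
  mismatch 0, gap 0 (so the optimal score counts matched characters,
  equivalently the longest common subsequence), normalised by
  2/(l₁ + l₂);
* **blocks** — recursive longest-contiguous-matching-block ratio
  2M/(l₁ + l₂).  The greedy block recursion is order-dependent, so the
  score is symmetrised by taking the better of the two argument orders.

A protein's representative conformation is the frame of the temporally
last topological state closest (Euclidean, ties to the earliest frame) to
that state's centroid.  Cross-protein similarity tables average pairwise
scores across runs; the diagonal holds the mean cross-run self-similarity
(1.0 for single-run proteins).

## Biophysical annotation

Contacts are annotated with the summed Kyte–Doolittle hydropathy of their
residues (positive = hydrophobic pair), an opposite-charge flag (D/E
negative, K/R positive; His neutral by default with a flag), and a pair
energy from a symmetric 20×20 contact-potential table.  The shipped table
(`data/synthetic_contact_potential.tsv`) is a *synthetic* stand-in built
from hydropathy sums plus charge complementarity; any symmetric 20×20
table in the same format can be substituted.  Sequence disorder propensity
uses the Dunker-school disorder-promoting {A,R,G,Q,S,P,E,K} and
order-promoting {W,C,F,I,Y,V,L,N} sets (H,M,T,D neutral), configurable via
the YAML scales file.  Population comparisons (e.g. short vs middle-life
energies) use rank-sum tests over repeated 300-point subsamples
(20 extractions by default).

## Synthetic generators

`synthetic` produces inputs with known ground truth: contact sets with a
controlled topology bias (serial / nested / crossing / mixed), contact
trajectories with transient contacts whose run lengths follow an exact
inverse-CDF discrete power law (default exponent 2, default 200 frames at
5 ns) plus scaffold contacts persisting for ≥ 60% of frames, Gaussian
landscape blobs emitted in temporal blocks, and companion sequences with
optional charge coupling (K/E placed at scaffold contact sites).  Each
contact is scheduled as a single contiguous run so the planted run length
*is* the maximum lifetime, making the lifetime round-trip exact.  The
generators reproduce statistical structure only: no excluded volume, no
chain connectivity constraints on which contacts may coexist, and no
kinetics.  Passing tests therefore certify the analysis machinery, not the
realism of any force field or sampling protocol.

Desk-scale study conditions used by the test suite and the acceptance
script: chains of ~120 residues, 120–200 frames, 2000-sample lifetime
draws, 300-point landscape clouds, and 10–20 seeds per stochastic check.

## Known limitations

* Contact detection assumes one chain and sequential numbering; multi-chain
  topology is unsupported.
* The regime boundaries inherit the noise sensitivity of prefix-R² fitting;
  they are reproducible under a seedless deterministic pipeline but depend
  on KDE bandwidth and grid step.
* BIC model selection can change k under different covariance
  regularisation; `reg_covar` is exposed for that reason.
* Global alignment of long raw strings is memory-hungry; coarse-grained
  alignment is the default operating mode.
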