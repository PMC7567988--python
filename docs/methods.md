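# Methods

## The classifier

For one residue with predicted secondary-structure probabilities
*(P(H), P(E), P(C))* on the 3-simplex, the diversity index is

DI = (P(H)² + P(E)² + P(C)²)⁻¹ ∈ [1, 3].

DI is the reciprocal Simpson (Herfindahl) concentration; it equals the
exponentiated Shannon entropy exactly at the certain (DI = 1) and uniform
(DI = 3) limits and differs slightly in between — the package asserts the
equivalence only at the limits. A sequence of length *L* yields a DI
trace; the classifier computes window means over every run of `cr`
consecutive residues lying inside positions
`[terminal_exclude + 1, L − terminal_exclude]` and calls the sequence
**metamorphic** iff the maximum window mean strictly exceeds `di_thre`.
A maximum exactly at the threshold is monomorphic: the decision rule is a
strict inequality, so `di_thre = 3` classifies everything monomorphic
(DI never exceeds 3).

Assumptions: fold switching expresses itself as *contiguous* elevated SSP
uncertainty (isolated single-residue spikes at element boundaries are
normal and are averaged away); the SSP program's probabilities are
calibrated enough that their concentration carries signal. Fold switchers
whose two folds share secondary structure violate the first assumption
and are invisible to this method.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `cr` | window length (residues) | 15 (CLI) | upper end of the trained grid; windows comparable to one secondary-structure element run |
| `di_thre` | threshold on max window-mean DI | 2.1 (CLI) | midpoint of the useful range between confident (~1.1) and uniform (3) |
| `terminal_exclude` | residues ignored per terminus | 5 | termini are systematically uncertain for SSP programs regardless of metamorphism; 5 per side matches the length-eligibility arithmetic used in dataset curation |

Training performs an exhaustive grid search, `cr` ∈ {6…15} ×
`di_thre` ∈ {1.40, 1.45, …, 2.60} (250 cells), maximizing the MCC; ties
break toward the smallest `cr`, then the smallest `di_thre`, making the
argmax deterministic. MCC is computed from integer confusion counts with
the standard degenerate-cell convention: if any marginal factor
(TP+FP)(TP+FN)(TN+FP)(TN+FN) is zero the coefficient is defined as 0,
which keeps one-sided cells comparable during the search. Metamorphic is
the positive class throughout.

Cross-validation shuffles once with a caller-supplied seed
(`numpy.random.default_rng`), splits into k chunks differing in size by
at most one (the first `n mod k` chunks take the extra entry), trains by
grid search on k−1 chunks and evaluates on the held-out chunk; summaries
are means and sample standard deviations (ddof = 1) over folds.

### Two-descriptor discriminant

When two SSP programs are available, each sequence maps to a point
(DI_a, DI_b) of window-max diversity indices and the decision boundary
becomes a line, trained again by exhaustively maximizing MCC. Lines are
parameterized by their unit normal at 1° steps over [0°, 180°) with
candidate offsets at the midpoints between consecutive projected points
(plus one offset outside each extreme), both orientations tried. Since
only the induced labeling matters and every distinct labeling achievable
by *some* line at those angles is visited, the search is exhaustive on
the sample up to angular resolution. The line is stored in Hessian
normal form (a, b, c, orientation) because the optimal boundary can be
vertical — a threshold on the first descriptor alone — which has no
finite slope; slope/intercept are exposed as derived properties.

## Reference-set curation

The monomorphic ("single-fold") reference set must not secretly contain
fold switchers, so a parent structure is kept only when every structure
pair in its family (the parent and all deposited "children" with ≥ 50%
sequence similarity) is structurally homogeneous:

* **RMSD rule** — drop the parent if any pair exceeds 2.4 Å Cα RMSD
  after optimal superposition (strict inequality).
* **SS-mismatch rule** — per aligned column, H vs E costs 2, C vs H or
  C vs E costs 1, identity and gapped columns cost 0; the score is the
  maximum cost sum over every 30-column window (full-length sum when the
  alignment is shorter). Drop the parent if any pair scores above 9
  (strict).

Gap columns cost 0 because the mismatch is a sum *over aligned
residues*; the window slides over alignment columns including gaps.
Metadata gates precede the structural rules: deposited ≥ 10 years,
X-ray resolution ≤ 2.2 Å (non-X-ray entries such as NMR pass this gate,
since the criterion filters *X-ray structures* of poor resolution),
more than 30 children, and sequence length strictly between 40 and 250.
An abstract keyword screen (case-insensitive substrings: "fold
switching", "metamorphic", "two folds" and synonyms) removes entries
whose publications already discuss metamorphism. Each drop carries
exactly one primary reason — the first failing criterion — so decisions
audit cleanly.

The metamorphic set applies eligibility rules: sequences shorter than
40 residues are dropped (the windowed classifier needs the largest
window, > 15 residues, plus > 5 excluded residues per terminus), as are
entries whose annotated switch region lies entirely within 20 residues
of either terminus. List revisions (removals for unavailability, short
length or terminal regions; additions of designed pairs and
single-structure candidates) run through an audited edit ledger whose
final count is `base − |removals| + |additions|`.

Superposition uses the least-squares (Kabsch) rotation via
`scipy.spatial.transform.Rotation.align_vectors` on centered
coordinates; the residual is recomputed explicitly after applying the
fitted rotation because the closed-form residual loses precision to
cancellation for near-congruent sets. Fewer than 3 points or collinear
configurations are rejected (the optimal rotation is not unique there).
The test suite checks the implementation against an independent
numerical minimization over rotation vectors from many random starts.

## The synthetic-data generator

The generator emulates the qualitative contrast the classifier relies
on, not real proteins:

* **Monomorphic profiles** — runs (4–12 residues) of one dominant state
  at confidence `mono_confidence` (default 0.95, background DI ≈ 1.11,
  matching a well-determined prediction); at element boundaries, with
  probability `boundary_jump_prob` (default 0.5), one residue splits its
  mass between the flanking states, producing the isolated DI spikes
  that make the *moving average*, not the raw DI, the discriminator.
* **Metamorphic profiles** — the same background plus one contiguous
  segment (default 20 residues) of rows drawn around the simplex point
  with diversity index `meta_segment_di` (default 2.8). The target point
  is taken on the path (p, (1−p)/2, (1−p)/2) from a pure state to the
  uniform distribution, with the closed-form inverse
  p = (1 + √(6/d − 2))/3; points with a zero component cap DI at 2, so
  this path (rather than a simplex edge) is required to reach targets
  above 2. The segment is placed uniformly at random at least 5 residues
  from each terminus so default terminal trimming cannot clip it.
* **Row jitter** — Dirichlet noise with concentration
  `noise_scale × target` (default 300; 0 disables it), the simplest
  perturbation that stays on the simplex and keeps DI a smooth function
  of the spec.
* **Toy structure clusters** — a single-fold-like family (one idealized
  helical Cα trace, members perturbed at σ = 0.25 Å under random rigid
  motions; all pairwise RMSD < 2.4 Å, SS mismatch ≤ 9) and a
  fold-switching-like family mixing helical and extended conformers of
  the same region (at least one pair with RMSD > 7 Å and SS mismatch
  ≥ 23), reproducing the contrast the curation filters must resolve.

Default study conditions: 50 metamorphic + 50 monomorphic sequences of
60–120 residues. Everything is deterministic given the spec's seed.

What passing on synthetic data shows — and does not: the tests prove the
machinery (DI, windowing, grid search, CV, filters) is correct and that
the classifier recovers a separating parameter cell whenever one exists.
They say nothing about real-world classification quality, which depends
on how strongly genuine fold switching perturbs a real SSP program's
confidence, on the PSSM sequence database behind it, and on reference-set
annotation quality; with real SSP outputs over hundreds of sequences the
separation is far from perfect and test MCCs land well below 1.

## Numerical choices and edge cases

* Ingest renormalization: SSP programs print 3-decimal probabilities
  that rarely sum exactly to 1; rows are divided by their own sum, and a
  sum outside 1 ± 0.05 marks the row corrupt. The renormalization
  perturbs DI by < 1e-2 at 3-decimal rounding.
* Window means use a cumulative sum (exact to ~1e-12 at DI scale);
  equality at the threshold is resolved by the strict inequality.
* A sequence whose usable length (after terminal exclusion) is below
  `cr` raises a dedicated too-short error listing the offending
  identifiers, mirroring the length-eligibility rule in curation.
* DSSP 8→3 reduction uses the standard convention H,G,I→H; E,B→E;
  rest→C.
* Dirichlet components with zero target probability get α = 1e-8 (the
  sampler requires strictly positive concentration); such components
  draw values indistinguishable from 0.

## Known limitations

* The classifier reports the argmax window but does not attempt to
  delimit the fold-switching region.
* Parsers cover PSIPRED `.ss2` and the package's normalized TSV; other
  SSP programs' native outputs must be converted externally.
* The curation pipeline consumes locally supplied, pre-aligned records;
  database crawling and parent de-duplication (sequence-similarity
  clustering) are the data supplier's responsibility.
* The discriminant search's 1° angular grid is exact for the induced
  labelings only up to that resolution; in the DI descriptor box
  [1, 3]² this is far finer than the data spacing in practice.
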