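# Methods

`paleophylo` implements the computational stages that sit downstream of a
Bayesian tip-dating (total-evidence) phylogenetic analysis: assembling the
morphology + biogeography supermatrix, reconstructing ancestral states for
discrete characters and ancestral positions for continuous geocoordinates,
counting fossil lineages through time by geographic zone, and summarizing
posteriors and model comparisons. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Time trees

Node ages in Ma before present are the primary representation; branch
lengths are derived as `parent.age − child.age`. This is because every
stage downstream (ancestral reconstruction, lineage counting, grafting of
locality subtrees) reasons in absolute time. Trees read from Newick with
edge lengths are converted to ages given tip dates; the implied root age
must agree across all root-to-tip paths within a tolerance (default
1e-6 Ma). Polytomies are allowed throughout. Labels are matched exactly
and case-sensitively; whitespace is normalized to underscores on read.

## Supermatrix preparation

* **Concatenation with duplication balancing.** Source matrices are
  concatenated into one partition each, with a matrix's character block
  physically repeated `factor` times. Duplication exists solely to
  upweight the likelihood signal of sparsely scored taxa during tree
  search; duplicated columns carry the same partition id, and
  `physical=False` builds the same bookkeeping without repeating columns
  so per-character statistics can use each character once.
* **Invariant-column removal.** A column is dropped iff its set of
  observed (non-missing) states has size ≤ 1, as required by
  ascertainment-bias ("variable") coding. All-missing columns count as
  invariant.
* **Longitudinal zones.** Five contiguous zones tile the circle:
  (0) 130 to −160° (Far East Asia/Beringia, crossing the dateline),
  (1) −160 to −100°, (2) −100 to −25°, (3) −25 to 60°, (4) 60 to 130°.
  Intervals are half-open `[lon_min, lon_max)` west→east, so a boundary
  longitude belongs to the zone whose lower bound it equals — the scheme
  is total and single-valued on (−180, 180]. The zone character is
  appended as a single ordered character in its own partition. A taxon
  whose localities span two adjacent zones takes the zone of its oldest
  occurrence; three or more zones, two non-adjacent zones, or an explicit
  flag (the wide-ranging-extant-species rule) code as `?`.
* **Multi-locality OTU splitting.** A taxon whose localities carry *n*
  distinct (age_min, age_max) ranges becomes *n* OTUs, grouped strictly
  by identical range. The OTU with the oldest range (ranked by age_max,
  then age_min, descending; ties by lowest locality id) keeps the
  original character coding; the others are recoded all-missing, so
  morphological distances are forced onto earliest occurrences. Each
  split taxon yields one clade constraint and per-OTU uniform tip-age
  priors, emitted as a reference MrBayes-style block (not executed).

## Discrete ancestral state reconstruction

Characters evolve under the symmetric k-state Markov (Mk) model on the
time tree. The rate matrix is `Q = r·A − diag(row sums)` where `A` is the
0/1 adjacency of allowed moves — all moves for unordered characters, only
|i−j| = 1 for ordered ones. `r` is therefore the *per-allowed-move* rate
(units: expected attempts per move per Ma), which keeps ordered and
unordered rates comparable. `Q` is symmetric, so transition matrices are
computed by eigendecomposition.

The likelihood uses Felsenstein pruning with per-node rescaling; missing
states contribute all-ones partials, and the root prior is uniform over k
(which is also the stationary distribution of the symmetric model). The
rate is estimated by bounded 1-D maximization on log r (default bracket
1e-6 to 1e3). Marginal node probabilities come from the standard
inside–outside (re-rooting) pass and are exact: they match exhaustive
enumeration over internal-state assignments to better than 1e-10 on random
five-tip trees.

An `mcmc` mode emulates sampler-averaged reconstructions: log-rate
random-walk Metropolis under a uniform prior on (0, 1e3], step adapted
toward ~0.3 acceptance during burn-in, node marginals averaged over the
samples (default 3,500 per character, the setting such toolkits commonly
use). The samplers of those toolkits are not documented in detail, so
this mode emulates their behaviour rather than replicating any one of
them.

**Unambiguous synapomorphies.** A branch is reported for a character when
the parent's and child's modal states both reach probability ≥ p* and
differ. p* defaults to 0.9; the notion of "unambiguous" is never defined
numerically in studies that report such lists, so the threshold is
configurable. Output uses the field's "character.state" notation with
1-based character indices.

## Continuous geocoordinates reconstruction

Ancestral positions are modelled as bivariate Brownian motion of
(longitude, latitude), with increments of covariance `Σ·Δt` (deg²/Ma).
Longitudes are unwrapped about the circular-mean meridian of the tips
before fitting and wrapped back on output, so the dateline-crossing zone
is handled correctly; coordinates are otherwise treated as planar (no
re-projection of latitudes — a documented limitation near the poles).
Geocoordinates reconstructions of this kind are often run with per-branch
variable rates inside an MCMC engine; this package implements the
homogeneous-rate model with closed-form estimators instead, because it is
exactly testable (a per-branch rate-scalar hook is the natural extension
point).

Estimators, with `C` the tip covariance matrix of shared root-to-MRCA path
lengths and `X` the n×2 tip coordinates:

* root (GLS): `â = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹X`;
* rate matrix (REML): `Σ̂ = (X−1â)ᵀC⁻¹(X−1â) / (n−1)`;
* node means: `â + cᵀC⁻¹(X−1â)` with `c` the node's shared-path vector;
* node covariance: `[t_v − cᵀC⁻¹c + (1−cᵀC⁻¹1)²/(1ᵀC⁻¹1)] · Σ̂` — the BM
  conditional variance plus the uncertainty of the estimated root.

Confidence ellipses use the χ² quantile with 2 d.f.: semi-axes are
`sqrt(eigenvalue × χ²₂(c))` along the covariance eigenvectors, at the 68%
level by default — a level chosen to show where roughly two-thirds of the
spatial estimate concentrates; the χ² form is exact for a known Gaussian.
Calibration holds on synthetic data: the true root falls inside the 68%
ellipse in ≈68% of replicates (binomial 99% band, 300 replicates of 200
tips; the acceptance script re-measures this).

### Two-pass tip splitting

Tips bundling several occurrence localities are handled in two passes.

1. **First pass** collapses each multi-locality tip to its spherical
   geocentroid (mean of unit vectors — robust across the dateline) and
   fits the model as-is. Extant species enter as the centroid of their
   range sample points.
2. **Scaling factor.** For each such tip, `s = Δt / d` (Ma/km), where Δt
   is the tip-to-parent age difference and `d` the haversine distance
   (R = 6,371 km; any reasonable geographic metric would serve, so the
   standard one is fixed here) from the tip's centroid to the parent's
   first-pass mean. Zero distances fall back to the median `s` across
   tips (logged).
3. **Two localities**: the terminal bifurcates; both new tips keep the
   original tip age; the new node sits at `tip age + d·s`. The wording
   "scaling that distance to time" is ambiguous between `d·s` and
   `d·s/2`; the full distance is the default and a `half_distance` switch
   selects the alternative.
4. **Three or more localities**: geodesic distance matrix → neighbor
   joining (Saitou–Nei; negative branch lengths clamped to zero with the
   deficit moved to the sibling, standard practice) → rooting at the
   midpoint of the terminal branch of the locality closest to the
   parent's first-pass mean (ties to the lowest locality id) →
   nonparametric rate smoothing to a flush-tipped tree → scaling to time
   → grafting so every new tip sits at the original tip age.
5. **Second pass** refits the Brownian model on the expanded tree, in
   which every tip is a single georeferenceable point.

**NPRS.** Ages minimize the sum over internal nodes of squared
differences between child-edge and parent-edge local rates
(length/duration), with the root term taken as the spread of the root
children's rates about their mean (the unweighted objective). Tips are
flush at relative age 0 and the root is fixed at relative age 1 — the
scale is not identifiable from rates alone. Optimization is Nelder–Mead
over logistic-transformed age fractions, initialized at
subtree-height-proportional ages, which is already exact for clock-like
input (objective 0, ages proportional to depths). All-zero-length input
falls back to uniform interpolation by node depth.

**Subtree time depth.** The smoothed subtree's relative ages must be
mapped to Ma before grafting. The depth is taken as the maximum pairwise
path distance between localities in the NJ tree, times `s`. For two
localities this equals the full inter-locality distance `d`, so the
NJ+NPRS path degenerates exactly to the two-locality rule — the two rules
are mutually consistent by construction. Overshoot past the parent node is
clamped to 1% of the original terminal-branch duration below the parent
(clamp events logged).

## Lineage counts through time

Counts are taken at fixed increments (default 0.5 Ma): an edge
(parent, child) is alive at slice age `t` iff `age(parent) > t ≥
age(child)`. A node exactly at a slice age therefore counts as already
split, and a fossil tip is counted at the slice equal to its age but not
at younger slices; the convention at exact boundaries is otherwise
arbitrary, so it is fixed here and tested. Species
represented by several dated OTUs are first reduced to their latest
occurrence (smallest tip age; ties lexicographic). Branches are assigned
to a zone only when parent and child modal reconstructions agree on it
with probability ≥ p* (tip branches use the tip's coded zone as the child
state); otherwise the branch is ambiguous — a transition is assumed to
have occurred along it — and zone counts plus the ambiguous column sum
exactly to the total at every slice. Percent decline between two counts
offers a floor-to-integer option to match "minimum of X%" phrasing.

## Posterior summaries

* **HDI**: shortest window over the sorted samples containing
  `ceil(mass·n)` points; ties take the leftmost window. Equals exhaustive
  minimal-window search (tested to n = 500).
* **Tip ages**: extracted per sampled tree as root age minus root-to-tip
  path; summarized as median + HDI after discarding a leading burn-in
  fraction (default 10%, the usual proportional convention).
* **Clock-rate prior**: each tip contributes one rate, the non-clock
  root-to-tip path length (substitutions/site) over the elapsed time
  (root age − tip age). One rate per tip, not per branch — the per-branch
  alternatives exist, so this choice is isolated in `implied_rates`. Candidate families {lognormal, gamma,
  exponential, normal} are ML-fitted and ranked by
  `BIC = k·ln(n) − 2·lnL`; the lognormal is reported as mean/sd of log
  rates, the scale on which such priors are specified.
* **Bayes factors**: `ln BF = lnL_A − lnL_B` from marginal
  log-likelihoods, labelled by odds-scale bands (>3 substantial, >10
  strong, >30 very strong, >100 decisive).

## Synthetic data generator

The generator produces the study conditions every stage is tested under:
a forward birth–death tree simulated from a crown age with Poisson fossil
recovery along lineages (λ = 0.12, μ = 0.09, ψ = 0.04 per Ma, crown age
50 Ma — heavy extinction, a few living survivors, tens of fossil tips,
emulating a sea-cow-like clade); discrete characters evolved through the
same Mk transition kernel the reconstruction code exponentiates (rate
0.02/Ma, k = 3, 83 characters of which ~22% ordered, matching the
composition of the empirical matrix); bivariate Brownian coordinates
(Σ = diag(60, 10) deg²/Ma from a root at 0°E 25°N, chosen so tip
longitudes span several zones over 50 Ma the way the empirical occurrence
set spans the globe); and occurrence tables in which ~40% of fossil taxa
carry 2–3 localities jittered ~300 km around the true position, each with
a uniform age range of half-width 1 Ma containing the true age (midpoint
at the true age by default; an asymmetry knob exists for robustness
checks), while extant taxa get 10 range points spread ~1,500 km.
Each fossil recovery is attached as a terminal tip with a positive
pendant branch (the bifurcation sits just above the sample age), matching
how occurrence OTUs enter the empirical matrix as tips rather than
sampled ancestors.

All randomness flows through NumPy's PCG64 generator; a fixed
configuration yields byte-identical files.

**What the generator does not emulate**: real morphological matrices have
correlated characters, ascertainment bias, and highly non-random missing
data; real dispersal is neither homogeneous-rate nor planar Brownian
(coastline-bound, episodic); fossil recovery is not a homogeneous Poisson
process; and posterior tree *distributions* are not simulated, only point
trees. Passing tests therefore demonstrate correctness of the algorithms
under their own model assumptions, and calibration of the estimators when
those assumptions hold — not robustness to their violation on real data.

## Numerical choices and degenerate inputs

* Transition matrices by symmetric eigendecomposition; rows renormalized
  after clipping tiny negative round-off.
* Pruning partials rescaled per node to avoid underflow.
* Rate MLE: bounded Brent on log r, tolerance 1e-8.
* BM fit: one Cholesky-backed solve for all node vectors; a 1e-10 ridge
  is added only if the tip covariance matrix is numerically singular
  (duplicate zero-length pendants).
* NJ tie-breaks take the first minimal pair in row order; rooting ties
  take the lowest locality id; HDI ties the leftmost window; "oldest
  range" ties rank by age_max, then age_min, then locality id — all
  deterministic.
* Split-node ages are clamped to at least 1e-6 and at most 99% of the
  available terminal-branch duration above the tip.
* Problem sizes used by the test suite and acceptance script (5-tip
  enumeration oracles, 40–200-tip calibration trees, 120–300 replicates)
  were chosen so the whole suite completes in well under a minute of
  compute per criterion while keeping Monte-Carlo standard errors small
  relative to the tolerances tested.

## Known limitations

* Homogeneous-rate Brownian motion replaces variable-rates MCMC engines
  for geocoordinates; node uncertainty is conditional on
  Σ̂ and does not propagate rate uncertainty.
* Planar treatment of lon/lat understates distances at high latitude;
  acceptable for the tropical-to-temperate occurrence sets this targets.
* The Mk implementation is symmetric-rates only (no asymmetric ordered
  chains), matching the models the pipeline needs.
* `mcmc` mode re-runs the pruning pass per sample; it is meant for
  per-character reconstruction at the study's scale, not for thousands of
  characters at once.
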