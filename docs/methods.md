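# Methods

`avimast` reimplements, as a tested library, a phylogenetic comparative
analysis of a binary behavioural trait (masturbation presence/absence)
surveyed across bird species: a data-adequacy screen, phylogenetic signal
from a Bayesian binary phylogenetic mixed model, ancestral-state estimation
by stochastic character mapping under a two-state "all rates different"
(ARD) Mk model, and a suite of single-predictor mixed models.  This note
documents the models, their assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Data model

The unit of observation is a *record*: one report (literature account,
expert questionnaire response, or citizen-science report) that a bird of a
given species was or was not observed masturbating, with categorical
covariates (sex, age, wild/captive origin, social housing, rearing,
condition, source) and species-level mating-system flags (social monogamy,
long-term pair bond, lekking, multiple mates, cooperative breeding).
Species-level *presence* follows the survey's classification rule: a single
confirming record classes the species as exhibiting the behaviour.  Record
state frequencies per species are also carried, so intraspecific variation
can enter the tree-based analyses as soft tip priors.  Proportions are
always over records (each row counts once; `n_observed` is carried but not
used as a weight).

Species names are matched between record tables and tree tip labels
case-insensitively with underscores equal to spaces — in practice the
dominant source of data bugs in comparative work.

## Trees

Input is a sample of rooted ultrametric phylogenies (multi-tree Newick or a
Nexus TREES block), e.g. a posterior sample downloaded by the user from a
supertree resource.  Polytomies are resolved arbitrarily into zero-length
branches with a fixed seed (pruning and mapping require binary traversal);
ultrametricity is checked to a relative depth spread of 1e-3, which
tolerates the rounding noise of published supertrees.

For stages that need one tree, the maximum clade credibility (MCC) tree is
the *member of the sample* maximising the sum of log clade frequencies
(equivalently the product of clade credibilities) computed from the whole
sample; ties break to the earliest tree in input order.  Restricting to
sample members matches common practice and guarantees a valid dated tree.

The phylogenetic covariance structure of the mixed models is the matrix A
with A_ij = (root-to-MRCA path length of i and j) / (tree depth) and unit
diagonal — the Brownian-motion correlation structure of an ultrametric
tree.  Non-ultrametric trees trigger a warning and per-tip normalisation
`d(mrca)/sqrt(d_i d_j)`.  A is positive semi-definite by construction and
invariant to uniform branch-length rescaling.

## Adequacy screen (PIR)

Before model fitting, the presence/absence vector is screened with the
phylogenetic imbalance ratio (PIR) of Gardner & Organ: a [0, 1] statistic
in which lower values indicate data more suitable for comparative model
fitting, with values below ~0.1 suggesting parameter estimation is
feasible.  This package operationalises the screen as a likelihood ratio:

    PIR = exp(ll_iid - ll_tree),  clipped to [0, 1]

where `ll_iid` is the maximised log-likelihood of the presence vector under
an iid Bernoulli model (no phylogeny) and `ll_tree` the maximised ARD Mk
log-likelihood on the tree.  A trait whose distribution is strongly
structured by the phylogeny makes the tree model far better than the iid
model and drives the ratio toward 0; PIR < 0.1 means the phylogeny improves
the fit by more than two nats.  A monomorphic trait carries no information
about trait evolution and returns 1.0 with a warning.  The statistic is
deterministic (the ML fit starts from a fixed grid).

## Two-state ARD model

The trait evolves along branches as a continuous-time Markov chain on
{absent, present} with gain rate `a = q01` and loss rate `b = q10`, per
unit branch length.  The transition kernel is closed-form (with s = a + b):
P00(t) = (b + a e^{-st})/s, P11(t) = (a + b e^{-st})/s; s = 0 gives the
identity.  Likelihoods use post-order pruning with per-node max rescaling;
tips enter as probability vectors (degenerate for hard presence calls, or
record frequencies).  Root weighting defaults to the stationary
distribution (b, a)/s for fitting; uniform weights and FitzJohn-style
conditional-scaled weights are available, the latter used for root-state
sampling in stochastic mapping.

ML fitting maximises over log-rates with L-BFGS-B from a fixed 5-point
start grid (deterministic), in a box from e^-14 to 200 expected changes per
tree height.  The upper box matters: with many uncertain (soft) tips the
ARD likelihood has an infinite-rate ridge on which the model degenerates to
an iid fit, and an unbounded optimiser will walk it.  Monomorphic tip data
are detected and returned directly as the boundary solution (rate out of
the observed state = 0) with a warning.  Profile-likelihood intervals
profile one log-rate against the other with a chi-square(1) cutoff.
Rates are estimated per tree by default (matching a workflow of 10 maps on
each tree of a posterior sample); a joint fit across the sample is
available by passing the `TreeSample` to `fit_ard`.

## Stochastic character mapping

One character history = (a) a joint draw of node states — root from the
normalised root partials (conditional scaled likelihoods), children
recursively from `P[s_parent, j](t) * partial_child[j]` — and (b) an
endpoint-conditioned path on every branch.  Paths are drawn by rejection
sampling of forward realisations conditioned on the child state (cap 1000
attempts), falling back to an exact uniformization bridge (jump count from
the Poisson mixture conditioned on the endpoints, jump times uniform,
states from the discrete bridge, virtual jumps dropped).  Per-branch parity
(odd change count iff endpoints differ) is asserted for every sampled path.

Mapping over a tree sample draws `n_per_tree` histories per tree (default
10) with per-(tree, simulation) RNG substreams derived from one master
seed.  The summary records gain/loss counts, the rates used and the root
state per simulation; gains vs losses are compared — both counts and rates
— by a Wilcoxon matched-pairs signed-rank test over simulations (exact
enumeration for <= 25 untied nonzero differences via scipy, normal
approximation with continuity and tie correction otherwise, zero
differences dropped).  Note a structural fact of binary traits: within one
history, `n_gain - n_loss` is determined by the node states alone (each
branch contributes `s_child - s_parent`), so the direction of the
gains-vs-losses comparison is carried by the ancestral reconstruction, not
by the rate asymmetry per se; at stationarity gain and loss fluxes balance
exactly.

## Binary phylogenetic mixed model (pGLMM)

Record-level latent model: `l = mu + x beta + u_species + e`, with
`u ~ N(0, V_phylo A)`, `e ~ N(0, V_resid)` iid per record, and
`P(yes) = logistic(l)`.  Priors follow the analysis this package
reimplements: inverse-Wishart with scale V = 1 and shape nu = 0.002 on each
variance component (scalar case: inverse-gamma(nu/2, nu V/2)) and a diffuse
zero-mean normal (variance 1e10) on fixed effects.  Each model carries at
most one explanatory variable; multi-level factors use treatment coding
with the most frequent level as reference, and records with an unknown
level of the model's factor are excluded from that model only.

Sampling is by Polya-Gamma data augmentation: `omega_i ~ PG(1, l_i)` makes
every conditional conjugate — a joint Gaussian update of (fixed effects,
u), an element-wise Gaussian update of e, and inverse-gamma updates of the
variances.  PG(1, z) is drawn with Devroye's alternating-series method.
The heavy loops are numba-compiled; a chain of 110,000 iterations on ~120
species takes seconds.  Chains are bit-reproducible from their seed.

Chain policy: the full profile is 11,000,000 iterations, 1,000,000 burn-in,
thinning 10,000 (posterior of 1000).  `ChainSettings.desk()` (110,000 /
10,000 / 100) and `.quick()` (11,000 / 1,000 / 10) keep the posterior at
1000 for routine runs; the pipeline's `paper_profile` flag restores the
full settings.  If any parameter's effective sample size falls below 200,
length, burn-in and thinning escalate tenfold, at most twice; a model still
failing its diagnostics is reported with status `"inadequate"`, never
dropped.  The pipeline default allows one escalation (its chains are the
quick profile; results are summaries of 1000 thinned samples either way).

Summaries per parameter: posterior mean, 95% HPD (shortest window over the
sorted samples, ties to the smallest lower bound), pMCMC = twice the
smaller of P(<= 0) and P(>= 0) (printed as "< 0.001" at posterior size 1000
when no sample crosses zero), and ESS.  Phylogenetic signal is the ratio of
posterior means, `mean(V_phylo) / (mean(V_phylo) + mean(V_resid))` — a
ratio of means, not a mean of ratios.

Two statistical caveats are faithfully retained rather than hidden.  First,
with a logistic link and a free residual variance, the latent scale of a
binary model is not identified: the variance components drift upward
together and fixed-effect magnitudes are interpretable only relative to the
latent scale (empirically this is visible as coefficient magnitudes of
hundreds).  The residual variance is sampled under the stated prior by
default (faithful); `fix_residual=1.0` pins it and is the recommended mode
for synthetic benchmarking, where effect sizes are then on the familiar
logistic scale.  Hard clamps at [1e-10, 1e12] on variance draws and a
relative 1e-12 ridge on the precision matrix are numerical guards only,
active in regimes that are already unidentified.  Second, strongly
conserved binary traits induce near-complete separation; a separation check
warns that latent-scale estimates may be extreme.

## Convergence diagnostics

Computed on the stored (thinned) chain: ESS by initial-positive-sequence
autocorrelation summation (capped at n; constant chains report n with a
zero-variance flag); lag autocorrelation (FFT); Geweke z comparing the
first 10% and last 50% window means with batch-means (10 batches) spectral
variances; Heidelberger & Welch's iterative Cramer-von-Mises stationarity
test discarding initial 10% increments, passing when a suffix of at least
half the chain is stationary at alpha = 0.05.  The chain verdict requires
every parameter to meet the ESS floor and pass stationarity; lag-10
autocorrelation above 0.1 is a warning, not a failure.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
offline:

* trees: birth-death trees conditioned on the tip count (default 120
  species, pure birth), unit height, with each terminal branch extended by
  the memoryless waiting time to the next event (the raw simulator stops
  exactly at the n-th birth, which would leave a zero-length cherry);
* tree samples: correlated perturbations of one base tree — a few
  ultrametric-preserving nearest-neighbour interchanges plus lognormal
  node-age jitter — mimicking a posterior sample around a common truth
  (independent draws would make every cross-tree analysis mis-specified);
* traits: forward CTMC simulation from a stationary (or conditioned) root,
  returning the true history so mapping accuracy is measurable;
* records: per species a record count from a shifted negative binomial
  (min 1, mean 2 — matching a ~200-record / 120-species survey);
  covariates from configurable level frequencies (even sex split, mostly
  adult, 70% captive records, no poor-condition records — so the condition
  model is unrunnable, as in the survey); mating-system flags drawn once
  per clade (subtrees of ~10 tips), because mating systems are
  phylogenetically conserved and iid flags would make the models' task
  unrealistically easy; responses from the latent logistic model with
  defaults `V_phylo = 100`, `V_resid = 1` (signal ~0.99 — the regime the
  analysis targets, where the trait is fixed or nearly so within clades)
  and effect sizes of |2| on the latent scale for sex, origin, mating
  system and rearing.

What the generator does *not* emulate: observer and reporting bias
(detection differing by captivity or charisma), taxonomic misidentification,
non-independence of records from one observer, and real supertree
calibration error.  Passing recovery tests on synthetic data therefore
shows the machinery is correct under the stated model, not that the model
is right for any particular survey.

## Scaled-down study sizes

Routine runs and the test suite use reduced sizes chosen to keep each check
statistically meaningful: pruning is verified exactly against brute-force
enumeration on trees of up to 6 tips; rate recovery uses 50 trees of 500
tips; sampler calibration uses 200 replicates of 50 species x 2 records
with a proper N(0, 4) effect prior matched between generation and fit
(a flat prior has no meaningful prior-predictive, so calibration is run at
a proper prior with variance components fixed at their generating values);
signal recovery uses 20 replicates of 100 species x 3 records per regime;
the acceptance script analyses one 120-species study over a 20-tree sample
with 10 maps per tree and quick-profile chains with the residual variance
fixed at 1.  The full-length profile remains one flag away.

## Known limitations

* The PIR screen is a documented likelihood-ratio operationalisation of
  the published statistic's stated properties (range, direction,
  monomorphic behaviour, rough threshold semantics); it has not been
  cross-checked against the reference implementation.
* The free-residual ("faithful") pGLMM mode reports latent-scale
  quantities whose magnitudes are not comparable across runs; use pMCMC
  and signs, or the fixed-residual mode.
* The MCC tree is restricted to sample members; no consensus construction.
* Only two trait states; no hidden-rate or multi-state generalisations.
* Single-chain diagnostics only (no multi-chain R-hat), matching the
  workflow the package reimplements.
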