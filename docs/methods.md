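# Methods

## The model

`mergm` analyses three linked networks observed in community-based systems
interventions:

* **A** — the directed collaboration network among the n members of a
  community steering committee (`A_ij = 1` iff member *i* nominated member
  *j* as a collaboration partner);
* **B** — the causal loop diagram (CLD) of the community's system drivers,
  treated as a directed graph (`B_uv = 1` iff driver *u* has a direct
  causal effect on driver *v*);
* **X** — the bipartite "action" network (`X_iv = 1` iff member *i*
  reports working to improve driver *v*), a single undirected tie variable
  per member–variable pair;
* **Y** — categorical member attributes (organisation type, education
  level, gender).

The multilevel exponential random graph model (MERGM) places a joint
distribution on the two free layers conditional on the fixed CLD and
attributes:

    P_theta(A = a, X = x | B = b, Y = y)
        = (1 / kappa) * exp( sum_Q theta_Q * z_Q(a, x, b, y) )

where each statistic `z_Q` counts (or geometrically smooths) a configuration
— a small subgraph pattern such as a reciprocated dyad, an alternating
k-star, a transitive triangle, or a cross-level four-cycle — and `kappa`
normalises over every possible (a, x) state.  A positive `theta_Q` means the
configuration occurs more often than expected given everything else in the
model.

### The configuration catalogue

Twenty-three effects are registered, grouped by level (see
`mergm.configs.CATALOGUE`):

* **A**: Density, Reciprocity, In2Star, alternating in-/out-stars AinS and
  AoutS, the in/out-degree correlation AinAoutS, alternating transitive and
  cyclic triangles ATT and ACT, and homophily matches Edu_Match, Org_Match.
* **X**: DensityX, alternating member-side and variable-side stars ASA and
  ASB, and ACA, the alternating count of action targets shared by a member
  pair.
* **AX**: ATXAX, the member-level association between collaboration
  activity and action activity.
* **BX**: In2StarBX and Out2StarBX (CLD degree times selection frequency),
  TXBX (one member acting on two causally linked drivers), and
  L3XBXreciprocity (two members acting on a reciprocated CLD dyad).
* **AXB**: L3AXBin (collaboration in-degree x action x CLD in-degree),
  and the four-cycles C4AXBentrainment (collaboration arc i->j with i and j
  acting on drivers joined by a CLD arc oriented u->v), C4AXBexchange (CLD
  arc oriented v->u), and C4AXBreciprocity (reciprocated collaboration dyad
  on a reciprocated CLD dyad).

Counting conventions are fixed explicitly: ordered node tuples, no symmetry
division, each pictured minimal configuration counts exactly 1, and TXBX
counts each *directed* CLD arc once (a reciprocated CLD dyad under one
member contributes 2).  Several interaction forms (AinAoutS, ATXAX, ACA,
L3XBXreciprocity, the C4 family) circulate in the literature only as
pictures; the formulas implemented here are declared in `configs.py` and
validated against an independent brute-force enumeration oracle, not
against any other software's internal forms.  Because the anchoring of ACA
(member pairs versus variable pairs) is genuinely ambiguous in prose
descriptions, both variants are implemented; `ACA` is the member-pair form
and `ACA_variable` the variable-pair form.

Alternating statistics use a damping parameter `lambda > 1`, default 2 —
the long-standing PNet/MPNet convention — configurable per effect.  Missing
attribute values never count as a match (conservative homophily).

### Change statistics

Every statistic implements an exact local change `dz` for toggling one tie,
written in terms of incrementally maintained degree vectors and row/column
slices (never a full re-evaluation).  The change statistics are the
workhorse of sampling and estimation; the suite asserts
`dz == z(present) - z(absent)` to 1e-9 for every effect over random
toggles, and the sampler re-synchronises its running statistic vector
against a full evaluation every 10^6 updates to exclude floating-point
drift (with the default `lambda = 2` the deltas are dyadic rationals and
exact in binary anyway).

## Sampling

`MetropolisSampler` is a single-chain Metropolis tie-toggle sampler over
the joint (A, X) space.  Each update proposes one tie variable and accepts
the toggle with probability `min(1, exp(theta . dz))`.  By default the
proposal distribution is uniform over all free tie variables, so the
A-versus-X mix equals the proportion of A ties among the
`n_A (n_A - 1) + n_A n_B` free variables; a layer that no modelled
statistic touches is frozen at its start state (the model conditions on
it).  Start state defaults to the observed network for inference-related
simulation and to the empty network for pure generation.

`exact_enumeration_moments` sums Boltzmann weights over all `2^m` states of
tie universes with `m <= 20`, returning exact expectations and `kappa`.
It is deliberately intractable beyond toy sizes and serves as the gold
standard: the suite checks MCMC means against it on 3-actor (64-graph) and
3-actor/2-variable joint models to within three Monte-Carlo standard
errors (batch-means estimates, robust to autocorrelation).

## Estimation

`fit` solves the maximum-likelihood moment equation `E_theta[z] = z_obs`
with a three-phase stochastic approximation:

1. **Phase 1** — 500 sampled networks at the initial parameters (density
   effects at the logit of the observed layer density, the rest at zero)
   estimate the statistic variances used as Robbins–Monro scaling.
2. **Phase 2** — 5 subphases of 200 iterations; each iteration advances
   the chain one expected sweep and updates
   `theta <- theta - a * (z_sim - z_obs) / var(z)` with the gain halved
   per subphase (initial 0.1).  The final subphase's iterates are
   Polyak-averaged.
3. **Phase 3** — two polish passes, each drawing 1.5x the phase-3 sample
   size at two-sweep thinning and applying one Newton–Raphson step
   `theta <- theta - Cov(z)^-1 (mean z_sim - z_obs)` (the covariance of
   the statistics is the exponential-family Fisher information); the two
   passes have independent Monte-Carlo noise and are averaged.  A final
   independent sample of 1000 vectors yields the convergence t-ratios
   `t_Q = (mean z_sim,Q - z_obs,Q) / sd(z_sim,Q)`, and standard errors as
   the square roots of the diagonal of the inverse statistic covariance.

A parameter is flagged significant when `|estimate / SE| > 2`.  A fit is
declared converged when every `|t_Q| < 0.1` (configurable).  Effects whose
statistic is constant at zero in both the data and the phase-1 simulation
(e.g. homophily when no two members share a category) are frozen at zero
and reported as *inestimable* rather than dropped; a zero-variance
statistic that does not match its observed value raises an error, as does
a singular phase-3 covariance (the offending collinear statistics are
named).  Degenerate simulation — a density statistic pinned at empty or
complete across a whole phase — also raises.

These schedule details (sample sizes, gains, polish) are this package's
own choices; field-standard software documents no canonical values.
Defaults were sized so that, for desk-scale models, the convergence
t-ratio reflects Monte-Carlo noise rather than optimiser error.

## Goodness of fit

`run_gof` simulates `n_graphs` networks at the fitted parameters (defaults
5000 graphs spaced `total_updates / n_graphs = 10^4` updates apart, i.e.
50 million updates in total) and compares observed statistics with the
simulated distribution through `t = (observed - mean) / SD`.  Fitted
effects must satisfy `|t| < 0.1` (they sat in the moment equation);
auxiliary effects — by default the full 23-effect catalogue plus the
in/out-degree standard deviations and the global clustering coefficient of
A — are adequately reproduced when `|t| < 2`.  A zero simulated SD with a
non-zero deviation is reported as an infinite t and flagged inadequate.

## Synthetic data

The community surveys behind published analyses of this design are not
public, so `synthgen` generates communities at the published scale and is
the fixture factory for every test:

* **CLD**: a directed random graph with a binomial arc count at density
  0.035 (about two arcs per variable, typical of hand-built CLDs) and
  preferential attachment on arc targets (`hub_bias`, default 1) so that
  high in-degree "central" drivers exist — needed to exercise L3AXBin.
  `hub_bias = 0` reduces to uniform placement.
* **Attributes**: independent multinomial draws per attribute; the two
  bundled profiles use the published communities' category frequencies
  (e.g. 14/18 female, 9/18 bachelor's degree for community 1).
* **(A, X)**: an MCMC draw from a MERGM at a declared true parameter
  vector.  The default structural truth is mild reciprocity (1.0) and
  member-side activity spread (ASA 0.5); the two density parameters are
  calibrated by bisection on realised mean degrees until the generated
  network's mean collaboration out-degree and mean actions per member are
  within 15% of the profile targets (7.1 and 5.4 for the community-1
  profile; 6.0 and 10.7 for community 2).  Calibration is monotone in each
  density parameter, and the returned draw itself is required to sit
  within the band.

What the generator does *not* emulate: survey non-response structure
(non-respondents are simply absent), feedback-loop motifs or signed
polarities of real CLDs, correlation between attributes and tie formation
(unless requested through `theta_true`), and any temporal dynamics.
Passing tests therefore certify the machinery — counting, sampling,
estimation, diagnosis — not substantive conclusions about real
communities.

## Numerical choices and limitations

* Statistics are evaluated in float64; oracle agreement is asserted to
  1e-9.  Change statistics for `lambda = 2` are exact dyadic rationals.
* `exact_enumeration_moments` uses a log-sum-exp guard on the weights.
* Estimation and GOF defaults in `RunConfig` use reduced problem sizes
  (e.g. 500 GOF graphs at desk scale); sizes are always explicit
  parameters, and the published-scale protocol (5000 graphs from 50
  million updates) is the library default in `run_gof`.
* The GOF convergence probe at 500 graphs has an irreducible Monte-Carlo
  spread of about 0.045 in t units, so the 0.1 adequacy bar for fitted
  effects is tight for large effect sets at that sample size.
* Parameter recovery is demonstrated for dyad-independent and reciprocity
  models at n = 20; full 17-effect fits at study scale estimate stably but
  near-collinear alternating-star terms (Density/AinS/AoutS/AinAoutS)
  carry large standard errors, exactly as in published tables.
* Single-chain sampling only; multiple chains are a harness concern.
* The model treats B as exogenous and binary; signed causal polarity, CLD
  construction, and model selection automation are out of scope.
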