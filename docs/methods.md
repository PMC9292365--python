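# Methods

`eai` simulates *extended active inference*: discrete-state active
inference agents coupled to a niche that is itself a variational learner of
its agents. This note records the model, the numerical choices, and what
the synthetic worlds do and do not establish.

## The organism side

Each agent carries a discrete generative model over hidden causes η,
sensations s and actions a:

    p(s, η) = p(s | η) p(η)

with a likelihood matrix **A** (one categorical column per hidden state), a
prior **D**, one column-stochastic transition matrix **B**_a per action,
and a preference distribution **C** over outcomes. All information
quantities are in nats.

**Perception** minimizes the variational free energy of a belief q(η):

    F(s, q) = KL[ q(η) ‖ p(η|s) ] − ln p(s)
            = E_q[ −ln p(s, η) ] − H[q]

F upper-bounds the surprisal −ln p(s), with equality exactly when q is the
true posterior. Because the state space is finite and the variational
family is the full simplex, the exact posterior is available by direct
Bayes rule and is used throughout the test suite as a brute-force oracle;
the production path is a damped fixed-point iteration in log space
(`update_beliefs`), whose convergence criterion is the analytically known
optimum F* = −ln p(s) rather than an oracle call. With the default step
size 1 the scheme lands on the optimum in one step; smaller steps descend
monotonically (verified per-iterate in the tests). Defaults: tol 1e-8
nats, max_iter 64.

**Action** scores each policy π (an exhaustively enumerated action
sequence up to the planning horizon, default H = 1, H ≤ 3 supported) by its
expected free energy accumulated over the policy's steps:

    G(π) = Σ_t  KL[ predicted outcomes_t ‖ C ]  +  E[ H(A-column) ]_t
           └────────── risk ──────────┘          └──── ambiguity ────┘

Minimizing ambiguity is maximizing expected accuracy; the epistemic value
of a policy is the complement of its ambiguity and is reported in the
`EFEReport`, not separately optimized. Preferences are floored at 1e-3 so
risk (a divergence) is always finite. Policies pass through a softmax with
inverse temperature γ (precision, default 4) plus an additive log-prior
*deontic* bonus κ·ln p̂(a | location) read off the niche's affordance field
(κ default 2 in the park scenario; κ = 0 recovers a niche-deaf agent and is
the ablation arm). The deontic influence is modelled as a prior over
policies; treating it instead as a modified likelihood is a defensible
alternative we did not take.

**Learning** is conjugate Dirichlet counting: after perceiving, the
posterior increments concentration parameters on the likelihood
(`counts[s, ·] += rate·q`) and the prior. Counts are floored at 1e-6 so
every expected distribution stays proper under decay. 0·ln 0 := 0
throughout; probabilities are clamped at 1e-300 inside logarithms only.

## The niche side

By the symmetry the Markov blanket imposes, the niche is modelled as an
inference machine whose *sensations are the agents' actions* and whose
hidden states are agent profiles. Its free energy,

    F(a, q) = KL[ q(μ) ‖ p(μ|a) ] − ln p(a),

is literally the organism-side functional evaluated on a mirrored
generative model (states = agent types, observations = actions); the
implementation delegates through one adapter (`as_generative_model`), so
every bound/equality contract is inherited and the same test battery runs
against both sides. The surprisal term −ln p(a) is the negative
*affordance*: affordance is the log evidence an action provides for the
niche's model of its agents.

The niche's agent-type hypothesis space is a finite set of preference
archetypes (café-goer, wanderer), each with a global action profile
p(a | type). This discretization keeps exact Bayes available as an oracle;
a continuous parameterization of "organismal priors" is the obvious
extension. Three belief structures coexist on deliberately different
timescales:

* **per-event**: exact posterior p(μ | a) for each observed action, logged
  with its free-energy report;
* **running**: cumulative action log-evidence, so the niche's type
  posterior equals sequential Bayes over the whole action stream (the
  Dirichlet-mean average alone provably stagnates — it is an average of
  per-event posteriors, not a product of likelihoods — and plateaus near
  0.75 where filtering reaches certainty);
* **slow**: a Dirichlet prior over types nudged toward each per-event
  posterior (rate 1), the population-level "who lives here" memory.

**Trace field.** Spatially, the niche keeps Dirichlet concentrations over
(location, action). Deposits add mass; decay multiplies all concentrations
by (1 − rate) per global step (default rate 0.01) — decay leaves the
expected distribution untouched (scale invariance of the Dirichlet mean)
but makes old traces light and hence easy to overwrite, drifting toward
uniform only at the floor. The affordance field is the log of the expected
per-location action distribution: a landscape of invitations whose peaks
are the locally most probable actions. `exp(field)` rows are valid
distributions at all times (enforced).

## The desire-path park

A bounded grid (default 10×10), a start gate, one café cell. Hidden states
of the agent model are the grid cells; observations are the local trace
intensity quantized to three levels — faint / visible / deep, thresholds
15 and 40 on total cell concentration, the minimal non-binary reading of
shallow versus consolidated traces — plus an at-goal flag that overrides
them. A geometric confusion kernel (noise 0.05) spreads observation
probability to adjacent levels, so sensation is not a one-to-one image of
its cause. Transitions are deterministic moves (up/down/left/right/stay);
off-grid moves clamp to staying. Agents know the current observation map
(the likelihood is rebuilt from the live field each global step and shared
by the population); their Dirichlet likelihood counts are still updated as
their own experiential record. Since the start cell is known and
transitions are deterministic, beliefs remain sharp; perception still pays
a surprisal cost through the confusion kernel.

Two calibrations were forced by experiment rather than taste, and both are
stated here as the package's own design:

* **Shallow deposits (0.1/step) vs. consolidation (10/cell).** With unit
  per-step deposits the deontic feedback loop closes on the depositor
  itself: an agent's own fresh trace becomes the dominant cue at its cell,
  policy entropy collapses and the walk freezes before any path exists.
  Trails must therefore deepen mainly when they demonstrably led somewhere:
  when an agent reaches the café, its realized path — loop-erased to the
  final exit action per visited cell, which is how a worn trail records a
  route rather than a meander — receives the consolidation deposit.
* **Salience gating.** Deontic cues only speak where total cell
  concentration reaches the 'visible' threshold. Shallow traces encode
  alternative action-outcome mappings of near-equal probability and carry
  no invitation; without this gate, generations following a luckless first
  cohort lock onto accumulated wander-noise.

With these two rules the default demo (20 agents/generation, 200
steps/episode, 5 generations, archetype mix 0.8 café-goer / 0.2 wanderer)
behaves as intended: the first generation random-walks (median time-to-café
on the order of 130 steps, some cohorts fully censored at 200), successful
walks carve a trail, and by generation 5 the median is near the Manhattan
optimum of 18 with per-location trace entropy on the worn path at ~5% of
the uniform ln 5. Resetting the niche between generations (the uploading
ablation) removes the gain; κ = 0 removes the complexity reduction.

Scheduling is synchronous — all agents act, then the niche decays once per
global step — chosen for bit-level reproducibility; every run is fully
determined by config + seed, and the writers print floats with 12
significant digits so regression diffs are meaningful. Between
generations, beliefs, Dirichlet counts and positions reset while
preferences (the phenotype) and, unless ablated, the niche persist —
inference, learning and niche construction deliberately occupy fast,
medium and slow timescales.

## Derived metrics

* **Joint free energy**: the organism's and niche's totals for the shared
  (s, a) pair simply add (extensivity); the identity is asserted at every
  logged step. Stricter blanket-conditioned formulations exist; the sum at
  matched events is what is implemented.
* **Mutual predictability**: per window (default 50 steps),
  KL[empirical action frequencies ‖ visit-weighted affordance mixture at
  the visited cells]. This direction is always finite (the field is
  strictly positive by the floor). Agents that sample from the field score
  ≈ 0; the series falls as coupling consolidates.
* **Complexity per decision**: mean policy-posterior entropy — the
  counterfactual load of a decision. Cues that tell the agent what to do
  collapse it.

## What the synthetic worlds do not show

The park and burrow worlds are deliberately minimal: deterministic
movement, a single goal economy, no obstacles, no trace transport or
diffusion, no selection or mutation over phenotypes, and a niche whose
type hypothesis space is tiny and correct by construction. Passing tests
establish the internal consistency of the variational machinery and the
qualitative emergence of stigmergic uploading under these idealized
dynamics — not that real pedestrian or earthworm systems are quantitatively
captured. Problem sizes throughout (grid 10×10, 20 agents, 200 steps, 5
generations, 20-seed replications) are the package's demo conditions,
chosen so the full property suite replicates in minutes on one CPU.

## Degenerate inputs and tie-breaks

Observations with zero marginal raise rather than renormalize (they signal
a malformed scenario). KL with a support violation reports the offending
index rather than overflowing. Exact ties in deterministic action
selection break toward the lowest policy index. Empty policy sets, empty
records and empty cell sets are errors, not silent zeros.
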