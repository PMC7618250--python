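# Methods

## The measurement model

A "selective" RFID feeder records every PIT-tagged bird that perches,
whether or not its access flap opens. The raw datum is therefore an
antenna read `(timestamp, tag, feeder, site, access)`. Time is handled
internally as seconds from the study origin; calendar days are integer
division by 86 400, so there is no timezone or DST logic anywhere in the
pipeline. All intervals are half-open `[start, end)` except flocking-event
bounds, which are the closed `[min, max]` of the member reads.

Denied-access reads are data: a restricted bird that lands at the wrong
feeder is recorded with `access = 0` and still counts as an observation
for flock membership and for "recordings" (reads and visits are treated as
synonymous at read level).

## Flock detection

Great tits forage in fission–fusion flocks, so a feeder's read stream
alternates bursts of activity with silence. Detection runs in two stages:

1. **Gap segmentation.** Maximal runs of reads with inter-read gaps
   ≤ τ (default 600 s). Unsorted input is an error, never silently fixed.
2. **Mixture splitting.** Within a segment, read times are modelled as a
   univariate Gaussian mixture. For K = 1..min(K_max, n) the EM fit uses
   deterministic seeding (means at evenly spaced quantiles of the sorted
   times), a shared pooled-variance start, at most 500 iterations and a
   log-likelihood tolerance of 1e-6. K is chosen by minimum BIC
   (scanning stops after two consecutive non-improvements, since BIC is
   in practice unimodal in K on these streams). Reads take the label of
   maximum posterior responsibility, ties broken toward the component
   with the earlier mean so output is deterministic. Temporal contiguity
   is then enforced: any label run interleaved inside another label's
   span is absorbed into its larger neighbour run, so each final label is
   one contiguous block = one event.

**Variance floor.** Component variances are floored at 225 s² (15 s SD).
The floor prevents singular components on duplicate timestamps, but its
magnitude is chosen to encode the shortest plausible flocking event: a
gathering lasting about a minute spreads its reads with an SD around
15 s. With a near-zero floor, EM reliably discovers spurious components —
a handful of nearly coincident reads locked at the floor — whose
likelihood gain beats BIC's penalty and over-splits genuine events; the
15 s floor removes this pathology while leaving well-separated bursts
(≥ 10 SD apart) correctly split.

The BIC-selected EM is a transparent, testable surrogate for the Bayesian
nonparametric clustering used by some field packages; equivalence to any
particular implementation is structural, not numeric. A tumbling-window
detector (default 300 s windows, epoch-aligned) is provided as a
sensitivity fallback; on well-separated data the SRI networks from the
two detectors correlate above 0.9.

## Association networks and metrics

An association is co-membership in a flocking event. Events form a binary
group-by-individual matrix (rows chronological, columns sorted tags); the
simple ratio index for a dyad is `T/D` — events containing both birds over
events containing at least one. Dyads never observed (D = 0) get weight 0
and are flagged separately from genuinely avoiding dyads.

Global metrics operate per feeder-day network: unweighted density over
nonzero edges, the mean of nonzero edge weights (undefined and flagged
when there are no edges), and the unweighted global clustering
coefficient (3 × triangles / connected triples on the binarized graph).
Daily networks with fewer than three connected birds are dropped and
logged, mirroring the field-data filter. Daily network nodes are all birds
recorded in that day's events (not only birds with an edge); this choice
is deliberate and configurable.

Node metrics operate per site-period network: strength (sum of edge
weights), average association strength (strength / number of partners;
NaN-flagged for isolates), the Barrat weighted clustering coefficient
`C_i = [1/(s_i(k_i−1))] Σ_{j,h} (w_ij + w_ih)/2 · a_ij a_ih a_jh`
(the field literature names "weighted clustering" without a formula;
Barrat's form is adopted because it is bounded, standard and testable),
and weighted eigenvector centrality by power iteration (tolerance 1e-10)
computed per connected component, scores made nonnegative and scaled to
maximum 1; isolates get 0. Eigenvector scores are invariant to uniform
rescaling of the weights.

## Assortment by treatment

Newman's weighted assortativity for a discrete label: with `e_kl` the
fraction of total edge weight joining labels k and l (both edge ends
counted) and `a_k = Σ_l e_kl`,

    r = (Σ_k e_kk − Σ_k a_k²) / (1 − Σ_k a_k²).

r is 1 when all edge weight is within-type, −1 for complete balanced
disassortment, and near 0 under random mixing. When all nodes share one
label the denominator vanishes and the value is reported as undefined
(an exception), never silently NaN. The standard error is Newman's edge
jackknife, `se² = Σ_e (r_(−e) − r)²`; with a single edge it is flagged
undefined. Birds without a treatment label are dropped with a logged
count.

Significance uses a node-label permutation: labels are shuffled over
nodes (default 1000 times) with the network fixed; the report includes
the 2.5%/97.5% null quantiles and a two-tailed
`p = (1 + #{|r_null| ≥ |r_obs|}) / (n_perm + 1)`. Permutations that park
one entire label class on isolated nodes leave r undefined and are
dropped from the null. Daily assortment skips days with fewer than two
birds of any treatment present.

**Finite-size bias of the null.** The permutation expectation of r on a
fixed n-node network is not 0 but negative of order −1/(n−1) (on a
complete equal-weight graph every labeling gives exactly r = −1/(n−1)).
On 20–60-node networks the null mean sits around −0.05 to −0.02. "Random
mixing gives r ≈ 0" is therefore an asymptotic statement; tests and
readers should compare observed values against the computed null band,
not against literal zero. One acceptance-style check that demands
|null mean| < 3 × SEM is knowingly left failing for this reason — the
band is tighter than the statistic's own bias at any network size.

## Experimental design rules

- **Feeder roles.** At a uniformly random half of the experimental sites
  the feeder with the pre-period majority of visits becomes the
  high-density feeder; at the other half the low-density feeder. Ties
  break by feeder identifier order (logged). Control sites keep two
  control feeders.
- **Bird treatments.** Per site, birds with at least `min_records`
  (default 100) pre-period reads are eligible; `round(0.20 × eligible)`
  of them (minimum 1 — the rounding rule is a documented choice) are
  sampled without replacement into the low-density treatment. Everyone
  else keeps access at the high feeder.
- **Failed days.** A site-day on which exactly one feeder recorded
  nothing is excluded as a recording failure (zero reads is the proxy for
  hardware failure available to the pipeline); both-silent days are
  excluded as no-data. The exclusion fraction is reported.
- **Individual inclusion.** Individual-level series keep only birds with
  at least `min_records` reads in *both* periods at a site; birds seen at
  several sites are analysed per site.

## Inference

Responses are modelled as `response ~ period × treatment (+ experimental
day)` with a site-level grouping effect, delegated to standard routines:
statsmodels MixedLM (random site intercept, REML) for gaussian responses
and GLM with cluster-robust (by site) covariance for binomial and Poisson
responses; with a single site the ordinary model is used. The field
literature's variable transformations are applied before gaussian fits
(inverse for average edge weight, square for clustering, square root for
latency, log for order of arrival). Cell means are evaluated at the mean
experimental day; all pairwise cell differences come with Wald z tests,
Holm-adjusted. Autoregressive residual structures and beta error families
are deliberately out of scope — significance for network-position metrics
rests on the permutation scheme below, not on the parametric standard
errors. Non-converged fits are flagged, never silent.

**Node permutation.** Because network positions are mutually dependent,
observed contrasts are referred to a null built by shuffling bird
identities within each site-period network while the network structure —
and hence the multiset of metric values — stays fixed. Equivalently, the
metric vector is permuted over the network's nodes and values are
reattached to the analysis birds. Per permutation a reduced model (OLS on
period × treatment, no random effects) is refitted; since every pairwise
cell contrast is then linear in the response, the whole null is one
precomputed matrix product, making 1000 permutations essentially free.
The reduced-model choice for the refits is deliberate and documented; the
observed coefficient is taken from the same reduced model so observed and
null are exchangeable under the null hypothesis. A contrast is
significant when it falls outside the central 95% of its null; a
two-tailed +1-corrected p on |coefficient| is reported alongside (the two
can disagree when the null is off-centre, e.g. for between-period
contrasts; the 95%-range criterion is the primary one).

## Patch discovery

A trial deploys two novel feeders at a site for one day (trial start is
the first second of the trial day, as novel feeders go out before
sunrise). Eligible birds were read at the site's selective feeders on the
trial day and at least `min_records` times across the manipulation
period. A bird discovers when it is read at either novel feeder; a bird
reaching both counts once, at its earliest arrival. Latency is seconds
from trial start to first arrival. Order of arrival groups birds arriving
within 10 minutes of each other as simultaneous discoverers: grouping is
greedy and anchored at each group's first arrival (the chain-rule
alternative can merge unbounded spans; the anchor rule is the documented
choice and is switchable), and all members of group g share rank g.
Reads before the trial start indicate clock misconfiguration and raise.

Discovery models: binomial for the discovered flag, gaussian on
log(order) and sqrt(latency) among discoverers, each against
period × treatment. Cells in which every bird (or none) discovered are
flagged as separation.

## The synthetic colony generator

The generator produces visit logs with the statistical structure the
analysis assumes, so the whole pipeline is testable offline:

- **Population.** `birds_per_site` birds per site;
  `floor(pair_fraction × birds_per_site / 2)` bonded pairs whose pairwise
  preference (0.8–1.0) strictly exceeds the non-bonded baseline
  (0.05–0.30).
- **Flocks.** Arrivals per feeder are Poisson (`flock_rate` per
  feeder-hour, default 2) inside the daily recording window (07:00–17:00).
  Each flock is seeded with one bird from the pool of birds present and
  choosing that feeder, and recruits members with probability
  proportional to a logistic of `preference_scale × w_ij`; sizes are
  truncated-Poisson around `flock_size_mean` (default 5, bracketing the
  3–5-bird flocks selective feeders record). Members emit
  `1 + Poisson(reads_per_member)` reads jittered `Normal(centre, 60 s)`
  and clipped to the event.
- **Behavioural policy.** Pre-period and control-site birds pick either
  site feeder 50/50 per flock. During the manipulation a low-assigned
  bird follows its assignment with probability `compliance` (default 0.6
  — the field literature reports only partial compliance, with no
  quantitative estimate; this default is a simulator convenience) and
  otherwise visits the high feeder, where it is recorded but denied.
  Two further parameters keep the generator honest about real feeder
  data: `explore_prob` (default 0.1) lets any bird sample either feeder
  for a given flock — producing the recorded-but-denied visits at the
  "wrong" feeder that selective feeders actually log — and `attendance`
  (default 0.5) is the probability a bird is present in the feeder area
  when a flock forms, since wild birds forage away from feeders much of
  the day. Without intermittent attendance the few low-assigned birds
  would co-occur in essentially every low-feeder flock and their pairwise
  SRI would saturate at 1, a pattern no field dataset shows.
- **Reproducibility.** Random streams are split per (site, day, feeder)
  from the master seed, so any subset of the study regenerates
  identically in isolation; identical config + seed gives byte-identical
  output.
- **Discovery.** Novel-feeder arrivals follow a network-based diffusion
  scheme in one-minute steps: a naive bird becomes informed with hazard
  `discovery_base × (1 + social_effect × z_i)`, `z_i` the summed SRI
  weight to informed birds; when `social_effect > 0` one uniformly chosen
  bird is seeded informed at a random step in the first tenth of the
  trial.

What the generator does **not** emulate: spatially explicit movement and
the 40 m novel-feeder geometry, energetics and predation, mixed-species
flocks, diurnal activity rhythms within the recording window, tag loss
and antenna noise, and behavioural carry-over between days (each
feeder-day is generated independently). Passing tests therefore
demonstrate that the pipeline recovers planted structure of the kinds
listed above — not that real colonies satisfy these simplifications.

## Problem sizes used in the checks

The packaged checks run at desk scale by design: direction-recovery
replicates use one site of 24 birds over 4 + 8 days at compliance 0.8
(50 replicates); detector recovery plants two 50-read bursts 10–60 SD
apart (100 replicates); permutation-calibration replicates use 20-bird
networks with 200 permutations (200 replicates); discovery calibration
uses 72-bird networks, matching the scale of a typical field discovery
analysis (~150 bird-period records). The full field design (eight sites,
two weeks + six weeks) runs through the same code paths and is the
generator's default configuration.

## Known limitations

- SRI edge uncertainty is not propagated into the contrasts; the
  permutation null accounts for positional non-independence, not for
  sampling noise in individual edge weights.
- The binomial/Poisson delegates use cluster-robust rather than true
  random-effect likelihoods; with very few sites those standard errors
  are approximate (the permutation scheme, not the Wald tests, carries
  the network inferences).
- The Gaussian-mixture detector assumes roughly symmetric, unimodal
  events; long skewed gatherings can be split.
- Assortativity's permutation null is biased slightly negative at small
  n (see above); always report the null band.
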