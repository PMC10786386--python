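# Methods

This note documents the models, conventions and design choices behind
`carepath`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Event-log model

The observational unit is a clinical interaction: patient id, care setting
(`ED` or `MHOA`, the adjacent short-stay Mental Health Observational Area),
presentation mode, a minute-precision timestamp, the agents involved, the
information systems accessed, and an optional action (referral or
discharge). Timestamps use the `DD/MM/YYYY HH:MM` 24-hour dialect and are
timezone-naive; trajectories are assumed not to cross midnight, which the
synthetic generator enforces by capping inter-interaction gaps.

A patient's presentation mode is taken from their first record; later
non-empty values must agree or validation fails. Multi-valued presentations
(`Ambulance+Police`) are a single categorical level. Trajectory time is the
span from first to last observation — an observation-window quantity, not a
length of stay; a single-record trajectory has time 0 by definition.

"Types of clinical staff" counts distinct staff *names* in the catalog (two
different interactions with `Nurse` count once). An alternative reading —
counting roles — would give smaller values; the catalog keeps staff
identities at the level the log records them.

**Cohort summaries.** Medians are reported with an empirical 95% interval,
the 2.5th–97.5th percentile of the per-patient values. A bootstrap interval
*of the median* would be narrower; the percentile-of-data convention was
chosen because it describes cohort spread and degrades gracefully for
degenerate cohorts (all-equal values collapse the interval to a point).

**MHOA exclusion.** Patients observed only in the short-stay observation
area are removed before trajectory statistics and interaction-network
construction (the unit serves a different function from the ED proper);
patients seen in both settings keep all records. The trajectory *transition*
network, by contrast, uses the combined data.

## Interaction network

Nodes are agents and information systems observed at least once; an
unweighted, undirected edge records at least one observed interaction for
the pair. Records list two or more parties; each record is expanded to the
clique over its agents plus every agent–system pair. The clique convention
treats an interaction among listed parties as pairwise interaction of all of
them — the natural reading when edges encode "ever interacted", and the only
one available when the log does not sub-structure multi-party records.

Forbidden edges are excluded everywhere, by construction rather than
post-hoc filtering: (a) system–system, (b) system with any non-staff agent,
(c) psychiatry-restricted system (PSOLIS, EDYHO) with staff outside the
Emergency Psychiatry team. Interaction frequency is kept as node metadata
for reporting only; no computation uses it.

## Centrality, efficiency, communities

Standard unweighted definitions (degree; closeness; pair-dependency
betweenness with exact Brandes path counting; global efficiency as the mean
inverse shortest-path length, with unreachable pairs contributing zero).
Conventions that needed fixing:

* **Betweenness normalization** divides by `(n−1)(n−2)/2`, the number of
  node pairs a given node could lie between (undirected, endpoints
  excluded). Values then live in [0, 1].
* **Closeness on disconnected graphs** uses the Wasserman–Faust scaling:
  within-component closeness times the fraction of other nodes reachable.
  The observed network is connected, so this matters only after node
  removal, where it keeps per-doctor closeness comparisons finite.
  Isolated nodes have closeness 0.
* **Communities** come from greedy agglomerative modularity maximization
  (networkx's implementation), which is deterministic for a given graph.
  On graphs small enough to enumerate every partition, the test suite
  checks the greedy result against the exhaustive modularity maximum.

These are standard measures, so the implementation delegates to networkx;
correctness is guarded by an independent brute-force oracle in the test
suite that enumerates all simple paths on graphs of up to 8 nodes.

## Null model: constrained connected double-edge swap

One attempt selects two distinct edges (i, j), (u, v) uniformly at random
with random orientation and proposes the rewiring (i, u), (j, v). The swap
applies only if the four endpoints are distinct, neither proposed edge
exists, neither is forbidden, and the graph remains connected; otherwise the
graph is unchanged and the attempt still counts. Degree sequences are
therefore preserved exactly. The connectivity check exploits a local
property: the rewired graph can only disconnect if i and j separate, so a
single reachability query suffices, checked (and reverted on failure) after
every applied swap rather than batched.

An ensemble runs 1,000 shuffles of 20,000 attempts each by default; the
scaled-down configuration used in the automated checks is 100 shuffles ×
20,000 attempts, which mixes the ~60-edge study-scale network thoroughly
(roughly 1,400 of 20,000 attempts succeed). RNG streams are spawned per
shuffle from one master seed via `numpy.random.SeedSequence`, making
ensembles bit-reproducible and parallelizable.

**Percentile test.** A node's observed betweenness is located within its own
ensemble distribution (not the pooled distribution over all nodes — the
pooled alternative would conflate degree classes). Exact ties get
average-rank handling so floating-point equality cannot flip the flag; the
flag threshold is the 95th percentile.

## Node removal and greedy restoration

Removal impact is `Δg% = 100·(g_after − g_before)/g_before` on the same
node set minus the removed node, plus the closeness change for every doctor
(the clinicians whose access to information the analysis cares about).

Restoration removes the compromised node, then repeatedly adds the candidate
edge maximizing the efficiency gain. Greedy choice stops being provably
optimal at the first tie, so the implementation enumerates: it maintains the
set of all prefixes attaining the step-wise (lexicographically) maximal
efficiency trace, branching over tied choices with a memoized efficiency
cache keyed by edge subset. For small candidate sets this equals brute-force
search over every ordering (tested up to 4 candidates); tie groups are
reported exactly, and a `max_sequences` cap guards fully symmetric candidate
sets whose optimal-order count grows factorially. The default candidate set
is every absent doctor–doctor pair spanning the two ED teams, overridable.
Ties are resolved to the lexicographically smallest edge for the canonical
reported sequence; the full optimal set is also returned.

## Referral prediction model

For each referred patient, a cumulative network state is built per
interaction (same node universe and forbidden policy as the full network)
up to and including the referral-precipitating interaction; the final state
is the positive example. States are vectorized as `n` node bits followed by
`n(n−1)/2` upper-triangle edge bits. The upper-triangle convention follows
from the feature-space cardinality `2^(n(n−1)/2+n)`: the full adjacency
would double-count symmetric entries.

The classifier is a hand-implemented Bernoulli naive Bayes with Laplace
smoothing `P(x_f=1|c) = (count + α)/(n_c + 2α)`, α = 1, priors from class
frequencies, posterior computed in log space, and exact posterior ties
resolved to class 0 (no referral) — the conservative default. The test
suite cross-checks posteriors against both an explicit product-form oracle
and scikit-learn's independent implementation.

Evaluation resamples 80:20 train/test splits at the *patient* level, so no
trajectory straddles the split; the training side oversamples the minority
class by duplicating whole state vectors with replacement (random
oversampling, implemented directly — it is a three-line operation). Splits
whose test or training partition lacks a class are rejected and redrawn,
since balanced accuracy is undefined there; rejections are counted in the
report. Permutation importance permutes each feature column once per split
*within the test partition* (the standard choice when the model is fixed)
and records the balanced-accuracy drop; per-feature means and percentile
95% intervals are reported, negatives included. Because the naive Bayes
margin is linear in the features, permuting one column shifts each margin
by `(x_perm − x)·w_f`; the implementation scores via that identity instead
of re-predicting, which is exact and is verified against naive recomputation
in the tests. The default is 10,000 splits; the automated checks use 1,000,
where trigger recovery is already unambiguous.

## Synthetic data generator

The generator emulates the *structure the analysis measures*, not clinical
content:

* **Care teams.** Each ED patient is treated by the triage nurse, a ward
  nurse, one junior doctor (RMO or Intern) and one senior doctor (Registrar
  or Consultant); referred patients additionally meet the Psychiatric
  Liaison Nurse and one psychiatry colleague. Interaction templates are
  drawn from per-patient pools built on that roster — this keeps the
  distinct-staff count per trajectory low (median 4), as observed, while
  the union over the cohort still covers the full staff graph.
* **Hub mediation.** With probability `hub_mediation_prob` (default 0.9) a
  cross-team interaction is routed through the liaison nurse, and the
  liaison nurse is the psychiatry team's patient-facing agent; at 0 the
  assigned colleague takes those contacts and the hub becomes an ordinary
  team member. This single dial plants (or removes) the high-betweenness
  bridge, and the hub's expected betweenness rises monotonically with it.
* **Referral triggers.** The referral decision is made by the patient's
  senior doctor, and the emitted record carries that doctor's signature —
  Registrar × Patient File or Consultant × Patient. These signatures never
  occur in routine-care templates, so the trigger is recoverable; senior
  doctors have other, non-trigger routine contacts (Registrar reviews the
  patient with the ED information system, the Consultant reviews the file).
* **Timing.** Inter-interaction gaps are exponential with mean 24 min,
  capped at 45 min so trajectories stay within one calendar day; at the
  median of 5 interactions this puts the median trajectory time near 1.5 h.
* **Interaction counts** follow a discrete distribution on 2–12 with
  median 5. Records never list an information system without at least one
  staff member entitled to access it (multi-party records may still imply
  forbidden *pairs*, exactly as real triage rows do; those are dropped at
  network construction).

`study_scale_fixture()` pins the cohort exactly: 43 trajectories / 272
interactions, of which 36 / 213 are in the ED; 20 referred patients whose
referral steps (13×4 + 7×5) yield 87 pre-referral states (23% positive).
The per-trajectory counts are hand-pinned multisets (ED: median 5, range
2–12, sum 213; observation area: sum 59), with referrals assigned to
mid-length trajectories — referred patients are handed over and leave the
ED, while the longest stays are non-referred observation cases.

**What passing tests do and do not show.** The generator plants exactly the
effects the pipeline is meant to detect, so planted-structure recovery
demonstrates that the machinery works — community detection separates teams
it was given, the percentile test flags a hub that was built in, the
classifier finds a trigger that deterministically precedes referral. It
does not show that real EDs have this structure, that effect sizes in real
data are comparable, or that the classifier would perform at this level on
noisy real-world referral processes where triggers are probabilistic and
confounded.

## Numerical choices and degenerate inputs

* Efficiency ties in restoration are compared at absolute tolerance 1e-12.
* Global efficiency raises for fewer than 2 nodes; removal impact requires
  at least 3; betweenness is 0 for n < 3 by convention.
* An empty event log builds an empty network with a warning (not an error);
  an empty cohort summary is an error.
* A referral action naming the team already treating the patient is ignored
  with a warning in the trajectory network.
* Seeds: all stochastic entry points take either an integer seed or an RNG;
  derived streams use `SeedSequence.spawn`.

## Known limitations

* Edges are binary; interaction frequency and duration are recorded but
  unused, so the information-flow model ignores intensity (a weighted
  extension would need a different efficiency definition).
* The event-log dialect assumes minute precision and no cross-midnight
  trajectories.
* Greedy-restoration tie enumeration is exponential in the worst
  (fully-symmetric) case and truncates at `max_sequences` orderings, with
  tie groups still exact.
* The generator's two-team, single-hub topology is one plausible ED; the
  pipeline itself makes no such assumption, but default-config test results
  should not be read as expectations for other service models.
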