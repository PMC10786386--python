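# carepath

Network modelling of clinical interactions along emergency-department (ED)
patient trajectories, aimed at health-services researchers studying how
clinical information flows around presentations with suicide or self-harm
risk.

Observational studies of emergency psychiatric care record *event logs*: one
timestamped row per clinical interaction, listing the agents involved (the
patient, nurses, doctors, paramedics, ...), the information systems accessed
(the ED information system, the paper patient file, psychiatry-specific
records), and resulting actions such as referrals or discharge. `carepath`
turns such logs into quantitative models:

1. **Trajectory statistics and networks** — per-patient trajectory time,
   interaction counts, staff diversity; a directed presentation → team →
   discharge transition network.
2. **Clinical interaction network** — an undirected simple graph over agents
   and systems with an edge wherever a pair was observed interacting at
   least once (`a_ij ∈ {0,1}`). Pairs that are operationally impossible are
   *forbidden* and excluded by construction: system–system pairs,
   system–non-staff pairs, and psychiatry-restricted systems (PSOLIS, EDYHO)
   with anyone outside the Emergency Psychiatry team.
3. **Centrality and communities** — degree `k_i = Σ_j a_ij`, closeness
   `c_i = (n−1)/Σ_j d_ij`, betweenness `b_i = Σ_{j<k} σ(j,k|i)/σ(j,k)`
   normalized by `(n−1)(n−2)/2`, global efficiency
   `g = 1/(n(n−1)) Σ_{i≠j} 1/d_ij`, and greedy modularity communities.
4. **Vulnerability analysis** — a *constrained connected double-edge swap*
   null model (degree-preserving, connectivity-preserving,
   forbidden-edge-free) locating a node's observed betweenness as a
   percentile of its shuffled distribution; node-removal impact on `g` and
   on doctors' closeness; and greedy edge *restoration*, which re-adds
   candidate edges one at a time to maximize the gain in `g`, enumerating
   all optimal orderings when ties occur.
5. **Referral prediction** — cumulative per-patient network states
   `X_{p,t} = [v_1..v_n | a_ij (i<j)]` up to the referral-precipitating
   interaction, a Bernoulli naive Bayes classifier with Laplace smoothing
   (α = 1), balanced accuracy `½(TP/(TP+FN) + TN/(TN+FP))` over
   patient-grouped 80:20 resamples with minority oversampling, and
   permutation feature importance.

Because no observational event log of this kind is publicly deposited, the
package ships a synthetic generator (`carepath.synthdata`) that plants the
structure the analysis measures — two clinical teams, a Psychiatric Liaison
Nurse (PLN) hub mediating cross-team information flow, and referral-trigger
interaction signatures — so the whole pipeline is testable end to end.

## Worked example

```python
from carepath import synthdata, eventlog, netbuild, netstats, vulnerability, referral

log = synthdata.study_scale_fixture()          # 43 trajectories, 272 interactions
ed = eventlog.exclude_mhoa_only_patients(log)  # 36 trajectories, 213 interactions

stats = eventlog.trajectory_statistics(ed)
print(stats.medians)
# {'trajectory_hours': 1.5333..., 'n_interactions': 5.0, 'n_staff_types': 4.0}

G = netbuild.build_interaction_network(ed)
print(len(netstats.detect_communities(G)))     # 2  (medical vs psychiatry)

ens = vulnerability.shuffle_ensemble(G, ed.catalog, n_shuffles=100,
                                     attempts=20000, seed=1)
res = vulnerability.betweenness_percentile_test(G, "Psychiatric Liaison Nurse", ens)
print(round(res.observed, 3), res.percentile)  # 0.444 100.0  -> flagged

impact = vulnerability.node_removal_impact(G, "Psychiatric Liaison Nurse")
print(round(impact.delta_g_percent, 1))        # -11.6  (largest of any staff)

ds = referral.build_dynamic_states(ed)         # 87 states, 20 positive (23%)
report = referral.permutation_importance(ds, n_splits=1000, seed=7)
print(round(report.baseline_scores.mean(), 2)) # 0.83
print(report.to_frame().iloc[0]["feature"])    # 'Patient File|Registrar'
```

The numbers mean: the cohort median trajectory is about 1.5 h with 5
interactions and 4 staff types; the interaction network splits into the two
team communities; the liaison nurse's betweenness exceeds every
degree-preserving shuffle (a genuine positional hub, not a degree artifact);
removing it costs more global efficiency than removing any other staff
member; and the referral classifier recovers the planted trigger edge
(Registrar accessing the Patient File) as the most important feature.

A command-line interface mirrors the library:

```bash
carepath simulate --study-scale -o log.csv
carepath stats log.csv --exclude-mhoa-only
carepath build-net log.csv -o net.graphml
carepath shuffle-test log.csv --node "Psychiatric Liaison Nurse" --shuffles 100 --seed 1
carepath referral-train log.csv --splits 1000 --seed 7 -o importance.csv
```

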