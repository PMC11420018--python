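# ersnet

Network analysis of emotion-regulation strategies and internalizing
symptoms.

Habitual emotion-regulation (ER) strategies — reappraisal, suppression,
rumination, distraction, engagement and arousal control, as measured by a
38-item, six-subscale survey — interact with individual symptoms of
depression (PHQ-9, nine items, 0–3) and anxiety (GAD-7, seven items, 0–3)
rather than with disorder sum-scores. `ersnet` implements the full
network-psychometrics pipeline for such data, for researchers who want to
estimate, probe and stress-test these strategy–symptom networks:

1. **Exploratory graph analysis (EGA).** The Gaussian graphical model of
   the 38 strategy items is estimated by graphical lasso over a penalty
   path, the extended Bayesian information criterion
   `EBIC = −2ℓ + E log n + 4γ E log p` (γ = 0.5) selects the fit, and
   walktrap communities of the partial-correlation network recover the
   subscale structure.
2. **Mixed graphical model (MGM).** The 22-node network over 6 continuous
   strategy sum-scores and 16 ordinal symptom items is estimated by
   nodewise lasso regressions on standardized variables with 10-fold
   cross-validated penalties; directed coefficients are aggregated into
   symmetric signed edges (AND rule).
3. **Centrality, global properties, stability.** Node strength
   (Σⱼ |wᵢⱼ|), bridge strength (the cross-group part of strength),
   density, average path length, transitivity and mean local clustering;
   the case-dropping bootstrap CS coefficient quantifies how many
   participants can be dropped while the statistic stays correlated ≥ 0.7
   with the full-sample value in ≥ 95% of replicates.
4. **Expected symptom activity (ESA).** Strategy nodes are clamped at
   chosen sum-scores and the fitted MGM is simulated by single-site Gibbs
   sampling; ESA is the resulting sum of the 16 symptom means (0–48
   scale). Each strategy is swept over its full range under three
   background scenarios (other strategies at their minimum, median or
   maximum), and profiles are compared with the baseline symptom activity
   (observed sum of symptom means).

Because the participant data this design comes from are not publicly
deposited, the package ships a synthetic-data generator
(`ersnet.generate`) that emulates their documented structure — six
correlated latent strategy factors, right-skewed ordinal symptoms, and a
fixed set of signed strategy–symptom partial correlations — so every stage
is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
sample and write their tables to `results/`:

```bash
python analysis/01_generate_data.py
python analysis/02_ega_communities.py
python analysis/03_mgm_network.py
python analysis/04_centrality_stability.py
python analysis/05_esa_sweeps.py
```

With the committed seed, `02` prints

```
item network: 262 edges over 38 items
walktrap communities: 6
  community 0: sup1, sup2, sup3, sup4, sup5, sup6, sup7, sup8
  ...
```

— EGA recovers exactly the six generating subscales. `03` reports the
22-node mixed model,

```
mixed graphical model: 115 edges (33 negative), density 0.498
average path length 1.502, transitivity 0.534, clustering coefficient 0.538
```

and lists the recovered strategy–symptom links; the strongest planted
ones (e.g. `reappraisal — hopelessness −0.271`,
`arousal_control — restlessness +0.180`) come back with their planted
signs. `04` finds a strength CS coefficient of 0.60 (the strength
ordering survives dropping 60% of participants), and `05` prints

```
baseline symptom activity: observed 15.375, model-implied 17.191
minimum-background sweeps (ESA range, crossing point):
       suppression: 22.809 .. 23.093  cross 8
       reappraisal: 14.419 .. 22.724  cross 8
   ...
```

Reading: with all other strategies clamped at their minimum, sweeping
reappraisal from 8 to 40 drives expected symptom activation down from
22.7 to 14.4 — in this synthetic network low strategy use is strongly
symptom-activating overall, because nine of the fourteen planted
strategy–symptom links are negative. The crossing point is the smallest
clamped sum-score whose ESA exceeds the observed baseline.

Library use mirrors the scripts:

```python
import ersnet as e

data = e.generate_dataset(e.GeneratorConfig(seed=1))
net = e.estimate_mgm(e.network_table(data), e.default_nodes())
profile = e.esa_scenario_sweep(net, "rumination", "minimum", baseline=14.6)
```

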