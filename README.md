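# symptomnet

Symptom-network analysis of anxiety–depression comorbidity for screening
questionnaires, aimed at researchers in network psychometrics and
psychiatric epidemiology who want to go beyond "which symptom is most
central?" to "which symptom should be targeted first?".

Given a participants × items table of PHQ-9 (depression) and GAD-7
(anxiety) scores, the package:

1. applies participant-quality screens (mean response time < 2 s;
   Tukey-fence slow outliers) and severity/caseness scoring (PHQ-9 and
   GAD-7 bands, strict > 9 comorbidity cutoffs, NMP-Q nomophobia bands);
2. binarizes items (present = score > 0) and estimates **Ising networks**
   — P(x) ∝ exp(Σᵢ τᵢxᵢ + Σ_{i<j} ω_{ij}xᵢxⱼ) — for depression, anxiety,
   and the combined comorbidity panel via **eLasso**: nodewise
   L1-penalized logistic regression with EBIC selection (γ = 0.25) and
   AND-rule symmetrization;
3. computes one-step **expected influence** (EIᵢ = Σⱼ ω_ij) and **bridge
   expected influence** (the same sum restricted to the other a-priori
   symptom community), with z-standardization and > 1 SD flags;
4. quantifies accuracy and stability by nonparametric bootstrap (95%
   edge CIs, difference tests) and case-dropping bootstrap summarized by
   the **correlation-stability coefficient** (CS-C);
5. checks that binarization preserved structure by fitting EBIC-glasso
   **partial-correlation networks** to the raw ordinal scores and
   comparing matrices with a permutation **Mantel test**;
6. ranks intervention targets by **simulation**: each symptom's threshold
   is shifted by ∓2 SD of the fitted threshold vector
   (alleviate/aggravate), the perturbed network is sampled with a
   Metropolis–Hastings chain (5,000 samples, seed 123 by default), and
   symptoms are ordered by |Δ expected network sum score|.

A fully seeded synthetic-data module (ground-truth Ising generators with
exact 2^p enumeration oracles, Gaussian-copula ordinal panels with
calibrated endorsement prevalences, planted response-time vectors) makes
every stage testable without survey data.

## Worked example

```python
from symptomnet.synthetic_data import default_panel_spec, generate_ordinal_panel
from symptomnet.preprocessing import binarize, describe
from symptomnet.ising_fit import fit_ising
from symptomnet.centrality import centrality_table
from symptomnet.nira import run_nira

panel = generate_ordinal_panel(default_panel_spec(n=1638, seed=42))
summary = describe(panel)
print(summary.group_percentages)

model = fit_ising(binarize(panel))          # combined 16-node network
print(model.n_edges)

cent = centrality_table(model)
print(cent.sort_values("EI", ascending=False).head(3)[["community", "EI", "bridge_EI"]])

nira = run_nira(model, "alleviate")          # 5,000 MH samples, seed 123
print(nira.baseline["expected_sum"])
print(nira.table.head(3)[["node", "expected_sum", "outcome", "rank"]])
```

Output:

```
{'neither': 59.0, 'depression_only': 15.5, 'anxiety_only': 12.6, 'both': 12.9}
75
       community        EI  bridge_EI
node
GAD6     anxiety  4.247948   0.897347
PHQ5  depression  4.170427   0.453831
PHQ7  depression  4.086979   0.606400
8.5508
   node  expected_sum  outcome  rank
0  PHQ1        7.5848   0.9660     1
1  GAD6        7.6170   0.9338     2
2  GAD2        7.6490   0.9018     3
```

Reading: the synthetic cohort of 1,638 shows 12.9% comorbid caseness
(both totals > 9). The fitted comorbidity network has 75 edges; the
irritability item (GAD6) has the largest expected influence, but the
simulation picks anhedonia (PHQ1) as the top alleviation target:
shifting its threshold by −2 SD lowers the expected number of active
symptoms from 8.55 to 7.58 (outcome 0.97). Centrality and intervention
priority need not coincide.

The same pipeline runs from the shell:

```bash
symptomnet simulate --n 1638 --seed 42 --out panel.csv
symptomnet fit panel.csv --out model.json
symptomnet nira model.json --outdir nira_out
symptomnet all --outdir full_run        # every stage + manifest
```

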