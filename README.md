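# cnsync

Carbon–nitrogen release synchronization analysis for swine diets.

Pigs fed diets with identical nutrient specifications can still grow at
different rates, because starch sources release glucose at very
different speeds while the protein fraction releases nitrogen on its own
schedule. When the carbon and nitrogen supplies fall out of step,
amino acids are burned for energy or left to ileal microbes instead of
being deposited as protein. `cnsync` implements the quantitative
toolkit for studying this: in vitro digestion release kinetics,
synchronization indices with a Syn/Asyn classification, marker-based
ileal digestibility, nitrogen/energy balance metrics, and the
starch-gradient diet design that generates the contrast — plus a
synthetic-data simulator so the entire pipeline runs and is testable
without any laboratory data.

It is written for animal-nutrition researchers working with two-phase
(gastric + intestinal) in vitro digestion time-courses and
ileal-cannulated pig trials using chromic oxide as an indigestible
marker.

## The model

**Release rates.** Cumulative release curves D(t) are sampled per phase
on that phase's own clock; the release rate over an interval is the
difference quotient

    K = (D_t2 − D_t1) / (t2 − t1)

with glucose in g/kg DM/min (diet level) or g/100 g/min (ingredient
level), soluble nitrogen in g/kg/min and total amino acids in
mmol/kg/min. No kinetic model is fitted to data; the direct calculation
is the method.

**Synchronization indices.** Over the common window of rapid release
(0–20 min of the intestinal phase), with reference rates K_R defined as
the across-diet averages of the per-diet rates:

    Relative G/N  = (K_Glucose / K_GlucoseR) / (K_Nitrogen / K_NitrogenR)
    Relative G/AA = (K_Glucose / K_GlucoseR) / (K_AA / K_AAR)
    G/N  = K_Glucose / K_Nitrogen          (g/g)
    G/AA = K_Glucose / K_AA                (g/mmol)

A diet with Relative G/AA inside a configurable band around 1 (default
[0.75, 1.50]) is classified `Syn` (synchronized); above the band it is
`Asyn_C` (relative glucose excess / nitrogen shortfall); below,
`Asyn_N` (relative nitrogen excess / glucose shortfall).

**Digestibility and balance.** With chromium concentrations (g/kg DM)
in diet and ileal digesta:

    AID  = [1 − (AA_digesta / AA_diet) · (Cr_diet / Cr_digesta)] × 100
    IAA  = AA_digesta · (Cr_diet / Cr_digesta)     (nitrogen-free diet)
    SID  = AID + (IAA / AA_diet) × 100
    ATTD = (intake − fecal) / intake × 100

IAA is the basal ileal endogenous loss (g per kg dry-matter intake),
estimated from animals fed a nitrogen-free diet. Balance fractions
(fecal/urinary energy or nitrogen over intake), ADG and ADFI round out
the trial-level reporting, with mean ± SEM and Tukey compact-letter
displays per diet.

## Worked example

Simulate the five-diet starch-gradient panel (3 replicates per diet,
2% replicate noise) and compute the synchronization table:

```python
from cnsync import simulate_diet_panel, sync_table

curves = simulate_diet_panel(noise_frac=0.02, seed=17)
print(sync_table(curves).round(3).to_string(index=False))
```

```
     diet  rel_gn_mean  rel_gn_sem  rel_gaa_mean  rel_gaa_sem  gn_mean  gn_sem  gaa_mean  gaa_sem letters_rel_gaa letters_gaa  class
  RGR_HGR        1.902       0.081         1.795        0.072   44.634   1.903     8.347    0.337               a           a Asyn_C
MRGR_MHGR        1.378       0.051         1.264        0.061   32.336   1.196     5.881    0.283               b           b    Syn
  MGR_MGR        0.945       0.004         0.952        0.033   22.186   0.092     4.426    0.152               c           c    Syn
MSGR_MLGR        0.574       0.059         0.609        0.053   13.464   1.380     2.833    0.247               d           d Asyn_N
  SGR_LGR        0.308       0.017         0.336        0.037    7.221   0.405     1.561    0.173               e           e Asyn_N
```

Each row is one diet: the four indices as mean ± SEM over replicates,
Tukey letters (diets sharing a letter do not differ at P < 0.05), and
the class label from the Relative G/AA band. In this default panel the
diets share one protein mix, so synchronization decays monotonically as
the waxy (rapidly digested) starch fraction falls: the all-waxy diet
over-supplies glucose relative to the panel (Asyn_C), the intermediate
blends are synchronized, and the high-amylose diets under-supply it
(Asyn_N).

The same pipeline runs from the shell:

```sh
cnsync simulate panel --seed 17 --out curves.csv
cnsync sync --in curves.csv --out sync_table.csv
cnsync simulate trial --seed 17 --out trial/
cnsync digest --diet trial/diet_assay.csv --digesta trial/digesta_assay.csv --out aid_sid.csv
cnsync balance --in trial/balance.csv --out balance_table.csv --summary
```

## Layout

- `src/cnsync/kinetics.py` — release curves, validation, interval rates
- `src/cnsync/synchronization.py` — indices, classification, panel table
- `src/cnsync/digestibility.py` — AID/SID/IAA, ATTD, balance, growth
- `src/cnsync/diet_design.py` — substitution gradient, formula completion
- `src/cnsync/simulate.py` — curve/panel/trial generators with truths
- `src/cnsync/stats.py` — ANOVA/Tukey, Kruskal–Wallis, letters, rendering
- `src/cnsync/io.py` — strict CSV schemas
- `docs/methods.md` — modelling assumptions and design choices
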