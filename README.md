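# gearmorph

Fishing gears do not capture fish at random: body shape influences who
escapes a trawl and who swims into a trap, so commercial fishing can act
as an evolutionary selection pressure on morphology
(fisheries-induced evolution). `gearmorph` re-implements, as a tested
and reusable Python pipeline, a laboratory-scale analysis of that
process: zebrafish-style cohorts are scored for vulnerability over
repeated simulated trawl and trap trials, and geometric morphometrics
is used to ask whether high- and low-vulnerability fish differ in
shape, condition and fin geometry.

It is aimed at fish ecologists and morphometricians who want the whole
chain — scoring, superimposition, permutation statistics, deformation
maps — in one scriptable package, with a synthetic-data generator that
has known ground truth for validating every step.

## What it computes

**Vulnerability scoring.** Each trawl trial ends in one of four outcomes
of increasing severity (escape beyond the net `E_B`, escape in front
`E_F`, caught in the net `C_N`, caught in the cod-end `C_C`), scored
50/100/200/300, plus a time penalty `600 − t` seconds for cod-end
captures. The per-fish index over three trials,

    V = Σᵢ (yᵢ + xᵢ),   i = 1..3

spans 150–2700. Trap captures are weighted 3/2/1 by trial (0–6). The
top and bottom 25% of each score distribution become the high/low
vulnerability groups.

**Shape analysis.** Landmarks (19 fixed + 72 sliding semi-landmarks on
six outline curves) are superimposed by generalized Procrustes analysis;
semi-landmarks slide along their neighbour chords to minimise
thin-plate-spline bending energy (or Procrustes distance). Shape is then
modelled with sequential (type-I) Procrustes ANOVA / MANCOVA — sums of
squares as traces of cross-product matrices, significance by residual
randomization (RRPP) — plus multivariate allometry, per-group Procrustes
variance (morphological disparity) with pairwise permutation tests, and
a size-adjusted linear discriminant classifier of high vs low fish.
Group mean differences are visualised as thin-plate-spline deformation
grids and log-Jacobian expansion/contraction heat maps.

**Condition.** Scaled mass index `SMIᵢ = Mᵢ (L0/Lᵢ)^bSMA` with the
standardized-major-axis slope of ln mass on ln length, caudal aspect
ratio `h²/A`, and OLS models with exhaustive AIC selection.

## Worked example

Run the whole pipeline on a simulated two-gear cohort (111 fish per
gear, default generator settings):

```python
from gearmorph import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(seed=42, out_dir="out", n_perm=999,
                                 simulate={"n_fish": 111}))
```

The output directory receives the score table, aligned coordinates,
ANOVA/allometry tables, LDA report, disparity matrices, deformation
figures and condition-model tables. The MANCOVA table for this seed:

```
              term     R2     SS  df      F     p
     centroid_size 0.0072 0.0130   1 0.7980 0.920
     vulnerability 0.0093 0.0169   1 1.0329 0.361
               sex 0.0171 0.0311   1 1.9048 0.001
              gear 0.0071 0.0130   1 0.7971 0.920
 vulnerability:sex 0.0076 0.0138   1 0.8444 0.837
vulnerability:gear 0.0110 0.0200   1 1.2249 0.076
         Residuals 0.9408 1.7158 105
             Total 1.0000 1.8237 111
```

Vulnerability accounts for ~1% of shape variance here — the magnitude
the generator injects by default — which at 112 high/low fish is real
but not individually significant; the sex effect (R² = 0.017) is
detected at p = 0.001. `summary["lda"]` reports held-out classification
accuracy per gear and `summary["smi"]` the mass–length SMA slope
(b_SMA ≈ 3.0, the isometric value the generator uses) and reference
length L0.

The same stages are available as CLI subcommands
(`gearmorph simulate|score|align|anova|lda|disparity|deform|condition|run`),
composable through intermediate CSV/TPS files.

## Acceptance script

`scripts/acceptance.py` recomputes the two headline scoring quantities
from scratch by constructing the corresponding trial records and running
the scoring module: the trawl vulnerability index of a fish caught in
the cod-end at t = 0 s in all three trials, and of a fish that escaped
beyond the net in all three trials.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
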