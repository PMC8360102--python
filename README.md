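# palasym

Directional and fluctuating asymmetry analysis of 3D palatal landmark
configurations — object-symmetry geometric morphometrics for skeletal-biology
and dental researchers studying how left–right asymmetry of the hard palate
changes across growth stages.

## The problem and the method

The hard palate is a bilaterally (object-)symmetric structure: a single
configuration of landmarks with an internal midline. Deviations from
symmetry decompose into **directional asymmetry** (DA, a consistent mean
left–right difference shared by a group — usually read as a signature of
lateralised mechanical loading) and **fluctuating asymmetry** (FA, random
individual deviations around the group pattern — usually read as
developmental instability).

`palasym` implements the standard object-symmetry protocol on a 41-point
palatal template (5 fixed landmarks, 12 curve semilandmarks at 20%
arc-length spacing on the cervical and median-suture curves, 24 surface
semilandmarks, with a bilateral pairing map):

1. For each individual *i* with configuration *O<sub>i</sub>*, build the
   reflected and relabelled copy *RR<sub>i</sub>* (negate *x*, permute
   landmarks by the left↔right pairing).
2. Superimpose all originals and copies jointly by **generalized Procrustes
   analysis** (centre, scale to centroid size 1, rotate with proper
   rotations only), optionally sliding semilandmarks along their curves and
   surfaces to minimise thin-plate-spline **bending energy** against the
   consensus.
3. Decompose: per-individual asymmetry vector
   *a<sub>i</sub> = O<sub>i</sub> − RR<sub>i</sub>*, group DA vector
   *d<sub>k</sub> = mean(a<sub>i</sub>)* with scalar
   *DA<sub>k</sub> = ‖d<sub>k</sub>‖*, and individual
   *FA<sub>i</sub> = ‖a<sub>i</sub> − d<sub>k</sub>‖*; per-landmark values
   are the 3-coordinate norms of the same vectors.
4. Test: per-group Procrustes ANOVA (individual / reflection / interaction,
   permutation p by residual randomisation), between-group ANOVA with Tukey
   HSD on per-landmark DA and FA, PERMANOVA and dispersion homogeneity on
   the Procrustes distance matrix, Spearman correlation of DA profiles,
   Kruskal–Wallis with Dunn post-hoc across landmarks, Mann–Whitney sex
   comparisons, Bonferroni correction.

A synthetic-data generator (`palasym.simulate`) draws palate-like
populations on an analytic dome with known injected DA fields, FA noise and
measurement error, so every stage is verifiable against ground truth. The
default design is six age groups of 5/14/11/26/82/45 individuals
(183 in total) from two collections.

## Worked example

```python
import numpy as np
from palasym import (SimulationSpec, simulate_population, build_symmetry_dataset,
                     gpa, decompose)
from palasym.stats import procrustes_anova_symmetry

spec = SimulationSpec(n_per_group=(20,), group_names=("II",), growth_scale=(0.7,),
                      vault_deepen=(1.0,), da_magnitude=(0.45,), seed=42)
dataset = simulate_population(spec)
doubled = build_symmetry_dataset(dataset)       # originals + mirrored copies
fit = gpa(doubled)                              # joint Procrustes superimposition
_, individuals, groups = decompose(fit, doubled)

g = groups["II"]
print(f"group II: n = {g.n}")
print(f"directional asymmetry DA = {g.da_scalar:.5f} (Procrustes units)")
print(f"mean fluctuating asymmetry FA = {np.mean([i.fa_scalar for i in individuals]):.5f}")
top = np.argsort(g.da_per_landmark)[-3:][::-1]
print("landmarks with largest DA:", [int(dataset.schema.ids[i]) for i in top])

anova = procrustes_anova_symmetry(fit.aligned[:20], fit.aligned[20:],
                                  n_perm=999, seed=0)
print(anova.round(5).to_string(index=False))
```

prints

```
group II: n = 20
directional asymmetry DA = 0.00571 (Procrustes units)
mean fluctuating asymmetry FA = 0.01566
landmarks with largest DA: [16, 28, 14]
           effect  df      SS      MS     Rsq        F     p
              Ind  19 0.08340 0.00439 0.96752 33.71331 0.001
      Reflections   1 0.00033 0.00033 0.00378  2.50229 0.001
Ind X Reflections  19 0.00247 0.00013 0.02870      NaN   NaN
```

The injected 0.45 mm directional field (anterior surface semilandmarks 14,
15, 16 and their left partners 26–28) is recovered: those landmarks carry
the largest per-landmark DA, and the `Reflections` (= DA) effect of the
Procrustes ANOVA is significant at the permutation floor (p = 0.001 with
999 permutations), while `Ind X Reflections` is the FA error term.

The same workflow runs end to end from the command line:

```bash
palasym run --seed 1 --permutations 999 --out my_run --figures
```

which writes the within-group ANOVA table, per-landmark DA/FA tables, the
between-group ANOVA + Tukey tables for DA and FA, the Spearman matrix, the
Kruskal–Wallis/Dunn tables, sex comparisons, a JSON run log and summary
figures into `my_run/`.

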