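# pvstereo

Design-based stereology and small-n aging inference for
parvalbumin-positive (PV+) neuron densities in the primate sensory
thalamus — the medial geniculate nucleus (MGN: vMGN, dMGN, mMGN) and the
lateral geniculate nucleus (LGN, layers 1–6).

It is written for quantitative neuroanatomists who have disector
counting records (or want to simulate them) and need the full chain
from raw counts to a defensible statistical verdict:

1. **Optical-fractionator density estimation.** Cells are counted in
   optical disectors — an unbiased counting frame (top/right inclusion
   edges, classical forbidden line) swept through the guarded core of a
   section so that fragments at the cut faces are never counted.  The
   estimated total is

   *E*ₙ = *N*ᵥ × *V*_ref,  with *N*ᵥ = ΣQ / (n · V_dis)

   (generalized to ΣQ / ΣV_dis,ᵢ for heterogeneous disector volumes)
   and *V*_ref the Cavalieri point-counting reference volume.  Because
   both refer to a common volume, the reported density *E*ₙ/*V*_ref is
   identical to *N*ᵥ and is robust to volume changes of the nucleus.

2. **Three-step inference.** Animals are split into middle-aged and
   aged groups at 65 human-equivalent years (21.66 monkey years; human
   years = months/4) and compared with an unpaired *t*-test at
   α = 0.01; per-region density is regressed on age with the Pearson
   product-moment correlation, requiring *r* > 0.7 **and** *p* ≤ 0.01;
   every regression is validated by a Monte Carlo permutation test
   (1000 re-assignments, *p* ≤ 0.05).  A relationship is significant
   only if it passes both criteria.

3. **Synthetic tissue.** Because raw counting data for such studies are
   rarely published, a first-class generator produces ground-truth 3D
   cell fields (Poisson or hard-core), sections them, and emits
   counting records whose density rises linearly with age — so the
   whole pipeline is testable against known truth, including the
   classical artifact that *thinner sections overestimate* naive
   profile counts while the guarded disector does not.

## Worked example

```python
from pvstereo import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(out_dir="out", seed=3,
                simulate=CohortConfig(seed=3), mc_iterations=1000)
bundle = run_pipeline(cfg)
print(bundle["results"].summary())
```

prints

```
Parvalbumin density vs age — three-step analysis
================================================================
animals: 7   groups: 2 middle-aged / 5 aged (cutoff 65 human-equiv years)
criteria: r > 0.7 & p <= 0.01 (regression); p <= 0.05 (Monte Carlo, 1000 reassignments, signed tail); t-test alpha 0.01

    region       r   p_param    p_mc  slope/yr  sig         t      p_t  ratio
      vMGN   0.870    0.0109   0.005     104.4   no     -2.05   0.0951   1.26
      dMGN   0.848    0.0160   0.009     158.9   no     -1.16   0.2971   1.28
      mMGN   0.865    0.0118   0.004     120.0   no     -1.23   0.2729   1.21
      LGN1   0.786    0.0360   0.022     121.1   no     -1.27   0.2616   1.24
      LGN2   0.877    0.0096   0.005      99.8  yes     -1.75   0.1401   1.23
      LGN3   0.873    0.0102   0.006     131.0   no     -2.11   0.0889   1.35
      LGN4   0.972    0.0003   0.000     111.6  yes     -2.30   0.0700   1.26
      LGN5   0.957    0.0007   0.000     160.4  yes     -4.46   0.0067   1.58
      LGN6   0.883    0.0084   0.004      98.0  yes     -1.53   0.1865   1.19
 LGN_magno   0.839    0.0182   0.009     110.4   no     -1.49   0.1960   1.24
 LGN_parvo   0.988    0.0000   0.000     125.2  yes     -2.83   0.0368   1.33
```

Reading it: each row is one region (plus the pooled magno/parvocellular
LGN layer groups).  `r`, `p_param`, `slope/yr` come from the regression
of per-animal density (cells/mm³) on age in monkey-years; `p_mc` is the
permutation p; `sig` applies the conjunction criterion — e.g. vMGN here
has r = 0.87 but p_param = 0.011 > 0.01, so it narrowly fails.  `t`,
`p_t` compare the middle-aged and aged group means; `ratio` is the
aged/middle-aged density fold change (here ~1.2–1.6, an age-related
increase).  The cohort defaults generate density 4000 cells/mm³ at 15
years rising by 10.5 cells/mm³ per month with 500 cells/mm³
between-animal noise, sampled with 0.5 mm² frames over 8 sections × 4
disectors per region.

The same run is available from the shell:

```sh
pvstereo run --config run.yaml          # simulate -> estimate -> infer
pvstereo simulate --config cohort.yaml --out sim/
pvstereo estimate --counts sim/counting_records.csv --out densities.csv
pvstereo infer --densities densities.csv --demographics sim/demographics.csv \
               --iterations 1000 --seed 1 --tail signed --out results/
```

Every run writes a `manifest.json` (config hash, seed, row counts);
identical config + seed reproduces byte-identical tables.

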