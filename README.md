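# mtdb — maternal-transfer database pipeline for reptile ecotoxicology

Concentrations of organic pollutants measured jointly in reptile mothers and
their offspring (eggs, yolk, albumen, follicles, hatchling blood) are
scattered across decades of publications that report in incompatible units
(ng/g, µg/kg, ppm, ...), on different measurement bases (wet weight, dry
weight, lipid weight), and with most values censored below a detection limit
that is sometimes reported and sometimes not.  `mtdb` turns such per-study
tables into one harmonized database and analyzes the maternal transfer it
documents.  It is written for ecotoxicologists doing data synthesis and risk
assessment on oviparous species.

The pipeline:

1. **ingest** — map heterogeneous study tables onto typed records, resolve
   compound synonyms (`4,4'-DDE` = `p,p'-DDE`; `PCB-153` → `PCB153`), and
   screen: bile observations, out-of-calibration measurements, and compound
   sums whose members are already reported individually are excluded with
   reason codes.
2. **harmonize** — convert every concentration *and its LOD* to ng/g, convert
   dry weight to wet weight via tissue water content
   (`C_ww = C_dw × (1 − f_water)`), and lipid-normalize
   (`C_lw = C_ww / f_lipid`) using a strict lipid-fraction fallback chain:
   study-reported → same-species literature → related-species literature.
   Censoring status is never altered.
3. **chemprops** — attach molecular descriptors (log K_ow, molecular weight,
   complexity, heavy atoms, H-bond donors/acceptors, TPSA, charge, rotatable
   bonds) from local snapshot tables, experimental K_ow preferred over model
   estimates, overrides for compounds the estimation model lacks; coelutions
   get a descriptor only when all members agree, sums never do.
4. **censoring audit** — count uncensored / quantitatively censored (known
   LOD) / qualitatively censored (unknown LOD) observations; only the first
   two carry quantitative information.
5. **transfer statistics** — pair offspring with their mothers and compute
   the partition ratio

   R = log₁₀(C_offspring / C_mother),

   where R = 0 is the lipid-normalized equilibrium expectation and |R| ≤ 1 a
   10-fold band around it; summarize per species × maternal tissue × compound
   class, correlate maternal tissues, and regress R on log₁₀ K_ow.  PFAS,
   being amphiphilic, are analyzed on a wet-weight basis as well.
6. **synthetic data** — a generator with known ground truth
   (`log₁₀ C_off = log₁₀ C_mom + α + β·log₁₀K_ow + ε`) that emulates the
   heterogeneity above, so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the default
synthetic fixture (two data-rich flagship studies with several maternal
tissues, one dry-weight-basis study, three small whole-egg studies, ~75%
censoring):

```
$ python analysis/01_simulate.py
wrote 3252 records from 6 studies -> results/synthetic/study_records.csv
...
expected: median ratio -0.200, censored fraction 0.755, qualitative share 0.377

$ python analysis/02_build.py
harmonized 3252 records; excluded 0; 0 diagnostics
numeric coverage: 808 wet-weight values, 808 lipid-normalized values

$ python analysis/03_audit.py
3252 records: 24.8% uncensored, 38.0% quantitatively censored, 37.2% qualitatively censored
2043 records carry quantitative information

$ python analysis/04_analyze.py
1173 partition ratios from 5796 pairs (4623 skipped: censored or zero)
overall median R = -0.097 (equilibrium = 0, generator offset = -0.2)
  within_10fold: 1173 (100.0%)
maternal tissue correlations (n=15 pairs): median r = 0.98, range 0.98-0.99
```

Reading the numbers: the audit recovers the configured censoring mix; every
partition ratio falls inside the 10-fold equilibrium band, consistent with a
modest true transfer offset (α = −0.2, ~37% less in eggs than mothers on a
lipid basis); and the observed median R (−0.10) sits above the true offset
because ratios can only use uncensored observations, which truncates the low
tail — exactly the bias pattern to expect in real censored data.  Maternal
tissues correlate near-perfectly because the generator puts tissues of one
mother in lipid-normalized equilibrium up to small scatter.

The same machinery is available as a CLI
(`mtdb simulate | build | audit | analyze`, see `mtdb --help`) and as plain
library functions (`import mtdb`).

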