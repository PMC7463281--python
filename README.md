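# xdrive

Population genetics of a selfish *Sex-Ratio* (SR) X chromosome.

Driving X chromosomes bias male meiosis so that nearly all functional
sperm carry the X, producing female-biased broods. In *Drosophila
pseudoobscura* the SR chromosome carries three inversions (basal,
medial, terminal) that lock a weak distorter to its enhancer; the
arrangement segregates against the standard (ST) X at ~13.5% in nature
despite a transmission advantage that should fix it. `xdrive` provides
the analyses used to dissect such a system end to end:

- **`xdrive.pooled_popgen`** — pool-seq allele-count tables (sync
  format): site filtering, methods-of-moments F\_ST with pool-size and
  read-sampling corrections in SNP windows, pooled π and Tajima's D in
  physical windows, consensus-based d\_XY, and fixed/shared/private
  site classification against an outgroup.
- **`xdrive.dating`** — divergence dating via T = −ln(1 − F\_ST) with
  per-window calibration against a known species split.
- **`xdrive.coalescent`** — a three-lineage Kingman coalescent
  (outgroup, ST, SR-as-single-founder inversion) and an empirical
  neutrality test for the observed π\_ST/π\_SR reduction.
- **`xdrive.ld`** — haplotype-panel LD: singleton/indel filtering,
  concatenated segregating-site matrices, haploid r², Fisher exact
  arrangement association, BH correction.
- **`xdrive.drive`** — deterministic drive dynamics: gametic LD decay
  D\_t = (1−c)^t D₀, haploid selection fitting, and a sex-structured
  diploid recursion with X linkage, male drive k, female recombination,
  and recessive viability costs, plus balance-cost and
  recombinant-exclusion solvers.
- **`xdrive.mapstats`** — exact binomial CIs, the Kosambi map function,
  reciprocal-class chi-square, survey LD, segregation proportion k.
- **`xdrive.simulate`** — seeded generators with truth records for
  every stage (pooled counts driven by the internal coalescent,
  haplotype panels, testcross/segregation/survey draws).

A natural-population survey table (ten surveys, 26,459 chromosomes)
ships as a packaged fixture; everything else is generated by code.

## Worked example

The two-locus story of the SR chromosome in five calls:

```python
>>> from xdrive import mapstats as ms, drive as dr
>>> survey = ms.pooled_survey_frequencies()     # SR, BM, T, ST pooled over surveys
>>> ms.survey_ld(survey)
{'p_A': 0.13459, 'q_B': 0.1347, 'D': 0.116420727, 'r2': 0.998370206085589}
```

The basal+medial and terminal inversion units are in near-perfect
association (D = 0.116, r² = 0.998). At the experimentally measured
recombination fraction between them, c = 0.0012, that association is
not durable on its own:

```python
>>> dr.half_life(0.0012)
(577.2760075200127, 577)
```

— LD would halve every 577 generations in a neutral gametic model.
With male drive and a balancing recessive cost it erodes even faster:

```python
>>> bal = dr.find_balance_cost(k_full=0.969, target=0.135)
>>> round(bal, 4)
0.4205
>>> params = dr.DriveParams(cost=(0.0, bal, 0.0, 0.0), c=0.0012)
>>> dr.ld_half_life(params)
{'half_life': 80, 'D0': 0.11642072699999997, 'D_final': 0.05815620748290151}
```

A 42% homozygous fitness reduction holds the driver at its observed
13.5% frequency, and the inversion association then halves within ~80
generations — so persistent selection against recombinants is needed.
Fitting haploid selection coefficients to the rarity of recombinants
in the surveys:

```python
>>> dr.fit_haploid_s(survey[[3, 0, 1, 2]], c=0.0012)   # ST, SR, BM, T order
{'BM': 0.6358752250671387, 'T': 0.31772375106811523}
```

— reconciling laboratory recombination with natural recombinant
frequencies requires selection intensities of roughly 0.32 and 0.64
against the terminal-only and basal+medial-only classes.

A command-line entry point mirrors the library
(`xdrive fst|diversity|dxy|classify|date|coaltest|ld|drive|mapstats|simulate`):

```bash
$ xdrive drive halflife --c 0.0012
{"exact": 577.2760075200127, "rounded": 577}
$ xdrive mapstats segregation --females 93 --males 3
{"k": 0.96875, "ci_low": 0.9110698110285887, "ci_high": 0.9934592491614072, "n": 96, "distorting": true}
```

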