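# tetralink

Tetrad analysis for budding-yeast meiotic crossover mapping.

When all four spores of a yeast meiosis are recovered and genotyped at two
linked heterozygous markers, the tetrad is a parental ditype (PD), tetratype
(TT) or non-parental ditype (NPD). From the class counts over `n = PD + TT +
NPD` scorable tetrads, `tetralink` computes the standard crossover statistics
used in yeast linkage studies:

* **Perkins map distance** — `cM = 100·(TT/2 + 3·NPD)/n`, correcting the
  single-crossover frequency for the double crossovers visible as NPDs, with
  the multinomial delta-method standard error
  `SE = (100/√n)·√(fT/4 + 9·fN − (fT/2 + 3·fN)²)` (`fT = TT/n`, `fN = NPD/n`);
* **Crossover interference** — the ratio of observed NPDs to the count
  expected from the tetratype frequency alone under no interference
  (Papazian): `fN_exp = ½·[1 − fT − (1 − 3·fT/2)^(2/3)]`; a ratio below 1
  indicates positive interference;
* **Random-spore recombination** — `100·r/t` with binomial standard error
  `100·√((r/t)(1 − r/t)/t)` for `r` recombinant of `t` viable colonies;
* **Gene-conversion (non-Mendelian segregation) tallies** — per-locus 3:1,
  1:3, 4:0 and 0:4 counts in four-spore-viable tetrads, with adjacent
  non-2:2 loci merged into single events;
* **Spore viability and sporulation summaries**, and two-tailed **Fisher
  exact** and **Mann-Whitney** tests implemented from first principles.

A meiosis simulator with gamma-renewal crossover interference (counting
model, parameter `m`; `m = 0` is a Poisson/no-interference process),
configurable spore viability and gene-conversion rates generates synthetic
tetrad datasets in the package's TSV dialect, so every estimator can be
verified by parameter recovery.

The package ships the per-interval PD/TT/NPD and random-spore count tables
of a published *zip1*/*pch2* crossover study (nine loci spanning chromosomes
III and VIII; `tetralink.datasets`) as an example dataset.

## Worked example

Fit the bundled count tables for the wild-type strain (K842) and a mutant
with a small N-terminal deletion in the synaptonemal-complex protein Zip1
(AM3684), and report the mutant's map relative to wild type:

```python
from tetralink.datasets import load_tetrad_counts
from tetralink.linkage import TetradLinkage

counts = load_tetrad_counts()
fits = {s: TetradLinkage.from_counts(g, s).fit()
        for s, g in counts.groupby("strain")}
wt, mut = fits["K842"], fits["AM3684"]
print(mut.summary(wt))
print("percent of wild type:", mut.percent_of(wt))
```

```
Tetrad linkage analysis: AM3684
intervals: 7   tetrads scored per interval (median): 542

   interval chromosome  PD  TT  NPD  total   cM  se pct_control cM_by_chrm pct_control_by_chrm npd_ratio npd_ratio_se
  HIS4-CEN3        III 463 107    3    573 10.9 1.2          41       71.3                  67      1.04         0.60
   CEN3-MAT        III 453 123    2    578 11.7 1.1          58       71.3                  67      0.52         0.37
  MAT-RAD18        III 315 204   15    534 27.5 2.3          76       71.3                  67      1.10         0.28
  RAD18-HMR        III 346 197    6    549 21.2 1.6          93       71.3                  67      0.50         0.20
SPO11-SPO13       VIII 394 143    5    542 16.0 1.5          41       54.7                  72      0.86         0.38
 SPO13-THR1       VIII 390  88    2    480 10.4 1.2         137       54.7                  72      0.87         0.61
  THR1-LYS2       VIII 262 203   11    476 28.3 2.2          96       54.7                  72      0.69         0.21

chromosome totals (cM): III: 71.3, VIII: 54.7

percent of wild type: 69.0
```

Reading the output: each row is one marker interval; `cM` is the Perkins map
distance with its standard error, `pct_control` the interval's map distance
as a percent of the wild-type value, `cM_by_chrm` the chromosome's summed
map length, and `npd_ratio` the observed/expected NPD interference ratio
(`n.d.` when no NPDs were observed). The mutant retains 69% of the wild-type
map summed over all seven intervals — crossovers are reduced but
interference ratios stay below 1 in most intervals.

Raw per-spore tetrad tables can be analyzed the same way via
`TetradLinkage(read_tetrad_table(path, marker_map))`, and
`results.simulate(...)` regenerates synthetic tetrads at the fitted map
lengths for parametric checks.

## Command line

```sh
tetralink simulate --seed 7 --out tetrads.tsv --markers-out markers.tsv
tetralink classify --tetrads tetrads.tsv --markers markers.tsv
tetralink map --tetrads wt=tetrads.tsv --markers markers.tsv --control wt --out reports/
tetralink rsa --counts random_spores.tsv
tetralink segstats --tetrads tetrads.tsv --markers markers.tsv
tetralink stats fisher 23 13 29 6
tetralink stats mwu x.txt y.txt
```

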