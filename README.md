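# gnis

Simulation-based power analysis for **genetic non-invasive sampling (gNIS)**
of SNP-genotyped wildlife populations.

DNA from scat, hair or feathers lets managers genotype a population without
catching animals, but it comes with three costs relative to blood/tissue
sampling: a reduced SNP panel, lower and more variable per-locus call rates,
and an unknown (usually small) fraction of the population sampled. Before
basing conservation decisions on such data, one wants to know *which genetic
measures survive that degradation, and how many individuals must be sampled*.

`gnis` answers this in silico. Starting from a complete, high-quality SNP
dataset of a spatially structured population — either real data or a
synthetic population generated by the package — it:

1. subsamples a fixed reduced SNP panel (default 1300 loci, drawn once);
2. thins individuals with a spatially explicit protocol that preserves the
   areal distribution of capture locations (sample sizes 40–420 by default);
3. degrades per-locus call rates to match the four global moments measured
   from experimentally aged scat genotyping (min 0.43, max 1.00,
   mean 0.62, sd 0.13);
4. re-applies the standard locus QC (reproducibility ≥ 0.95,
   call rate > 0.70, MAF > 0.01, one SNP per contig); and
5. measures, per replicate, the population diversity statistics, individual
   internal relatedness, and fine-scale spatial genetic structure, comparing
   each against the full-data truth.

## The measures

For biallelic loci with observed alt-allele frequency *p*:

- expected heterozygosity **H<sub>e</sub>** = 2p(1−p), averaged over loci;
- Shannon's information index **I** = −[p ln p + (1−p) ln(1−p)];
- inbreeding coefficient **F<sub>IS</sub>** = (H<sub>e</sub> − H<sub>o</sub>)/H<sub>e</sub>
  from the multilocus means;
- **internal relatedness** IR = (2H − Σf<sub>i</sub>) / (2N − Σf<sub>i</sub>),
  where H is the individual's homozygous-locus count, N its typed-locus
  count, and Σf<sub>i</sub> the summed cohort frequencies of its 2N allele
  copies;
- **spatial autocorrelation**: squared pairwise genetic distances
  (0 / 1 / 4 per locus for identical / hom-vs-het / opposite-homozygote
  genotypes) are double-centered, c = −½ J D² J, and within each geographic
  distance class *h* (250-m classes to 3500 m by default)

  r<sub>h</sub> = Σ<sub>(x,y)∈h</sub> c<sub>xy</sub> / Σ<sub>(x,y)∈h</sub> (c<sub>xx</sub>+c<sub>yy</sub>)/2,

  with a 95% CI from 999 within-class pair bootstraps and a null band from
  999 permutations of individual coordinates. A class shows *positive
  genetic structure* when r > 0 and the bootstrap CI excludes zero.

## Worked example

The `analysis/` scripts run the whole study on a synthetic population
emulating a continuous ~430-individual marsupial population genotyped at
8650 DArTseq-style loci with fine-scale isolation by distance:

```
$ python analysis/01_simulate_population.py --seed 1
generating 430 individuals x 8650 loci ...
pre-filter measures: He=0.282 I=0.431 FIS=0.140

$ python analysis/02_ground_truth.py --seed 1
filtering: 8650 loci -> 6333 (removed per step: {'reproducibility': 432,
  'call_rate': 0, 'maf': 582, 'secondary': 1303})
He = 0.303 +/- 0.002, I = 0.462 +/- 0.002, FIS = 0.140,
mean IR = 0.140 (range 0.09 to 0.19)
  [all] first-class r = 0.0263 (boot CI 0.0257..0.0268, null -0.0030..-0.0017)
```

The first-class (0–250 m) autocorrelation r = 0.026 sits far above the
permutation null band: neighbours are genetically more similar than a random
geographic arrangement would allow, i.e. the population shows fine-scale
structure. Males and females give closely comparable correlograms.

```
$ python analysis/03_run_experiment.py --seed 1
 sample_size  bias_he  bias_fis  mean_ir_correlation  detection_rate_250
          40   0.0043   -0.0167               0.2137                 0.2
          80   0.0036   -0.0043               0.1929                 0.3
         120  -0.0026   -0.0023               0.2279                 0.9
         160   0.0033   -0.0019               0.1773                 1.0
         ...
smallest size with >95% detection in the 250-m class: 160
```

Reading the summary: diversity biases are small at every sample size;
F<sub>IS</sub> is *under*-estimated at low sampling intensity; and reliably
detecting the (synthetic) population's fine-scale structure in the first
distance class requires sampling ≈160 of 430 individuals under the default
reduced grid (the full design uses 100 replicates per size and 999
bootstraps; pass `--full`). `04_figures.py` renders the correlogram,
detection-rate and bias figures from these tables.

The same machinery is exposed as a CLI (`gnis simulate-population`,
`gnis filter`, `gnis stats`, `gnis spatial-autocorr`, `gnis simulate-gnis`,
`gnis run-experiment`, `gnis summarize`) for use with your own data; the
genotype CSV dialect is a trio of files sharing a prefix —
`<prefix>.csv` (header `individual_id` + locus IDs, dosage genotypes 0/1/2,
missing `NA`), `<prefix>.loci.csv` (`locus_id, contig_id,
position_in_contig, reproducibility`) and `<prefix>.individuals.csv`
(`individual_id, sex, x, y` in planar metres). Uncompressed biallelic
VCF 4.2 is supported for interchange.

## Layout

- `src/gnis/` — the library: dataset container and I/O, synthetic
  populations, QC filtering, gNIS degradation, genetic estimators, spatial
  autocorrelation, experiment engine, CLI.
- `analysis/` — numbered narrative drivers reproducing the study.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
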