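# pedmorph

Analysis toolkit for discrete and quantitative colour inheritance over a
two-generation breeding pedigree of a throat-colour-polymorphic lizard:

* **Mendelian model testing** — three candidate architectures for the four
  morphs (O, Y, OY, G): one locus / four alleles, one locus / three
  co-dominant alleles, and two dominant presence loci; autosomal or
  Z-linked (ZW, females hemizygous). Expected offspring morph frequencies
  are computed per mating under three parental-zygosity assumptions
  (equal 50:50, Hardy–Weinberg, expression threshold) and compared to
  observed counts with likelihood-ratio G tests (df = 3).
* **Categorical exclusion checks** — parent–offspring morph
  incompatibilities under the four-allele model and father–daughter rules
  under Z linkage.
* **Heritability of quantitative colour expression** — numerator
  relationship matrix, univariate REML animal model (fixed effects for
  sex, cohort, generation), mid-parent/sire/dam offspring regressions,
  cross-trait regressions, and a mixed ANCOVA test for unequal sire/dam
  slopes (sex-linkage screen). Analyses run on arcsine-square-root
  transformed proportions; yellow in OY morphs is parameterized as the
  sum of orange and yellow.
* **Synthetic data** — a pedigree simulator (Mendelian genotype
  transmission honouring ZW, morph phenotypes, additive-genetic +
  residual trait variation, sex-limited expression scaling) plus a
  deterministic study-shaped fixture (23 sires, 17 dams, 25 clutches, 58
  offspring in two cohorts).
* **Paternity** — microsatellite allele-mismatch counting and
  exclusion-based sire assignment (assign at ≤ 1 mismatching locus), with
  per-locus Ho/He/PIC summaries and wide-CSV or GenePop input.

## Command line

All stages are exposed through one entry point (`pedmorph --help`):

```sh
pedmorph simulate --seed 1 --out-dir out/             # pedigree.csv, traits.csv, truth.json
pedmorph classify --pedigree ped.csv --out labelled.csv
pedmorph fit-mendelian --pedigree ped.csv --out fits.csv
pedmorph exclusions --pedigree ped.csv --out excl.csv
pedmorph heritability --pedigree ped.csv --trait orange --method animal --out h2.json
pedmorph paternity --genotypes geno.csv --trios trios.csv --out calls.csv
pedmorph gtest --out g.csv                            # recompute G from bundled counts
```

Pedigrees are CSVs with the header
`id,sex,generation,cohort,clutch,sire,dam,prop_orange,prop_yellow,morph`;
missing values are empty cells. Every output directory gets a
`run_manifest.json` with parameters, input digests and the package
version.

## Layout

```
src/pedmorph/
  pedigree.py    # domain types, validation, CSV I/O
  phenotype.py   # thresholds, morph classification, trait transforms
  mendelian.py   # genetic models, zygosity schemes, crossing, G tests, exclusions
  quantgen.py    # A-matrix, REML animal model, regressions, ANCOVA
  simulate.py    # synthetic pedigrees, trait simulation, study-shaped fixture
  paternity.py   # mismatch counting, assignment, locus summaries
  cli.py         # click entry point
  data/          # bundled observed/expected morph-count table
tests/           # unit + property tests and test_acceptance.py
scripts/acceptance.py
```
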