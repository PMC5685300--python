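# fetalfrac

Fetal DNA fraction estimation from shallow-depth sequencing of maternal
plasma cell-free DNA.

## The problem

Noninvasive prenatal testing (NIPT) screens for fetal chromosomal
abnormalities by sequencing the cell-free DNA in maternal plasma, typically
at very low depth (~0.03-fold genome coverage). The fraction of that DNA
that is fetal — the **fetal DNA fraction** *F* — is a critical quality
parameter: too little fetal DNA and an aneuploidy can be missed. Most
accurate fraction estimators need deep or targeted sequencing; `fetalfrac`
implements an estimator that works at routine NIPT depths, for laboratories
that also genotype the maternal blood cells on a SNP array.

## The method

At a SNP site where the mother is **homozygous**, every maternal plasma
molecule should carry her allele. A sequenced base that differs from it is
either a paternally inherited fetal allele or a sequencing/genotyping error.
Let *X* be the percentage of non-maternal bases aggregated over all
maternal-homozygous sites genome-wide. Assuming the error rate is constant
across cases, *X* is an affine function of the true fetal fraction, so a
linear calibration

```
F̂ = a·X + b
```

estimates *F* from *X* alone. The calibration shipped with the package is
**F̂ = 18.9 X − 6.6** (percent scale); it is platform-specific and can be
refitted from training samples whose true fraction is known. The
gold-standard fraction for training uses sites where the mother is
homozygous (AA) and the fetus heterozygous (AB):

```
F = 2p / (p + q) × 100
```

with *p* the reads carrying the fetal-specific allele B and *q* the reads
carrying the shared allele A.

The package covers the whole workflow: panel derivation from maternal
genotypes (VCF/TSV), allele counting from SAM/BAM pileups, calibration
fitting (`FetalFractionModel.fit()` returning `CalibrationResults`, in the
statsmodels style), k-fold cross-validation, read/SNP downsampling, a
depth × panel-size accuracy grid, and a synthetic-data generator that
reproduces the statistical structure the estimator assumes, so everything is
testable without access to patient data.

## Worked example

Simulate a 23-sample training cohort at full study depth (4.5×, a 1.94M
locus panel), fit the calibration, and apply it:

```sh
$ fetalfrac simulate --n-samples 23 --coverage 4.5 --seed 11 --out train
wrote 23 samples to train/cohort.tsv

$ fetalfrac train --samples train/cohort.tsv --out model.json
Fetal fraction calibration  F_hat = a*X + b  (percent scale)
------------------------------------------------------------
slope a           18.8817   (SE 0.0250)
intercept b       -6.5940   (SE 0.0190)
R^2                1.0000
n_train                23
X at F=0           0.3492 %

$ fetalfrac predict --model model.json --x 0.878
X = 0.8780%  ->  estimated fetal fraction = 9.98%

$ fetalfrac predict --model published --x 0.878
X = 0.8780%  ->  estimated fetal fraction = 9.99%
```

The fitted slope and intercept recover the published line (18.9, −6.6)
within their standard errors, and a sample in which 0.878% of bases at
maternal-homozygous sites are non-maternal is estimated to carry ~10% fetal
DNA. For real data the pipeline is `panel` → `count` → `predict`:

```sh
fetalfrac panel --genotypes mother.vcf --out panel.tsv
fetalfrac count --alignments plasma.bam --panel panel.tsv \
    --out-counts counts.tsv --out-summary summary.json
fetalfrac predict --model published --summary summary.json
```

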