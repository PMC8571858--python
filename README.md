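# herbita

Herbarium ITS barcoding toolkit: can century-old pressed plant
specimens still be identified to species from their DNA?

`herbita` implements the computational side of a herbarium DNA-barcoding
study of the grass genus *Phalaris*: quality control of DNA extracted
from historic (1882–2001) and fresh specimens, detection of
species-diagnostic SNPs in the nuclear ribosomal internal transcribed
spacers (ITS1 and ITS2, excluding the conserved 5.8S gene), distance
trees for spotting misidentified accessions, and barcode-based
classification of query sequences. It is aimed at herbarium curators,
plant systematists and anyone validating GenBank sequence labels.

## What it computes

**Specimen QC** (`herbita.specimen_qc`). For a table of specimens with
DNA concentration (ng/µl), OD260/280 and OD260/230 purity ratios,
amplification outcome and sequencing outcome: group means ± sample SD,
success rates, collection-year stratification by amplification outcome,
and the OLS regression of DNA concentration on specimen age
(x = extraction year − collection year) used to test whether older
vouchers yield less DNA. Transcriptions of the study's 52 herbarium and
7 fresh specimens ship with the package.

**Diagnostic sites** (`herbita.diagnostic_barcode`). A column of the
masked ITS1+ITS2 alignment is diagnostic for a species set *S* when all
determinate members of *S* share one state *s* (a base or a gap, `DEL`)
and no member outside *S* carries *s*. The scan emits a coded barcode
table (`T1`, `B-C3`, `AR4`, …; positions are 1-based over the
5.8S-masked columns), reports species without sites and species pairs
with no fixed difference anywhere (indistinguishable), and classifies
query sequences by concordance with the table.

**Distance trees** (`herbita.distance_tree`). p-distance or
Jukes–Cantor (−¾ ln(1 − 4p/3)) over unmasked columns with pairwise or
complete gap deletion; classic Saitou–Nei neighbor joining (exact on
additive matrices, deterministic tie-breaking); column-bootstrap support
on internal edges; and monophyly-based misassignment flagging — the
smallest set of leaves whose removal makes every multi-member species
monophyletic, each flagged leaf re-assigned to the majority species of
its three nearest neighbours by patristic distance.

**Synthetic data** (`herbita.synthetic_data`). A ground-truthed
generator emulating the study's data: ~600 nt ITS templates per species,
planted species- and group-diagnostic sites (including deletions),
within-species polymorphism, mislabeled accessions, missing data, and
herbarium metadata with age-independent DNA concentration but
age-dependent amplification failure.

## Worked example

```python
from herbita.specimen_qc import (packaged_herbarium_records,
                                 summarize_purity, success_rates,
                                 regress_concentration_on_age)

herb = packaged_herbarium_records()
s = summarize_purity(herb, "od_260_280")
print(f"OD260/280: {s.mean:.2f} +/- {s.sd:.2f} (n={s.n})")
for r in success_rates(herb):
    print(f"{r.label}: {r.numerator}/{r.denominator} = {r.percent_display}")
fit = regress_concentration_on_age(herb)
print(f"conc ~ age: slope={fit.slope:.3f}, r2={fit.r_squared:.4f}, "
      f"p={fit.p_value:.2f}")
```

prints

```
OD260/280: 2.11 +/- 0.79 (n=52)
amplified/total: 41/52 = 78.8%
full_sequence/total: 31/52 = 59.6%
full_sequence/amplified: 31/41 = 75.6%
conc ~ age: slope=0.095, r2=0.0178, p=0.35
```

— the historic specimens yield usable DNA (mean OD260/280 ≈ 2.1), four
out of five amplify, and DNA concentration is uncorrelated with specimen
age (p ≈ 0.35). The same numbers are available from the command line:

```sh
herbita simulate --seed 17 --out fixtures/        # synthetic bundle
herbita qc --specimens fixtures/specimens.csv --out report/
herbita barcode --aln fixtures/alignment.fasta \
    --annot fixtures/annotation.json --out barcode.tsv
herbita tree --aln fixtures/alignment.fasta --bootstrap 100 --seed 17 \
    --out tree.nwk --report misassign.tsv
```

On the synthetic study-structured alignment (12 species, planted site
counts mirroring the published barcode table), the scan recovers every
planted site with precision = recall = 1.0, finds diagnostic sites for
8/12 species (66.7%), and reports the *P. brachystachys* /
*P. canariensis* pair as indistinguishable.

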