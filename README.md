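# aexapr

Screening therapeutic proteins for **aggregation-prone regions (APRs)** —
short, mostly hydrophobic peptide stretches that can nucleate protein
aggregation and, through aggregates, drive anti-drug-antibody responses.
`aexapr` implements a physicochemical classification model that separates
APR peptides from non-aggregating control peptides, and extends it into a
sliding-window scanner for arbitrary protein sequences. It is aimed at
developability assessment in non-clinical biologic drug development.

## The model

Eight per-residue physicochemical descriptors are aggregated to sequence
level: six by a **sum rule** (AM, non-conjugated amine groups; AC,
carboxylic acid groups; ROT, rotatable bonds; HBA, hydrogen-bond
acceptors; IP, ionization potential in eV; NON, non-aromatic ring atoms)
and two by a **mean rule** dividing by the number of distinct residue
types (QPCaco, predicted Caco-2 permeability in nm/s; QPlogS, aqueous
solubility). Six of them combine into the arithmetic-expression score

```
AEx = ln(AM − IP + AC·ROT) − (QPCaco − NON)
```

Each sequence is then placed in one of four quadrant classes of the
(QPlogS, AEx) plane, evaluated in order with the first match winning:

| class | rule                    | meaning              |
|-------|-------------------------|----------------------|
| A     | QPlogS > 0 and AEx < 0  | not aggregation-prone |
| B     | QPlogS ≥ 0 and AEx > 0  | not aggregation-prone |
| C     | QPlogS < 0 and AEx ≥ 0  | not aggregation-prone |
| D     | QPlogS ≤ 0 and AEx ≤ 0  | **APR candidate**    |

The packaged reference set (148 peptides: 84 APRs from therapeutic
proteins, 22 tregitopes, 42 control 5-mers sliced from the tregitopes)
yields the confusion table Tp=67 Fn=17 Tn=41 Fp=1 and Cooper validation
statistics Sn 79.76 %, Sp 97.62 %, Ac 85.71 %. Because only
sequence-level descriptor values are published, per-residue tables are
recovered from the reference set by minimum-norm least squares on the
residue-composition matrix (`infer_params`); the integer-count
descriptors are recovered exactly.

## Worked example

Scan a 14-residue fragment of a therapeutic-antibody framework region
that contains the known APR `VVSVLTVL`:

```
$ printf '>demo\nNSTYRVVSVLTVLH\n' > demo.fa
$ aexapr score --fasta demo.fa | cut -f1-4,12-15
seq_id  start  end  window  QPlogS   AEx      class  apr_flag
demo    1      5    NSTYR   0.0772   -0.2033  A      0
demo    2      6    STYRV   -0.0484  -0.2907  D      1
demo    3      7    TYRVV   -0.0988  -0.7253  D      1
demo    4      8    YRVVS   -0.0596  -2.0166  D      1
demo    5      9    RVVSV   -0.0390  -6.5650  D      1
demo    6      10   VVSVL   -0.0871  -7.5800  D      1
...
```

Each row is one 5-residue window with its solubility (QPlogS), AEx score
and quadrant class; `apr_flag 1` marks class-D windows, i.e. the
aggregation-prone candidates. The run of class-D windows from position 2
onward covers the embedded APR. Other commands:

```
aexapr data dump --group APR        # emit the packaged reference table
aexapr reproduce --out report/      # class counts, Cooper stats, summaries
aexapr infer-params --out tables.json
```

`aexapr reproduce` prints

```
confusion: tp=67 fn=17 tn=41 fp=1 n=126
Cooper: sn=79.76 sp=97.62 ac=85.71 er=14.29 pp=98.53 np=70.69 fp_oc=2.38 fn_uc=20.24
Mann-Whitney AEx APR vs CS: |Z|=7.137 p=9.56e-13
Mann-Whitney QPlogS APR vs CS: |Z|=6.089 p=1.14e-09
```

i.e. the classifier recovers 67 of 84 APRs while misclassifying only one
of 42 controls, and both AEx and QPlogS separate the two groups far
beyond chance.

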