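# hspreg

Tools for asking whether two chromosomal arrangements of *Drosophila
subobscura* — the cold-climate O_ST and the warm-climate O_3+4+7 — differ
in the regulatory architecture or the basal expression of their *hsp70*
genes. The package is aimed at population geneticists working with
haplotype alignments from isochromosomal lines and qPCR expression data,
and it bundles three analyses that are usually scattered across separate
programs:

1. **Motif annotation** of *hsp70* promoters and 3'UTRs: heat-shock
   elements (maximal runs of ≥ 3 alternating nGAAn/nTTCn pentamer units),
   GAGA sites (GAGAG/CTCTC), TATA boxes (TATAWAWR), AU-rich elements
   (AUUUA, scanned as ATTTA on DNA), all in TSS-relative coordinates, plus
   exact-match in-silico PCR for primer pairs.
2. **Differentiation statistics** between arrangements on gap-free
   alignments: site classification (shared / exclusive / fixed
   polymorphisms), D<sub>xy</sub>, Hudson's
   F<sub>st</sub> = 1 − H<sub>w</sub>/H<sub>b</sub>, and Hudson's
   nearest-neighbour statistic S<sub>nn</sub> with a label-permutation
   test.
3. **Expression ANOVA** on relative expression 2^(−ΔCt) under the nested
   mixed model
   *y*<sub>ijkl</sub> = μ + A<sub>i</sub> + L<sub>j(i)</sub> + S<sub>k</sub> + AS<sub>ik</sub> + ε<sub>ijkl</sub>
   (arrangement fixed, line random within arrangement, sex fixed), with
   Type III sums of squares, mixed-model F denominators, and a four-stage
   restricted permutation test — one exchange scheme per term — to
   validate the parametric P values.

A synthetic-data module generates haplotype alignments with planted
motifs/site classes and nested-design Ct tables with known effects, so the
whole pipeline is testable without any external data. See
`docs/methods.md` for the models, assumptions and design choices.

## Worked example

A fully synthetic end-to-end run (alignment with planted promoter motifs
and a Ct table with a 1-cycle sex effect):

```sh
hspreg run --outdir demo_run --seed 7
```

`demo_run/annotation_five_prime_A.tsv` (per-line motif table, 1-based
coordinates, TSS-relative starts; −248 means 248 bp upstream of the TSS):

```
sequence  kind        start  end  unit_count  tss_relative_start
OST_L1    HSE            41   55           3                -248
OST_L1    GAGA_MINUS     71   75           0                -218
OST_L1    HSE            90  109           4                -199
...
```

`demo_run/differentiation.tsv` — one row per region × gene copy (plus a
concatenated row when both copies are present). Here 5 sites segregate
only in O_ST (SP1SF2), 3 only in O_3+4+7, 2 in both, 1 is fixed between
arrangements; S<sub>nn</sub> = 1 means every sequence's nearest neighbours
are all from its own arrangement, and P is its permutation significance at
1000 relabellings:

```
Region      Gene copy  SP1SF2  SP2SF1  Shared  Fixed  Sites  Dxy     Fst    Snn  P
five_prime  A          5       3       2       1      548    0.0103  0.453  1.0  0.003
```

`demo_run/anova.tsv` — the planted sex effect is recovered (F = 96.2 on
1 and 53 df) while arrangement and interaction are null, and the
permutation P values track the parametric ones:

```
Source                   d.f.  MS        F      P (parametric)  P (permutation)
arrangement              1     2.61e-05  0.63   0.445           0.465
line_within_arrangement  10    4.14e-05  0.92   0.526           0.541
sex                      1     4.35e-03  96.17  1.7e-13         0.001
arrangement_by_sex       1     8.80e-08  0.002  0.965           0.976
error                    53    4.52e-05
```

The same operations are available as library calls
(`hspreg.scan_hse`, `hspreg.differentiate`, `hspreg.fit_nested_anova`,
`hspreg.permutation_anova`, ...) and as the subcommands
`hspreg annotate | diff | anova | simulate | run`.

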