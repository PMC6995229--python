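# Methods

This note documents the models and procedures implemented in `hspreg`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Biological setting

*Drosophila subobscura* carries a rich inversion polymorphism on its O
chromosome. The cold-climate standard arrangement (O_ST) and the
warm-climate overlapping-inversion arrangement (O_3+4+7) show repeatable
clinal and seasonal frequency patterns driven by temperature. The hsp70
locus — two gene copies, hsp70A and hsp70B — sits inside the inverted
region, making its regulatory regions natural candidates for
arrangement-specific adaptive differences. The package analyses three
layers of evidence from isochromosomal lines (lines made homozygous for a
single wild O chromosome, so each contributes one haplotype):

1. cis-regulatory architecture of the proximal promoter (heat-shock
   elements, GAGA sites, TATA box) and the 3'UTR (AU-rich elements);
2. population differentiation between arrangements on the regulatory-region
   alignments;
3. basal hsp70 mRNA expression from qPCR Ct data, tested with a nested
   mixed-model ANOVA validated by restricted permutation.

## Motif model

**HSE.** A heat-shock element is modelled as a maximal run of contiguous
5-mers whose central trinucleotide alternates between GAA and TTC
(`nGAAnnTTCn...`, either phase first), with at least `min_units = 3` units.
Positions 1 and 5 of each pentamer are unconstrained, reflecting the
observation that they are the least conserved positions of the HSF-monomer
binding unit; the core is matched exactly by default (an optional per-core
mismatch allowance exists for exploratory scans but is off because unit
counts in this system are perfectly conserved). "Maximal" means the run
cannot be extended by another valid alternating unit on either side. The
boundary between one long element and two adjacent elements is a
convention, not an observable: no maximum spacer is imposed, and two HSEs
closer than 5 bp are flagged (`close_to_previous_hse`) rather than merged.

**GAGA, ARE, TATA.** GAGA sites are literal `GAGAG` (sense, G+) and `CTCTC`
(antisense, G−) matches. AREs are `AUUUA` pentamers scanned as `ATTTA` on
the DNA sense strand, since the inputs are genomic sequences. Overlapping
fixed-motif hits are all reported; consumers may collapse them. The TATA
box uses the IUPAC consensus `TATAWAWR` and is annotation-only — it stands
in for the neural-network promoter predictor used in the original
annotation work, which is out of scope; nothing downstream depends on TATA
calls.

**Coordinates.** Internally 0-based half-open on the ungapped sequence;
user-facing tables are 1-based inclusive. Promoter positions are also
reported TSS-relative with the biological convention that the TSS is +1 and
there is no position 0; the mapping is a bijection on ungapped positions.

**In-silico PCR.** Exact primer matching (primers must be unambiguous
ACGT; IUPAC degeneracy in the template is expanded). Only innermost
primer pairings count as products; zero products and multiple products are
distinct errors, the latter listing every product. This matches how a
printed primer pair designed against an exact target behaves.

## Differentiation statistics

All statistics operate after complete deletion: restricted to the
sequences under comparison, every column containing a gap or `N` in any
retained sequence is removed (`analysed_sites` is the surviving column
count). Columns gapped only in excluded sequences are kept, which
maximizes sites per comparison; a strict whole-alignment deletion mode is
available for sensitivity checks.

* **Site classes** partition the analysed columns: monomorphic; fixed
  difference (each population invariant, different alleles); shared
  polymorphism (segregating within both); exclusive polymorphism
  (segregating in exactly one). Multi-allelic columns are classified by
  the same within-population variability rule as bi-allelic ones.
* **Dxy** is the mean cross-population pairwise Hamming distance per
  analysed site.
* **Fst** is Hudson's 1 − Hw/Hb with Hb = Dxy and Hw the unweighted mean
  of the two within-population mean pairwise diversities. With equal
  sample sizes (6 vs 6 here) the unweighted and pair-count-weighted means
  coincide; the weighted option exists because some programs weight by
  sample size. Fst is undefined (an error, not a number) when Hb = 0.
* **Snn** is Hudson's nearest-neighbour statistic: for each sequence, the
  fraction of its nearest neighbours (all sequences at the minimal
  distance — ties share the denominator) belonging to its own population,
  averaged over sequences. Significance comes from uniformly random label
  permutations preserving group sizes, with the tie-inclusive counting
  rule p = (1 + #{permuted ≥ observed}) / (B + 1), B = 1000 by default.

A property worth knowing: Snn lives on a small lattice (means of
nearest-neighbour fractions), so permutation p-values carry substantial tie
mass and are *conservative* on null data (empirical mean ≈ 0.57 rather
than 0.5) at any realistic sample size. They are valid — P(p ≤ α) ≤ α —
but not exactly uniform; the test suite checks validity, not uniformity.

**Concatenated rows.** The published comparison includes a concatenated
data set per region whose site counts are not the sum of the per-copy rows,
and the concatenation scheme is not defined in the source. The default
here joins each line's A and B sequences end to end before gap deletion
(6 sequences per arrangement); pooling A and B haplotypes as 12 sequences
per arrangement is implemented behind `concat_scheme="pooled"`. Without the
deposited alignments the scheme that reproduces the published concatenated
counts cannot be determined from a desk run; both remain available.

## Expression model

Relative expression per biological replicate is 2^(−ΔCt), with ΔCt the
mean target Ct minus mean reference Ct over technical replicates. The
linear model is

    y_ijkl = μ + A_i + L_j(i) + S_k + AS_ik + ε_ijkl

with arrangement A and sex S fixed, line L random and nested within
arrangement, fitted by least squares on relative expression. Sums of
squares are Type III with sum-to-zero contrasts, computed as reduced-model
RSS differences; on balanced data this coincides with the sequential
decomposition and with the textbook cell-mean formulas (verified to 1e-10
relative error). F denominators follow the mixed-model expectations:
arrangement over the line mean square; line, sex and interaction over the
error mean square. The original analysis ran in a commercial package whose
default is Type III, but the exact SS type is unstated; with the published
raw data unavailable offline, the choice cannot be discriminated here and
Type III is used throughout.

Because 2^(−ΔCt) is log-normal when ΔCt is normal, parametric P values are
checked by a four-stage restricted permutation test (B = 9999 by default,
p = (1 + #{F* ≥ F}) / (B + 1), ties counted toward the tail):

1. **line** — observations re-shuffled among lines within each arrangement
   (implemented as permuting the line-label column within arrangement, so
   each observation keeps its own arrangement and sex);
2. **arrangement** — whole lines, with all their observations, reassigned
   to arrangements preserving 6/6;
3. **sex** — sex labels exchanged within each line, preserving the nuisance
   line structure (a global exchange is available behind
   `sex_scheme="global"` since the source wording does not fix the
   exchange unit);
4. **interaction** — observations shuffled freely across the four
   arrangement × sex cells (a Freedman–Lane residual-permutation variant is
   available behind `interaction_scheme="freedman_lane"`).

Stages 3 and 4 are algebraically equivalent to permuting the response
against a fixed design, so they are computed as quadratic forms in fixed
residual-maker matrices (vectorized over permutations); stages 1 and 2
rebuild only the design blocks that change. Each stage mixes its index
into the seed, so stages are independently reproducible. Calibration at
the study's design size (2 arrangements × 6 lines × 2 sexes × 3 replicates)
is checked by simulation: type-I error at α = 0.05 within the binomial 95%
CI over 500 null datasets, and agreement with parametric p on normal
homoscedastic responses to within 3 binomial standard errors at B = 9999.

The reference-gene homogeneity check is a one-way ANOVA on reference Ct
values across the four sex × arrangement groups (technical replicates
averaged per biological replicate first) plus Levene's test, reported both
median-centred (Brown–Forsythe) and mean-centred; when every group has
zero spread, W = 0 by convention.

## Synthetic data

The generators define the study conditions used by every simulation-based
test; their defaults are the published design sizes (6 + 6 haplotypes,
regulatory-region-sized alignments of 550 bp; 2 × 6 × 2 × 3 expression
design with 5/72 of biological replicates missing completely at random,
matching the 67-of-72 analysed dataset — no mechanism for the missing
replicates is given in the source, so MCAR is assumed).

Haplotype alignments start from a uniform random background that is
repaired until free of spontaneous motif signal (alternating GAA/TTC core
runs ≥ 3, literal GAGAG/CTCTC/ATTTA, and the TATA consensus), so planted
truth is unambiguous; the repair loop only ever mutates positions outside
planted footprints, so it can break a spurious hit but never a planted
motif, keeping the recovery test meaningful. Planted site classes
(fixed differences, exclusive and shared polymorphisms, gap-bearing
columns) occupy distinct random columns outside motif footprints; minor
alleles land on random proper subsets of a population, so realized class
counts equal requested counts exactly.

Expression data are simulated on the ΔCt scale by default: line effects
are zero-mean normal (sd 0.15 cycles), residuals normal (sd 0.3 cycles,
the scale at which a 1-cycle sex effect gives the high power the published
F = 8.55 suggests), technical noise normal (sd 0.1 cycles), and
reference-gene Cts drawn independently of the design (mean 20, sd 0.5).
Effect sizes are the full level difference (added to the O347/male cells).
The `response_scale="relative"` mode instead draws a normal homoscedastic
response directly on the 2^(−ΔCt) scale — the only regime in which the
parametric F null is exact — and is what the permutation-vs-parametric
convergence check uses.

What passing these tests shows: the statistics, the permutation schemes
and the generators agree with their definitions and are well calibrated
under the stated noise model. What they do not show: anything about
sequencing or alignment error, primer-efficiency differences,
non-normal or heteroscedastic real Ct noise, or selection/demography in
real haplotypes — none of which the generators emulate.

## Numerical choices and degenerate inputs

* Alignment statistics use exact integer Hamming distances; no floating
  error accumulates before the final divisions.
* The ANOVA raises a distinct error for a response with no residual
  variance (F undefined) and for designs missing a whole arrangement × sex
  cell or an arrangement with fewer than two lines. The model contains no
  line × sex term, so an empty line × sex cell (possible under MCAR
  missingness) does not block estimation; the generator records it as a
  warning in the truth object.
* Permutation ties count toward the extreme tail (conservative); the +1/+1
  rule keeps every p strictly positive and bounded by 1.
* All-identical alignments: Snn returns the tie-share value (n_own−1)/(n−1)
  rather than erroring; Fst errors because Hb = 0.
* Simulation sizes in the test suite (500 null datasets × 999 permutations
  for calibration; 200 datasets for power; 100 seeds for recovery; 200
  alignments for oracle agreement) follow the package's stated acceptance
  surface.

## Known limitations

* The published concatenated-row scheme and the original software's SS
  type remain undetermined without the deposited data; both alternatives
  are implemented and flagged above.
* Snn permutation p-values are conservative by construction (lattice
  ties); do not interpret them as uniform under the null.
* The in-silico PCR is exact-match by design and will not find products
  for primers with template mismatches.
* Efficiency-corrected ΔΔCt models, heat-induction contrasts and REML
  variance-component estimation are out of scope.
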