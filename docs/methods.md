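# Methods

This note documents the models implemented in `piriscope`, the assumptions
behind the synthetic-data generator, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The library-cloning model behind the β-elimination assay

Each molecule is described by a molar abundance *a* and a methylation
fraction *m* ∈ [0, 1] (the fraction of its cellular copies carrying the
3′-terminal 2′-O-methyl group). Two chemistry/enzymology facts drive the
model:

1. Periodate oxidation followed by β-elimination removes the terminal
   ribose of any copy with free 2′,3′-OH, which blocks adapter ligation.
   Each non-methylated copy is destroyed with probability *e* (the
   *cleavage efficiency*, default 0.98).
2. Methylated 3′ ends ligate with reduced efficiency *b* ≤ 1 (the
   *incorporation bias*, default 0.5) — but only while competing with
   3′-OH ends. After treatment the 3′-OH pool is essentially gone, so the
   surviving molecules clone at full efficiency.

Expected cloning weights per molecule:

    untreated (NT):  w_NT = a · (m·b + (1 − m))
    treated   (T):   w_T  = a · (m + (1 − m)(1 − e))

A library of depth *D* is one multinomial draw of *D* reads over the
normalized weights, so read totals are conserved exactly and all
randomness flows from a single integer seed (independent named
sub-streams per library). Reads are emitted pre-trimmed with constant
qualities; a substitution-rate knob exists but defaults to 0 because
annotation is exact-match by default.

Consequence worth spelling out: the per-molecule CPM ratio is
(w_T / w_NT) · S with S = W_NT / W_T a whole-library factor. In a library
dominated by non-methylated material (miRNAs), S is substantially above 1
— this is exactly why fully methylated piRNAs *gain* relative abundance
after treatment. With the default composition (below) S ≈ 3.5, placing
the three methylation classes at log₂ ratios of about +2.8 / +1.2 / −3.9,
cleanly separated by the fixed ±2 thresholds.

## 2. Spike-in calibration

The four synthesized oligos (SS-22/SS-28 with 3′-OH, mSS-22/mSS-28 with
3′-2′-O-methyl; 22 and 28 nt) are pooled equimolar and added at a fixed
molar share (default 6% of the molecule pool; knob `spike_fraction`).
Depletion efficiency is estimated as 1 − mean retention of the 3′-OH
spikes, with retention the treated/untreated double ratio anchored on the
methylated spikes:

    retention_s = [(t_s / t_meth) / (nt_s / nt_meth)] / b̂

The anchor removes depth differences between the two libraries. The final
division by b̂ corrects for the incorporation bias: methylated anchors
clone at *b* in the untreated library but at ≈1 after treatment, so the
raw double ratio estimates b·(1 − e) rather than (1 − e). Because the
pool is equimolar, b̂ is directly measurable as the untreated
methylated/non-methylated spike count ratio. The correction is on by
default (`bias_correction=True`); without it the estimator is only
consistent when b = 1.

## 3. Methylation classification

Classification applies to molecules annotated to the configured categories
(default piRNA) and expressed above 0.1 CPM untreated. The call is based
on log₂((t_cpm + c)/(nt_cpm + c)) with pseudocount c = 0.5 CPM (keeps the
ratio finite at zero counts); thresholds are strict, so ratios of exactly
±2 fall in `partially_methylated`. Significance uses the exact conditional
binomial: given n = t + nt reads of a molecule, t ~ Binomial(n, p₀) under
no treatment effect, with p₀ the treated share of the two library totals;
p-values are BH-adjusted across molecules and non-significant molecules
default to `partially_methylated` (knob `drop_nonsignificant` removes
them instead, at the cost of an exhaustive partition). The gate is applied
after computing the ratio, so both orders of the gate-vs-threshold
question are reproducible (`adjust="none"` gives raw-p gating).

## 4. RIP enrichment statistics

The design is {input, IP1, IP2, IgG, NoAb} × replicates (default 3).
Counts are compared with a negative-binomial exact test:

* **Normalization.** Median-of-ratios (DESeq-style) size factors by
  default. Rationale: at fixed sequencing depth, a strong pull-down
  (planted gain 16×) depresses every unbound molecule's library share in
  the IP samples; plain CPM then biases fold changes and enrichment
  factors downward by that compositional factor, while scaling on the
  unbound majority removes it. `normalization="total"` restores plain
  CPM. Columns with zero totals (a class that cannot contain the molecule
  type, e.g. input libraries in the fragment analysis) receive a neutral
  factor.
* **Dispersion.** One common φ (Var = μ + φμ²) by method of moments,
  pooled over molecules and classes on normalized counts, clamped to
  [0, 10]; the test degenerates to the conditional binomial as φ → 0.
* **Test.** Replicate counts are scaled to a common library size and
  summed per class; conditional on the pair total t, the class-A sum is
  tested against its null split (NB sums with sizes n/φ), two-sided by
  summing all outcomes no more probable than the observed one. BH across
  molecules, per antibody.
* **Decision rule.** enriched = (log₂FC > 2 ∧ FDR < 0.01); bound =
  enriched in IP1 ∧ IP2 ∧ not NoAb-enriched. Exclusion and intersection
  commute, which the tests assert. IgG is always tested and reported;
  it joins the exclusion only with `exclude_igg=True`, since only the
  no-antibody control defines non-specific bead binding in this design.
* **Enrichment factor.** (mean IP + c)/(mean input + c) on the normalized
  per-million scale, per antibody and pooled; zero-input molecules are
  flagged rather than dropped.

## 5. piRISC target capture and pairing

Reads of 46–75 nt (closed window) are collapsed and assigned to every
transcript containing them as a sense-strand substring; multi-mapping
reads count 1/n per transcript (integer mode available). Transcript-level
enrichment reuses the RIP machinery with total-count normalization (the
fragment pool is small and sparse, so a median-of-ratios reference is not
estimable).

The complementarity rule is this package's explicit definition (the
original study used an external predictor whose internals are not
public): the piRNA pairs the transcript antiparallel; positions 2–11 of
the piRNA (1-based from its 5′ end) must pair Watson–Crick; overall
complementarity ≥ 80% of piRNA length; G:U wobble (piRNA G against
transcript U, piRNA U against transcript G) counts as paired outside the
seed only. All three knobs (`seed_start`/`seed_end`,
`min_complementarity`, `wobble`) are exposed. Coordinates are 0-based
half-open; a site's region (5′UTR/CDS/3′UTR) is decided by its 5′-most
transcript position. Relaxing the overall threshold can only add sites
(tested monotonicity).

## 6. Promoter CpG gates

β values (methylation fractions in [0, 1]) per sample × CpG site. A site
is flagged hypomethylated when ≥ `frac_min` (default 0.10) of tumor
samples lie below the normal-class median minus `delta_min` (default
0.30 β). The defaults are deliberate round numbers — the subgroup size
reported in colorectal cohorts (~14%) is descriptive, not a cutoff — and
an island-level mode applies the same rule to the across-site mean.
The correlation gate computes Pearson r of each site's β against
expression with the two-sided p-value; passing requires p < 0.01 and
r < −0.2. Zero-variance vectors raise instead of returning NaN.

## 7. What the generator emulates — and what it does not

Emulated: the category mixture of a miRNA-dominated somatic small-RNA
library (base abundance shares miRNA .45, rRNA .05, tRNA .10, ensembl
.05, rfam .02, piRNA .20, unannotated .13; within-category lognormal
spread σ = 0.7); per-category methylation (miRNA/rRNA/rfam 0, tRNA and
ensembl 0.5, piRNA and unannotated a 30/30/40 mixture of m = 1/0.5/0);
the treatment-driven composition shift (miRNA share collapses, piRNA
share rises ~2–3×); a planted bound set (10 piRNAs, pull-down gain 16×),
a sticky bead background (5 molecules, gain 8× in all four pull-downs —
exercising the NoAb exclusion); mild biological replicate noise (CV 10%);
and co-captured transcript fragments (46–75 nt, 5% of IP reads) from 10
target transcripts carrying a perfect reverse-complement site of a
distinct bound piRNA in their 3′UTR plus 5 enriched decoys without sites
and 5 idle transcripts. rRNA and tRNA database entries are longer parent
sequences containing the planted fragment, so the cascade's substring
matching is exercised, not just equality.

Not emulated: ligation sequence bias, PCR duplicates/UMIs, adapter
remnants, genome-scale references, multi-locus piRNA families, partial
overlap between databases, and chemistry kinetics of partial
β-elimination. Passing tests therefore demonstrate correctness of the
statistical machinery and decision rules under a faithful abstraction of
the designs — not robustness to every artifact of real libraries.

## 8. Problem sizes and numerical choices

Default study conditions: 158 molecules across 7 categories, 20
transcripts, libraries of 10⁵ reads (the demo pipeline uses 2×10⁴ for
quick runs); RIP in triplicate. Recovery checks in the test suite use
10–20 independent seeds per condition. Ties in multi-hit database matches
break to the lowest-lexicographic identifier; antisense database hits are
not counted (small-RNA databases are directional); sequence uniqueness in
the generator is enforced by cross-substring rejection sampling so planted
categories stay unambiguous. The exact test computes the full conditional
distribution (arrays of length t + 1), which is exact and fast at these
depths; pair totals in the millions would call for a saddle-point
approximation instead.

## 9. Known limitations

* The depletion-efficiency estimator assumes the spike pool is equimolar;
  deviations fold directly into the bias correction.
* The common-dispersion NB test ignores per-molecule dispersion
  differences; with only 2–3 replicates per class, molecule-wise
  dispersions are not estimable, and the planted designs have homogeneous
  noise. Real data with outlier molecules would motivate an
  empirical-Bayes shrinkage instead.
* Transcript mapping is substring-based; it does not model splicing,
  indels, or near-duplicate transcript families beyond fractional
  assignment.
* The methylation caller treats the T/NT pair as unreplicated (the
  treatment triplicates of the original design are collapsed into one
  pair); replicate-aware calling would need a hierarchical count model.
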