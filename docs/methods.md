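# Methods

## Quantification model

Expression is measured by counting 21-mer cDNA tags (NlaIII site CATG plus
the 17 nt released by MmeI). The model assumes sense-strand sequencing
anchored at the 3' fragment, so exactly one canonical tag per transcript —
the 3'-most eligible CATG site — is sampled; sites with fewer than 17 nt
downstream are never cut, and windows containing N are unusable. All
eligible sites of a transcript still enter the mapping index, because
incomplete digestion and internal priming produce non-canonical tags in
real libraries, and mapping must not mistake those for another gene's
signal.

Mapping tolerates at most one substitution (tags are fixed-length, so
indels are not modelled). Exact matches take precedence over one-mismatch
candidates: a sequencing error on one gene's abundant tag must not alias a
different gene's exact tag. Ambiguity is assessed at the gene level — a
tag within distance one of several reference tags of the *same* gene is
still unambiguous; only multi-*gene* candidates are filtered. The library
size N used for TPM (count × 10⁶/N) includes filtered and unmapped tags:
"per million clean tags" is defined on clean tags, not on mapped ones.

## The between-library test

Single libraries carry no replicate dispersion, so differential expression
uses the conditional Poisson (Audic–Claverie) law: given x tags in library
1, the count y in library 2 with size ratio r = N₂/N₁ follows

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),

a negative-binomial mass in y that sums to one over y ≥ 0 (the exponent
x+y+1 is what makes the geometric series close; dropping the +1 inflates
the total to 1+r). All terms are evaluated with log-gamma and
exponentiated once.

Numerical conventions, each isolated behind one function:

- **Two-sided p** = min(1, 2·min(lower, upper)) with inclusive tails; the
  upper tail is computed as 1 − (exclusive lower sum) to avoid infinite
  summation, and is floored at the point mass p(y|x) to guard against
  cancellation when the lower sum approaches 1.
- **Conditioning** is on the first library's count, so swapping libraries
  changes p-values slightly; the asymmetry vanishes with count magnitude
  (≈9% relative at counts of a few hundred, exact equality at x = y with
  equal sizes). Log-ratios flip sign exactly under a swap.
- **Zero floor**: TPM of zero is floored at half of one tag (0.5 × 10⁶/N)
  before any ratio, keeping log-ratios finite while preserving
  |log₂| ≥ 1 for a 0-versus-1-tag contrast at equal depth.
- **Testing family**: only genes with x + y > 0 are tested, and the
  Benjamini–Hochberg family is exactly that set; all-zero genes carry no
  evidence and would only dilute the FDR. Significance means
  q ≤ 0.001 and |log₂ ratio| ≥ 1, ties inclusive.

## Inheritance-mode classification

Mid-parent is the arithmetic mean of the parental TPMs (the standard
mid-parent value in heterosis work). Below-/above-mid use
log₂(F1/MP) ≤ −t / ≥ t with t = 1; underdominant (vs the low parent) and
overdominant (vs the high parent) are flags that are provably subsets of
the outer categories since LP ≤ MP ≤ HP. Genes with all three TPMs zero
are flagged untestable rather than classified.

The "comparable genes" gate tests the hybrid library against a constructed
mid-parent pseudo-library (rounded average counts, averaged library size)
with the same conditional test and FDR threshold. The gate and the ratio
classification are deliberately separate operations: category membership
is a ratio statement, while *calling* a gene non-additive combines the
gate with the ratio (q ≤ 0.001 and |log₂ F1/MP| ≥ 1), matching how such
calls are made in practice. At the scaled depths used here (200k tags per
library, ~100 tags per gene median) the gate is power-limited for scarce
transcripts — a gene needs roughly 80 expected tags for near-certain
detection of a 2.8-fold deviation at q ≤ 0.001 — so recovery statements
about the gate are made either per expression stratum or on the gated
subset. This is a property of the statistics at desk scale, not of the
implementation.

## Pathway enrichment

One-sided hypergeometric upper tail P(X ≥ k), inclusive, with the
background restricted to genes carrying at least one pathway annotation
(published tag-DGE enrichment tables compute their percentage columns on
annotated universes, e.g. 16810 annotated genes rather than ~19,500
detected). Multi-pathway genes count in each pathway; q-values are BH over
the pathways tested in the run. The implementation delegates the tail to
`scipy.stats.hypergeom` and is cross-checked against exact rational
enumeration in the tests.

Recomputing the published table on its printed gene-level contingencies
reproduces the 3-decimal rows (e.g. P(X ≥ 8 | N=16810, K=118, n=291) =
0.001) but not the two most significant rows: the exact tail for the
top row is 4.41e-09 against a printed 1.445e-08, and no standard variant
(binomial, Poisson, Fisher, chi-square, one- or two-sided, ±1 tail
offsets, alternative universes) reproduces all printed values
simultaneously. The printed Q/P ratios indicate a BH family of ~100
pathways, and back-solving them yields internal p-values inconsistent
with the printed counts — the original pipeline evidently computed its
contingencies on a different (database-version-dependent) annotation
granularity than the gene counts it printed. This package reports the
exact tails of the printed contingencies.

## The simulator

`SyntheticConfig` defaults define the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | desk-scale stand-in for ~19,500 detected genes |
| `depth` | 200,000 | keeps the ~10 tags-per-gene-per-100k ratio of 5M-tag libraries |
| `transcript_length` | (200, 2000) nt | typical cDNA range |
| `abundance_sigma` | 1.5 (natural log) | heavy-tailed many-low/few-high tag counts |
| `error_rate` | 0.001 /base | residual error of quality-filtered ("clean") tags |
| `effect_log2` | 1.5 | comfortably recoverable under the ±1 calling rule |
| `category_proportions` | 0.9441 / 0.0089 / 0.0251 / 0.0153 / 0.0066 | published category counts over ~19,500 genes (below-mid-only 490, above-mid-only 173, overdominant 298, underdominant 129) |
| `n_pathways`, `spiked_pathways` | 50, 2 | table-scale pathway count, recoverable spike |
| `annotated_fraction` | 0.86 | 16810-annotated / ~19,500-detected |

The hybrid is constructed per category on un-normalized parental
abundances (additive = MP; above/below-mid = MP × 2^±e; over/under =
HP × 2^e / LP × 2^−e), then every library is renormalized to sum to one.
At the default (realistic) non-additive mass of ~5.6% the renormalization
shifts observed ratios by only ~0.02–0.03 log₂; at artificially heavy
non-additive loads (tens of percent) the shift reaches ~0.3–0.4 log₂ and
places true ratios on the calling threshold, so recovery claims are only
meaningful near realistic proportions. Ground-truth ratios are recorded
pre-normalization; recovery tests compare against the composition-scale
truth (normalized abundances), which is what any relative-abundance assay
can at best recover.

The log-normal abundance choice is a stand-in, not a fit to any deposited
data set. The simulator omits, by design: raw 35-bp reads, adaptors and
base qualities; PCR duplication; indels; antisense tags; replicate
libraries; and correlated (batch) noise. Passing recovery tests therefore
demonstrates correctness of the statistics under multinomial sampling with
independent substitution noise — not robustness to the artefacts real
libraries add before the clean-tag stage.

Determinism: every stage draws from `numpy` Generators seeded from the
config seed via fixed per-stage substream keys, so identical configs give
byte-identical outputs, and re-running one stage in isolation reproduces
it. Transcripts are (re)drawn until all 21-mers are unique across the
transcriptome — random collisions are astronomically rare, but the
guarantee makes noise-free libraries map back exactly.

## qPCR conventions

Relative expression uses 2^−ΔΔCt with amplification efficiency fixed at
2.0 and replicate Cts averaged before differencing (the standard Livak
convention). ChIP signals are expressed as 2^(Ct_control − Ct_target) of a
control amplicon from the same immunoprecipitate, with no additional
input normalization. Standard errors propagate replicate Ct spread by the
first-order delta method: sem(rq) = ln2 · rq · sd(log₂ rq).

## Known limitations

- No replicate/dispersion modelling: the conditional Poisson test is
  anti-conservative against biological variability; with replicated
  designs a negative-binomial framework should replace it.
- One-mismatch mapping cannot rescue tags with two errors (~2% of tags at
  1% per-base error) and has no quality awareness.
- The mid-parent pseudo-library halves the parental evidence by
  construction (rounded averages); it is a modelling convention for the
  "comparable genes" notion, not a statistically optimal pooling.
- Enrichment q-values depend on the set of pathways tested in the run;
  comparisons across runs with different pathway sets are not meaningful.
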