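# Methods

`tcgi` models a pooled dual-guide CRISPR screen in which two protospacers
are expressed from a single Pol III transcript, separated by a tRNA spacer
that endogenous RNase P/Z processing excises to release both functional
guides.  Position 1 of every library member carries a guide against a fixed
*anchor* gene (or a scrambled non-targeting control); position 2 carries a
guide against any gene (or a control).  Comparing construct abundance after
14 days of growth (T14) with the post-selection baseline (T0) yields a
fitness phenotype per construct, and comparing the anchor-target arm with
the control-target arm yields genetic-interaction calls against the anchor.

## Library architecture

The cassette is `adapter5 – gRNA1 – trcRNA – tRNA – gRNA2 – adapter3`,
synthesised as two overlapping half-oligos:

* slot 1: `adapter5 – gRNA1 – trcRNA – tRNA(5′ part)`
* slot 2: `trcRNA(3′ part) – tRNA – gRNA2 – adapter3`

For a 20-nt protospacer each half-oligo is 129 nt; the two share a 31-nt
overlap across the trcRNA/tRNA junction, so overlap PCR yields a 227-nt
product.  The split points are derived from the half-oligo target length
(129 nt) and the component lengths, and the four pool-amplification primers
sit at the resulting termini.  The packaged components use the canonical
76-nt Cas9 single-guide scaffold and a synthetic 71-nt glycine-tRNA-like
spacer sized to this arithmetic (`src/tcgi/data/components.fasta`);
components are configuration, not constants — any FASTA with the required
record ids can replace them.  Assembled cassettes are screened for BsmBI
recognition sites outside the two adapters, since an internal site would
destroy the construct during Golden-Gate cloning.

Scrambled controls are drawn uniformly over ACGT and rejected if present,
on either strand, in an exact k-mer index of a user-supplied reference;
generation is deterministic under a fixed seed and fails loudly (with the
attempt count) if the exclusion set is too dense.

## Read deconvolution

Each mate carries one protospacer followed by fixed cassette sequence: the
forward mate reads gRNA1 then the scaffold; the reverse mate reads back
from the scaffold placed downstream of gRNA2, i.e. reverse-complemented
gRNA2 then reverse-complemented tRNA.  Reads are trimmed at a 12-nt anchor
of the adjacent fixed sequence, truncated to the 19 protospacer bases at
the end where the read enters the protospacer (slot 1: the first 19 bases
of the protospacer; slot 2: the last 19), and reverse mates are flipped
into cassette sense.  Key pairs are matched to the library by exact hash
lookup (optionally allowing one mismatch, which is monotone: it can only
add mapped pairs).  A pair whose two keys both resolve but whose
combination is not a library member is *discordant* (the signature of
template switching or chimeric PCR) and is never assigned; per sample,
`mapped + unmapped + discordant = total pairs` by construction.

The 19-base truncation means the base adjacent to the junction does not
discriminate guides; manifests whose guides collide after truncation are
rejected with an explicit collision listing.

## Screen simulation

The generator is first-class, tested code with a planted truth table.  Its
model: plasmid abundances are log-normal; each construct's per-doubling
log2 growth deficit is `e1·s(g1) + e2·s(g2) + i(g2)` where `s` is the
single-gene effect, `e` the per-guide efficiency, and `i` the interaction
effect applied only to anchor–target pairs; T14 expected proportions are
the T0 proportions times `2^(deficit × doublings)`, renormalized.
Sequencing is multinomial at the configured depth, or negative-binomial
around the multinomial expectation when overdispersion is configured.
Fitness additivity in log-growth with multiplicative guide efficiency is
the simplest model consistent with the additive single-effect adjustment
used in scoring; it is a stand-in, not a biological claim.

Default study conditions (all exposed in `SimulationConfig`, YAML-
configurable through the CLI):

| parameter | default | rationale |
| --- | --- | --- |
| anchor guides / controls in position 1 | 3 + 1 | screen layout |
| guides per gene (position 2) | 3 | screen layout |
| replicates, timepoints | 2, T0/T14 (+ plasmid) | screen layout |
| doublings T0→T14 | 10 | 14 days of exponential growth at ~1.4 d/doubling; the paper-scale interval is not otherwise specified |
| depth | 500 read pairs per construct | comfortably above the ~250× infection coverage |
| NB dispersion | 0.02 | biological-replicate scale (BCV ≈ 0.14) for a cell-line pool |
| plasmid log-normal σ | 1.0 | array-synthesised libraries are uneven (~13× decile ratio) |
| fitness landscape | 5% of genes "essential-like", `s ~ N(−0.15, 0.05)` per doubling; the rest 0 | genome-wide fitness effects are sparse and bimodal |
| anchor fitness | −0.005 per doubling | the anchor is chosen to be viability-neutral on its own — the premise of an anchor screen, and what the validation growth data show |
| guide efficiency | U(0.7, 1.0) | optimized guide libraries |

`single_effect_set` and `interaction_set` plant exact effects for named
genes, which is how every recovery test obtains its truth.

What the generator does **not** emulate: lentiviral MOI/infection
statistics, template-switching recombination, PCR jackpots, sequencing
error beyond uniform substitutions, and the truncated single-guide side
product of the shared-scaffold design (removed by gel purification in the
protocol this models).  Passing recovery tests therefore demonstrate the
*analysis chain* is correct and calibrated under the stated noise model,
not that real screens of arbitrary quality will reach the same recall.

## Interaction scoring

The chain: (1) per sample, subtract the median count of the
control–control constructs and floor at zero, then drop those rows;
(2) keep constructs with ≥5 CPM in ≥2 samples; (3) TMM normalization;
(4) per-construct negative-binomial exact test of T14 vs T0;
(5) gene-level aggregation and ratio calls.

**TMM** follows the published estimator: per column against a reference
column, log-ratios (M) and average log-abundances (A) over rows positive
in both columns are double-trimmed (30% on M, 5% on A, rank-based),
averaged with inverse-variance weights, and the factors rescaled to
geometric mean 1.  The default reference is the column whose 75th
abundance percentile is closest to the mean of those percentiles.  The
implementation agrees with the Bioconductor reference to ~1e-10 on toy
matrices (asserted in the test suite via `Rscript`).

**Differential abundance** uses the exact conditional NB test on
replicate-group sums of counts scaled to a common effective library size,
with Benjamini–Hochberg FDR.  Dispersion is estimated by Cox–Reid adjusted
profile likelihood, in three modes: a single common value (default for the
bare function; verified to give 0.05 type-I error at α = 0.05 on null
simulations), a trended value per abundance bin, and the default for the
full chain, *tagwise*: per-construct estimates on a dispersion grid shrunk
toward the abundance-bin profile with 10 prior degrees of freedom.  The
tagwise mode matters after background subtraction (below).  logFC is
log2 of mean scaled T14 counts over mean scaled T0 counts with a 0.5-count
prior; depletion at T14 is negative.

**Background subtraction and its consequences.**  Subtracting a per-sample
constant comparable to a typical construct's count, then flooring at zero,
is not variance-stabilizing: constructs whose abundance is near or below
the control–control median become uninformative, and constructs just above
it can show spuriously extreme depletion when sampling noise (or a small
composition shift that raises the controls' share at T14) pushes their T14
counts under the median.  Three design choices keep the chain honest under
this transformation:

* *Tagwise dispersion* gives those near-background rows the large
  dispersion their replicate disagreement implies, so they are not called
  significant on their own, without inflating the dispersion of clean
  high-abundance rows.
* *The anchor-alone phenotype is never FDR-gated.*  It is a nuisance
  quantity to subtract, not a hit to test; gating it selects exactly the
  artifact constructs.  It is the plain mean logFC over all anchor–control
  constructs.
* *Gene-level gating* (default): each arm's construct p-values are
  combined per gene by Fisher's method and BH-corrected across genes.  A
  gene is evaluated only if its double-knockout arm passes; a
  single-knockout phenotype is believed (non-zero) only if the single arm
  passes, otherwise it is taken as 0 ("no reproducible single effect").
  This pools consistent weak evidence across a gene's nine double
  constructs — which construct-level gating discards — while one aberrant
  construct cannot carry a gene.  Construct-level gating with a
  reproducibility threshold (`gate="construct"`, `min_sig_constructs`)
  is retained as an option.

**Calls.**  Gene phenotypes are arithmetic means of construct logFC per
arm.  The anchor's own effect is removed additively in log space,
`P_double_adj = P_double_raw − P_anchor` (log-additivity = abundance
multiplicativity; a `divide` mode preserves the alternative reading).  The
ratio statistic is `r = P_single / P_double_adj`, computed only when the
adjusted double phenotype is a depletion (below a −0.1 log2 floor;
otherwise the gene is UNDEFINED and never called), and a gene is called
synergistic when `r < 0.5`, i.e. the adjusted double effect is more than
twice the single effect.  The orientation (single over adjusted-double) is
deliberate and documented here because the opposite reading is possible;
with this orientation, smaller r means stronger synergy, and a neutral
single knockout with a lethal double gives r ≈ 0.

Under the default study conditions, five planted interactions of −2
log2/doubling among 200 genes are recovered with pooled recall ≥ 0.9 and a
false-call rate on non-interactor genes ≤ 0.05 over five seeded screens.

## Amplicon editing quantification

Reads are globally aligned to the ~100-bp wild-type window with affine gap
penalties (match +2, mismatch −3, gap open −5, gap extend −1; a gap of
length L costs open + (L−1)·extend), all configurable; alignments below
60% identity (matches over alignment columns) are UNALIGNED and excluded
from the rate denominator.  Within ±10 nt of the cut site, the largest
overlapping indel wins (deletion on ties); a window substitution with no
indel is SUBSTITUTION; otherwise WT.  The cleavage rate is the edited
fraction of aligned reads; substitutions count by default (`--indel-only`
excludes them, since whether point mutations reflect cleavage is
ambiguous).  Alignment scores are checked against an independent Gotoh
dynamic-programming oracle on exhaustively small instances.

## Validation statistics

Percent transduction is `100 × cells(+puro) / cells(−puro)`.  Bliss
independence expects combined inhibition `iA + iB − iA·iB` from the
single-agent margins (row/column at dose 0); the synergy score is the mean
observed-minus-expected excess over both-drug cells, ×100 (percentage
points).  Negative inhibitions can optionally be clipped to 0 before the
computation (their handling upstream of the model is not standardized).
Relative proliferation fold change is `(T14/T0) / (refT14/refT0)`,
scale-free by construction.  Validation accuracy is `100 ×
confirmed/tested` to one decimal.

## Numerical choices and degenerate inputs

* Correlation of replicates: Pearson on log10(count + 1) or Spearman on
  raw counts; constant vectors are an error, not NaN.
* Exact-test totals above 2×10⁵ pseudo-counts switch to a normal
  approximation of the conditional null.
* TMM on identical columns returns exactly 1 (the M-spread short-circuit),
  and permuting rows never changes factors.
* The background-corrected matrix is rounded to integers (counts), and the
  subtraction can never increase a count.
* 0-based, half-open coordinates throughout; N bases never match a key.
* All stochastic code takes explicit integer seeds; identical seed and
  inputs give byte-identical outputs.

## Problem sizes

Tests and the acceptance script run desk-scale versions of each analysis:
screens of 500–2,520 constructs at 500–2,000 read pairs per construct,
2,000-read amplicon sets, and a single genome-scale cross-product
construction (231,728 members, id-only).  These sizes were chosen so the
full suite completes in well under a minute while every statistical check
retains enough resolution (e.g. 2,000 null constructs bound the type-I
error estimate's binomial half-width at ±0.0096).

## Known limitations

* The median-of-controls background subtraction intrinsically discards the
  lower tail of the library and degrades gracefully only while the pool's
  composition is roughly stable between T0 and T14.  When a large
  abundance share depletes strongly (a fitness-costly anchor, or dense
  strong fitness effects), the controls' relative rise floors a wide band
  of neutral constructs at T14 and the false-call rate of the ratio test
  degrades; equally, TMM's composition correction breaks down once the
  depleted abundance share exceeds its 30% trimming breakdown point.
  These are properties of the published chain, reproduced faithfully, and
  bounded here by the study conditions rather than patched around.
* The ratio statistic is undefined for non-depleting adjusted double
  phenotypes; suppressor (positive) interactions are out of scope.
* Guide-level activity prediction, off-target scoring, and external
  network/enrichment analyses are out of scope.
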