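# Methods

## Scope and data model

`truncscore` scores protein-truncating variants — stop-gains and frameshifts
— on transcript models given as CDS intervals. Coordinates are stored
0-based half-open internally; GTF/VCF input and all public function
signatures use 1-based inclusive positions, converted exactly once at the
boundary. The CDS is taken to include the natural stop codon (CCDS-like
convention), so a transcript with L coding nucleotides encodes L/3 − 1
residues; transcripts whose CDS length is not a multiple of three, or whose
intervals overlap, are excluded at load time with a logged reason rather
than aborting the run.

Only coding exons are modelled. Every feature (truncated fraction, domain
loss, NMD targeting) is computed on coding coordinates, so the "3'-most
exon-exon junction" of the NMD rule is the junction between the last two
*CDS segments*. For a transcript whose final exon contains 3'-UTR sequence
this coincides with the true last junction; when the stop codon and the last
junction fall in different exons the CDS-only junction is shifted 5' of the
true one, making the NMD call conservative (some true targets are called
escapes, never the reverse). Users with full exon structure can compensate
by extending the final CDS interval; the limitation is accepted rather than
guessed around.

## Features

A truncating variant is reduced to the codon containing its (possibly
dialect-adjusted) genomic position; every residue from that codon to the
protein end counts as lost. Frameshifts are treated identically to
stop-gains — truncating from the indel-containing codon onward, with no
scan for a downstream re-encoded stop — because no nucleotide sequence is
modelled and the positional features are the same for both classes. Under
the `esp_frameshift_plus1` input dialect one base is added to reported
frameshift positions so the stored coordinate names the actual indel event;
stop-gains are untouched. Variants falling in the natural stop codon clamp
to the last residue with a warning instead of erroring.

Per gene, with A the set of isoforms whose CDS contains the position:

- `fraction_affected_max` = max over A of (P − codon + 1)/P, P the isoform's
  protein length. Expressed as a fraction (an absolute-residue variant is a
  trivial rescaling and deliberately not a second code path).
- `domain_truncation_max` = max over A and over each isoform's domains of
  the fraction of domain residues at/after the truncation codon. A domain is
  *completely lost* exactly when this fraction is 1. When no domain is
  annotated on any affected isoform the value is imputed to 0 and flagged.
- `n_isoforms`, `ratio_isoforms_affected` = |A| / n. A position is
  *constitutive* when every isoform carries it.
- `principal_truncated`: whether the designated principal isoform is in A;
  without a designation the longest CDS substitutes (ties broken by
  lexicographically smallest transcript id, deterministically) and the
  substitution is flagged.
- `nmd_target`: the premature stop lies strictly more than 50 nt upstream of
  the last coding junction. Single-segment transcripts escape by definition.
  The classifier-level flag aggregates over isoforms as "any affected
  isoform is a target"; the stricter all/some/none classification is kept as
  an analysis flag. The aggregation choice is not dictated by the model —
  "any" was chosen because a single degraded transcript already reduces
  expression — and both views are exposed.

Distance is measured from the variant's first affected CDS nucleotide: the
substituted base for stop-gains, the adjusted indel base for frameshifts.

## Classifier

Mixed naïve Bayes with K = 6 features: four modelled as Gaussian
(`fraction_affected_max`, `domain_truncation_max`, `n_isoforms`,
`ratio_isoforms_affected`) and two as Bernoulli (`principal_truncated`,
`nmd_target`). Fitting is maximum likelihood: class means per continuous
feature and a single pooled intra-class variance vector
ν = E[(xᵢ − μ_cᵢ)²], the plain mean over all N rows (divisor N, not
N − 2, matching the expectation formula literally). Bernoulli rates get
Laplace smoothing α = 1 and variances are floored at 1e−9 (feature units
squared); neither constant affects well-conditioned fits, both prevent
degenerate likelihoods on small or separable training sets. Features are
fitted on raw values; no transform is applied by default (none is clearly
motivated, and the posterior ranking is insensitive to monotone rescalings
only through the fitted means/variances, so this is a real modelling choice
worth stating). The posterior is evaluated in log space and mapped through
the logistic function; the only supported missingness is imputed upstream
(domain truncation → 0, principal isoform → longest CDS), anything else is
an error.

The ranking induced by the posterior is invariant to the shared prior
p₁ ∈ (0, 1); the default is the empirical class fraction and can be
overridden freely.

## Evaluation

- **AUC** is the Mann-Whitney statistic with half credit for ties; the ROC
  curve takes one operating point per distinct score, and its trapezoidal
  area equals the Mann-Whitney value by construction.
- **Subsampling validation**: each iteration draws an unstratified random
  75/25 train/validation split, refits, and scores the held-out rows; all
  held-out (score, label) pairs are pooled across iterations into one ROC.
  Splits leaving a training class with fewer than two rows are redrawn and
  counted; a stratified option exists. All stochastic operations take an
  explicit integer seed and are bit-reproducible.
- **Randomization control**: identical, except every feature column is
  independently permuted across rows once per iteration before fitting.
  The **label-permutation null** likewise permutes the label vector once per
  iteration. A single fixed permutation is *not* an adequate null here:
  train and validation rows come from the same finite dataset and share its
  sampling-level spurious feature–label correlation, which the classifier
  partially recovers (measured pooled AUC ≈ 0.57 at n = 400 under one fixed
  permutation, vs 0.5 under per-iteration permutation).
- Pooling mixes scores from differently-fitted models, so degenerate
  all-ties behaviour (e.g. a constant feature giving AUC exactly 0.5) holds
  only under a fixed prior: with the empirical prior the posterior equals
  each split's own class fraction, which varies across splits.
- **Joint score** = product of the sequence-based and a gene-based
  probability (conditional independence); raw RVIS converts via
  1/(1 + exp(RVIS)), the logistic of its negation.
- **Rank percentile** of a variant = percentage of variants scored strictly
  more pathogenic; 0 is the most pathogenic rank and ties share a value.
- **HWE exact test**: conditional on observed allele counts, the probability
  of each heterozygote configuration is computed by log-factorial
  enumeration and the p-value sums all configurations as or less probable
  than the observed one (two-sided, as-or-less-probable convention — the
  natural reading of "Fisher's exact" for three genotype cells). The filter
  keeps variants with p ≥ α (default 0.05).
- **MAF trend**: logistic regression (Newton/IRLS, tolerance 1e−8) of
  feature presence on log MAF per variant class; slopes compared by the
  heterogeneity z-test z = (β_A − β_B)/√(se_A² + se_B²), valid because the
  classes are disjoint variant sets.
- **Correlation**: Spearman ρ with a paired percentile bootstrap CI.

## Expression validation

Expression is standardized per gene with the population convention
(divisor n; the sample-variance alternative is a parameter away and changes
z by √(n/(n−1))). A variant's impact is the mean z of its carriers for the
affected gene, one value per (variant, gene) pair. Group comparisons use the
one-sided Wilcoxon rank-sum test: exact enumeration for groups of ≤ 25
without ties, the tie-corrected normal approximation otherwise. The quintile
view bins carrier z into five equal-count bins (bin 1 = strongest decrease)
and reports the score rank-percentile distribution per bin.

## Synthetic study conditions

The generators produce every input the pipeline consumes, at desk scale,
with ground truth attached. Defaults, fixed once: 20 genes on autosomes
(1–3 isoforms, weights 0.35/0.40/0.25; 1–6 coding exons of 30–150 nt in
multiples of three; introns 50–500 nt; one single-exon and one
single-isoform multi-exon gene always present for edge coverage), domain
annotations on ~70 % of transcripts, a principal designation for ~80 % of
genes, 100 variants per class, and 50 expression samples. Pathogenic-like
variants land at relative CDS position 0.02–0.30 on the principal (or
longest) isoform with MAF 1e−4–2e−3 and a 50 % singleton rate; benign-like
variants land at 0.70–0.98 on a random isoform with MAF 0.01–0.20. These
sizes keep the full pipeline and test suite in seconds while leaving every
feature informative; class placement can additionally be constrained to
force or forbid NMD targeting for controlled experiments.

Ground truth is computed by brute-force per-base and per-residue
enumeration over explicit coordinate lists — an implementation deliberately
independent of the interval arithmetic in the annotation engine, so the
end-to-end equality check between generator truth and pipeline output is a
genuine oracle test, not a tautology.

Expression is log-normal (log-scale baseline mean 3.0, SD 0.5, noise SD
0.2) with the planted NMD effect: carriers of NMD-target variants have the
affected gene's value multiplied by 1 − 0.5; multiple NMD variants on one
(gene, carrier) cell compound multiplicatively. The direct feature-matrix
sampler draws rows straight from the per-class Gaussian/Bernoulli models
(class-1 means 0.75/0.50/3.0/0.85, shared SDs 0.20/0.20/1.5/0.25, rates
0.80/0.70; class-0 means 0.35/0.15/3.0/0.55, rates 0.35/0.25), which makes
the naïve Bayes assumptions true by construction and enables exact
parameter-recovery and Bayes-optimal-AUC checks.

What passing these tests shows — and does not. The synthetic conditions
satisfy the classifier's independence assumption, plant a clean homogeneous
expression effect, and separate the classes far more than population data
would; AUC ≈ 0.99 here says the machinery is correct, not that real
truncating variants are this separable. Real data add feature correlation,
annotation error, tissue-specific isoform usage and allele-specific
expression, none of which are emulated.

One integer seed drives everything; per-stage streams are derived
deterministically so stages can be regenerated independently, and the golden
bundle checked into `tests/data/golden/` is asserted byte-identical to a
fresh regeneration.

## Known limitations

- No nucleotide sequence: frameshift downstream stop-scan and stop-codon
  read-through are out of scope by design.
- CDS-only transcript models shift the NMD junction 5' when the final exon
  is UTR-containing (conservative direction; see above).
- Variants overlapping several genes are scored once per gene; no
  single-gene attribution is attempted.
- Tissue-specific isoform weighting is not modelled; all isoforms count
  equally in the ratio and maxima.
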