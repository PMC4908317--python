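# Methods

## Motif models and exact p-values

A PWM over the 20 standard amino acids is estimated from the equal-length
binding peptides of one domain (phage display libraries are fixed-length,
so no internal alignment is attempted; at least two peptides are
required). Pseudocount mass `m·κ·b_a` is added to each cell, i.e. a total
of `m·κ` virtual observations per column distributed proportionally to
the background `b`; the default `κ = 0.05` therefore adds one virtual
count per column. Weights are log₂ odds of the column frequency against
the background; zero-frequency cells (possible only at `κ = 0`) are
floored at −30 bits so arithmetic stays bounded. The background is either
uniform or the residue frequencies of the scanned proteome
(`proteome_background`, add-one regularized); the proteome background
reduces composition bias and is recomputed per run.

Window scores are sums of per-column weights (bits). The null
distribution of the score of a background-random window is computed
exactly by column-wise convolution: per-column weights are rounded to a
grid (default granularity 1e-3 bits) and the distribution of their sum is
accumulated one column at a time over the integer grid. The tail function
of this distribution converts scores into p-values; `pvalue_of_score`
rounds the query with the same rule, so the scan and any re-scoring agree
bit for bit. The p-value error induced by rounding is bounded by the
probability mass within `n·granularity/2` of the query score. A score
threshold for a requested p-value is the smallest support score whose
tail probability does not exceed it; requests below the smallest
attainable tail raise an error rather than silently returning the
maximum score.

Column importance is measured by relative entropy against the background,
`IC_j = Σ_a f_aj log₂(f_aj / b_a)`; columns with `IC ≥ 1` bit (default)
are the *significant positions*, the residues over which the per-site
evidence scores average. The cutoff is configurable because the
specificity mass of real SH3 matrices varies; an empty significant set is
an error the caller must handle since the averages are undefined.

## Scanning

Every window of every protein is scored (no heuristic skipping);
coordinates are 1-based inclusive. Windows containing residues outside
the alphabet (X, U, B, ...) are skipped and counted in the scan log —
an ambiguous residue invalidates only the windows covering it.
Overlapping hits are all reported; binding sites are counted
individually. Overlap between two sites is measured as intersection
length over the shorter site's length, so a site nested in a longer one
counts as a full overlap (the denominator is configurable in principle;
the shorter-length convention is the implemented default).

## Peptide evidence

`DR`, `SA` and `PC` are means over the significant residues of a hit:
fraction of residues called disordered (probabilistic tracks binarized at
0.5 by default; 0/1 tracks pass through), fraction exposed (RSA ≥ 0.25,
boundary inclusive), and mean conservation. Conservation tracks may come
from any upstream source; `conservation_from_msa` provides a sum-of-pairs
implementation (mean pairwise substitution score per column, gap pairs
scoring 0, reference-gap columns dropped, z-normalized across columns so
the feature is comparable between proteins; the substitution matrix
defaults to identity and is configurable).

`SC` transfers contacts from co-complex base models. Each model is a
domain sequence, a peptide sequence and residue-pair contact areas
normalized by the model's largest pair (largest contact ≡ 1.0). The query
domain is aligned to the model domain and the query peptide to the model
peptide independently — contacts are defined between the two chains, so
the two alignments share no coordinates — with global affine-gap
alignment (BLOSUM62; first gap residue −10, each further residue −1;
these are the conventional defaults for this matrix). A contact pair
contributes its area only when both of its residues align to query
residues, while the denominator is the model's total number of contact
pairs: a gap at a contact residue therefore lowers the score in
proportion to that contact's area, and repairing a gap can only raise it.
The reported score is the best mean over all base models. Among
co-optimal alignments the aligner's deterministic first traceback is
used; alignment *scores*, which are what the contact transfer depends on
through the aligned-residue sets only weakly, are tie-independent.

## Protein evidence

GO similarity uses a topological-clustering measure. Topology information
content `ICT(t) = −ln(|desc(t) ∪ {t}| / |namespace|)` is computed per
term (natural log, following the measure's convention). Terms meeting the
per-ontology cutoff whose ancestors all fall below it form the cut
frontier; each frontier term roots a sub-graph of its descendants (a term
below two frontier terms belongs to both sub-graphs), and the frontier
plus everything above it forms the meta-graph. Annotation counts are
propagated by the true-path rule; annotation IC `−ln(count/total)` is
normalized by the maximum over each graph's terms, making general and
specific regions comparable. Term-pair similarity is the normalized IC of
the most informative common ancestor, evaluated in a sub-graph containing
both terms when one exists (taking the best across overlapping
sub-graphs) and otherwise in the meta-graph through the terms' sub-graph
roots. The protein-pair score is the maximum over annotated term pairs
(best-match average available as an option). Electronically inferred
annotations (IEA) are excluded at load time by default. The cutoffs for
the three namespaces default to 2.4 (cellular component), 3.5 (biological
process) and 3.3 (molecular function).

Co-expression combines per-profile Pearson correlations in Fisher
z-space: `EX = tanh(mean atanh(rᵢ))`. Profiles where either gene is
absent, fewer than three shared conditions are non-missing, or variance
is zero are skipped with a log record; if no profile qualifies the
feature is *missing*, never a fabricated zero. Correlations at ±1 are
clipped at 1−1e-6 before the transform.

The signature score is estimated from a reference interaction set: every
signature on one side of a reference pair crossed with every signature on
the other side contributes one observation to the unordered pair counts,
and each side's signatures to the marginals. A Jeffreys-style pseudocount
(0.5) keeps all probabilities positive so the score is defined for
unseen pairs. The score of a query pair sums `log₂(p_ij / (p_i p_j))`
over the cross pairs of its signatures — positive for signature pairs
enriched on interacting proteins. Base-2 follows the signature-score
literature; a sign switch is provided for conventions that report the
negated sum.

## Classification and combination

Continuous features are discretized into 10 bins — equal-width over the
known range for bounded features (`DR`, `SA`, `SC`, `CC`, `BP`, `MF` on
[0,1]; `EX` on [−1,1]), training-quantile bins for unbounded ones (`PC`
z-scores, `SS`) — and class-conditional bin likelihoods are estimated
with Laplace smoothing 1.0. Binning makes the likelihoods auditable and
robust to distributional assumptions. Missing values are excluded from a
feature's table at training time and contribute no factor at prediction
time, which under naive independence equals marginalizing the feature
out; consequently scoring with a feature missing is identical to scoring
with a model never trained on it. The class prior defaults to 0.5,
matching training on balanced positives and sampled negatives, and is
configurable for deployment-time imbalance.

The two posteriors are combined by Bayes' theorem under classifier
independence (each posterior carries one factor of the prior, which the
combination divides out once). The formula is symmetric, monotone in each
argument, returns the prior when both classifiers return the prior, and
leaves one posterior unchanged when the other is uninformative.
Boundary posteriors are clipped to [1e-12, 1−1e-12]. Per-pair scores
aggregate site-level records by maximum (one true site suffices for an
interaction); noisy-or is available where sites are believed
independent. Candidates with no evidence in one scope fall back to the
other classifier's posterior; candidates with no evidence at all are
excluded and counted in the run report.

Evaluation reports AUROC (rank statistic with tie averaging), AUPRC
(average precision), Brier score, and F1 / MCC / accuracy at a stated
decision threshold (default 0.9), via scikit-learn.

## Synthetic data

The fixture generator emulates the shape of every input so the whole
pipeline is testable with a known answer key. All sampling is a pure
function of the spec and its seed (independent child streams per
component), so outputs are byte-reproducible.

* Proteome: 60 proteins of 120–220 residues of uniform background
  composition; two 9-mer motifs (class I-like `RKLPPLPKR` and class
  II-like `PAMPARPSV`), each planted 6 times at recorded, non-overlapping
  coordinates. Planted windows and training peptides (30 per motif) are
  sampled from the consensus with 15% per-position noise.
* Tracks: Beta-distributed disorder and RSA (sites Beta(6,2), background
  Beta(2,5)) and Gaussian conservation z-scores (sites N(0.8, 0.6),
  background N(0,1)) — planted sites are disordered, exposed and
  conserved on average.
* Ontology: three namespaces, each a depth-3, branching-3 tree;
  interacting pairs are annotated to a shared leaf, non-interacting pairs
  to leaves under different top-level branches.
* Expression: 6 profiles × 12 conditions; each positive pair shares a
  latent factor with loading √r⁺ (default r⁺ = 0.7), giving the pair an
  expected correlation of r⁺; negatives are independent noise.
* Signatures: 24-signature vocabulary, 1–3 per protein; 80% of positive
  reference pairs additionally carry one of a few favored signature
  pairs, creating the co-occurrence enrichment the signature model
  estimates.
* Labeled feature vectors: class-conditional Beta distributions for
  bounded features and Gaussians for unbounded ones, with parameters
  encoding the qualitative ordering seen in real SH3 data — disorder and
  accessibility strongly discriminative, conservation weak (most yeast
  peptides are conserved whether or not they bind), ontology and
  signature features stronger than expression. An optional missingness
  rate hides each value independently (the "unfiltered" regime).

What the fixtures do **not** model: realistic yeast sequence composition
and domain architecture, correlated features (each synthetic feature is
drawn independently given the class, which flatters the naive Bayes
assumption), annotation sparsity and evidence-code structure of real GO,
and experimental noise structure of real expression compendia. Passing
tests therefore demonstrate mechanical correctness and recoverability of
planted signal, not biological performance; performance numbers on real
curated interaction sets require the external datasets those sets come
from.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately small scale:
toy PWMs with motif length ≤ 4 are cross-checked against exhaustive
enumeration of all 20ⁿ windows; alignment scores against exhaustive
search for sequences up to length 6; classifier recovery uses 2000
vectors per class for training and as many held out. Score-grid
granularity is 1e-3 bits; invariant checks use 1e-9 tolerances and
closed-form identities 1e-12. Determinism is enforced end to end: fixed
tie-breaks in sorting (score descending, then candidate id), fixed float
formatting (6 decimals) in all tables, and seeded generators everywhere,
so identical inputs and seeds yield byte-identical outputs.

## Known limitations

* The significant-position rule (per-column relative entropy, 1-bit
  cutoff) is a reasonable stand-in where the upstream tooling this
  package interoperates with does not document its rule; it is exposed
  as a parameter.
* Contact-area normalization is per model (max pair ≡ 1); absolute
  inter-model area scales are not preserved.
* The ontology similarity assigns overlapping sub-graph membership to
  terms under multiple frontier roots and takes the best; other
  resolutions of the overlap exist.
* The combination formula assumes the two classifiers' errors are
  independent given the class; correlated evidence (e.g. disorder and
  accessibility both reflecting surface loops) makes the combined
  posterior overconfident.
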