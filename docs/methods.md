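# Methods

## Screening model

Candidates are screened with a profile hidden Markov model estimated from
a reference multiple alignment of labeled MPK or MKK proteins.  The
architecture is a Plan-7-style core: one match state per alignment column
whose gap fraction is below 0.5, with insert and delete states between
matches.  Emission and transition probabilities are maximum-likelihood
counts with a Laplace pseudocount (default 1.0); the background is
uniform 1/20, and insert states emit the background, so inserted residues
are score-neutral.  Scoring is local Viterbi in log₂ odds with free entry
and exit at any match state; forward scoring is deliberately omitted so
that an exact brute-force path-enumeration oracle exists and is run in
the test suite for every model with ≤ 4 match states.  Zero-probability
transitions are floored at −10⁵ bits rather than −∞ so the dynamic
program never forms ∞ − ∞; the floor exceeds any feasible path penalty by
orders of magnitude.

E-values come from a Gumbel fit (`scipy.stats.gumbel_r`) to Viterbi
scores of sequences drawn i.i.d. from the background (default 1000
nulls, lengths resampled from the reference set), scaled by the searched
database size.  The acceptance threshold is a full-sequence e-value
≤ 0.01.  Per-domain envelopes, multi-domain parsing and acceleration
filters are out of scope.

## Motif grammar and gating

Signature motifs use a fixed-width grammar: capital letters are exact
residues, `x` is any standard residue, `(A/B/…)` an alternation over
single residues.  Fixed width keeps the scanner exactly equivalent to
naive sliding-window matching, which the tests verify exhaustively.
Windows containing the ambiguity letter X never match (conservative
evidence).  Mandatory MPK motifs are the catalytic C-loop `HRD(L/I)KPxN`
(with a relaxed fallback `D(L/I/V)K`, near-matched with budget 1 to admit
the reported Phe-variant catalytic loops) and the activation-loop
`T(D/E)Y`; mandatory MKK motifs are the relaxed C-loop and `GTxxYMSPER`,
the latter tolerating one mismatch at non-wildcard positions because
GTxxYMAPER/GTxxYMSPEK variants occur in real families.  The P-loop,
ATP-anchor `VA(I/V/M)KK(I/M)xxx(F/Y)`, `DFGLAR` and `TRWYRAPE` are
optional and recorded as flags when absent (short MPKs genuinely lack
the P-loop).  Domain order is encoded relationally — first C-loop <
DFGLAR < T-loop < TRWYRAPE whenever all four occur — rather than by
coordinates, which is robust to length variation.  How many mismatches
the original domain scanners tolerated is not documented anywhere we
know of; budget 1 is a design choice surfaced as a parameter.

## Clade assignment and nomenclature

Family calls combine the HMM decision with motif gating.  Clades A–D are
assigned from the best Smith–Waterman hit (BLOSUM62, gap open −11,
extend −1, BLAST-like defaults) among same-family references; first in
the reference list wins ties.  T-loop type (TEY ⇒ A/B, TDY ⇒ C/D) and
the Hamming distance of the best C-terminal window (last 60 residues) to
the clade's common-docking consensus corroborate the call but never
override the top hit, because real clade-C families retain TEY members;
discordance is recorded.  The docking window uses each consensus's own
length (16 for clade A, 17 for B–D).  Names are species prefix + family
+ homolog number of the top reference; when several queries share a
(family, number), paralog suffixes 1..k follow chromosome natural order
then start coordinate — the published suffix conventions inherit from
homology and do not state an ordering rule, so a deterministic,
data-derived one was chosen.

## Phylogeny

Trees are corroboration, not the classifier.  Distances are
Poisson-corrected p-distances with pairwise gap deletion; trees are
Saitou–Nei neighbor joining, exact on additive matrices (tested against
random additive trees of ≤ 8 taxa and cross-checked against
scikit-bio's implementation).  Negative NJ branch lengths are clamped to
zero with the deficit moved to the sibling branch, preserving path
lengths through the joined pair.  Bootstrap (default 100 replicates)
resamples alignment columns, rebuilds NJ, and annotates the full-data
tree by bipartition matching; replicates whose resampled distances
saturate (p = 1) are skipped.  Maximum-likelihood inference under
JTT+Γ+I is a deliberate deviation replaced by this distance method; the
pipeline's clade calls rest on top-hit classification, with the tree as
a check.  Progressive multiple alignment is not implemented; any
externally produced alignment is accepted.

## Protein properties

Net charge follows the Henderson–Hasselbalch form with a
Bjellqvist-style pKa table (N-terminus 7.50, C-terminus 3.55, D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0), termini counted once and
side chains by occurrence; pI is the zero crossing found by bisection on
[0, 14] (tolerance 10⁻³, guaranteed by the always-ionizing termini) and
is validated against a 10⁻⁴-step grid-search oracle within 2×10⁻³.
Residue-specific terminal pKa variants used by common web calculators
are not modelled; the table is editable.  Molecular weight uses average
(not monoisotopic) residue masses plus one water, additive up to one
water per peptide bond.  Published per-protein pI/Mw values in the
packaged annotation table are consumed as data; computed values are
validated against the oracle and against Biopython loosely, not against
the table.

## Expression

The emulated design is pooled, replicate-free libraries over two tissues
(leaf, root) × four conditions (control, SA, NaCl, Peg).  With no
replication there is no dispersion estimate, so no count-model
inference is attempted: the effect measure is
log₂((TPM + 1)/(TPM_control + 1)) with the control matched within
tissue; the pseudocount is a flag.  Standardization uses the sample
(n−1) standard deviation with a `ddof` switch, dropping zero-variance
rows with a warning.  k-means (k = 4, matching the four reported
response groups; configurable) is seeded kmeans++/Lloyd, best of 50
restarts by within-cluster sum of squares, with the objective asserted
non-increasing per iteration; scikit-learn's KMeans serves as an
independent WCSS oracle in the tests.  Hierarchical clustering is
average linkage on 1 − Pearson correlation (scipy), with merge heights
checked monotone and against a brute-force recomputation for small
inputs.  Heatmap matrices are clipped at |Z| = 4.  Whether the original
interactive analysis clustered log₂FC or standardized TPM is ambiguous;
this package clusters standardized log₂FC.

## Evolution statistics

The relative rate test counts, over triplet sites with no gap or
ambiguity, substitutions unique to each lineage relative to the
outgroup: χ² = (m_a − m_b)²/(m_a + m_b) on 1 df, p from the upper tail
(erfc closed form, via scipy).  Tajima's D runs on residue alignments of
any alphabet after a 95% site-coverage filter: S counts kept columns
with ≥ 2 observed states (multi-state columns count once), π is the mean
per-pair mismatch count with pairwise deletion, and D uses the standard
coefficient set (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) on the count scale
consistently with S.  The infinite-sites assumption is violated on
protein data either way; no correction is applied.  π is reported both
as a count and per-site.  D is undefined at S = 0 and raises.

## Synthetic data

The generator emulates the study conditions end to end: clade archetypes
stamped with the signature motifs in kinase order (TEY in clades A/B,
TDY in C/D, GTxxYMSPER and clade-specific S/T spacing for MKKs,
docking consensi appended C-terminally), homolog numbers distributed
over clades, per-site uniform substitution at a tunable divergence with
motif windows protected, kinase decoys with the activation loop ablated,
and composition-matched shuffles.  Accidental T(D/E)Y occurrences
outside the designated window are scrubbed so planted order constraints
hold by construction.  Gene models follow clade-conditioned exon counts
(e.g. clade-B MPKs 3 exons, clade-C/D MKKs intronless) with paralog
groups placed on distinct chromosomes unless co-location is requested.
Expression draws control TPM log-normal (meanlog 3, sdlog 1) and
multiplies in planted fold changes with Gaussian log₂ noise (default SD
0.25).  All generators are pure functions of (parameters, seed).

What passing tests show — and do not show.  The generator's uniform
substitution model has no BLOSUM bias, no indels inside domains, no
compositional drift, and its decoys are harder negatives than most of a
real proteome (they are true profile matches minus one motif) but easier
than distant kinase relatives.  Recovery ≥ 0.95 at divergence 0.15
therefore demonstrates the funnel's logic and thresholds, not its
performance on real proteomes with fragmentary gene models and
alternative isoforms.

## Problem sizes and numerical choices

Default test/acceptance problem sizes: proteomes of 235 sequences
(10 + 5 planted, 20 + 200 decoys) over 20 seeds; Gumbel calibration with
300 nulls in the recovery runs (1000 by default in the pipeline);
relative-rate simulations with 300–500 sites and 200–1500 replicates —
sizes chosen to give stable Monte-Carlo estimates on a single CPU.  The
observed type-I error of the relative-rate test sits slightly above the
nominal 0.05 (≈ 0.055 over large replicate counts), as expected for the
χ² approximation at ~30 informative sites; individual 500-replicate
estimates fluctuate by about ±0.02.  Bisection and grid tolerances, the
Viterbi score floor, and the NJ clamping rule are described above.

## Known limitations

No nucleotide-level models (splice sites, synteny, Ks dating); no
subcellular localization prediction (consumed as an annotation column);
no de-novo motif discovery; no ML phylogenetics or divergence-time
estimation; hierarchical-clustering dendrograms are exported as linkage
tables rather than rendered figures.
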