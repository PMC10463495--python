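# Methods

## Substitution model

Amino-acid evolution is modelled as a reversible continuous-time Markov
chain on the 20 canonical residues. The generator is built from the
JTT empirical exchangeabilities s_ij and stationary frequencies π as

    Q_ij = s_ij · π_j   (i ≠ j),    Q_ii = −Σ_{j≠i} Q_ij,

then rescaled so that the expected rate at equilibrium,
−Σ_i π_i Q_ii, equals 1; branch lengths therefore remain expected
substitutions per site throughout. The JTT constants are embedded as a
plain-text data file in PAML residue order (A R N D C Q E G H I L K M F
P S T W Y V) and verified against a sha256 checksum at load time.
Frequencies default to the JTT model vector; empirical (+F) frequencies
counted over the non-missing residues of an input alignment are used by
the fitting routine (with a 0.5 pseudocount so no residue has
probability zero) and can be supplied explicitly anywhere a model is
accepted. The exchangeability slot is pluggable — any symmetric
non-negative matrix with a matching frequency vector defines a valid
model — but only JTT constants ship with the package.

Among-site rate variation uses the discrete-gamma approximation: K
equal-probability categories of a Gamma(α, α) distribution (mean 1),
K = 4 by default. Category rates are the conditional means of the
quantile bins, computed from the regularised incomplete gamma function
of shape α + 1, so the rates average to exactly 1 and no silent
rescaling of branch lengths occurs (a median-of-bin discretisation
would need renormalisation). Transition matrices P(rt) = exp(Q·r·t)
are computed through the eigendecomposition of the
reversibility-symmetrised generator D^{1/2} Q D^{−1/2} (D = diag π);
t = 0 returns an exact identity, and entries are clipped to [0, 1]
after an internal row-sum check at 1e−8.

## Likelihood, fitting, ancestral reconstruction

Site likelihoods are computed by Felsenstein pruning, vectorised over
all sites and rate categories, with per-node, per-site log scaling so
long alignments on deep trees never underflow. GAP and ambiguity codes
(B, Z, X, J, U, O) are treated as fully missing data — their partial
likelihood vector is all ones — matching the permissive handling of
incomplete columns in standard ML phylogenetics tools; an all-missing
column has log-likelihood 0.

`fit_parameters` estimates branch lengths and the gamma shape on a
fixed topology by deterministic coordinate ascent: each branch in turn
is optimised by bounded scalar search (bounds [1e−8, 50]) on the edge
decomposition of the likelihood — with the inside partials of the child
subtree and the outside partials of the rest of the tree held fixed,
the log-likelihood is a cheap function of that one branch length — then
α is optimised the same way (bounds [0.02, 99]), and the cycle repeats
until the relative log-likelihood improvement falls below 1e−6 or 100
cycles. A candidate update is accepted only if it improves the
current log-likelihood, so the trace is non-decreasing by construction.
There are no stochastic restarts; fits are reproducible bit for bit.

`marginal_ancestral_states` computes empirical-Bayes marginal
posteriors per internal node and site: inside (pruning) partials are
combined with outside partials obtained by a root-to-node walk, per
rate category, and categories are mixed using each site's posterior
category weights. The MAP residue is the posterior argmax with exact
ties broken in favour of the alphabetically first residue letter, for
determinism. Sites are processed in chunks (default 5,000) to bound
memory on long alignments.

## Null simulation and planted truth

`simulate_null` draws, per site, a rate category uniformly and a root
residue from π, then propagates states along each branch by sampling
from the corresponding transition-matrix row. No indels are produced.
A single NumPy generator seeded from the configuration drives the run;
`generate_orthogroup_set` spawns one child stream per gene from the
master seed, so per-gene alignments do not depend on how many genes are
generated. Planted convergences overwrite the simulated residues
outright — one residue a in every foreground taxon, a distinct residue
b in every background taxon — giving unambiguous ground truth for
recovery tests rather than a selection-driven simulation.

## The study conditions

The built-in tree (`ccs.datasets`) has 14 taxa: six cleaner wrasses as
foreground, two non-cleaner wrasses and six reference teleosts as
background, with the spotted gar as outgroup. The topology follows
accepted relationships for these lineages; branch lengths are plausible
amino-acid distances for a clade spanning roughly 300 My (tip depths
around 0.3–0.35 substitutions per site, short internal branches of
0.015–0.06 within the wrasse radiation). The gamma shape default for
simulations is α = 0.7, a typical value for concatenated vertebrate
proteomes. These values were fixed once as the package's reference
conditions; noise counts scale with them (deeper background branches
produce more misreconstruction, hence more false convergences at the
relaxed stage).

Null simulations for the headline noise report use 100,000 sites, and
parameter-recovery checks use 5,000 sites over three seeds — sizes at
which the statistical behaviour of the method is already stable while a
complete run remains a desk-scale computation.

## Site classification and noise report

A detected (relaxed) convergence requires some residue a carried by at
least m = 3 foreground taxa and absent from every background taxon —
"differs from any background species" is read as differing from *every*
background residue, the only reading under which the CCS restriction is
a strict subset. The CCS restriction additionally requires all
background taxa to share one residue b. The gene-level (CEG) rule is
stricter still: all foreground taxa carry a, all background taxa carry
b ≠ a. If two residues each reach the foreground-share threshold at
one site, the site yields one call per qualifying residue.

Gap handling defaults to `exclude_site`: any GAP/UNKNOWN among the taxa
relevant to the rule removes the site from classification, the
conservative choice. The alternative `treat_as_mismatch` lets missing
cells simply never match anything (a gap in the background breaks
unanimity but not the relaxed rule).

Noise classification on null data compares the MAP residue
reconstructed at the most recent common ancestor of the background taxa
minus the outgroup with the outgroup's observed residue at that site: a
detection is **false** when they disagree (the detection rests on a
misreconstructed ancestral state) and **random** otherwise. Because the
background is paraphyletic on the study tree, that MRCA subtends
foreground taxa too; this is accepted as-is since the audit only needs
a deep background ancestor anchored by the outgroup. A site-level
diagnostic flag also records whether more than two foreground taxa
share a residue with the background, but it is not the primary
classifier — for a detected convergence the convergent residue already
differs from all background residues, so that textual criterion cannot
partition detections on its own. The noise class is a property of the
site (it depends only on the ancestor and the outgroup), so the report
counts sites, not (site, residue) pairs. Percent reduction is
100·(1 − after/before), reported as "n/a" when the before-count is
zero. The report also carries the overall ancestral accuracy: the
fraction of all sites at which the background-ancestor MAP residue
equals the outgroup residue.

## Evidence filters

The dN/dS curation removes a gene when any of the following holds:
dS > 1; N > sequence length; N + S ≥ sequence length + 50 bp;
N·dN < 1; S·dS < 1 (the synonymous site count is named `S_sites` to
avoid clashing with the exchangeability matrix symbol). The PSG
intersection keeps genes with branch-site LRT FDR < 0.05 *and* a BEB
site posterior > 0.95 *and* BUSTED-MH LRT FDR < 0.05 — strict
inequalities as printed by the upstream tools' conventions. The DEG
filter keeps records with FDR ≤ 0.05, basemean ≥ 10 and
|log2 fold-change| ≥ 0.3 — inclusive boundaries, and the effect size is
read as an absolute value because both up- and downregulated genes
qualify. The cross-region direction summary reports two
operationalisations of "reduced expression across all regions": down in
every region where the gene is a DEG (lenient) and DEG-and-down in
every region (strict); both counts are returned because the phrase is
genuinely ambiguous.

## Design choices made where the design was open

* Per-gene vs concatenated fits: both are supported (`fit_parameters`
  takes any alignment); the pipeline treats the concatenated fit as the
  reference use because the noise estimation is defined on a
  concatenated null alignment.
* Polytomies are rejected at parse time rather than arbitrarily
  resolved; resolution belongs upstream where the tree is estimated.
* Site coordinates are 0-based in memory and 1-based in every written
  report.
* The simulator draws the root sequence from the stationary
  distribution, the standard convention for equilibrium simulations.

## What the synthetic data does and does not show

The generator emulates independent, identically distributed
gap-free columns under a stationary, homogeneous JTT + gamma process
with planted strict-parallel sites as positive controls. Real
orthogroup alignments violate several of these assumptions — indels and
alignment error, compositional heterogeneity across lineages,
site-specific constraint shifts, and correlation between neighbouring
sites. Passing the recovery and noise tests therefore demonstrates the
correctness of the algorithms under the stated model, not robustness of
the biological inference to model violations; on real data the
false-convergence rate after the CCS restriction need not be exactly
zero.

## Numerical tolerances

Likelihoods agree with exhaustive state enumeration to 1e−10 on small
trees; ancestral posteriors normalise to 1 within 1e−8; generator rows
sum to zero within 1e−10; discrete-gamma category rates average to 1
within 1e−12; transition-matrix rows are checked to sum to 1 within
1e−8 before clipping. Re-rooting changes the likelihood by < 1e−8
under reversibility.

## Known limitations

No codon models (upstream selection scans are consumed as tables, only
their stated thresholds are applied); no topology search; no joint
ancestral reconstruction; no indel simulation; no statistical
significance attached to CEG counts — the scan reports raw counts, as
the underlying screening procedure does.
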