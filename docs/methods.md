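# Methods

## Scope and data model

The package analyses a fixed seven-taxon clade of non-WGD yeasts with the
two *Dekkera* species (and their stem branch) labelled as the foreground
class. Real inputs are per-species genome FASTA, GFF3 gene coordinates,
protein/CDS FASTA, gene-set and GO label TSVs and a newick guide tree with
`#1` branch marks; the synthetic-data module can generate all of these with
full ground truth, and the bundled tests and the acceptance script run
exclusively on such synthetic worlds. Codon alignments are assumed given
in-frame and aligned (synthetic alignments are gap-free by construction);
no aligner is bundled.

## Codon substitution model

The engine implements the Goldman–Yang (GY94) model on the 61 sense codons
of the standard code. The instantaneous rate i→j is zero for multi-position
changes and changes into stop codons, otherwise

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

with the diagonal set so rows sum to zero. Codon frequencies π default to
F3x4 (position-specific nucleotide composition of the analysed alignment);
F61 and equal frequencies are options. The model is reversible, so the
likelihood is root-invariant; transition matrices are computed from the
symmetrized eigendecomposition (D Q D⁻¹ with D = diag(√π)), cached per
(κ, ω), with `scipy.linalg.expm` retained for the public
`transition_probabilities` entry point and used by the test oracles.

**Scaling.** Every branch's generator is rescaled so one unit of branch
length equals one expected substitution per codon at stationarity. For the
branch-site mixture the scaling factor of a branch is the expectation over
the four site classes of the class-specific rates on that branch, so site
classes keep their relative speeds while branch lengths keep their units.
The simulator uses the same convention, which makes simulated and fitted
branch lengths directly comparable.

**Models.** One-ratio (M0), free-ratio (one ω per branch), two-ratio branch
(ω per branch class) and branch-site model A. Model A mixes four site
classes — (0) ω₀ < 1 everywhere, (1) ω = 1 everywhere, (2a) ω₀ background /
ω₂ foreground, (2b) 1 background / ω₂ foreground — with proportions
p₀, p₁, p₂a = p₂·p₀/(p₀+p₁), p₂b = p₂·p₁/(p₀+p₁). The null fixes ω₂ = 1.
Gaps and ambiguous codons are missing data (all-ones conditional vectors);
per-site log-likelihoods are rescaled per node to avoid underflow.

**Fitting.** Bounded L-BFGS-B on transformed parameters (log κ, log ω,
log branch lengths, logit ω₀, log(ω₂−1), softmax logits for the
proportions), multi-start with jittered initial points (3 starts by
default; heavy simulation loops use 1), lnL tolerance 1e-8. Branch lengths
are optimised jointly under M0 and then held fixed for the free-ratio,
branch and branch-site fits (two-stage protocol); whether per-gene branch
lengths should be re-estimated is genuinely open, and the two-stage choice
trades a small loss of per-gene flexibility for stability and speed at
desk scale. The branch-site alternative is warm-started from the fitted
null with ω₂ nudged to 1.3 — at ω₂ = 1 the log(ω₂−1) coordinate has a
vanishing gradient and the optimiser would stall — and the exact null
representation is evaluated as a final candidate so the alternative can
never score below the null it nests.

**Tests and site identification.** LRTs use 2ΔlnL against χ²(df);
significance at α = 0.05, which for df = 1 is the 3.84 boundary. The
branch-site LRT uses χ²(1) rather than the ½:½ boundary mixture, matching
the conventional 3.84 criterion (conservative for the null on the
boundary). Site identification is naive empirical Bayes at the MLE:
posterior class probabilities per site from the class likelihoods times the
fitted proportions; full Bayes-empirical-Bayes averaging over a parameter
prior is out of scope, and the 0.95 flagging threshold is configurable.
Nei–Gojobori (1986) pathway-averaged counting with Jukes–Cantor correction
is implemented independently of the likelihood path as a cross-check; when
a difference proportion reaches the JC pole (p ≥ 3/4) the uncorrected
proportion is reported with a saturation flag, and ω is undefined when
dS = 0.

## Synthetic data

Sequences evolve by per-branch Gillespie jump sampling (exponential waiting
times on the embedded chain), not by draws from P(t), so that every
substitution is recorded — branch, site, from/to codon, syn/nonsyn flag,
time. This ledger is the oracle for the recovery tests: expected events per
codon per unit branch length is 1 by the scaling convention, ω = 0 yields
zero nonsynonymous events, zero-length branches yield identical leaves.
A separate generator draws data under branch-site model A itself (site
classes sampled from the fitted proportions, mixture-scaled rates), which
is the correct generating process for testing the branch-site fit: genes
simulated with per-branch-scaled uniform ω deliberately lack the
class-rate elevation model A expects.

Promoters are i.i.d. uniform ACGT, the simplest null with a known per-window
motif hit probability. Planting places exactly one AATTTT or its reverse
complement AAAATT (fair coin) at a uniform start inside the chosen window;
under the `exclude` background policy the assembled promoter is
rejection-sampled until its motif occurrences are exactly the planted ones,
so the planted ledger is exhaustive. Genome assembly alternates gene
strands, placing each promoter immediately upstream of its gene in coding
orientation on either strand; gene coordinates are 1-based inclusive GFF3.
Default study conditions: 7 species on the fixed guide tree, 600 bp
promoters in twelve 50 bp windows, κ = 2, uniform codon frequencies,
background ω = 0.2. What the generator does **not** emulate: indels and
alignment error, paralogy and gene loss, non-uniform intergenic
composition, nucleosome structure, and among-site rate variation beyond the
branch-site classes — so passing recovery tests demonstrate correctness of
the estimators under the model's own assumptions, not robustness to real
genomic mess.

## Orthology

Protein pairs are scored with Smith–Waterman local alignment (BLOSUM62,
affine gaps 11/1, a gap of length L costing open + (L−1)·extend). A pair is
a reciprocal best hit when each member is the other's unique argmax at or
above the score threshold (default 50; the choice is arbitrary units, there
being no published cutoff to inherit); ties disqualify, which is the
conservative reading of one-to-one filtering. Clusters are assembled
reference-star style (every species against one reference species) and
retained only when every species contributes exactly one gene and no gene
is claimed twice.

## Promoter motif profiles

Windows are anchored at the start codon and counted outward (window 1 =
1–50 bp upstream). A motif occurrence belongs to the window containing its
5'-most base; the statistic is gene-level presence (≥ 1 occurrence starting
in the window), with raw occurrence counts kept in the audit table.
Truncated promoters enter a window's denominator when they cover any of its
bases, so denominators vary per window. Cross-species comparison is a
repeated-measures ANOVA with windows as subjects and species as the
within-subject condition, computed directly (two-way layout without
replication, error = species×window interaction) so the degenerate strata
have defined behaviour: zero condition variance reports F = 0, p = 1; zero
residual with non-zero condition variance is flagged degenerate rather than
reported as a spurious finite F. The factor/subject layout is a design
choice the source analysis leaves open; the direct implementation is
cross-checked against `pingouin.rm_anova` on non-degenerate data.

## Category rates and fold classification

Per-gene foreground/background rates are the medians of per-branch ω within
each branch class from free-ratio fits; branches with ω at the optimisation
ceiling (the dS→0 pathology) or near-zero length are excluded, and a gene
with an undefined group rate is excluded from fold classification. GO terms
need more than five member orthologs; each term's rates come from a
free-ratio fit to the concatenated member alignments. Enrichment is a
two-sided exact binomial test of the count of foreground-faster genes in
the term against the genome-wide foreground-faster proportion — the
construction uses only quantities the pipeline itself computes; a
substitution-count binomial would be an alternative reading — with
Benjamini–Hochberg adjustment across terms at adjusted p < 0.05.

## Codon adaptation index

Relative adaptiveness w is codon count over the maximal synonymous count in
the reference set, with a 0.5 pseudo-count for unobserved codons (an unseen
whole family falls back to uninformative w = 1). CAI is the geometric mean
of w over codons excluding Met, Trp and stops. The reference set defaults
to the species' CRP (cytoplasmic ribosomal) genes, the conventional
highly-expressed proxy, since no reference set is prescribed by the
analysis this reproduces. z-scores use the sample standard deviation of the
genome CAI distribution and are undefined at zero spread.

## Structure mapping

PDB ATOM records are parsed with Biopython (first model, HETATM ignored,
highest-occupancy altLoc conformer); author residue numbering is preserved.
Side-chain distance is the minimum over atom pairs, either over all atoms
beyond Cβ or over charge groups (Glu/Asp carboxylate oxygens, Arg
guanidinium nitrogens, Lys NZ, His ring nitrogens) — the charge-group
minimum is the implemented reading of "distance between side chains" for a
salt-bridge claim. Site-to-residue mapping is a global pairwise alignment
(BLOSUM62, gaps 10/0.5) of the query protein against the sequence derived
from structure residues, refused below 30% identity. No crystal-structure
file is bundled; structure tests run on synthetic fixtures with geometry
known by construction.

## Pipeline and problem sizes

The pipeline chains simulate → orthology → alignments → motifs → model fits
→ categories → selection scan → CAI (→ structure), logging one line of
parameters per stage, and writes per-stage TSVs, two figures and a
`report.json` whose numbers are all recomputable from the TSVs. Reports are
deterministic under the seed. The CLI exposes each stage as a subcommand
(`simulate`, `orthologs`, `motifs`, `rates`, `selection`, `cai`,
`structure`, `report`, `all`).

Default problem sizes are chosen for single-CPU desk scale: pipeline smoke
worlds of 8–10 genes × 45–60 codons; recovery studies of 20 replicates at
500 codons; LRT null calibration of 200 replicates at 100 codons with
branch lengths held at their simulated values (isolating the ω test from
branch-length estimation noise, which also keeps the calibration loop
fast); motif recovery over 2,000 promoters. The acceptance script derives
every sub-seed from its `--seed` argument.

## Known limitations

* NEB rather than BEB site identification (documented above); posterior
  flags at 0.95 are conservative on short genes.
* The free-ratio model with fixed branch lengths can pin per-branch ω at
  the bound when a branch carries no synonymous signal; such branches are
  excluded from medians rather than imputed.
* The RBH stand-in scores every gene pair exactly (no heuristic seeding),
  which is quadratic in proteome size — appropriate for the desk-scale
  synthetic worlds, not for full genomes.
* The repeated-measures windows are spatially autocorrelated in real
  promoters; treating them as exchangeable subjects is a simplification.
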