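# Methods

## The model

`evoscape` simulates experimental protein evolution as a stochastic process
in a data-driven sequence landscape. The landscape is a Potts model over
aligned sequences of length L on the 21-state alphabet (gap + 20 amino
acids, fixed order `-ACDEFGHIKLMNPQRSTVWY`): fields h_i(a) and pairwise
couplings J_ij(a,b) define the statistical energy

    E(a_1..a_L) = - Σ_i h_i(a_i) - Σ_{i<j} J_ij(a_i, a_j),

with sequence probability P ∝ exp(−E). Low energy is a proxy for high
fitness; the couplings encode epistasis, and the strongest ones reflect
residue–residue contacts. Landscapes are supplied as externally inferred
parameter files (e.g. from Boltzmann-machine DCA on a family alignment) or
generated synthetically (below). A fields-only profile model is the
non-epistatic baseline throughout.

Evolution runs at the nucleotide level while selection acts on the protein.
The state is a coding sequence paired with its translation (standard
genetic code; a gap is a triplet of gaps and is never touched; stop codons
are excluded everywhere). One Monte Carlo step:

1. choose a non-gap site i uniformly at random;
2. choose the replacement amino acid b from the accessible set
   A_acc(codon_i) — the translations of the codon and of its nine
   single-nucleotide neighbors, stops removed — with probability
   P(b) ∝ exp{β [h_i(b) + Σ_{j≠i} J_ij(b, a_j)]}, i.e. ∝ exp(−β ΔE);
3. choose the new codon uniformly among the sense codons of b within one
   nucleotide of the current codon.

Every step counts, including synonymous and identity moves, so the Hamming
distance to the wildtype never exceeds the step count. A library is M
independent chains started in the wildtype; snapshots at several step
counts reuse the same long runs, and smaller libraries are drawn by seeded
subsampling without replacement — this mirrors how large simulation scans
are made affordable.

The selection temperature T = 1/β scales selection strength. T = 0 is
implemented as an exact argmax over the accessible set with uniform
tie-breaking (greedy directed evolution; avoids overflow of exp(βx)), and
T = ∞ as β = 0 (mutation accumulation without selection). An auxiliary
`seec` mode proposes all 20 amino acids regardless of codon accessibility;
at β = 1 it is a random-scan Gibbs sampler of the landscape and is used for
stationarity tests and for quantifying what codon accessibility changes.

Because the genetic code makes the process a Markov chain in nucleotide
space but not in amino acid space, site selection over non-gap sites
(uniform resampling vs reject-and-repeat on gaps) is operationally
identical; the implementation samples uniformly from the non-gap site list.

## Calibration

Two simulation parameters have no direct experimental counterpart and are
fitted to library statistics:

* **Chain length N_MC** is matched to the reference library's mean Hamming
  distance: a pilot library records the mean-distance trajectory and the
  smallest step whose mean is closest to the target is taken.
* **Selection temperature T** is tuned so that simulated libraries
  reproduce the reference's energy-versus-distance slope: per-sequence
  ΔE = E(seq) − E(wildtype) is regressed on Hamming distance by OLS with a
  free intercept (binned means are available as an option). For each
  candidate T the chain length is first matched to the reference
  divergence; candidates that cannot reach it within the step budget are
  disqualified, because a slope measured at lower divergence is
  systematically smaller along the saturation curve and not comparable.
  Each candidate uses an independent pilot RNG stream, and the final
  estimate inverts an isotonic (monotone) fit of slope versus log T at the
  reference slope; the inversion averages pilot noise over candidates,
  which proved markedly more stable than picking the single
  nearest-slope candidate, and refinement rounds add candidates by
  bisection around the current crossing. Defaults: pilot libraries of 500
  chains, 400 steps, 4 refinement rounds.

`slope_subsample_error` quantifies slope estimation error by repeated
subsampling without replacement; on synthetic libraries the spread shrinks
with subsample size and stabilizes by a few hundred sequences, so T can be
estimated from moderate sequencing effort.

## Library statistics and contact prediction

Library comparisons use Hamming distances to the wildtype, site-specific
frequency spectra f_i(a), Spearman correlations between spectra (entry
filters: all entries / non-wildtype entries / only amino acids accessible
from the wildtype codons — the default, since accessibility dominates which
entries can be populated at all; all three are reported in verbose use),
and per-distance energy profiles.

Contact scores are a Gaussian DCA: sequences are one-hot encoded over q−1
states per site (the gap is an ordinary state; the last alphabet state is
dropped), one- and two-site frequencies are computed with optional
phylogenetic reweighting (w_s = 1/#{t: identity(s,t) ≥ threshold}; off by
default for simulated libraries, whose chains are independent by
construction; 0.8 is the default threshold for experimental alignments) and
mixed with a pseudocount λ toward the uniform independent model (λ/q for
one-site, λ/q² for two-site; default λ = 0.6, with 0.5 used for the
acetyltransferase-style setting). The inverse of the covariance matrix
yields coupling blocks; the pair score is the Frobenius norm of the (i,j)
block, followed by the average-product correction
S'_ij = S_ij − S_i·S_·j/S_·· over off-diagonal means. Ranking excludes
pairs closer than the minimum separation and breaks ties lexicographically
for determinism.

Contacts are defined from minimal heavy-atom distance tables: distance
strictly below 8 Å (5.5 Å for families with well-represented structural
variability) and separation ≥ 5 positions. Prediction quality is PPV@n,
the fraction of true contacts among the top n ranked pairs (n = 100 at
protein-family scale; the desk-scale studies use n = 20, of the order of
the number of planted contacts). A permutation Monte Carlo provides the
null distribution of PPV under random ranking (mean equal to the contact
density among eligible pairs).

`parameter_scan` maps mean PPV (with replicate sd and mean divergence) over
grids of (T, steps, M), simulating one max-M library per (T, replicate) and
subsampling the rest.

## Synthetic data

The generator emulates the study conditions end to end:

* `random_potts` — sparse landscapes with planted contacts: i.i.d. Gaussian
  fields (sd `field_scale`) and Gaussian coupling blocks (sd
  `coupling_scale`) only on a planted edge set (Erdős–Rényi over pairs with
  separation ≥ 5 by default; chain and 2D-lattice topologies for sampler
  tests). Coupling rows/columns touching the gap state are zeroed (gaps do
  not interact), and the model is returned in the zero-sum gauge. The fast
  default (L=30, q=4, edge probability 0.08, scales 0.75/0.4) puts
  single-mutant |ΔE| from a low-energy wildtype in roughly [0, 4], the
  dynamic range typical of mutational-effect predictions; codon-level
  integration studies use q=21 with unit scales, which gives planted-edge
  signal strong enough to recover at library sizes of a few hundred.
* `gibbs_sample` — equilibrium alignments ("natural homologs") by
  heat-bath sweeps, exact against enumeration at L=3, q=3 (total variation
  < 0.01 at 10^6 steps).
* `synthetic_wildtype` — a greedy quench truncated after 3 full coordinate
  sweeps (2 by default in the integration landscape helper), then random
  synonymous codon assignment. Truncation matters: a quench to convergence
  would put the wildtype at a strict local optimum, where strong selection
  could no longer decrease energy; real wildtypes are highly fit but
  improvable. The wildtype still lands well below the equilibrium energy
  distribution.
* `toy_bm_learn` — persistent-chain Boltzmann-machine learning, guarded to
  L ≤ 25, q ≤ 8. It exists to close the inference → simulation → contact
  recovery loop in tests and is not a production inference engine.

What the generator does **not** emulate: error-prone PCR mutation biases,
transition/transversion asymmetry, codon usage bias, multiple mutations per
selection round, indels, and phylogenetic correlation between library
members. Passing tests therefore demonstrate the correctness of the
machinery and the qualitative emergence phenomena on clean landscapes, not
quantitative agreement with any particular experimental system.

## Validation studies and problem sizes

`evoscape.validation` contains the self-contained studies behind
`tests/test_acceptance.py` and `scripts/acceptance.py`. Oracles are
independent of the code paths they check: brute-force double-loop energy
sums, exhaustive single-nucleotide codon enumeration via an independent
translation table, exact state enumeration for stationarity, permutation
nulls for PPV. Library-level studies run on a 21-state planted-contact
landscape (L=30, 25±5 planted contacts): temperature recovery uses
reference libraries of 1000 chains at a target divergence of 8
substitutions and pilot budgets of 800 chains (recovered within 15%
relative error for T* ∈ {0.5, 1.0, 1.4, 2.0}, 3 replicates each);
emergence scans use 5 replicates over steps {1, 40, 150} × depths
{30, 200, 800} with PPV@20; the selection-strength scan runs 5 replicates
over T ∈ {0.05, 0.5, 1.4, 4, 20} at 80 steps and depth 600. These sizes
were chosen as the smallest at which the phenomena are unambiguous.

Statistical checks with many simultaneous cells (one-step selection
frequencies, β = 0 uniformity) report per-cell multinomial z-scores and are
judged by the number of >3σ cells against its binomial expectation, since a
rare 3σ excursion among ~200 cells is expected. Near-zero-divergence PPV
cells are compared against the spread of the permutation-null distribution
itself, because replicate rankings there are strongly correlated and do not
constitute independent draws.

## Numerical choices and edge cases

* Conditional distributions are max-shifted before exponentiation;
  normalization is checked to 1e-12.
* T = 0 ties are broken uniformly within a relative tolerance of 1e-12.
* Per-chain RNG streams are spawned from the master seed (`SeedSequence`),
  making libraries reproducible and chains independent; each step consumes
  exactly three uniforms.
* Chain energies are tracked incrementally from local fields and agree with
  full re-evaluation to ~1e-13 over 300-step runs.
* The parameter file format is a documented plain-text dialect
  (`h i a value`, `J i j a b value`, upper-triangular J on write,
  symmetrized on read, exact round trip via shortest float repr).
* Degenerate inputs raise informative errors: all-gap sequences (no mutable
  site), single-distance libraries (degenerate slope design), singular DCA
  covariances (advice to raise the pseudocount), unreachable divergence
  targets.

## Known limitations

* The profile model's pseudocount (default 0.01) and the entry filter of
  the spectra correlation are conventions, not inferred quantities; both
  are parameters.
* Gaussian DCA is used for throughput; absolute PPV values would differ
  with pseudo-likelihood scoring, though the emergence structure should
  not.
* The calibration assumes the energy-versus-distance relation is compared
  at matched divergence and that slope grows monotonically with T in the
  scanned range; both hold on the synthetic landscapes studied here and in
  the moderate-divergence regime the method targets, but saturation (mean
  distance approaching the number of mutable sites) degrades the slope as
  a statistic.
* Desk-scale landscapes (L≈30) cannot exhibit the sequence-number
  thresholds of real protein families (PPV transitions near 10^4–10^5
  sequences at L≈200); the package reproduces the structure of those
  phenomena, scaled down.
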