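# evoscape

Stochastic models of experimental protein evolution in data-driven
sequence landscapes.

In vitro evolution experiments alternate random mutagenesis (error-prone
PCR) with selection for function, producing libraries of functional
sequences some 10–40 substitutions away from a wildtype. `evoscape` models
such experiments as a Markov chain over coding sequences: single-nucleotide
mutations are proposed through the standard genetic code, and selection
acts on the translated protein through a Potts (direct coupling analysis)
statistical-energy landscape

    E(a_1..a_L) = − Σ_i h_i(a_i) − Σ_{i<j} J_ij(a_i, a_j),   P(a) ∝ e^{−E(a)}

with a replacement amino acid b at site i accepted from the codon-accessible
set A_acc with probability ∝ exp{−β ΔE}. The selection temperature
T = 1/β tunes selection strength from greedy directed evolution (T → 0) to
neutral mutation accumulation (T → ∞). The package is aimed at
computational biologists who want to reanalyze evolved sequence libraries,
forecast the outcome of evolution protocols, or study when epistatic
(coevolutionary) signal becomes detectable in a library.

It provides:

* Potts/profile landscapes: energies, single-mutant ΔE scans, local
  conditionals, gauge transforms, a plain-text parameter format
  (`evoscape.landscape`);
* the genetic-code accessibility structure and codon/protein paired states
  (`evoscape.codons`);
* the codon-level mutation–selection chain with snapshotting, plus an
  amino-acid-level Gibbs ("SEEC") mode (`evoscape.evolver`);
* calibration of (T, N_MC) to reference libraries via mean divergence and
  the energy-versus-distance slope, with subsampling error analysis
  (`evoscape.calibrate`);
* library statistics: Hamming distances, mutational spectra f_i(a),
  spectra correlations, energy–distance profiles (`evoscape.libstats`);
* Gaussian-DCA contact scoring with APC, PPV evaluation against
  distance-defined contact maps, permutation nulls, and (divergence,
  depth, T) parameter scans (`evoscape.contacts`);
* synthetic landscapes with planted contacts, equilibrium samples,
  low-energy wildtypes and a toy Boltzmann-machine learner, so everything
  is testable without external data (`evoscape.synthgen`);
* a statsmodels-style front-end (`SequenceEvolutionModel.fit()` →
  `SequenceEvolutionResults`), config-driven pipelines
  (`evoscape.pipeline`) and an `evoscape` CLI.

## Worked example

Calibrate the selection temperature against a (here: simulated) reference
library on a synthetic planted-contact landscape, then predict contacts
from a library generated at the fitted parameters:

```python
from evoscape import (SyntheticLandscapeSpec, random_potts, synthetic_wildtype,
                      SequenceEvolutionModel, CalibrationBudget,
                      gauss_dca_scores, ppv)

spec = SyntheticLandscapeSpec(L=30, q=21, coupling_scale=1.0,
                              field_scale=1.0, seed=0)
landscape, contact_map = random_potts(spec)
wildtype = synthetic_wildtype(landscape, seed=1)

model = SequenceEvolutionModel(landscape, wildtype)
reference = model.simulate(T=1.4, n_steps=40, n_chains=1000, seed=2)
model.reference = reference.msa()          # pretend this came from an experiment

results = model.fit(T_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
                    budget=CalibrationBudget(n_pilot=500, max_steps=200, seed=3))
print(results.summary())

lib = results.simulate(n_chains=800, seed=5)
scores = gauss_dca_scores(lib.msa(), pseudocount=0.6, q=21)
print("PPV@20:", ppv(scores, contact_map, 20))
```

Output:

```
Sequence evolution calibration results
==============================================
landscape            L=30, q=21, Potts
mode                 codon
reference library    M=1000
wildtype energy      -72.027
----------------------------------------------
selection temperature T   1.32
chain length N_MC         43
target mean Hamming       11.187
target dE/distance slope  1.4589 (se 0.0521)
candidate temperatures    9
==============================================
PPV@20: 0.5
```

The fit recovers the generating temperature (1.32 vs the true 1.4, ~6%)
and the chain length reproducing the reference's mean divergence of ~11
substitutions; the energy of evolved sequences rises by ~1.46 per
substitution at this selection strength. A library of 800 sequences at the
fitted parameters already ranks planted contacts far above the random
baseline (PPV@20 = 0.50 against a contact density of ~0.08 among eligible
pairs).

The same steps are available from the shell:

```bash
evoscape synth make-landscape -L 30 -q 21 --seed 0 --out land
evoscape synth wildtype --model land.params --seed 1 --out wt.fasta
evoscape simulate --model land.params --wt-dna wt.fasta -T 1.4 \
    --steps 40 --chains 1000 --seed 2 --out library/
evoscape calibrate --model land.params --wt-dna wt.fasta \
    --reference library/library_step40.fasta --out calibration.json
evoscape contacts score --msa library/library_step40.fasta --out scores.tsv
```

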