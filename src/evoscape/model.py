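"""Model/Results front-end for evolutionary simulation and calibration.

:class:`SequenceEvolutionModel` bundles the data defining an in-silico
evolution experiment — a Potts (or profile) landscape, a wildtype with its
codon assignment, and optionally a reference library of evolved sequences.
``fit()`` calibrates the two free simulation parameters (selection
temperature T and chain length N_MC) against the reference library and
returns a :class:`SequenceEvolutionResults` carrying the estimates, their
uncertainty diagnostics and a ``summary()`` table; ``simulate()`` (on the
model or at the fitted parameters on the results) generates libraries, and
plotting helpers render the energy-versus-distance and frequency-spectrum
views used to compare simulation with experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import PROTEIN
from .calibrate import (CalibrationBudget, CalibrationResult,
                        energy_vs_distance_slope, fit_temperature)
from .codons import EvolvingState, assign_codons
from .evolver import EvolverConfig, LibrarySnapshots, evolve_library
from .landscape import PottsModel, ProfileModel, energy
from .libstats import (energy_distance_profile, hamming_to_reference,
                       site_frequencies, spectra_correlation)

__all__ = ["SequenceEvolutionModel", "SequenceEvolutionResults"]


@dataclass
class SequenceEvolutionModel:
    """An in-silico evolution experiment over a data-driven landscape.

    Parameters
    ----------
    landscape : PottsModel or ProfileModel
        The statistical-energy landscape (fitness proxy).
    wildtype : EvolvingState
        Starting sequence with codon assignment (see
        :func:`evoscape.codons.assign_codons`).
    reference : ndarray, optional
        An (M, L) aligned reference library (amino acid indices) used to
        calibrate T and N_MC.
    """

    landscape: PottsModel | ProfileModel
    wildtype: EvolvingState
    reference: np.ndarray | None = None
    mode: str = "codon"

    @classmethod
    def from_files(cls, params_path, wildtype_dna_path=None, wildtype_protein=None,
                   reference_path=None, mode: str = "codon",
                   codon_seed: int = 0) -> "SequenceEvolutionModel":
        """Build from a parameter file, wildtype FASTA and reference FASTA."""
        from .io import read_dna_fasta, read_msa
        from .landscape import read_params

        landscape = read_params(params_path)
        if wildtype_dna_path is not None:
            dna = read_dna_fasta(wildtype_dna_path)
            from .codons import translate
            aa = translate(dna)
            wt = assign_codons(aa, mode="given_dna", dna=dna)
        elif wildtype_protein is not None:
            wt = assign_codons(wildtype_protein, mode="random_synonymous", seed=codon_seed)
        else:
            raise ValueError("provide wildtype_dna_path or wildtype_protein")
        reference = None
        if reference_path is not None:
            _, reference = read_msa(reference_path)
        return cls(landscape, wt, reference, mode=mode)

    def fit(self, T_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
            budget: CalibrationBudget | None = None,
            binned: bool = False) -> "SequenceEvolutionResults":
        """Calibrate (T, N_MC) against the reference library."""
        if self.reference is None:
            raise ValueError("fitting requires a reference library")
        cal = fit_temperature(self.landscape, self.wildtype, self.reference,
                              T_grid=T_grid, budget=budget, mode=self.mode,
                              binned=binned)
        return SequenceEvolutionResults(model=self, calibration=cal)

    def simulate(self, T: float, n_steps: int, n_chains: int,
                 snapshot_steps=None, seed: int = 0) -> LibrarySnapshots:
        """Simulate a library of independent chains from the wildtype."""
        cfg = EvolverConfig(T=T, n_steps=n_steps, n_chains=n_chains,
                            snapshot_steps=snapshot_steps, seed=seed, mode=self.mode)
        return evolve_library(self.wildtype, self.landscape, cfg)

    def wildtype_energy(self) -> float:
        return energy(self.landscape, self.wildtype.aa.astype(np.intp))


@dataclass
class SequenceEvolutionResults:
    """Calibrated simulation parameters with diagnostics."""

    model: SequenceEvolutionModel
    calibration: CalibrationResult

    @property
    def params(self) -> pd.Series:
        return pd.Series({"T": self.calibration.fitted_T,
                          "n_steps": float(self.calibration.fitted_steps)})

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.calibration.diagnostics

    def simulate(self, n_chains: int, seed: int = 0,
                 snapshot_steps=None) -> LibrarySnapshots:
        """Simulate at the fitted (T, N_MC)."""
        return self.model.simulate(self.calibration.fitted_T,
                                   self.calibration.fitted_steps,
                                   n_chains, snapshot_steps=snapshot_steps,
                                   seed=seed)

    def spectra_agreement(self, n_chains: int = 1000, seed: int = 0,
                          entry_filter: str = "accessible_only") -> float:
        """Spearman correlation between simulated and reference f_i(a)."""
        lib = self.simulate(n_chains, seed=seed)
        f_sim = site_frequencies(lib.msa(), q=self.model.landscape.q)
        f_ref = site_frequencies(self.model.reference, q=self.model.landscape.q)
        return spectra_correlation(f_sim, f_ref, entry_filter=entry_filter,
                                   wildtype=self.model.wildtype)

    def summary(self) -> str:
        cal = self.calibration
        ref = self.model.reference
        lines = [
            "Sequence evolution calibration results",
            "=" * 46,
            f"landscape            L={self.model.landscape.L}, "
            f"q={self.model.landscape.q}, "
            f"{'Potts' if self.model.landscape.has_couplings else 'profile'}",
            f"mode                 {self.model.mode}",
            f"reference library    M={0 if ref is None else ref.shape[0]}",
            f"wildtype energy      {self.model.wildtype_energy():.3f}",
            "-" * 46,
            f"selection temperature T   {cal.fitted_T:.4g}",
            f"chain length N_MC         {cal.fitted_steps}",
            f"target mean Hamming       {cal.target_mean_hamming:.3f}",
            f"target dE/distance slope  {cal.target_slope:.4f} "
            f"(se {cal.target_slope_stderr:.4f})",
            f"candidate temperatures    {len(cal.diagnostics)}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # plotting
    # ------------------------------------------------------------------

    def plot_energy_vs_distance(self, library: LibrarySnapshots | None = None,
                                seed: int = 0, n_chains: int = 500, ax=None):
        """Scatter of dE versus Hamming distance for a simulated library,
        with the fitted and reference slopes overlaid."""
        import matplotlib.pyplot as plt

        lib = library or self.simulate(n_chains, seed=seed)
        step = lib.steps[-1]
        d = lib.distances[step]
        dE = lib.energies[step] - self.model.wildtype_energy()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(d, dE, s=6, alpha=0.4, label="simulated")
        xs = np.array([d.min(), d.max()], dtype=float)
        cal = self.calibration
        ax.plot(xs, cal.target_slope * xs, "k--",
                label=f"reference slope {cal.target_slope:.2f}")
        ax.set_xlabel("Hamming distance to wildtype")
        ax.set_ylabel(r"$\Delta E$")
        ax.legend()
        return ax
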