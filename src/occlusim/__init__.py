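"""Transporter occlusion dynamics toolkit.

Subpackages
-----------
synthetic
    Ground-truth-known surrogates: discrete Markov chains, 2-D Langevin
    occlusion dynamics with ligand-conditioned potentials, observable
    emission, and patch-clamp current protocols.
featurize
    Structure parsing, gate distances, pairwise nonbonded interaction
    energies, occlusion labelling and interaction-strength splits.
modes
    Principal component analysis and functional mode analysis with
    mode-filtered RMSF profiles.
msm
    tICA -> k-means microstates -> reversible Markov state model ->
    free-energy surface, with implied-timescale, Chapman-Kolmogorov and
    bootstrap validation.
kinetics
    Electrophysiology / uptake fitting equations: mono-exponential
    relaxation, dose-dependent rate curves, recovery, IC50,
    Michaelis-Menten, and inhibition-mode classification.
pipeline
    Configuration and orchestration of the full synthetic study.
"""

__version__ = "0.1.0"

KB_KJ_PER_MOL_K = 0.0083145
"""Boltzmann constant in kJ/mol/K."""

DEFAULT_TEMPERATURE_K = 310.0
"""Physiological temperature used throughout (K)."""


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_B * T in kJ/mol (2.5775 kJ/mol at 310 K)."""
    return KB_KJ_PER_MOL_K * temperature_k
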