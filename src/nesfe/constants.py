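"""Physical constants and package-wide defaults.

All free energies and work values are handled internally in kcal/mol;
file readers convert from kJ/mol at the boundary.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K: float = 0.0019872041

#: Default simulation temperature (K) for the stochastic-dynamics protocol.
DEFAULT_TEMPERATURE_K: float = 298.0

#: Unit conversion for work / dH/dlambda files written in kJ/mol.
KJ_PER_KCAL: float = 4.184

#: Lower bound on experimental affinity uncertainty (kcal/mol) used when a
#: dataset reports no per-ligand error, following best-practice guidance.
EXP_SIGMA_FLOOR_KCAL: float = 0.43

#: Floor on edge standard errors entering weighted-least-squares weights, so
#: a zero-SE edge cannot acquire infinite weight.
SE_FLOOR_KCAL: float = 0.1

#: Separator used in directed edge identifiers "a→b".
EDGE_ARROW: str = "→"
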