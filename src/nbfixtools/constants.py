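"""Physical constants and package-wide defaults.

All energies are kcal/mol, distances Å, temperatures K.
"""

#: Boltzmann constant, kcal mol^-1 K^-1 (RT at 298 K = 0.59219 kcal/mol).
KB = 0.0019872041

#: Default simulation / analysis temperature, K.
DEFAULT_TEMPERATURE = 298.0

#: Default NBfix shift applied to the combination-rule minimum-energy
#: distance of the H8/H6...O5' pairs (negative = closer approach allowed).
DEFAULT_NBFIX_OFFSET = -0.25

#: eRMSD threshold separating folded from un(mis)folded frames.
DEFAULT_FOLD_THRESHOLD = 0.7

#: eRMSD ellipsoid semi-axes (Å) and cutoff in scaled units.
ERMSD_A = 5.0
ERMSD_B = 3.0
ERMSD_CUTOFF = 2.4


def rt(temperature: float) -> float:
    """k_B * T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
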