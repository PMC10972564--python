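"""Sequence-dependent intrinsic (unstructured) amide exchange rates.

Reference-rate model for backbone amide hydrogen exchange in D2O,
referenced to poly-DL-alanine with nearest-neighbour side-chain
correction factors, acid-, base- and water-catalysed terms, and
Arrhenius temperature scaling.  In the pD range used for labelling
(around pD 7) exchange is overwhelmingly base-catalysed, so rates scale
linearly with the deuteroxide concentration (tenfold per pD unit).

This feeds the forward simulator only; the analysis stages never invert
it.  Absolute magnitudes therefore matter less than the structure of the
model (neighbour dependence, catalysis regimes, proline handling).
"""

from __future__ import annotations

import numpy as np

__all__ = ["intrinsic_rates"]

# Reference rate constants for poly-DL-alanine in D2O at 20 C, on a
# per-second basis: acid (M^-1 s^-1), base (M^-1 s^-1), water (s^-1).
_LOG10_KA_REF = 0.30
_LOG10_KB_REF = 8.30
_LOG10_KW_REF = -4.30

# Activation energies, kcal/mol.
_EA_ACID = 14.0
_EA_BASE = 17.0
_EA_WATER = 19.0
_R_KCAL = 1.987204e-3
_T_REF_K = 293.15

# Ion product of D2O near 25 C (pK_D2O); held constant over the narrow
# temperature range of interest.
_PKW_D2O = 15.05

# log10 nearest-neighbour side-chain factors, (acid, base) for the
# residue carrying the amide ("self", i.e. the right-hand side of the
# peptide bond) and for the preceding residue ("prev").  Values follow
# the widely used poly-alanine-referenced convention for D2O exchange;
# alanine defines zero by construction.  Proline rows apply only in the
# "prev" role since prolines have no amide proton of their own.
_FACTORS: dict[str, tuple[float, float, float, float]] = {
    #        acid_self base_self acid_prev base_prev
    "A": (0.00, 0.00, 0.00, 0.00),
    "C": (-0.54, 0.62, -0.46, 0.55),
    "D": (0.90, 0.10, 0.58, -0.18),
    "E": (-0.90, -0.11, -0.31, -0.15),
    "F": (-0.52, -0.24, -0.43, 0.06),
    "G": (-0.22, 0.27, 0.22, 0.17),
    "H": (-0.80, 0.80, -0.51, 0.83),
    "I": (-0.91, -0.59, -0.59, -0.73),
    "K": (-0.56, -0.04, -0.29, 0.12),
    "L": (-0.57, -0.13, -0.13, -0.58),
    "M": (-0.64, -0.01, -0.28, 0.11),
    "N": (-0.58, 0.49, -0.13, 0.32),
    "P": (0.00, 0.00, -0.19, -0.24),
    "Q": (-0.47, 0.06, -0.27, 0.20),
    "R": (-0.59, 0.08, -0.32, 0.22),
    "S": (-0.44, 0.37, -0.39, 0.30),
    "T": (-0.79, -0.07, -0.47, -0.18),
    "V": (-0.74, -0.70, -0.30, -0.70),
    "W": (-0.40, -0.41, -0.44, -0.11),
    "Y": (-0.41, -0.27, -0.37, 0.05),
}


def _arrhenius(log10_k_ref: float, ea: float, temperature_C: float) -> float:
    t_k = temperature_C + 273.15
    return 10.0**log10_k_ref * np.exp(-(ea / _R_KCAL) * (1.0 / t_k - 1.0 / _T_REF_K))


def intrinsic_rates(
    sequence: str, pD: float = 7.0, temperature_C: float = 25.0
) -> np.ndarray:
    """Per-residue intrinsic exchange rates (1/s) for a peptide sequence.

    Returns an array aligned with ``sequence``; position 0 (no informative
    amide in bottom-up HDX) and proline positions hold ``nan``.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid codes.
    pD : float
        Glass-electrode-corrected pD of the labelling buffer.
    temperature_C : float
        Labelling temperature.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    unknown = set(sequence) - set(_FACTORS)
    if unknown:
        raise ValueError(f"unknown residue code(s): {sorted(unknown)}")

    k_acid = _arrhenius(_LOG10_KA_REF, _EA_ACID, temperature_C)
    k_base = _arrhenius(_LOG10_KB_REF, _EA_BASE, temperature_C)
    k_water = _arrhenius(_LOG10_KW_REF, _EA_WATER, temperature_C)
    conc_d = 10.0**-pD
    conc_od = 10.0 ** (pD - _PKW_D2O)

    rates = np.full(len(sequence), np.nan)
    for i in range(1, len(sequence)):
        res = sequence[i]
        if res == "P":
            continue
        prev = sequence[i - 1]
        a_self, b_self, _, _ = _FACTORS[res]
        _, _, a_prev, b_prev = _FACTORS[prev]
        fa = 10.0 ** (a_self + a_prev)
        fb = 10.0 ** (b_self + b_prev)
        rates[i] = k_acid * fa * conc_d + k_base * fb * conc_od + k_water * fb
    return rates
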