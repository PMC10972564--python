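"""Domain types shared across the package.

The two-state conformational model (:class:`ConformerModel`) is the hub:
every HDX forward simulation, NMR peak-pair simulation, and population
estimate refers to the same pair of global conformers R and L with
populations ``p_R`` and ``p_L = 1 - p_R`` exchanging at ``k_ex``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class ConformationalClass(enum.Enum):
    """Ground-truth inhibitor behaviour in the two-state model."""

    R_SELECTIVE = "R_SELECTIVE"
    EXCHANGE = "EXCHANGE"
    INTERMEDIATE = "INTERMEDIATE"


class LeftSideGroup(enum.Enum):
    """Left-side substituent chemistry (hinge / solvent channel contact)."""

    PYRAZOLE = "PYRAZOLE"
    TETRAHYDROPYRAN = "TETRAHYDROPYRAN"
    OTHER = "OTHER"


class Scaffold(enum.Enum):
    """Central scaffold chemistry; AMIDOPYRROLE marks the VTX11e/BVD523 pair."""

    AMIDOPYRROLE = "AMIDOPYRROLE"
    PYRIDONE = "PYRIDONE"
    TRIAZOLOPYRAZINE = "TRIAZOLOPYRAZINE"
    OTHER = "OTHER"


class ProbeCategory(enum.Enum):
    """Behavioural category of a methyl probe."""

    EXCHANGE_REPORTER = "EXCHANGE_REPORTER"
    R_STATE_REPORTER = "R_STATE_REPORTER"
    LEFT_SIDE_REPORTER = "LEFT_SIDE_REPORTER"
    CONTACT_BROADENED = "CONTACT_BROADENED"
    CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE = "CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE"
    UNCLASSIFIED = "UNCLASSIFIED"


class Region(enum.Enum):
    """Protection-model region class of a peptide segment.

    CONTACT regions gain steric protection from any bound ligand in both
    phosphoforms; CONTACT_2P regions (strands beta7-beta8) only in 2P;
    ALLOSTERIC regions (DFG/beta9, P+1, helix alphaF) respond to
    conformation selection and receive class-dependent protection in 2P.
    """

    CONTACT = "CONTACT"
    CONTACT_2P = "CONTACT_2P"
    ALLOSTERIC = "ALLOSTERIC"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ConformerModel:
    """Two-state (R<->L) conformational ensemble.

    Parameters
    ----------
    p_R : float
        Fractional population of the R conformer, in [0, 1].
    k_ex : float
        Conformational exchange rate constant in 1/s (default 300).
    temperature_C : float
        Sample temperature in Celsius.
    """

    p_R: float
    k_ex: float = 300.0
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_R <= 1.0:
            raise ValueError(f"p_R must lie in [0, 1], got {self.p_R}")
        if self.k_ex <= 0:
            raise ValueError("k_ex must be positive")

    @property
    def p_L(self) -> float:
        return 1.0 - self.p_R


#: 2P-ERK2 apoenzyme at 25 C: R:L = 80:20.
APO_2P_25C = ConformerModel(p_R=0.8, k_ex=300.0, temperature_C=25.0)
#: 2P-ERK2 apoenzyme at 5 C: R:L = 50:50.
APO_2P_5C = ConformerModel(p_R=0.5, k_ex=300.0, temperature_C=5.0)
#: 0P-ERK2 apoenzyme: R:L = 0:100 at both temperatures.
APO_0P = ConformerModel(p_R=0.0, k_ex=300.0, temperature_C=25.0)


@dataclass(frozen=True)
class ResidueExchangeSpec:
    """Per-residue amide exchange parameters in the two-state ensemble.

    ``protection_factor_L`` / ``protection_factor_R`` are the ratios of the
    intrinsic (unstructured) rate to the observed rate in the pure L and R
    conformers; both are >= 1 for structured amides.
    """

    residue_index: int
    amino_acid: str
    intrinsic_rate: float
    protection_factor_L: float = 1.0
    protection_factor_R: float = 1.0
    is_proline: bool = False

    def __post_init__(self) -> None:
        if self.is_proline:
            if self.intrinsic_rate != 0.0:
                raise ValueError("prolines carry no amide exchange rate")
        elif self.intrinsic_rate <= 0:
            raise ValueError("intrinsic_rate must be > 0 for non-proline residues")
        if self.protection_factor_L < 1.0 or self.protection_factor_R < 1.0:
            raise ValueError("protection factors must be >= 1")


@dataclass(frozen=True)
class InhibitorClassSpec:
    """Ground-truth conformational effect of one inhibitor.

    ``bound_p_R`` is the R population of the saturated 2P complex.
    ``contact_protection_multiplier`` scales protection factors in ligand
    contact regions (steric shielding); ``allosteric_protection_multiplier``
    applies to the DFG/beta9, P+1 and helix-alphaF segments of the 2P form
    only, modelling the long-range rigidification by R-state trapping.
    """

    inhibitor_id: str
    conformational_class: ConformationalClass
    bound_p_R: float
    left_side_group: LeftSideGroup = LeftSideGroup.OTHER
    contact_protection_multiplier: float = 20.0
    allosteric_protection_multiplier: float = 1.0
    scaffold: Scaffold = Scaffold.OTHER

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_p_R <= 1.0:
            raise ValueError("bound_p_R must lie in [0, 1]")
        if self.contact_protection_multiplier < 1.0:
            raise ValueError("contact_protection_multiplier must be >= 1")
        if self.allosteric_protection_multiplier < 1.0:
            raise ValueError("allosteric_protection_multiplier must be >= 1")
        if (
            self.conformational_class is ConformationalClass.R_SELECTIVE
            and self.bound_p_R != 1.0
        ):
            raise ValueError("R_SELECTIVE inhibitors must have bound_p_R = 1.0")

    def validate_against_apo(self, apo: ConformerModel) -> None:
        """Check class/population consistency relative to an apo model."""
        if self.conformational_class is ConformationalClass.EXCHANGE:
            if not math.isclose(self.bound_p_R, apo.p_R, abs_tol=1e-12):
                raise ValueError(
                    f"{self.inhibitor_id}: EXCHANGE class requires bound_p_R equal "
                    f"to the apo p_R ({apo.p_R}), got {self.bound_p_R}"
                )
        elif self.conformational_class is ConformationalClass.INTERMEDIATE:
            if not apo.p_R < self.bound_p_R < 1.0:
                raise ValueError(
                    f"{self.inhibitor_id}: INTERMEDIATE class requires "
                    f"apo p_R < bound_p_R < 1"
                )


@dataclass(frozen=True)
class PeptideDef:
    """A proteolytic peptide on the protein's (author) numbering.

    ``n_exchangeable`` follows the standard bottom-up HDX convention:
    the first residue and every proline beyond it are excluded.
    """

    start: int
    end: int
    sequence: str
    region: Region = Region.OTHER
    name: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"{self.start}-{self.end}"
            )

    @property
    def n_exchangeable(self) -> int:
        return len(self.sequence) - 1 - self.sequence[1:].count("P")

    @property
    def segment_id(self) -> str:
        label = self.name or self.sequence
        return f"{label}_{self.start}-{self.end}"


#: 1H resonance frequency (MHz) of the spectrometer used for slow-exchange
#: checks; 13C is lower by the gyromagnetic ratio.
SPECTROMETER_MHZ = 900.0
_GAMMA_C_OVER_H = 0.2514


def angular_shift_gap(
    shift_a: tuple[float, float],
    shift_b: tuple[float, float],
    spectrometer_mhz: float = SPECTROMETER_MHZ,
) -> float:
    """Angular frequency gap (rad/s) between two (1H ppm, 13C ppm) positions."""
    dh_hz = (shift_a[0] - shift_b[0]) * spectrometer_mhz
    dc_hz = (shift_a[1] - shift_b[1]) * spectrometer_mhz * _GAMMA_C_OVER_H
    return 2.0 * math.pi * math.hypot(dh_hz, dc_hz)


@dataclass(frozen=True)
class MethylProbeSpec:
    """A methyl (ILV) probe with R- and L-state 2D peak positions.

    For exchange reporters the slow-exchange condition Delta-omega >> k_ex
    (ratio > 10) is enforced at construction so that separate R and L peaks
    with population-proportional volumes are a valid observable.
    """

    probe_id: str
    shift_R: tuple[float, float]
    shift_L: tuple[float, float]
    category: ProbeCategory
    k_ex: float = 300.0
    delta_omega: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "delta_omega", angular_shift_gap(self.shift_R, self.shift_L)
        )
        if self.category is ProbeCategory.EXCHANGE_REPORTER:
            if self.shift_R == self.shift_L:
                raise ValueError(
                    f"{self.probe_id}: exchange reporter requires shift_R != shift_L"
                )
            if self.delta_omega <= 10.0 * self.k_ex:
                raise ValueError(
                    f"{self.probe_id}: slow-exchange condition violated "
                    f"(delta_omega {self.delta_omega:.0f} rad/s vs k_ex {self.k_ex})"
                )
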