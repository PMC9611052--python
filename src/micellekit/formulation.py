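"""Charge-stoichiometry arithmetic for copolymer/siRNA formulations.

The N/P ratio of a polyplex formulation is the molar ratio of protonatable
polymer amine groups (N) to nucleic-acid backbone phosphate groups (P).  For
an mPEG45-PLL10-PLA25 triblock copolymer each chain carries 10 lysine amines;
a 21-mer siRNA duplex carries 20 backbone phosphates per strand, 40 per
duplex.  Every amine is counted as +1 and every phosphate as -1 (raw group
counts, no pKa model).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CopolymerSpec",
    "SiRNASpec",
    "MixRecipe",
    "np_ratio",
    "copolymer_mass_for_ratio",
    "copolymers_per_sirna_at_unity",
]


class FormulationError(ValueError):
    """Invalid formulation input (negative amount, missing molar mass...)."""


@dataclass(frozen=True)
class CopolymerSpec:
    """Triblock copolymer composition.

    Defaults describe mPEG45-PLL10-PLA25: 45 ethylene-glycol units, 10
    lysines (the cationic block — one protonatable amine each) and 25
    lactide units.  The default chain molar mass follows from the reported
    stock pairing 0.3 mM copolymer at 1.59 mg/mL (5300 g/mol).
    """

    peg_units: int = 45
    lysine_units: int = 10
    lactide_units: int = 25
    amines_per_chain: int | None = None
    chain_molar_mass: float = 5300.0

    def __post_init__(self) -> None:
        if self.amines_per_chain is None:
            object.__setattr__(self, "amines_per_chain", self.lysine_units)
        if min(self.peg_units, self.lysine_units, self.lactide_units) <= 0:
            raise FormulationError("block unit counts must be positive")
        if self.amines_per_chain != self.lysine_units:
            raise FormulationError(
                "amines_per_chain must equal lysine_units "
                "(one epsilon-amine per lysine; terminal amine not counted)"
            )
        if self.chain_molar_mass <= 0:
            raise FormulationError("chain_molar_mass must be positive")


@dataclass(frozen=True)
class SiRNASpec:
    """A double-stranded siRNA payload.

    Defaults describe a 21-mer duplex (19-bp core + dTdT overhangs,
    13,330.21 g/mol): each n-mer strand contributes n - 1 backbone
    phosphates, i.e. 40 per duplex.
    """

    sense_length: int = 21
    antisense_length: int = 21
    phosphates_per_duplex: int | None = None
    molar_mass: float = 13330.21

    def __post_init__(self) -> None:
        expected = (self.sense_length - 1) + (self.antisense_length - 1)
        if self.phosphates_per_duplex is None:
            object.__setattr__(self, "phosphates_per_duplex", expected)
        if self.phosphates_per_duplex != expected:
            raise FormulationError(
                f"phosphates_per_duplex must be {expected} for "
                f"{self.sense_length}+{self.antisense_length}-mer strands"
            )
        if self.molar_mass <= 0:
            raise FormulationError("molar_mass must be positive")


@dataclass(frozen=True)
class MixRecipe:
    """Amounts mixed in one formulation.

    Amounts are either moles (``*_mol``) or grams (``*_g``); give exactly one
    per component.  Mass inputs are resolved through the spec molar masses.
    """

    copolymer_mol: float | None = None
    copolymer_g: float | None = None
    sirna_mol: float | None = None
    sirna_g: float | None = None
    volume_l: float = 1.0

    def __post_init__(self) -> None:
        for pair, name in (
            ((self.copolymer_mol, self.copolymer_g), "copolymer"),
            ((self.sirna_mol, self.sirna_g), "siRNA"),
        ):
            given = [v for v in pair if v is not None]
            if len(given) != 1:
                raise FormulationError(f"give exactly one {name} amount (mol or g)")
            if given[0] < 0:
                raise FormulationError(f"{name} amount must be nonnegative")
        if self.volume_l <= 0:
            raise FormulationError("volume must be positive")

    def copolymer_moles(self, cop: CopolymerSpec) -> float:
        if self.copolymer_mol is not None:
            return self.copolymer_mol
        return self.copolymer_g / cop.chain_molar_mass

    def sirna_moles(self, rna: SiRNASpec) -> float:
        if self.sirna_mol is not None:
            return self.sirna_mol
        return self.sirna_g / rna.molar_mass


def np_ratio(
    recipe: MixRecipe,
    cop: CopolymerSpec | None = None,
    rna: SiRNASpec | None = None,
) -> float:
    """N/P charge ratio of a mixing recipe.

    (mol copolymer x amines per chain) / (mol siRNA x phosphates per duplex).
    Zero copolymer gives 0; zero siRNA is undefined and raises.
    """
    cop = cop or CopolymerSpec()
    rna = rna or SiRNASpec()
    n = recipe.copolymer_moles(cop) * cop.amines_per_chain
    p = recipe.sirna_moles(rna) * rna.phosphates_per_duplex
    if p == 0:
        raise FormulationError("N/P undefined: siRNA amount is zero")
    return n / p


def copolymer_mass_for_ratio(
    target_np: float,
    sirna_moles: float,
    cop: CopolymerSpec | None = None,
    rna: SiRNASpec | None = None,
) -> float:
    """Copolymer mass (g) hitting a target N/P for a given siRNA amount.

    Inverse of :func:`np_ratio`; round-trips to floating precision.
    """
    cop = cop or CopolymerSpec()
    rna = rna or SiRNASpec()
    if target_np < 0:
        raise FormulationError("target N/P must be nonnegative")
    if sirna_moles <= 0:
        raise FormulationError("siRNA amount must be positive")
    cop_moles = target_np * sirna_moles * rna.phosphates_per_duplex / cop.amines_per_chain
    return cop_moles * cop.chain_molar_mass


def copolymers_per_sirna_at_unity(
    cop: CopolymerSpec | None = None, rna: SiRNASpec | None = None
) -> float:
    """Copolymer chains per siRNA duplex at charge neutrality (N/P = 1)."""
    cop = cop or CopolymerSpec()
    rna = rna or SiRNASpec()
    return rna.phosphates_per_duplex / cop.amines_per_chain
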