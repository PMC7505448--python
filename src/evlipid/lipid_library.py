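"""Phospholipid and sphingolipid mass library.

Defines lipid species as a headgroup class plus acyl/sphingoid chain
composition, derives elemental formulas and monoisotopic masses, computes
adduct precursor m/z values and predicts MS2 fragment ions from a small,
editable rule registry (headgroup ions, acyl neutral losses, carboxylate
anions, single-chain-loss ions).

Chain notation follows the field convention ``C:D`` (carbons:double bonds),
with a ``d`` prefix for sphingoid bases (e.g. ``d18:1/16:0`` sphingomyelin).
sn-positional isomers are not distinguished: ``16:0/18:1 == 18:1/16:0``.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "FragmentIon",
    "LipidLibrary",
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ADDUCT_SHIFTS",
    "FRAGMENTATION_RULES",
    "UnsupportedClassError",
    "InvalidSpeciesError",
    "elemental_formula",
    "monoisotopic_mass",
    "precursor_mz",
    "predict_fragments",
    "build_default_library",
    "headgroup",
    "preferred_polarity",
    "export_library_csv",
    "import_library_csv",
    "save_rules",
    "load_rules",
]

# ---------------------------------------------------------------------------
# Constants: monoisotopic atomic masses (CODATA/NIST), adduct shifts
# ---------------------------------------------------------------------------

MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466879

# m/z shift added to the neutral monoisotopic mass for singly charged adducts
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+HCOO]-": (
        MONOISOTOPIC_MASSES["C"]
        + MONOISOTOPIC_MASSES["H"]
        + 2 * MONOISOTOPIC_MASSES["O"]
        + ELECTRON_MASS
    ),
}

POSITIVE_ADDUCTS = ("[M+H]+", "[M+Na]+")
NEGATIVE_ADDUCTS = ("[M-H]-", "[M+HCOO]-")

DIACYL_CLASSES = ("PC", "PE", "PI", "PS", "PG")
LYSO_CLASSES = ("LPC", "LPE", "LPI")
SUPPORTED_CLASSES = DIACYL_CLASSES + LYSO_CLASSES + ("SM", "CL")

# Glycerophospho-headgroup cores: the full polar skeleton (glycerol +
# phosphate + headgroup alcohol, already condensed); acylation then adds
# each fatty acid minus one water.
_CLASS_CORES: dict[str, dict[str, int]] = {
    "PC": {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1},   # glycerophosphocholine
    "PE": {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1},
    "PI": {"C": 9, "H": 19, "O": 11, "P": 1},
    "PS": {"C": 6, "H": 14, "N": 1, "O": 8, "P": 1},
    "PG": {"C": 6, "H": 15, "O": 8, "P": 1},
    "CL": {"C": 9, "H": 22, "O": 13, "P": 2},          # bis(glycerophospho)glycerol
}
_CLASS_CORES["LPC"] = _CLASS_CORES["PC"]
_CLASS_CORES["LPE"] = _CLASS_CORES["PE"]
_CLASS_CORES["LPI"] = _CLASS_CORES["PI"]

# Phosphocholine residue (phosphocholine minus water) for sphingomyelin.
_PHOSPHOCHOLINE_RESIDUE = {"C": 5, "H": 12, "N": 1, "O": 3, "P": 1}
# Phosphocholine headgroup cation C5H15NO4P+ observed at m/z 184.0733.
_PHOSPHOCHOLINE_ION_FORMULA = {"C": 5, "H": 14, "N": 1, "O": 4, "P": 1}

_CHAIN_COUNT = {**{c: 2 for c in DIACYL_CLASSES}, **{c: 1 for c in LYSO_CLASSES},
                "SM": 2, "CL": 4}

WATER = {"H": 2, "O": 1}


class UnsupportedClassError(ValueError):
    """Raised for a lipid class outside the supported registry."""


class InvalidSpeciesError(ValueError):
    """Raised when chains violate the class composition rules."""


def _merge(*formulas: Mapping[str, int], subtract: Sequence[Mapping[str, int]] = ()) -> dict[str, int]:
    out: dict[str, int] = {}
    for f in formulas:
        for el, n in f.items():
            out[el] = out.get(el, 0) + n
    for f in subtract:
        for el, n in f.items():
            out[el] = out.get(el, 0) - n
    out = {el: n for el, n in sorted(out.items()) if n != 0}
    if any(n < 0 for n in out.values()):
        raise InvalidSpeciesError(f"negative element count in formula: {out}")
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty acyl or sphingoid chain, ``carbons:double_bonds``."""

    carbons: int
    double_bonds: int
    linkage: str = "ester"  # "ester" (also used for the SM amide) or "sphingoid-d"

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise InvalidSpeciesError("chain counts must be non-negative")
        if self.double_bonds > self.carbons / 2:
            raise InvalidSpeciesError(
                f"{self.carbons}:{self.double_bonds} has more double bonds than chemically possible"
            )
        if self.linkage not in ("ester", "sphingoid-d"):
            raise InvalidSpeciesError(f"unknown linkage {self.linkage!r}")

    @property
    def fatty_acid_formula(self) -> dict[str, int]:
        """Free fatty acid CnH(2n-2d)O2 for an ester/amide chain."""
        if self.linkage != "ester":
            raise InvalidSpeciesError("sphingoid chain has no free fatty acid form")
        return {"C": self.carbons, "H": 2 * self.carbons - 2 * self.double_bonds, "O": 2}

    @property
    def sphingoid_formula(self) -> dict[str, int]:
        """Sphingoid base CnH(2n+3-2d)NO2 (d18:1 -> sphingosine C18H37NO2)."""
        if self.linkage != "sphingoid-d":
            raise InvalidSpeciesError("not a sphingoid chain")
        return {"C": self.carbons, "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1, "O": 2}

    def __str__(self) -> str:
        prefix = "d" if self.linkage == "sphingoid-d" else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        text = text.strip()
        linkage = "ester"
        if text.startswith("d"):
            linkage = "sphingoid-d"
            text = text[1:]
        c, d = text.split(":")
        return cls(int(c), int(d), linkage)


def elemental_formula(lipid_class: str, chains: Sequence[AcylChain]) -> dict[str, int]:
    """Elemental formula of the neutral species from class + chains.

    Glycerophospholipids: headgroup core + one (FA - H2O) per ester chain.
    Sphingomyelin: sphingoid base + phosphocholine residue + N-acyl (FA - H2O).
    """
    if lipid_class not in SUPPORTED_CLASSES:
        raise UnsupportedClassError(f"unsupported lipid class {lipid_class!r}")
    expected = _CHAIN_COUNT[lipid_class]
    if len(chains) != expected:
        raise InvalidSpeciesError(
            f"{lipid_class} requires {expected} chain(s), got {len(chains)}"
        )
    if lipid_class == "SM":
        base, acyl = chains[0], chains[1]
        if base.linkage != "sphingoid-d":
            raise InvalidSpeciesError("first SM chain must be a sphingoid-d base")
        if acyl.linkage != "ester":
            raise InvalidSpeciesError("second SM chain must be the N-acyl chain")
        if base.carbons < 2 or acyl.carbons < 2:
            raise InvalidSpeciesError("chains must have at least 2 carbons")
        return _merge(base.sphingoid_formula, _PHOSPHOCHOLINE_RESIDUE,
                      acyl.fatty_acid_formula, subtract=[WATER])
    for ch in chains:
        if ch.linkage != "ester":
            raise InvalidSpeciesError(f"{lipid_class} chains must be ester-linked")
        if ch.carbons < 2:
            raise InvalidSpeciesError("acyl chains must have at least 2 carbons")
    acyl_parts = [ch.fatty_acid_formula for ch in chains]
    return _merge(_CLASS_CORES[lipid_class], *acyl_parts,
                  subtract=[WATER] * len(chains))


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass over the formula (Da)."""
    total = 0.0
    for el, n in formula.items():
        if el not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unknown element {el!r}")
        total += n * MONOISOTOPIC_MASSES[el]
    return total


def _canonical_chains(lipid_class: str, chains: Sequence[AcylChain]) -> tuple[AcylChain, ...]:
    """Sort ester chains (sn-position not resolved); SM keeps base first."""
    chains = tuple(chains)
    if lipid_class == "SM":
        return chains[:1] + tuple(sorted(chains[1:]))
    return tuple(sorted(chains))


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species: headgroup class + canonicalized chain composition."""

    lipid_class: str
    chains: tuple[AcylChain, ...]
    formula: Mapping[str, int] = field(compare=False, default=None)  # type: ignore[assignment]
    monoisotopic_mass: float = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chains", _canonical_chains(self.lipid_class, self.chains))
        formula = elemental_formula(self.lipid_class, self.chains)
        object.__setattr__(self, "formula", formula)
        object.__setattr__(self, "monoisotopic_mass", monoisotopic_mass(formula))

    @property
    def name(self) -> str:
        return f"{self.lipid_class} {'/'.join(str(c) for c in self.chains)}"

    def __str__(self) -> str:
        return self.name

    @classmethod
    def parse(cls, text: str) -> "LipidSpecies":
        """Parse e.g. ``"PC 16:0/18:1"`` or ``"SM d18:1/16:0"``."""
        lipid_class, chain_text = text.strip().split(None, 1)
        chains = tuple(AcylChain.parse(t) for t in chain_text.split("/"))
        return cls(lipid_class, chains)


@dataclass(frozen=True)
class FragmentIon:
    """One predicted product ion."""

    label: str
    mz: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


def precursor_mz(species: LipidSpecies, adduct: str, charge: int = 1) -> float:
    """Singly charged precursor m/z for a supported adduct."""
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    if charge != 1:
        raise ValueError("only singly charged adducts are supported")
    return (species.monoisotopic_mass + ADDUCT_SHIFTS[adduct]) / abs(charge)


def adduct_polarity(adduct: str) -> str:
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return "positive" if adduct.endswith("+") else "negative"


def headgroup(lipid_class: str) -> str:
    """Headgroup family used for within-class quantification (LPC -> PC etc.)."""
    return {"LPC": "PC", "LPE": "PE", "LPI": "PI"}.get(lipid_class, lipid_class)


def preferred_polarity(species: LipidSpecies) -> str:
    """Ionization mode in which the class is detected by the rule set."""
    return "positive" if headgroup(species.lipid_class) in ("PC", "SM") else "negative"


# ---------------------------------------------------------------------------
# Fragmentation rule registry
# ---------------------------------------------------------------------------
# Rule names:
#   phosphocholine_ion : headgroup cation at 184.0733 (choline lipids, +)
#   acyl_fa_loss       : [M+H-FA]+ neutral loss of each acyl as free acid
#   acyl_ketene_loss   : [M+H-(FA-H2O)]+ ketene loss of each acyl
#   carboxylate        : [RCOO]- anion of each acyl chain (-)
#   chain_fa_loss      : [M-H-FA]-  loss of one chain as free acid
#   chain_ketene_loss  : [M-H-(FA-H2O)]- loss of one chain as ketene

FRAGMENTATION_RULES: dict[str, dict[str, tuple[str, ...]]] = {
    **{c: {"positive": ("phosphocholine_ion", "acyl_fa_loss", "acyl_ketene_loss"),
           "negative": ("carboxylate", "chain_fa_loss", "chain_ketene_loss")}
       for c in ("PC", "LPC", "SM")},
    **{c: {"positive": ("acyl_fa_loss", "acyl_ketene_loss"),
           "negative": ("carboxylate", "chain_fa_loss", "chain_ketene_loss")}
       for c in ("PE", "PI", "PS", "PG", "LPE", "LPI", "CL")},
}


def save_rules(rules: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: {p: list(v) for p, v in d.items()}
                                      for k, d in rules.items()}, indent=1))


def load_rules(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {k: {p: tuple(v) for p, v in d.items()} for k, d in raw.items()}


def predict_fragments(
    species: LipidSpecies,
    polarity: str,
    adduct: str | None = None,
    rules: Mapping[str, Mapping[str, tuple[str, ...]]] | None = None,
) -> list[FragmentIon]:
    """Deterministic fragment inventory for one species/adduct.

    The list is sorted by m/z with near-duplicate ions merged (identical
    chains produce one loss ion, not two). Negative-mode losses are computed
    from the deprotonated molecule regardless of the precursor adduct
    (formate adducts lose HCOOH before backbone fragmentation).
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if adduct is None:
        adduct = "[M+H]+" if polarity == "positive" else "[M-H]-"
    if adduct_polarity(adduct) != polarity:
        raise ValueError(f"adduct {adduct} inconsistent with polarity {polarity}")
    rules = rules if rules is not None else FRAGMENTATION_RULES
    active = rules[species.lipid_class][polarity]

    ester_chains = [c for c in species.chains if c.linkage == "ester"]
    frags: list[FragmentIon] = []

    if polarity == "positive":
        precursor = precursor_mz(species, adduct)
        if "phosphocholine_ion" in active:
            frags.append(FragmentIon(
                "phosphocholine headgroup",
                monoisotopic_mass(_PHOSPHOCHOLINE_ION_FORMULA) + PROTON_MASS,
                polarity))
        for ch in ester_chains:
            fa = monoisotopic_mass(ch.fatty_acid_formula)
            if "acyl_fa_loss" in active:
                frags.append(FragmentIon(f"loss of {ch} as acid", precursor - fa, polarity))
            if "acyl_ketene_loss" in active:
                frags.append(FragmentIon(
                    f"loss of {ch} as ketene",
                    precursor - (fa - monoisotopic_mass(WATER)), polarity))
    else:
        base = species.monoisotopic_mass - PROTON_MASS  # [M-H]-
        for ch in ester_chains:
            fa = monoisotopic_mass(ch.fatty_acid_formula)
            if "carboxylate" in active:
                frags.append(FragmentIon(f"{ch} carboxylate", fa - PROTON_MASS, polarity))
            if "chain_fa_loss" in active:
                frags.append(FragmentIon(f"loss of {ch} as acid", base - fa, polarity))
            if "chain_ketene_loss" in active:
                frags.append(FragmentIon(
                    f"loss of {ch} as ketene",
                    base - (fa - monoisotopic_mass(WATER)), polarity))

    # merge duplicates (identical chains), sort by m/z
    seen: dict[int, FragmentIon] = {}
    for f in frags:
        seen.setdefault(round(f.mz * 1e6), f)
    return sorted(seen.values(), key=lambda f: f.mz)


# ---------------------------------------------------------------------------
# Library container and enumeration
# ---------------------------------------------------------------------------

class LipidLibrary:
    """Ordered collection of species with fast precursor lookup."""

    def __init__(self, species: Iterable[LipidSpecies]):
        uniq: dict[tuple, LipidSpecies] = {}
        for sp in species:
            uniq.setdefault((sp.lipid_class, sp.chains), sp)
        self.species: list[LipidSpecies] = sorted(
            uniq.values(), key=lambda s: (s.lipid_class, s.chains))
        self._index: dict[str, tuple[list[float], list[LipidSpecies]]] = {}

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def _adduct_index(self, adduct: str):
        if adduct not in self._index:
            pairs = sorted(((precursor_mz(sp, adduct), sp) for sp in self.species),
                           key=lambda p: (p[0], p[1].name))
            self._index[adduct] = ([m for m, _ in pairs], [s for _, s in pairs])
        return self._index[adduct]

    def candidates(self, mz: float, adduct: str, tol_ppm: float) -> list[LipidSpecies]:
        """Species whose adduct precursor lies within tol_ppm of mz."""
        masses, specs = self._adduct_index(adduct)
        tol = mz * tol_ppm * 1e-6
        lo = bisect_left(masses, mz - tol)
        hi = bisect_right(masses, mz + tol)
        return specs[lo:hi]


def _chain_grid(carbons=(12, 24), double_bonds=(0, 6)) -> list[AcylChain]:
    return [AcylChain(c, d)
            for c in range(carbons[0], carbons[1] + 1)
            for d in range(double_bonds[0], double_bonds[1] + 1)
            if d <= c / 2]


def build_default_library(
    classes: Sequence[str] = SUPPORTED_CLASSES,
    carbons: tuple[int, int] = (12, 24),
    double_bonds: tuple[int, int] = (0, 6),
    sphingoid_bases: Sequence[str] = ("d16:1", "d18:0", "d18:1", "d18:2", "d20:1"),
) -> LipidLibrary:
    """Enumerate the default search space.

    Diacyl classes take every unordered chain pair on the grid; lyso classes
    every single chain; SM every (base, N-acyl) combination; CL four identical
    chains (capped at 22 carbons) — a tractable stand-in for the full
    four-chain space, which no reported species requires.
    """
    grid = _chain_grid(carbons, double_bonds)
    species: list[LipidSpecies] = []
    for cls in classes:
        if cls in DIACYL_CLASSES:
            species += [LipidSpecies(cls, pair)
                        for pair in combinations_with_replacement(grid, 2)]
        elif cls in LYSO_CLASSES:
            species += [LipidSpecies(cls, (ch,)) for ch in grid]
        elif cls == "SM":
            bases = [AcylChain.parse(b) for b in sphingoid_bases]
            species += [LipidSpecies("SM", (b, ch)) for b in bases for ch in grid]
        elif cls == "CL":
            species += [LipidSpecies("CL", (ch,) * 4) for ch in grid
                        if ch.carbons <= 22]
        else:
            raise UnsupportedClassError(cls)
    return LipidLibrary(species)


def export_library_csv(library: LipidLibrary, path: str | Path) -> None:
    rows = [{"class": sp.lipid_class,
             "chains": "/".join(str(c) for c in sp.chains),
             "formula": "".join(f"{el}{n}" for el, n in sp.formula.items()),
             "monoisotopic_mass": sp.monoisotopic_mass}
            for sp in library]
    pd.DataFrame(rows).to_csv(path, index=False)


def import_library_csv(path: str | Path) -> LipidLibrary:
    df = pd.read_csv(path)
    return LipidLibrary(LipidSpecies.parse(f"{r['class']} {r['chains']}")
                        for r in df.to_dict("records"))
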