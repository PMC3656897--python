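"""Formula algebra and monoisotopic-mass arithmetic for (cyclic) lipopeptides.

The verification step of an NRPS product prediction is chemical: the peptide
sequence read off the assembly line, the N-linked 3-hydroxy fatty acid and the
macrolactone together fix a neutral molecular formula, whose monoisotopic mass
and adduct m/z must match the high-resolution MS observations.  This module
provides that arithmetic: residue compositions (amino acid minus one water, as
incorporated in a chain), fatty-acid compositions for 3-hydroxy acids
(CnH(2n-2d)O3 for d double bonds), condensation/lactonization bookkeeping
(-H2O each), proton/sodium adducts, and a small table of compositional
hypotheses for observed mass differences between congeners (CH2 for an
Ile<->Val swap or a +/-CH2 chain change, C2H2 for two extra carbons with one
unsaturation, H2O for ring opening).

Monoisotopic atomic masses come from the NIST table shipped with pyteomics;
protonated species use the proton mass (1.007276 Da), not the H-atom mass.
Masses are rounded half-even at 4 decimals by :func:`round_mass`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ElementComposition",
    "ResidueSpec",
    "FattyAcidSpec",
    "LipopeptideStructure",
    "RESIDUES",
    "monoisotopic_mass",
    "average_mass",
    "round_mass",
    "compose_formula",
    "adduct_mz",
    "mass_delta_explain",
    "enumerate_glx_isoforms",
    "GLX_MASS_SPREAD",
]

#: Mass of a proton (Da); used for [M+zH]z+ adducts.
PROTON_MASS = 1.007276

#: Monoisotopic Gln/Glu mass difference (NH vs O), the per-Glx ambiguity.
GLX_MASS_SPREAD = 0.984

_NIST = _pmass.nist_mass


def _monoisotopic(element: str) -> float:
    try:
        return _NIST[element][0][0]
    except KeyError:
        raise KeyError(f"unknown element: {element!r}") from None


def _average(element: str) -> float:
    table = _NIST[element]
    return sum(m * frac for _, (m, frac) in table.items() if frac)


_HILL_FIRST = ("C", "H")


class ElementComposition:
    """An element -> non-negative count mapping with algebra and Hill rendering.

    Supports ``+``, ``-`` (raising on negative results), scalar ``*`` and
    element-wise equality.  ``str()`` renders the formula in Hill order
    (C first, H second, remaining elements alphabetical), e.g.
    ``C84H146N18O23``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        self._counts = {el: n for el, n in merged.items() if n}

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self):
        return iter(self._counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        out = dict(self._counts)
        for el, n in other._counts.items():
            out[el] = out.get(el, 0) + n
        return ElementComposition(out)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        out = dict(self._counts)
        for el, n in other._counts.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {el} count ({new})"
                )
            out[el] = new
        return ElementComposition(out)

    def __mul__(self, k: int) -> "ElementComposition":
        if k < 0:
            raise ValueError("negative multiplier")
        return ElementComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill_formula(self) -> str:
        parts = []
        rest = sorted(el for el in self._counts if el not in _HILL_FIRST)
        order = [el for el in _HILL_FIRST if el in self._counts] + rest
        for el in order:
            n = self._counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill_formula()

    def __repr__(self) -> str:
        return f"ElementComposition({self.hill_formula()!r})"

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-style formula string such as ``C84H146N18O23``."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            if not m.group(0):
                break
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)


WATER = ElementComposition(H=2, O=1)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Monoisotopic mass (Da) of a composition; unknown elements raise."""
    return sum(n * _monoisotopic(el) for el, n in comp.counts.items())


def average_mass(comp: ElementComposition) -> float:
    """Isotope-abundance-weighted (average) mass in Da."""
    return sum(n * _average(el) for el, n in comp.counts.items())


def round_mass(m: float, ndigits: int = 4) -> float:
    """Round half-even at `ndigits` decimals (supplementary-figure precision)."""
    return round(m, ndigits)


# ---------------------------------------------------------------------------
# Residues


@dataclass(frozen=True)
class ResidueSpec:
    """A peptide residue: 3-letter code + composition as incorporated in chain
    (i.e. amino acid minus one water)."""

    name: str
    residue_composition: ElementComposition
    ambiguous_over: tuple[str, ...] = ()

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.ambiguous_over)


def _aa(code1: str) -> ElementComposition:
    return ElementComposition(
        {el: n for el, n in _pmass.std_aa_comp[code1].items()}
    )


_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: Registry of residue specs: the 20 proteinogenic residues plus the
#: non-proteinogenic substrates seen in Pseudomonas lipopeptide assembly
#: lines (allo-Thr; 2,3-dehydro-2-aminobutyric acid; 2,4-diaminobutyric
#: acid; 3-hydroxy-Asp) and the Xle / Glx ambiguity classes.
RESIDUES: dict[str, ResidueSpec] = {
    three: ResidueSpec(three, _aa(one)) for three, one in _THREE_TO_ONE.items()
}
RESIDUES.update(
    {
        # allo-threonine: diastereomer of Thr, same composition
        "aThr": ResidueSpec("aThr", _aa("T")),
        # 2,3-dehydro-2-aminobutyric acid: Thr residue minus H2O... i.e.
        # C4H5NO as a residue (Abu minus H2)
        "DHB": ResidueSpec("DHB", ElementComposition(C=4, H=5, N=1, O=1)),
        # 2,4-diaminobutyric acid residue: C4H8N2O
        "DAB": ResidueSpec("DAB", ElementComposition(C=4, H=8, N=2, O=1)),
        # 3-hydroxyaspartate residue: Asp + O
        "OH-Asp": ResidueSpec("OH-Asp", _aa("D") + ElementComposition(O=1)),
        # Leu/Ile unresolved — isobaric, so composition is well defined
        "Xle": ResidueSpec("Xle", _aa("L"), ambiguous_over=("Leu", "Ile")),
        # Glu/Gln unresolved — NOT isobaric (0.984 Da apart); must be
        # resolved before composing a formula
        "Glx": ResidueSpec("Glx", _aa("E"), ambiguous_over=("Glu", "Gln")),
    }
)


def get_residue(name: str) -> ResidueSpec:
    try:
        return RESIDUES[name]
    except KeyError:
        raise KeyError(f"unknown residue name: {name!r}") from None


# ---------------------------------------------------------------------------
# Fatty acids and full structures


@dataclass(frozen=True)
class FattyAcidSpec:
    """A 3-hydroxy fatty acid: chain length, OH position, double bonds.

    Composition of the free acid is CnH(2n-2d)O3 for d double bonds; the
    3-hydroxy group contributes the third oxygen.  `double_bonds` is an
    ordered tuple of (position, geometry) with geometry one of
    'cis' | 'trans' | 'unknown'.
    """

    carbons: int
    hydroxyl_position: int = 3
    double_bonds: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError("fatty acid needs >= 2 carbons")
        if not (1 <= self.hydroxyl_position < self.carbons):
            raise ValueError("hydroxyl position out of range")
        for pos, geom in self.double_bonds:
            if not (1 <= pos < self.carbons):
                raise ValueError(f"double-bond position {pos} out of range")
            if geom not in ("cis", "trans", "unknown"):
                raise ValueError(f"bad double-bond geometry {geom!r}")

    @property
    def composition(self) -> ElementComposition:
        d = len(self.double_bonds)
        h = 2 * self.carbons - 2 * d
        return ElementComposition(C=self.carbons, H=h, O=3)

    @property
    def label(self) -> str:
        d = len(self.double_bonds)
        return f"C{self.carbons}:{d}-3OH"

    @classmethod
    def from_label(cls, label: str) -> "FattyAcidSpec":
        """Parse labels like ``C10:0-3OH`` or ``C12:1(5c)-3OH``."""
        import re

        m = re.fullmatch(
            r"C(\d+):(\d+)(?:\(([\dA-Za-z,]+)\))?(?:-3OH)?", label.strip()
        )
        if not m:
            raise ValueError(f"cannot parse fatty-acid label {label!r}")
        n, d = int(m.group(1)), int(m.group(2))
        bonds: list[tuple[int, str]] = []
        if m.group(3):
            for tok in m.group(3).split(","):
                tok = tok.strip()
                geom = "unknown"
                if tok.endswith(("c", "t")):
                    geom = "cis" if tok[-1] == "c" else "trans"
                    tok = tok[:-1]
                bonds.append((int(tok), geom))
        while len(bonds) < d:
            bonds.append((5, "unknown"))  # unspecified position placeholder
        return cls(carbons=n, double_bonds=tuple(bonds[:d]))


Stereo = Literal["L", "D", "unknown"]

_HYDROXYL_DONORS = frozenset({"Ser", "Thr", "aThr"})


@dataclass(frozen=True)
class LipopeptideStructure:
    """A (possibly cyclic, possibly N-acylated) lipopeptide.

    residues: ordered (ResidueSpec, stereo) pairs, N- to C-terminus.
    fatty_acid: optional N-acyl 3-hydroxy fatty acid.
    lactone_donor: optional 1-based index of the hydroxyl-bearing residue
        (Ser/Thr/aThr) whose side chain esterifies the C-terminal carboxyl;
        0 designates the fatty-acid 3-OH as donor.
    """

    residues: tuple[tuple[ResidueSpec, str], ...]
    fatty_acid: FattyAcidSpec | None = None
    lactone_donor: int | None = None
    name: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError("structure needs at least one residue")
        for _, stereo in self.residues:
            if stereo not in ("L", "D", "unknown"):
                raise ValueError(f"bad stereo flag {stereo!r}")
        if self.lactone_donor is not None:
            d = self.lactone_donor
            if d == 0:
                if self.fatty_acid is None:
                    raise ValueError("fatty-acid 3-OH donor without fatty acid")
            elif 1 <= d <= len(self.residues):
                spec = self.residues[d - 1][0]
                if spec.name not in _HYDROXYL_DONORS:
                    raise ValueError(
                        f"lactone donor residue {d} ({spec.name}) has no "
                        "hydroxyl side chain"
                    )
            else:
                raise ValueError(f"lactone donor index {d} out of range")

    @property
    def is_cyclic(self) -> bool:
        return self.lactone_donor is not None

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(spec.name for spec, _ in self.residues)

    @classmethod
    def from_sequence(
        cls,
        residue_names: Sequence[str],
        stereo: Sequence[str] | None = None,
        fatty_acid: FattyAcidSpec | str | None = None,
        lactone_donor: int | None = None,
        name: str = "",
    ) -> "LipopeptideStructure":
        if stereo is None:
            stereo = ["unknown"] * len(residue_names)
        if isinstance(fatty_acid, str):
            fatty_acid = FattyAcidSpec.from_label(fatty_acid)
        residues = tuple(
            (get_residue(rn), st) for rn, st in zip(residue_names, stereo, strict=True)
        )
        return cls(residues, fatty_acid, lactone_donor, name)


class UnresolvedGlx(ValueError):
    """Raised when a formula is requested for a structure still carrying Glx."""


def compose_formula(structure: LipopeptideStructure) -> ElementComposition:
    """Neutral molecular formula of a lipopeptide structure.

    Sum of residue compositions + H2O for the chain termini, + fatty-acid
    composition - H2O for the N-acyl amide, - H2O for the lactone if cyclic.
    Structures containing unresolved Glx raise :class:`UnresolvedGlx`
    (Glu and Gln differ by 0.984 Da, so there is no single answer); see
    :func:`enumerate_glx_isoforms`.
    """
    glx = [i + 1 for i, (spec, _) in enumerate(structure.residues)
           if spec.name == "Glx"]
    if glx:
        raise UnresolvedGlx(
            f"residues {glx} are Glx; resolve to Glu/Gln or enumerate isoforms"
        )
    total = ElementComposition()
    for spec, _ in structure.residues:
        total = total + spec.residue_composition
    total = total + WATER
    if structure.fatty_acid is not None:
        total = total + structure.fatty_acid.composition - WATER
    if structure.is_cyclic:
        total = total - WATER
    return total


def enumerate_glx_isoforms(
    structure: LipopeptideStructure,
) -> list[LipopeptideStructure]:
    """All structures obtained by resolving each Glx to Glu or Gln.

    With k Glx residues this returns 2**k structures; the monoisotopic masses
    span k * 0.984 Da.  Structures without Glx are returned unchanged.
    """
    from itertools import product as _prod

    idx = [i for i, (spec, _) in enumerate(structure.residues)
           if spec.name == "Glx"]
    if not idx:
        return [structure]
    out = []
    for choice in _prod(("Glu", "Gln"), repeat=len(idx)):
        residues = list(structure.residues)
        for i, nm in zip(idx, choice):
            residues[i] = (get_residue(nm), residues[i][1])
        out.append(
            LipopeptideStructure(
                tuple(residues), structure.fatty_acid,
                structure.lactone_donor, structure.name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Adducts and mass-difference hypotheses

_ADDUCTS: dict[str, tuple[float, int]] = {
    # name -> (total added mass, charge)
    "[M+H]+": (PROTON_MASS, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
    "[M+3H]3+": (3 * PROTON_MASS, 3),
    "[M+Na]+": (_monoisotopic("Na") - 5.48579909e-4, 1),  # Na+ = Na - e-
}


def adduct_mz(
    comp: ElementComposition,
    adduct: str = "[M+H]+",
    *,
    added_mass: float | None = None,
    charge: int | None = None,
) -> float:
    """m/z of an adduct ion: (M + added species mass) / z.

    Protonated species use the proton mass (1.007276 Da).  Either pass a
    known `adduct` name ([M+H]+, [M+2H]2+, [M+3H]3+, [M+Na]+) or explicit
    `added_mass` and `charge`.
    """
    if added_mass is None or charge is None:
        try:
            added_mass, charge = _ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    if charge == 0:
        raise ValueError("charge must be nonzero")
    return (monoisotopic_mass(comp) + added_mass) / charge


@dataclass(frozen=True)
class DeltaHypothesis:
    """A compositional explanation for an observed mass difference."""

    name: str
    delta_composition: str
    exact_mass: float
    interpretation: str
    error: float = field(default=0.0, compare=False)


#: Built-in mass-difference hypotheses for lipopeptide congeners.
DELTA_TABLE: tuple[DeltaHypothesis, ...] = (
    DeltaHypothesis(
        "identity", "", 0.0,
        "no compositional change (same formula)",
    ),
    DeltaHypothesis(
        "CH2", "CH2", monoisotopic_mass(ElementComposition(C=1, H=2)),
        "one methylene: Ile<->Val (or Leu<->Val) substitution, or fatty-acid "
        "chain +/-CH2",
    ),
    DeltaHypothesis(
        "C2H2", "C2H2", monoisotopic_mass(ElementComposition(C=2, H=2)),
        "two carbons with one unsaturation: e.g. C10:0 -> C12:1 fatty acid",
    ),
    DeltaHypothesis(
        "H2O", "H2O", monoisotopic_mass(WATER),
        "one water: macrolactone opening/closure (linear vs cyclic)",
    ),
    DeltaHypothesis(
        "Na-H", "Na - H",
        _monoisotopic("Na") - _monoisotopic("H"),
        "sodium/proton exchange ([M+Na]+ vs [M+H]+ ion pairing)",
    ),
)


def read_congener_table(path) -> list[LipopeptideStructure]:
    """Load structures from a congener TSV.

    Columns: ``name``, ``residues`` (dash-separated 3-letter codes),
    ``fatty_acid`` (label like ``C10:0-3OH``; empty for none),
    ``lactone_donor`` (1-based residue index; empty for linear).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    need = {"name", "residues", "fatty_acid", "lactone_donor"}
    if not need <= set(df.columns):
        raise ValueError(f"congener table needs columns {sorted(need)}")
    out = []
    for row in df.itertuples(index=False):
        donor = str(row.lactone_donor).strip()
        out.append(
            LipopeptideStructure.from_sequence(
                str(row.residues).split("-"),
                fatty_acid=str(row.fatty_acid).strip() or None,
                lactone_donor=int(donor) if donor else None,
                name=str(row.name),
            )
        )
    return out


def mass_delta_explain(
    delta: float,
    tolerance: float = 0.05,
    table: Iterable[DeltaHypothesis] = DELTA_TABLE,
) -> list[DeltaHypothesis]:
    """Hypotheses whose exact mass matches |delta| within `tolerance`.

    Returned sorted by absolute error (best first); empty if nothing matches.
    The built-in table covers the differences seen between lipopeptide
    congeners (CH2, C2H2, H2O, Na/H exchange); pass a custom `table` to
    extend it.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    adelta = abs(delta)
    out = [
        DeltaHypothesis(
            h.name, h.delta_composition, h.exact_mass, h.interpretation,
            error=adelta - h.exact_mass,
        )
        for h in table
        if abs(adelta - h.exact_mass) <= tolerance
    ]
    out.sort(key=lambda h: (abs(h.error), h.name))
    return out
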