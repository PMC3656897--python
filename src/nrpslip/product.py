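"""Co-linear product prediction: from a called assembly line to structures.

The co-linearity rule of NRPS biosynthesis says the order and number of
modules match the order and number of residues in the product.  Given one
substrate call per module this module derives:

* the predicted peptide (primary label per position, alternatives carried
  through from call ties — the source of single-residue congeners),
* the D/L configuration vector: a dual C/E domain in module i epimerizes the
  residue loaded on module i-1's carrier, so residue i-1 is D iff module i's
  C domain is of the C/E type; the final residue stays L.  The output is
  explicitly labelled a prediction — deviations from this sequence-based
  rule are documented for this family of compounds,
* macrolactonization candidates: with a TE present, every internal
  Ser/Thr/allo-Thr can in principle donate its side-chain hydroxyl to the
  C-terminal carboxyl.  Candidates are enumerated, never auto-selected: the
  "last hydroxyl residue" heuristic demonstrably fails (entolysin closes at
  Ser10, ring size 5, not at Ser13), so the choice needs NMR evidence,
* congeners: the Cartesian product of per-position alternatives and
  fatty-acid variants, each rendered with formula and monoisotopic mass,
* two NMR-evidence heuristics — a hydroxyl site whose H-beta resonances sit
  well downfield of random-coil values marks the depsi (ester) bond, and the
  sign of the 13C shift changes of the carbons flanking a fatty-acid double
  bond relative to the saturated analog separates cis from trans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product as _cartesian
from typing import Literal, Sequence

from . import chem
from .annotation import AssemblyLine
from .classification import CDomainCall, SpecificityCall

__all__ = [
    "ResidueCall",
    "PeptidePrediction",
    "ShiftTable",
    "RandomCoilReference",
    "DEFAULT_RANDOM_COIL",
    "CongenerRecord",
    "DepsiFlag",
    "predict_peptide",
    "assign_stereochemistry",
    "enumerate_cyclization",
    "enumerate_congeners",
    "flag_depsi_sites",
    "classify_alkene_geometry",
]

STEREO_CAVEAT = (
    "predicted — sequence-based C/E epimerization rule; deviations have been "
    "documented in this compound family and experimental validation is needed"
)

_HYDROXYL = {"Ser", "Thr", "aThr"}


@dataclass(frozen=True)
class ResidueCall:
    primary: str
    alternatives: tuple[str, ...] = ()

    @property
    def options(self) -> tuple[str, ...]:
        return (self.primary,) + self.alternatives


@dataclass(frozen=True)
class PeptidePrediction:
    """Predicted peptide with stereo flags and cyclization candidates."""

    residues: tuple[ResidueCall, ...]
    stereo: tuple[str, ...]
    lipid_attached: bool
    cyclization_candidates: tuple[tuple[int, int], ...]  # (donor, ring size)
    stereo_caveat: str = STEREO_CAVEAT

    def __post_init__(self):
        if len(self.stereo) != len(self.residues):
            raise ValueError("stereo vector length must equal peptide length")
        n = len(self.residues)
        for donor, ring in self.cyclization_candidates:
            if not (1 <= donor <= n):
                raise ValueError(f"donor index {donor} out of range")
            if ring != n - donor + 1:
                raise ValueError("ring size must equal n - donor + 1")
            if self.residues[donor - 1].primary not in _HYDROXYL:
                raise ValueError(
                    f"donor {donor} is not a hydroxyl-bearing residue"
                )

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(r.primary for r in self.residues)


def predict_peptide(
    line: AssemblyLine,
    calls: Sequence[SpecificityCall],
    c_subtypes: Sequence[str] | None = None,
) -> PeptidePrediction:
    """Apply the co-linearity rule: residue i = substrate call of module i.

    `calls` must provide exactly one call per module, in module order; call
    ties are carried through as alternatives.  If `c_subtypes` (one of
    starter/dual/conventional/unassigned per module) is given the stereo
    vector follows the C/E rule, otherwise it is all-unknown.
    """
    n = line.n_modules
    if len(calls) != n:
        raise ValueError(
            f"need one substrate call per module ({n}), got {len(calls)}"
        )
    residues = tuple(
        ResidueCall(c.label, tuple(t for t in c.ties if t != c.label))
        for c in calls
    )
    if c_subtypes is not None:
        stereo = assign_stereochemistry(c_subtypes)
    else:
        stereo = ("unknown",) * n
    candidates = enumerate_cyclization(
        [r.primary for r in residues], te_present=bool(line.te_hits)
    )
    return PeptidePrediction(
        residues=residues,
        stereo=stereo,
        lipid_attached=line.has_starter_c,
        cyclization_candidates=tuple(candidates),
    )


def assign_stereochemistry(c_subtypes: Sequence[str]) -> tuple[str, ...]:
    """D/L vector from the per-module C-domain subtypes.

    Residue i-1 is D iff module i's C domain is dual C/E (i >= 2); residues
    followed by a conventional (or starter) C stay L; the terminal residue is
    L.  An unassigned subtype makes the affected residue's stereo unknown.
    The result is a prediction (see :data:`STEREO_CAVEAT`).
    """
    n = len(c_subtypes)
    out: list[str] = []
    for i in range(1, n + 1):
        if i == n:
            out.append("L")
            continue
        nxt = c_subtypes[i]  # module i+1, 0-based index i
        if nxt == "dual":
            out.append("D")
        elif nxt in ("conventional", "starter"):
            out.append("L")
        else:
            out.append("unknown")
    return tuple(out)


def enumerate_cyclization(
    sequence: Sequence[str], te_present: bool
) -> list[tuple[int, int]]:
    """All C-terminal macrolactone candidates, N- to C-terminal order.

    With a TE present, every internal Ser/Thr/allo-Thr is a candidate donor
    closing to the C-terminus with inclusive ring size n - donor + 1.  No
    candidate is ever auto-selected.  No TE, or no hydroxyl residue, means a
    linear product (empty list).
    """
    if not sequence:
        raise ValueError("empty peptide")
    if not te_present:
        return []
    n = len(sequence)
    return [
        (i + 1, n - i)
        for i, r in enumerate(sequence[:-1])
        if r in _HYDROXYL
    ]


@dataclass(frozen=True)
class CongenerRecord:
    structure: chem.LipopeptideStructure
    formula: str
    monoisotopic_mass: float
    mz_mh: float  # [M+H]+

    @property
    def name(self) -> str:
        return self.structure.name


def enumerate_congeners(
    pred: PeptidePrediction,
    fatty_acids: Sequence[chem.FattyAcidSpec | str],
    lactone_donor: int | None,
    glx_mode: Literal["error", "enumerate"] = "error",
) -> list[CongenerRecord]:
    """All (residue-alternative x fatty-acid) variants with formulas/masses.

    The primary-only combination with the first fatty acid is listed first.
    Total count = (product of per-position option counts) x len(fatty_acids),
    times 2 per Glx when `glx_mode="enumerate"`; an unresolved Glx under
    `glx_mode="error"` raises.
    """
    fas = [
        chem.FattyAcidSpec.from_label(fa) if isinstance(fa, str) else fa
        for fa in fatty_acids
    ]
    if not fas:
        raise ValueError("need >= 1 fatty acid")
    out: list[CongenerRecord] = []
    option_sets = [rc.options for rc in pred.residues]
    for combo in _cartesian(*option_sets):
        for fa in fas:
            structure = chem.LipopeptideStructure.from_sequence(
                combo, stereo=pred.stereo, fatty_acid=fa,
                lactone_donor=lactone_donor,
                name="/".join(combo) + "+" + fa.label,
            )
            if glx_mode == "enumerate":
                variants = chem.enumerate_glx_isoforms(structure)
            else:
                variants = [structure]
            for s in variants:
                comp = chem.compose_formula(s)  # raises on unresolved Glx
                m = chem.monoisotopic_mass(comp)
                out.append(
                    CongenerRecord(
                        structure=s,
                        formula=comp.hill_formula(),
                        monoisotopic_mass=chem.round_mass(m),
                        mz_mh=chem.round_mass(chem.adduct_mz(comp, "[M+H]+")),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# NMR-evidence heuristics


@dataclass(frozen=True)
class ShiftTable:
    """Observed chemical shifts: rows of (residue_index, residue, atom, ppm).

    Residue index 0 is reserved for the fatty-acid moiety.
    """

    rows: tuple[tuple[int, str, str, float], ...]

    def __post_init__(self):
        for idx, res, atom, ppm in self.rows:
            if not math.isfinite(ppm):
                raise ValueError(f"non-finite shift at {res}{idx} {atom}")

    @classmethod
    def from_tsv(cls, path) -> "ShiftTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        need = {"residue_index", "residue", "atom", "shift_ppm"}
        if not need <= set(df.columns):
            raise ValueError(f"shift table needs columns {sorted(need)}")
        return cls(
            tuple(
                (int(r.residue_index), str(r.residue), str(r.atom),
                 float(r.shift_ppm))
                for r in df.itertuples(index=False)
            )
        )


#: residue -> atom -> random-coil shift (ppm)
RandomCoilReference = dict[str, dict[str, float]]

#: Minimal random-coil reference: the Ser H-beta pair, Thr H-beta and the
#: 3-hydroxy-acyl methine proton of the lipid moiety (index 0, "FA").
DEFAULT_RANDOM_COIL: RandomCoilReference = {
    "Ser": {"HB2": 3.79, "HB3": 3.95},
    "Thr": {"HB": 4.22},
    "aThr": {"HB": 4.22},
    "FA": {"HB": 4.00},
}


@dataclass(frozen=True)
class DepsiFlag:
    residue_index: int
    residue: str
    mean_delta_ppm: float
    flagged: bool
    n_atoms: int


def flag_depsi_sites(
    shifts: ShiftTable,
    rc: RandomCoilReference | None = None,
    threshold_ppm: float = 0.3,
) -> list[DepsiFlag]:
    """Flag candidate ester-bond donor sites by H-beta downfield shift.

    A site is flagged when the mean of (observed - random coil) over its
    reference-covered atoms exceeds `threshold_ppm` — the anisotropic
    deshielding by the ester carbonyl pulls the donor's H-beta well downfield,
    while an uninvolved hydroxyl (e.g. the lipid 3-OH methine) is not
    shifted.  Sites with no random-coil reference are skipped with a warning.
    """
    if rc is None:
        rc = DEFAULT_RANDOM_COIL
    grouped: dict[tuple[int, str], list[tuple[str, float]]] = {}
    for idx, res, atom, ppm in shifts.rows:
        grouped.setdefault((idx, res), []).append((atom, ppm))
    out: list[DepsiFlag] = []
    for (idx, res), atoms in sorted(grouped.items()):
        ref = rc.get(res)
        deltas = []
        for atom, ppm in atoms:
            if ref and atom in ref:
                deltas.append(ppm - ref[atom])
        if not deltas:
            warnings.warn(
                f"no random-coil reference for site {res}{idx}; skipped",
                stacklevel=2,
            )
            continue
        mean = sum(deltas) / len(deltas)
        out.append(
            DepsiFlag(idx, res, mean, mean > threshold_ppm, len(deltas))
        )
    return out


def classify_alkene_geometry(
    delta_gamma_ppm: float, delta_zeta_ppm: float
) -> Literal["cis", "trans", "ambiguous"]:
    """cis/trans call from 13C shift changes of the allylic carbons.

    Inputs are observed minus saturated-analog shifts of the carbons
    flanking the double bond.  A cis double bond shifts both upfield
    (gamma-gauche effect, both deltas negative); trans shifts both downfield
    (both positive); mixed signs are ambiguous.
    """
    if not (math.isfinite(delta_gamma_ppm) and math.isfinite(delta_zeta_ppm)):
        raise ValueError("shift deltas must be finite")
    if delta_gamma_ppm < 0 and delta_zeta_ppm < 0:
        return "cis"
    if delta_gamma_ppm > 0 and delta_zeta_ppm > 0:
        return "trans"
    return "ambiguous"
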