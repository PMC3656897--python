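"""Seeded generator of synthetic NRPS panels, assembly lines and ground truth.

Every pipeline stage is testable without downloads: this module emits
multi-modular NRPS proteins built from the packaged consensus templates —
ordered C-A-T modules with the conserved core motifs, substrate-class-specific
residues at the A-domain signature positions, C-domain subtype blocks, an
optional terminal TE tandem — joined by random linkers, under a seeded
per-site substitution model.  The ground truth records every planted feature
(domain coordinates, subtypes, substrates, signatures, expected peptide,
stereochemistry and cyclization candidates) so detector and classifier
output can be checked exactly.

Class ancestry: each substrate class (and C/TE subtype) descends from its own
ancestor, a copy of the kind template whose non-anchor scaffold columns are
independently diverged (default 25% per site) and, for A domains, whose 10
diagnostic signature columns carry class-specific residues.  Ancestors are
deterministic per (kind, label) — independent of the simulation seed — so
panels and assembly lines generated in separate calls share them.  Anchor
columns (the conserved columns the scanner keys on) are exempt from class
divergence but not from the per-instance mutation rate: conserved columns
stay conserved across classes, diagnostic and scaffold columns carry the
class signal.

The default configuration mirrors the xantholysin architecture: three
proteins of 2 + 8 + 4 modules, starter C on module 1, dual C/E on modules
2-11 and 14, conventional C on 12 and 13, a TE tandem, the 14-residue
Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile substrate plan and a
3-hydroxydecanoate lipid.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import chem
from .annotation import ProteinRecord, Profiles, default_profiles
from .classification import C_CLASSES, TE_CLASSES, ReferenceDomain

__all__ = [
    "AA_ALPHABET",
    "DEFAULT_CLASS_DIVERGENCE",
    "SimulationConfig",
    "PlantedDomain",
    "GroundTruth",
    "mutate",
    "class_signature",
    "class_ancestor",
    "make_reference_panel",
    "simulate_assembly_line",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_CLASS_DIVERGENCE = 0.25
_SIG_SALT = "nrpslip-class-signature-v1"
_ANC_SALT = "nrpslip-class-ancestor-v1"

# degenerate core-motif patterns; linkers are rejection-sampled against these
_MOTIF_PATTERNS = [
    re.compile(p)
    for p in (r"HH...DG", r"SGTTG.PK", r"[IL]GG.S[IL]", r"G.S.G")
]

_XTL_LIKE_SUBSTRATES = (
    "Leu", "Glu", "Gln", "Val", "Leu", "Gln", "Ser",
    "Val", "Leu", "Gln", "Leu", "Leu", "Gln", "Ile",
)
_XTL_LIKE_C_PLAN = (
    ("starter",) + ("dual",) * 10 + ("conventional", "conventional") + ("dual",)
)


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability `rate` to a different residue."""
    if not (0.0 <= rate <= 0.5):
        raise ValueError("mutation rate must lie in [0, 0.5]")
    if rate == 0.0:
        return sequence
    seq = list(sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = AA_ALPHABET.replace(seq[i], "")
        seq[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def _label_rng(salt: str, *parts: str) -> np.random.Generator:
    key = ":".join((salt,) + parts)
    return np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)


def class_signature(label: str) -> str:
    """The 10 class-specific diagnostic residues for a substrate label.

    Deterministic per label; independent labels disagree at nearly all
    positions (the panel generator verifies >= 6/10 pairwise differences).
    """
    rng = _label_rng(_SIG_SALT, label)
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=10))


def class_ancestor(
    kind: str,
    label: str,
    profiles: Profiles | None = None,
    divergence: float = DEFAULT_CLASS_DIVERGENCE,
) -> str:
    """Ancestor sequence of one substrate class / domain subtype.

    A: the A template with non-anchor scaffold columns diverged and the
    class signature planted at the 10 diagnostic columns.  C/TE: the subtype
    template (subtype block planted) with non-anchor, non-block columns
    diverged.  T: the template itself.  Deterministic per (kind, label).
    """
    prof = profiles or default_profiles()
    if kind == "T":
        return prof.template("T")
    rng = _label_rng(_ANC_SALT, kind, label)
    spec = prof.domains[kind]
    if kind == "A":
        base = prof.template("A")
        cols34 = spec["signature34_cols"]
        diag_cols = [cols34[i - 1] for i in spec["signature10_idx"]]
        frozen = set(spec["anchor_cols"]) | set(diag_cols)
    elif kind in ("C", "TE"):
        if label not in spec["subtypes"]:
            raise ValueError(f"unknown {kind} subtype {label!r}")
        base = prof.subtype_template(kind, label)
        frozen = set(spec["anchor_cols"]) | set(spec["subtype_cols"])
    else:
        raise ValueError(f"unknown domain kind {kind!r}")
    seq = list(base)
    for i in range(len(seq)):
        if i in frozen:
            continue
        if rng.random() < divergence:
            choices = AA_ALPHABET.replace(seq[i], "")
            seq[i] = choices[int(rng.integers(0, len(choices)))]
    if kind == "A":
        sig = class_signature(label)
        for c, r in zip(diag_cols, sig):
            seq[c] = r
    return "".join(seq)


def _signatures_from_columns(seq: str, profiles: Profiles) -> tuple[str, str]:
    cols34, idx10 = profiles.signature_columns()
    s34 = "".join(seq[c] for c in cols34)
    s10 = "".join(s34[i - 1] for i in idx10)
    return s34, s10


def make_reference_panel(
    kind: str,
    class_labels: Sequence[str],
    n_per_class: int,
    seed: int,
    ref_rate: float = 0.05,
    profiles: Profiles | None = None,
) -> list[ReferenceDomain]:
    """A labelled synthetic panel: seeded mutants of each class ancestor.

    Requires >= 2 classes with >= 2 references each; labels must come from
    the kind's vocabulary (residue registry for A, the three C classes, the
    two TE classes).  For A panels the planted class signatures are verified
    to differ at >= 6/10 diagnostic positions for every class pair.
    Deterministic per seed.
    """
    prof = profiles or default_profiles()
    labels = list(class_labels)
    if len(labels) < 2 or len(set(labels)) != len(labels):
        raise ValueError("need >= 2 distinct class labels")
    if n_per_class < 2:
        raise ValueError("need >= 2 references per class")
    vocab = {
        "A": set(chem.RESIDUES),
        "C": set(C_CLASSES),
        "TE": set(TE_CLASSES),
    }[kind]
    extra = set(labels) - vocab
    if extra:
        raise ValueError(
            f"labels outside the {kind} vocabulary: {sorted(extra)}"
        )
    if kind == "A":
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                same = sum(
                    a == b for a, b in zip(class_signature(la), class_signature(lb))
                )
                if same > 4:
                    raise ValueError(
                        f"class signatures of {la!r} and {lb!r} collide at "
                        f"{same}/10 positions; rename one class"
                    )
    rng = np.random.default_rng(seed)
    out: list[ReferenceDomain] = []
    for label in labels:
        anc = class_ancestor(kind, label, prof)
        for k in range(n_per_class):
            seq = mutate(anc, ref_rate, rng)
            s34 = s10 = ""
            if kind == "A":
                s34, s10 = _signatures_from_columns(seq, prof)
            out.append(
                ReferenceDomain(
                    id=f"{label}.r{k}", kind=kind, label=label,
                    sequence=seq, signature_34=s34, signature_10=s10,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Assembly-line simulation


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated assembly line.

    Defaults mirror the xantholysin architecture (2 + 8 + 4 modules, starter
    C, dual C/E except two conventional C before the terminal module, TE
    tandem, 3-hydroxydecanoate lipid) at a 5% per-site substitution rate.
    """

    seed: int
    modules_per_protein: tuple[int, ...] = (2, 8, 4)
    substrates: tuple[str, ...] = _XTL_LIKE_SUBSTRATES
    c_subtypes: tuple[str, ...] = _XTL_LIKE_C_PLAN
    te_tandem: bool = True
    mutation_rate: float = 0.05
    linker_range: tuple[int, int] = (10, 60)
    fatty_acids: tuple[str, ...] = ("C10:0-3OH",)

    def __post_init__(self):
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation rate must lie in [0, 0.5]")
        n = sum(self.modules_per_protein)
        if n < 1 or any(m < 1 for m in self.modules_per_protein):
            raise ValueError("every protein needs >= 1 module")
        if len(self.substrates) != n:
            raise ValueError("substrate plan does not match module plan")
        if len(self.c_subtypes) != n:
            raise ValueError("C-subtype plan does not match module plan")
        bad = set(self.c_subtypes) - set(C_CLASSES)
        if bad:
            raise ValueError(f"unknown C subtypes: {sorted(bad)}")
        lo, hi = self.linker_range
        if not (0 <= lo <= hi):
            raise ValueError("bad linker range")


@dataclass(frozen=True)
class PlantedDomain:
    protein_id: str
    kind: str
    label: str  # substrate for A, subtype for C/TE, "T" for T
    start: int
    end: int


@dataclass
class GroundTruth:
    """Everything planted in one simulated line, for exact checking."""

    domains: list[PlantedDomain]
    substrates: list[str]  # per module, in line order
    c_subtypes: list[str]
    signatures_10: list[str]  # per module
    te_labels: list[str]
    expected_peptide: list[str]
    expected_stereo: list[str]
    cyclization_candidates: list[tuple[int, int]]  # (donor 1-based, ring size)
    fatty_acids: list[str]
    congener_formulas: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _stereo_from_c_plan(c_subtypes: Sequence[str]) -> list[str]:
    # residue i is epimerized (D) iff the NEXT module's C domain is dual C/E;
    # the final residue stays L (no downstream condensation acts on it)
    n = len(c_subtypes)
    out = []
    for i in range(1, n + 1):
        if i == n:
            out.append("L")
        elif c_subtypes[i] == "dual":  # module i+1 (0-based index i)
            out.append("D")
        else:
            out.append("L")
    return out


_HYDROXYL = {"Ser", "Thr", "aThr"}


def _random_linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    while True:
        n = int(rng.integers(lo, hi + 1))
        s = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=max(n, 0)))
        if not any(p.search(s) for p in _MOTIF_PATTERNS):
            return s


def simulate_assembly_line(
    config: SimulationConfig,
    profiles: Profiles | None = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Simulate one multi-protein NRPS assembly line with ground truth.

    Byte-identical output for equal configs (single RNG stream per call).
    """
    prof = profiles or default_profiles()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.linker_range
    records: list[ProteinRecord] = []
    planted: list[PlantedDomain] = []
    signatures: list[str] = []
    module_idx = 0
    n_total = sum(config.modules_per_protein)
    for p, n_modules in enumerate(config.modules_per_protein):
        pid = f"synP{p + 1}"
        parts: list[str] = []
        pos = 0

        def _emit(kind: str, label: str, seq: str):
            nonlocal pos
            planted.append(PlantedDomain(pid, kind, label, pos, pos + len(seq)))
            parts.append(seq)
            pos += len(seq)

        def _linker():
            nonlocal pos
            s = _random_linker(rng, lo, hi)
            parts.append(s)
            pos += len(s)

        _linker()
        for _ in range(n_modules):
            sub = config.substrates[module_idx]
            csub = config.c_subtypes[module_idx]
            c_seq = mutate(class_ancestor("C", csub, prof), config.mutation_rate, rng)
            _emit("C", csub, c_seq)
            _linker()
            a_seq = mutate(class_ancestor("A", sub, prof), config.mutation_rate, rng)
            _emit("A", sub, a_seq)
            signatures.append(_signatures_from_columns(a_seq, prof)[1])
            _linker()
            t_seq = mutate(class_ancestor("T", "T", prof), config.mutation_rate, rng)
            _emit("T", "T", t_seq)
            _linker()
            module_idx += 1
        te_labels: list[str] = []
        if p == len(config.modules_per_protein) - 1 and config.te_tandem:
            for lab in TE_CLASSES:
                te_seq = mutate(
                    class_ancestor("TE", lab, prof), config.mutation_rate, rng
                )
                _emit("TE", lab, te_seq)
                _linker()
                te_labels.append(lab)
        records.append(ProteinRecord(pid, "".join(parts)))

    peptide = list(config.substrates)
    stereo = _stereo_from_c_plan(config.c_subtypes)
    candidates = [
        (i + 1, n_total - i)
        for i, r in enumerate(peptide[:-1])
        if r in _HYDROXYL
    ] if config.te_tandem else []
    formulas: dict[str, str] = {}
    if not any(chem.get_residue(r).name == "Glx" for r in peptide):
        donor = candidates[0][0] if candidates else None
        for fa in config.fatty_acids:
            structure = chem.LipopeptideStructure.from_sequence(
                peptide, fatty_acid=fa, lactone_donor=donor
            )
            formulas[fa] = str(chem.compose_formula(structure))
    gt = GroundTruth(
        domains=planted,
        substrates=list(config.substrates),
        c_subtypes=list(config.c_subtypes),
        signatures_10=signatures,
        te_labels=list(TE_CLASSES) if config.te_tandem else [],
        expected_peptide=peptide,
        expected_stereo=stereo,
        cyclization_candidates=candidates,
        fatty_acids=list(config.fatty_acids),
        congener_formulas=formulas,
    )
    return records, gt
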