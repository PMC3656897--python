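"""NRPS domain detection and assembly-line construction.

An NRPS protein is a chain of modules, each canonically condensation (C) -
adenylation (A) - thiolation (T), with one or two thioesterase (TE) domains
at the C-terminal end of the last protein of the assembly line.  This module
finds those domains in protein sequences and assembles them into modules and
multi-protein lines.

Detection is motif-anchored template matching against the packaged profile
set (``data/profiles.json``): each domain kind has a synthetic consensus
template of nominal length (C ~450, A ~500, T ~80, TE ~250 aa) carrying the
canonical core motifs (C: HHxxxDG; A: the A3 "SGTTGxPK"-like and A8 cores;
T: xGGxSx with the invariant Ser; TE: GxSxG) plus a spread of conserved
anchor columns.  A window is a candidate hit when the fraction of matching
anchor columns reaches the configured threshold (default 0.6); overlaps are
resolved by score, then leftmost start, then kind order C < A < T < TE, so
output is deterministic.  Users who prefer profile-HMM annotation can import
third-party domain coordinate tables instead (:func:`read_domain_table`).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "Module",
    "AssemblyLine",
    "AnnotatedProtein",
    "Profiles",
    "load_profiles",
    "scan_domains",
    "build_modules",
    "annotate_protein",
    "assemble_line",
    "read_domain_table",
    "write_domain_table",
]

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")
KIND_ORDER = {"C": 0, "A": 1, "T": 2, "TE": 3}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier (uppercase, 20 letters + X)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One detected domain: kind, subtype, 0-based half-open span, score."""

    kind: str  # C | A | T | TE
    start: int
    end: int
    score: float
    subtype: str = "unassigned"

    def __post_init__(self):
        if self.kind not in KIND_ORDER:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Module:
    """A C-A-T unit; `index` is 1-based along the assembly line."""

    index: int
    protein_id: str
    c: DomainHit
    a: DomainHit
    t: DomainHit

    @property
    def domains(self) -> tuple[DomainHit, DomainHit, DomainHit]:
        return (self.c, self.a, self.t)


@dataclass(frozen=True)
class AnnotatedProtein:
    record: ProteinRecord
    hits: tuple[DomainHit, ...]
    modules: tuple[Module, ...]
    te_hits: tuple[DomainHit, ...]
    diagnostics: tuple[str, ...]


@dataclass(frozen=True)
class AssemblyLine:
    """Ordered proteins, continuously numbered modules, terminal TE hits."""

    proteins: tuple[ProteinRecord, ...]
    modules: tuple[Module, ...]
    te_hits: tuple[DomainHit, ...]  # on the last protein only
    has_starter_c: bool
    te_tandem: bool
    diagnostics: tuple[str, ...] = ()

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def domain_sequence(self, module: Module, which: str) -> str:
        """Sequence of one domain of a module, cut from its protein."""
        hit = {"C": module.c, "A": module.a, "T": module.t}[which]
        prot = {p.id: p for p in self.proteins}[module.protein_id]
        return prot.sequence[hit.start:hit.end]

    def te_sequence(self, ordinal: int) -> str:
        hit = self.te_hits[ordinal]
        return self.proteins[-1].sequence[hit.start:hit.end]


# ---------------------------------------------------------------------------
# Profiles


class Profiles:
    """The packaged motif/profile set used by the scanner."""

    def __init__(self, payload: dict):
        self.threshold: float = float(payload["scan"]["score_threshold"])
        self.domains: dict = payload["domains"]
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        for kind, spec in self.domains.items():
            tmpl = spec["template"]
            cols = np.asarray(spec["anchor_cols"], dtype=np.int64)
            res = np.frombuffer(
                "".join(tmpl[c] for c in cols).encode("ascii"), dtype=np.uint8
            )
            self._anchors[kind] = (cols, res, len(tmpl))

    def template(self, kind: str) -> str:
        return self.domains[kind]["template"]

    def template_length(self, kind: str) -> int:
        return len(self.domains[kind]["template"])

    def subtype_template(self, kind: str, subtype: str) -> str:
        """Kind template with the subtype block residues planted."""
        spec = self.domains[kind]
        cols = spec["subtype_cols"]
        block = spec["subtypes"][subtype]
        seq = list(spec["template"])
        for c, r in zip(cols, block):
            seq[c] = r
        return "".join(seq)

    def subtypes(self, kind: str) -> tuple[str, ...]:
        return tuple(self.domains[kind].get("subtypes", {}))

    def signature_columns(self) -> tuple[list[int], list[int]]:
        """(34 signature columns in the A template, 1-based indices of the
        10 diagnostic positions within the 34)."""
        a = self.domains["A"]
        return list(a["signature34_cols"]), list(a["signature10_idx"])

    def anchors(self, kind: str) -> tuple[np.ndarray, np.ndarray, int]:
        return self._anchors[kind]


def load_profiles() -> Profiles:
    text = (
        resources.files("nrpslip").joinpath("data/profiles.json").read_text()
    )
    return Profiles(json.loads(text))


_DEFAULT_PROFILES: Profiles | None = None


def default_profiles() -> Profiles:
    global _DEFAULT_PROFILES
    if _DEFAULT_PROFILES is None:
        _DEFAULT_PROFILES = load_profiles()
    return _DEFAULT_PROFILES


# ---------------------------------------------------------------------------
# Scanning


def _candidate_hits(seq: np.ndarray, kind: str, profiles: Profiles):
    cols, res, tlen = profiles.anchors(kind)
    n_pos = len(seq) - tlen + 1
    if n_pos <= 0:
        return
    scores = np.zeros(n_pos)
    for c, r in zip(cols, res):
        scores += seq[c:c + n_pos] == r
    scores /= len(cols)
    for p in np.nonzero(scores >= profiles.threshold)[0]:
        yield DomainHit(kind, int(p), int(p) + tlen, float(scores[p]))


def scan_domains(
    protein: ProteinRecord, profiles: Profiles | None = None
) -> list[DomainHit]:
    """All non-overlapping domain hits on one protein, sorted by start.

    Candidates from every kind template are pooled; overlaps are resolved
    greedily by highest anchor-identity score, ties by leftmost start, then
    by kind order C < A < T < TE.  A motif-free sequence yields no hits.
    """
    if profiles is None:
        profiles = default_profiles()
    seq = np.frombuffer(protein.sequence.encode("ascii"), dtype=np.uint8)
    candidates = []
    for kind in ("C", "A", "T", "TE"):
        candidates.extend(_candidate_hits(seq, kind, profiles))
    candidates.sort(key=lambda h: (-h.score, h.start, KIND_ORDER[h.kind]))
    chosen: list[DomainHit] = []
    for h in candidates:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen


def build_modules(
    hits: Sequence[DomainHit], start_index: int = 1
) -> tuple[list[Module], list[DomainHit], list[str]]:
    """Greedy left-to-right (C A T)+ (TE){0,2} grammar over sorted hits.

    Returns (modules, trailing TE hits, diagnostics).  Hits that do not fit
    the grammar are reported in the diagnostics, never silently dropped.
    `start_index` allows continuous module numbering across proteins.
    """
    hits = sorted(hits, key=lambda h: h.start)
    for a, b in zip(hits, hits[1:]):
        if b.start < a.end:
            raise ValueError("hits must be non-overlapping")
    modules: list[Module] = []
    te: list[DomainHit] = []
    diagnostics: list[str] = []
    i = 0
    idx = start_index
    while i < len(hits):
        h = hits[i]
        if (
            h.kind == "C"
            and i + 2 < len(hits)
            and hits[i + 1].kind == "A"
            and hits[i + 2].kind == "T"
        ):
            modules.append(Module(idx, "", h, hits[i + 1], hits[i + 2]))
            idx += 1
            i += 3
        elif h.kind == "TE" and modules and i >= len(hits) - 2 and all(
            x.kind == "TE" for x in hits[i:]
        ):
            te = list(hits[i:])
            i = len(hits)
        else:
            diagnostics.append(
                f"orphan {h.kind} domain at [{h.start}, {h.end}) does not fit "
                "the (C A T)+ (TE){0,2} grammar"
            )
            i += 1
    if not modules:
        diagnostics.append("no complete C-A-T module found")
    return modules, te, diagnostics


def annotate_protein(
    record: ProteinRecord,
    profiles: Profiles | None = None,
    start_index: int = 1,
) -> AnnotatedProtein:
    hits = scan_domains(record, profiles)
    modules, te, diags = build_modules(hits, start_index=start_index)
    modules = [replace(m, protein_id=record.id) for m in modules]
    return AnnotatedProtein(
        record, tuple(hits), tuple(modules), tuple(te), tuple(diags)
    )


def assemble_line(
    records: Sequence[ProteinRecord],
    profiles: Profiles | None = None,
) -> AssemblyLine:
    """Annotate proteins in the user-declared order and join them.

    Gene order is biological knowledge supplied by the caller, not inferred.
    Modules are numbered continuously across proteins; TE hits are only
    tolerated on the terminal protein (anything else is an error).
    """
    if not records:
        raise ValueError("assembly line needs >= 1 protein")
    annotated: list[AnnotatedProtein] = []
    idx = 1
    for rec in records:
        ap = annotate_protein(rec, profiles, start_index=idx)
        idx += len(ap.modules)
        annotated.append(ap)
    for ap in annotated[:-1]:
        if ap.te_hits:
            raise ValueError(
                f"TE domain(s) on non-terminal protein {ap.record.id!r}; "
                "check the declared protein order"
            )
    modules = tuple(m for ap in annotated for m in ap.modules)
    te = annotated[-1].te_hits
    diagnostics = tuple(
        f"{ap.record.id}: {d}" for ap in annotated for d in ap.diagnostics
    )
    has_starter = bool(modules) and modules[0].index == 1
    return AssemblyLine(
        proteins=tuple(r for r in records),
        modules=modules,
        te_hits=te,
        has_starter_c=has_starter,
        te_tandem=len(te) == 2,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Domain-table import/export (for users with external HMM annotation)

_TABLE_COLUMNS = ["protein_id", "kind", "subtype", "start", "end", "score"]


def write_domain_table(path, hits_by_protein: dict[str, Iterable[DomainHit]]):
    """TSV with columns protein_id, kind, subtype, start, end, score
    (coordinates 0-based half-open)."""
    import pandas as pd

    rows = [
        [pid, h.kind, h.subtype, h.start, h.end, h.score]
        for pid, hits in hits_by_protein.items()
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_domain_table(path) -> dict[str, list[DomainHit]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    out: dict[str, list[DomainHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append(
            DomainHit(
                kind=str(row.kind),
                start=int(row.start),
                end=int(row.end),
                score=float(row.score),
                subtype=str(row.subtype),
            )
        )
    for hits in out.values():
        hits.sort(key=lambda h: h.start)
    return out
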