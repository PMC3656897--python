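"""Substrate and subtype calling for NRPS domains.

Two independent routes predict which amino acid an adenylation (A) domain
activates:

* **signature nearest neighbor** — the ~10-residue diagnostic code (a subset
  of the 34-residue active-site signature, extracted by aligning the domain
  to a reference anchor) is compared against a labelled panel; the call is
  the label of the reference with most identities out of 10, with all
  co-optimal labels reported as ties.
* **phylogenetic placement** — the query is placed in a neighbor-joining
  tree together with the panel sequences and takes the label of the
  reference at smallest patristic distance; a second label within a small
  margin of the minimum makes the call ambiguous.

The same placement machinery types condensation domains (starter / dual C,E
/ conventional) and thioesterase domains (TE1 / TE2).  Reference panels are
FASTA + TSV files (id, kind, label, signature_34, signature_10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

from . import phylo
from .annotation import Profiles, default_profiles

__all__ = [
    "ReferenceDomain",
    "SpecificityCall",
    "SignatureTemplate",
    "default_signature_template",
    "extract_signature",
    "call_substrate_nn",
    "call_substrate_placement",
    "classify_c_domain",
    "classify_te",
    "CDomainCall",
    "TECall",
    "read_reference_panel",
    "write_reference_panel",
    "load_packaged_panel",
]

C_CLASSES = ("starter", "dual", "conventional")
TE_CLASSES = ("TE1", "TE2")

#: Minimum identities out of 10 for a confident nearest-neighbor call.
DEFAULT_NN_FLOOR = 6
#: Patristic margin below which a second label makes a placement ambiguous.
DEFAULT_PLACEMENT_DELTA = 0.05

MIN_DOMAIN_LENGTH = 200


@dataclass(frozen=True)
class ReferenceDomain:
    """A labelled reference domain (panel member)."""

    id: str
    kind: str  # A | C | TE
    label: str
    sequence: str
    signature_34: str = ""
    signature_10: str = ""

    def __post_init__(self):
        if self.kind not in ("A", "C", "TE"):
            raise ValueError(f"bad reference kind {self.kind!r}")
        if self.signature_34 and len(self.signature_34) != 34:
            raise ValueError("signature_34 must have length 34")
        if self.signature_10 and len(self.signature_10) != 10:
            raise ValueError("signature_10 must have length 10")


Confidence = Literal["confident", "ambiguous", "none"]


@dataclass(frozen=True)
class SpecificityCall:
    """Per-domain substrate prediction with method, score and ties."""

    domain_id: str
    label: str
    method: Literal["signature-NN", "placement"]
    score: float  # identities /10 for NN; patristic distance for placement
    ties: tuple[str, ...]
    confidence: Confidence

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(t for t in self.ties if t != self.label)


@dataclass(frozen=True)
class SignatureTemplate:
    """Reference anchor for signature extraction.

    `positions_34` are 0-based columns in `anchor_sequence`; `positions_10`
    are strictly increasing 1-based indices into the 34.
    """

    anchor_sequence: str
    positions_34: tuple[int, ...]
    positions_10: tuple[int, ...]

    def __post_init__(self):
        if len(self.positions_34) != 34:
            raise ValueError("need exactly 34 template positions")
        if len(self.positions_10) != 10:
            raise ValueError("need exactly 10 diagnostic indices")
        if list(self.positions_10) != sorted(set(self.positions_10)):
            raise ValueError("diagnostic indices must be strictly increasing")
        if not all(1 <= i <= 34 for i in self.positions_10):
            raise ValueError("diagnostic indices must lie within 1..34")

    def own_signature(self) -> tuple[str, str]:
        s34 = "".join(self.anchor_sequence[c] for c in self.positions_34)
        s10 = "".join(s34[i - 1] for i in self.positions_10)
        return s34, s10


def default_signature_template(
    profiles: Profiles | None = None,
) -> SignatureTemplate:
    prof = profiles or default_profiles()
    cols34, idx10 = prof.signature_columns()
    return SignatureTemplate(
        prof.template("A"), tuple(cols34), tuple(idx10)
    )


class SignatureNotExtractable(ValueError):
    pass


def _global_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def extract_signature(
    a_domain_sequence: str,
    template: SignatureTemplate | None = None,
    min_coverage: float = 0.6,
) -> tuple[str, str]:
    """(signature_34, signature_10) of an A domain.

    The domain is globally aligned to the template anchor (BLOSUM62, affine
    gaps open 11 / extend 1); the query residues aligned to the 34 template
    columns are reported, '-' where the alignment places a gap.  If fewer
    than `min_coverage` of the template residues align to query residues the
    signature is declared not extractable.
    """
    if template is None:
        template = default_signature_template()
    if len(a_domain_sequence) < MIN_DOMAIN_LENGTH:
        raise ValueError(
            f"A-domain sequence too short ({len(a_domain_sequence)} aa; "
            f"need >= {MIN_DOMAIN_LENGTH})"
        )
    aligner = _global_aligner()
    aln = aligner.align(template.anchor_sequence, a_domain_sequence)[0]
    # template position -> query position (or None at gaps)
    mapping: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            mapping[t0 + off] = q0 + off
    coverage = len(mapping) / len(template.anchor_sequence)
    if coverage < min_coverage:
        raise SignatureNotExtractable(
            f"alignment covers only {coverage:.0%} of the template anchor "
            f"(< {min_coverage:.0%}); signature not extractable"
        )
    s34 = "".join(
        a_domain_sequence[mapping[c]] if c in mapping else "-"
        for c in template.positions_34
    )
    s10 = "".join(s34[i - 1] for i in template.positions_10)
    return s34, s10


# ---------------------------------------------------------------------------
# Nearest-neighbor signature calling


def call_substrate_nn(
    signature_10: str,
    references: Sequence[ReferenceDomain],
    domain_id: str = "query",
    floor: int = DEFAULT_NN_FLOOR,
) -> SpecificityCall:
    """Call the substrate as the panel label with most signature identities.

    Score is exact identities over the 10 positions; all labels co-optimal
    at the maximum are reported as ties in deterministic order (by the id of
    the first reference achieving the score for that label).  A maximum
    below `floor` yields confidence "none"; >1 tied label yields
    "ambiguous"; otherwise "confident".  Invariant to panel ordering.
    """
    refs = sorted(references, key=lambda r: r.id)
    if not refs:
        raise ValueError("reference panel is empty")
    for r in refs:
        if not r.signature_10:
            raise ValueError(f"reference {r.id!r} lacks signature_10")
    scores = [
        sum(a == b for a, b in zip(signature_10, r.signature_10))
        for r in refs
    ]
    best = max(scores)
    tied_labels: list[str] = []
    for r, s in zip(refs, scores):
        if s == best and r.label not in tied_labels:
            tied_labels.append(r.label)
    tied_labels.sort()
    label = tied_labels[0]
    if best < floor:
        conf: Confidence = "none"
    elif len(tied_labels) > 1:
        conf = "ambiguous"
    else:
        conf = "confident"
    return SpecificityCall(
        domain_id, label, "signature-NN", float(best), tuple(tied_labels), conf
    )


# ---------------------------------------------------------------------------
# Phylogenetic placement

_QUERY_LABEL = "@query"


def _placement(
    query_sequence: str,
    references: Sequence[ReferenceDomain],
    tree: phylo.PhyloTree | None,
    delta: float,
    domain_id: str,
    model: str = "p-distance",
) -> SpecificityCall:
    refs = sorted(references, key=lambda r: r.id)
    if len(refs) < 3:
        raise ValueError("placement needs >= 3 references")
    by_id = {r.id: r for r in refs}
    if tree is None:
        lens = {len(r.sequence) for r in refs} | {len(query_sequence)}
        if len(lens) != 1:
            raise ValueError(
                "query not alignable: placement without a tree requires the "
                "query and all references to be pre-aligned (equal length)"
            )
        aln = phylo.MultipleAlignment.from_pairs(
            [(_QUERY_LABEL, query_sequence)]
            + [(r.id, r.sequence) for r in refs]
        )
        d = phylo.pairwise_distances(aln, model=model)
        tree = phylo.nj_tree(d)
    pat = phylo.patristic_distances(tree)
    if _QUERY_LABEL not in pat.labels:
        raise ValueError("tree does not contain the query leaf")
    dists = sorted(
        (pat[_QUERY_LABEL, r.id], r.id) for r in refs if r.id in pat._index
    )
    if not dists:
        raise ValueError("tree contains none of the reference leaves")
    best_d, best_id = dists[0]
    label = by_id[best_id].label
    ties = [label]
    for dd, rid in dists[1:]:
        if dd - best_d <= delta and by_id[rid].label not in ties:
            ties.append(by_id[rid].label)
    conf: Confidence = "confident" if len(ties) == 1 else "ambiguous"
    return SpecificityCall(
        domain_id, label, "placement", float(best_d), tuple(sorted(ties)), conf
    )


def call_substrate_placement(
    a_domain_sequence: str,
    references: Sequence[ReferenceDomain],
    tree: phylo.PhyloTree | None = None,
    delta: float = DEFAULT_PLACEMENT_DELTA,
    domain_id: str = "query",
) -> SpecificityCall:
    """Call the substrate as the label of the patristically nearest reference.

    Without a pre-built tree the query is joined to the panel by NJ on
    p-distances (query and panel must be pre-aligned / equal length).  A tree
    built externally (e.g. imported from newick with the query as leaf
    ``@query``) can be supplied instead.
    """
    return _placement(a_domain_sequence, references, tree, delta, domain_id)


@dataclass(frozen=True)
class CDomainCall:
    """C-domain subtype call plus positional starter-candidate evidence."""

    domain_id: str
    subtype: str  # starter | dual | conventional
    score: float  # patristic distance to nearest reference
    starter_candidate: bool  # module-1 position
    confidence: Confidence
    ties: tuple[str, ...] = ()


def classify_c_domain(
    c_domain_sequence: str,
    references: Sequence[ReferenceDomain],
    position_in_line: int,
    delta: float = DEFAULT_PLACEMENT_DELTA,
    domain_id: str = "query",
) -> CDomainCall:
    """Type a condensation domain by placement against a labelled panel.

    The panel must contain all three classes (starter, dual C/E,
    conventional).  A module-1 domain is additionally annotated as starter
    candidate on positional grounds, independent of the sequence call.
    """
    if len(c_domain_sequence) < MIN_DOMAIN_LENGTH:
        raise ValueError(
            f"C-domain sequence too short ({len(c_domain_sequence)} aa)"
        )
    present = {r.label for r in references}
    missing = set(C_CLASSES) - present
    if missing:
        raise ValueError(f"C panel lacks classes: {sorted(missing)}")
    call = _placement(
        c_domain_sequence, references, None, delta, domain_id
    )
    return CDomainCall(
        domain_id=domain_id,
        subtype=call.label,
        score=call.score,
        starter_candidate=position_in_line == 1,
        confidence=call.confidence,
        ties=call.ties,
    )


@dataclass(frozen=True)
class TECall:
    """TE subtype call; an ordinal/sequence disagreement is flagged."""

    domain_id: str
    subtype: str  # TE1 | TE2
    ordinal_in_tandem: int  # 0 = first, 1 = second
    score: float
    confidence: Confidence
    ordinal_mismatch: bool = False


def classify_te(
    te_sequence: str,
    references: Sequence[ReferenceDomain],
    ordinal_in_tandem: int,
    delta: float = DEFAULT_PLACEMENT_DELTA,
    domain_id: str = "query",
) -> TECall:
    """Type a thioesterase domain (TE1 = release/cyclization, TE2 = editing).

    The ordinal position in the tandem (first/second) is reported alongside
    the sequence-based call; a disagreement between the two is flagged,
    never silently resolved.
    """
    present = {r.label for r in references}
    missing = set(TE_CLASSES) - present
    if missing:
        raise ValueError(f"TE panel lacks classes: {sorted(missing)}")
    call = _placement(te_sequence, references, None, delta, domain_id)
    expected = TE_CLASSES[ordinal_in_tandem] if ordinal_in_tandem in (0, 1) else None
    return TECall(
        domain_id=domain_id,
        subtype=call.label,
        ordinal_in_tandem=ordinal_in_tandem,
        score=call.score,
        confidence=call.confidence,
        ordinal_mismatch=expected is not None and call.label != expected,
    )


# ---------------------------------------------------------------------------
# Panel IO (FASTA + TSV)


def write_reference_panel(
    references: Sequence[ReferenceDomain], tsv_path, fasta_path
) -> None:
    import pandas as pd

    from .io import write_fasta
    from .annotation import ProteinRecord

    rows = [
        [r.id, r.kind, r.label, r.signature_34, r.signature_10]
        for r in references
    ]
    pd.DataFrame(
        rows, columns=["id", "kind", "label", "signature_34", "signature_10"]
    ).to_csv(tsv_path, sep="\t", index=False)
    write_fasta(
        [ProteinRecord(r.id, r.sequence) for r in references], fasta_path
    )


def read_reference_panel(tsv_path, fasta_path) -> list[ReferenceDomain]:
    import pandas as pd

    from .io import read_fasta

    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    df = pd.read_csv(sep="\t", filepath_or_buffer=tsv_path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        rid = str(row.id)
        if rid not in seqs:
            raise ValueError(f"panel TSV id {rid!r} missing from FASTA")
        out.append(
            ReferenceDomain(
                id=rid,
                kind=str(row.kind),
                label=str(row.label),
                sequence=seqs[rid],
                signature_34=str(row.signature_34),
                signature_10=str(row.signature_10),
            )
        )
    return out


def load_packaged_panel() -> list[ReferenceDomain]:
    """The packaged synthetic reference panel (A + C + TE domains).

    Synthetic: panel members are seeded mutants of the packaged consensus
    scaffolds, not natural sequences.
    """
    from importlib import resources
    import tempfile, pathlib

    base = resources.files("nrpslip").joinpath("data")
    with tempfile.TemporaryDirectory() as td:
        tsv = pathlib.Path(td) / "panel.tsv"
        fasta = pathlib.Path(td) / "panel.fasta"
        tsv.write_text(base.joinpath("synthetic_panel.tsv").read_text())
        fasta.write_text(base.joinpath("synthetic_panel.fasta").read_text())
        return read_reference_panel(tsv, fasta)
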