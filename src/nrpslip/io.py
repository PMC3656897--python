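"""File IO: FASTA, GenBank flat files, and pipeline configuration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .annotation import ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genbank_proteins",
    "PipelineConfig",
]


def read_fasta(path) -> list[ProteinRecord]:
    """Protein records from FASTA; duplicate ids and illegal characters are
    errors, lowercase input is uppercased with a warning."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(
                f"record {rec.id!r}: lowercase residues uppercased",
                stacklevel=2,
            )
            seq = seq.upper()
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_genbank_proteins(path) -> list[ProteinRecord]:
    """One record per CDS feature carrying a translation, in file order.

    The id is the locus_tag, else the gene name, else a positional CDS
    label; a CDS without a translation is skipped with a warning.
    """
    out: list[ProteinRecord] = []
    n = 0
    for gb in SeqIO.parse(str(path), "genbank"):
        for feat in gb.features:
            if feat.type != "CDS":
                continue
            n += 1
            q = feat.qualifiers
            name = (
                q.get("locus_tag", [None])[0]
                or q.get("gene", [None])[0]
                or f"CDS_{n}"
            )
            translations = q.get("translation", [])
            if not translations:
                warnings.warn(
                    f"CDS {name!r} has no translation; skipped", stacklevel=2
                )
                continue
            out.append(ProteinRecord(name, translations[0].upper().rstrip("*")))
    if not out:
        warnings.warn("no translated CDS features found", stacklevel=2)
    return out


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    `protein_order` fixes the biosynthetic order of the input proteins (gene
    order is user-supplied knowledge).  Empty panel paths fall back to the
    packaged synthetic panel.
    """

    proteins_fasta: str
    output_dir: str
    protein_order: tuple[str, ...] = ()
    panel_tsv: str = ""
    panel_fasta: str = ""
    tree_newick: str = ""  # optional imported A-domain tree
    fatty_acids: tuple[str, ...] = ("C10:0-3OH",)
    patristic_threshold: float = 0.45
    nn_floor: int = 6
    placement_delta: float = 0.05
    depsi_threshold_ppm: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for v, name in (
            (self.patristic_threshold, "patristic_threshold"),
            (self.placement_delta, "placement_delta"),
            (self.depsi_threshold_ppm, "depsi_threshold_ppm"),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def validate_paths(self) -> None:
        missing = [
            p for p in (
                self.proteins_fasta, self.panel_tsv, self.panel_fasta,
                self.tree_newick,
            )
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"configured input files do not exist: {missing}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("protein_order", "fatty_acids"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
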