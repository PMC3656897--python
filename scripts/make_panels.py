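"""Regenerate the packaged synthetic reference panel.

The shipped panel (src/nrpslip/data/synthetic_panel.{tsv,fasta}) is
synthetic: seeded mutants of the packaged consensus scaffolds, labelled with
the substrate classes relevant to Pseudomonas lipopeptide assembly lines,
plus the three condensation-domain classes and the two thioesterase classes.
Deterministic; rerun from the repository root after changing the profiles:

    python scripts/make_panels.py
"""

import pathlib

from nrpslip.classification import write_reference_panel
from nrpslip.simulate import make_reference_panel

SEED = 424247
A_LABELS = ["Leu", "Glu", "Gln", "Val", "Ser", "Ile", "Asp", "Thr"]

OUT = pathlib.Path(__file__).resolve().parents[1] / "src/nrpslip/data"


def main():
    panel = (
        make_reference_panel("A", A_LABELS, n_per_class=3, seed=SEED)
        + make_reference_panel(
            "C", ["starter", "dual", "conventional"], n_per_class=3,
            seed=SEED + 1,
        )
        + make_reference_panel("TE", ["TE1", "TE2"], n_per_class=3, seed=SEED + 2)
    )
    write_reference_panel(
        panel, OUT / "synthetic_panel.tsv", OUT / "synthetic_panel.fasta"
    )
    print(f"wrote {len(panel)} references to {OUT}")


if __name__ == "__main__":
    main()
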