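"""Regenerate the packaged domain profile set (src/nrpslip/data/profiles.json).

The templates are synthetic consensus scaffolds — random sequences with the
canonical NRPS core motifs embedded at fixed offsets — not copies of natural
domains.  Each template carries:

  * anchor columns used by the scanner (the motif columns plus a spread of
    conserved scaffold columns),
  * for C and TE: a subtype block (columns whose residues distinguish
    starter / dual C,E / conventional, and TE1 / TE2),
  * for A: the 34 active-site signature columns and the 10 diagnostic
    indices into them (Stachelhaus-style code).

Deterministic: rerunning this script reproduces the shipped file byte for
byte.  Run from the repository root:  python scripts/make_profiles.py
"""

import json
import pathlib

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
SEED = 733412  # fixed so the shipped file is reproducible

OUT = pathlib.Path(__file__).resolve().parents[1] / "src/nrpslip/data/profiles.json"


def rand_seq(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def plant(seq, motif, at):
    return seq[:at] + motif + seq[at + len(motif):]


def pick_cols(rng, length, want, exclude):
    pool = [c for c in range(length) if c not in exclude]
    cols = rng.choice(len(pool), size=want, replace=False)
    return sorted(pool[int(c)] for c in cols)


def main():
    rng = np.random.default_rng(SEED)
    domains = {}

    # --- C domain: 450 aa, HHxxxDG catalytic motif
    c_seq = rand_seq(rng, 450)
    c_motif_at = 130
    c_seq = plant(c_seq, "HHILVDG", c_motif_at)
    motif_cols = list(range(c_motif_at, c_motif_at + 7))
    subtype_cols = pick_cols(rng, 450, 40, set(motif_cols))
    extra = pick_cols(rng, 450, 33, set(motif_cols) | set(subtype_cols))
    domains["C"] = {
        "template": c_seq,
        "motifs": {"HHxxxDG": c_motif_at},
        "anchor_cols": sorted(motif_cols + extra),
        "subtype_cols": subtype_cols,
        "subtypes": {
            name: rand_seq(rng, 40) for name in ("starter", "dual", "conventional")
        },
    }

    # --- A domain: 500 aa, A3 and A8 cores, 34-col signature
    a_seq = rand_seq(rng, 500)
    a3_at, a8_at = 190, 420
    a_seq = plant(a_seq, "SGTTGNPKG", a3_at)
    a_seq = plant(a_seq, "GRIDNQVKIRG", a8_at)
    motif_cols = list(range(a3_at, a3_at + 9)) + list(range(a8_at, a8_at + 11))
    sig34 = pick_cols(rng, 180, 34, set())  # within [210, 390)
    sig34 = [c + 210 for c in sig34]
    extra = pick_cols(rng, 500, 20, set(motif_cols) | set(sig34))
    sig10_idx = sorted(
        int(i) + 1 for i in rng.choice(34, size=10, replace=False)
    )  # 1-based indices into the 34
    domains["A"] = {
        "template": a_seq,
        "motifs": {"A3_SGTTGxPK": a3_at, "A8_GRxDxQVKIRG": a8_at},
        "anchor_cols": sorted(motif_cols + extra),
        "signature34_cols": sig34,
        "signature10_idx": sig10_idx,
    }

    # --- T domain: 80 aa, (I/L)GGxS(L/I) with invariant Ser
    t_seq = rand_seq(rng, 80)
    t_motif_at = 35
    t_seq = plant(t_seq, "LGGHSLI", t_motif_at)
    motif_cols = list(range(t_motif_at, t_motif_at + 7))
    extra = pick_cols(rng, 80, 17, set(motif_cols))
    domains["T"] = {
        "template": t_seq,
        "motifs": {"xGGxSx": t_motif_at},
        "anchor_cols": sorted(motif_cols + extra),
    }

    # --- TE domain: 250 aa, GxSxG serine-hydrolase motif
    te_seq = rand_seq(rng, 250)
    te_motif_at = 80
    te_seq = plant(te_seq, "GYSQG", te_motif_at)
    motif_cols = list(range(te_motif_at, te_motif_at + 5))
    subtype_cols = pick_cols(rng, 250, 30, set(motif_cols))
    extra = pick_cols(rng, 250, 35, set(motif_cols) | set(subtype_cols))
    domains["TE"] = {
        "template": te_seq,
        "motifs": {"GxSxG": te_motif_at},
        "anchor_cols": sorted(motif_cols + extra),
        "subtype_cols": subtype_cols,
        "subtypes": {name: rand_seq(rng, 30) for name in ("TE1", "TE2")},
    }

    payload = {
        "scan": {"score_threshold": 0.6},
        "domains": domains,
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
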