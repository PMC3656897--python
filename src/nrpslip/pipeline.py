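"""The end-to-end pipeline: annotate -> classify -> predict -> chem-verify.

Writes a report bundle into the configured output directory:

* ``domains.tsv``    — detected domains (0-based half-open coordinates)
* ``calls.tsv`` / ``calls.json`` — substrate and subtype calls per module
* ``prediction.json`` — peptide, stereo, cyclization candidates, congeners
  with formulas and [M+H]+ masses
* ``summary.txt``    — human-readable summary (1-based coordinates)
* ``run.json``       — seed, thresholds and package version for provenance

Deterministic: rerunning with an identical configuration produces an
identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__, chem, classification, product
from .annotation import assemble_line, write_domain_table
from .io import PipelineConfig, read_fasta

log = logging.getLogger("nrpslip")

__all__ = ["run_pipeline"]


def _module_domain(line, module, which: str) -> str:
    return line.domain_sequence(module, which)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full inference chain; returns the report as a dict."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_fasta(config.proteins_fasta)
    if config.protein_order:
        by_id = {r.id: r for r in records}
        missing = [pid for pid in config.protein_order if pid not in by_id]
        if missing:
            raise ValueError(f"protein_order names unknown ids: {missing}")
        records = [by_id[pid] for pid in config.protein_order]

    if config.panel_tsv and config.panel_fasta:
        panel = classification.read_reference_panel(
            config.panel_tsv, config.panel_fasta
        )
    else:
        panel = classification.load_packaged_panel()
    a_refs = [r for r in panel if r.kind == "A"]
    c_refs = [r for r in panel if r.kind == "C"]
    te_refs = [r for r in panel if r.kind == "TE"]

    # --- annotate
    line = assemble_line(records)
    write_domain_table(
        outdir / "domains.tsv",
        {
            p.id: [
                h
                for m in line.modules if m.protein_id == p.id
                for h in m.domains
            ] + (list(line.te_hits) if p.id == line.proteins[-1].id else [])
            for p in line.proteins
        },
    )

    # --- classify
    calls = []
    c_calls = []
    for m in line.modules:
        a_seq = line.domain_sequence(m, "A")
        try:
            _, sig10 = classification.extract_signature(a_seq)
            call = classification.call_substrate_nn(
                sig10, a_refs, domain_id=f"A{m.index}", floor=config.nn_floor
            )
        except classification.SignatureNotExtractable:
            call = classification.call_substrate_placement(
                a_seq, a_refs, domain_id=f"A{m.index}",
                delta=config.placement_delta,
            )
        calls.append(call)
        c_calls.append(
            classification.classify_c_domain(
                line.domain_sequence(m, "C"), c_refs,
                position_in_line=m.index,
                delta=config.placement_delta, domain_id=f"C{m.index}",
            )
        )
    te_calls = [
        classification.classify_te(
            line.te_sequence(k), te_refs, ordinal_in_tandem=k,
            delta=config.placement_delta, domain_id=f"TE{k + 1}",
        )
        for k in range(len(line.te_hits))
    ]

    # --- predict
    c_subtypes = [c.subtype for c in c_calls]
    pred = product.predict_peptide(line, calls, c_subtypes=c_subtypes)
    donor = (
        pred.cyclization_candidates[0][0]
        if len(pred.cyclization_candidates) == 1
        else None
    )
    congeners = []
    if donor is not None or not pred.cyclization_candidates:
        try:
            congeners = product.enumerate_congeners(
                pred, config.fatty_acids, lactone_donor=donor,
            )
        except chem.UnresolvedGlx:
            log.warning("unresolved Glx in prediction; congener masses skipped")

    # --- write bundle
    import pandas as pd

    call_rows = [
        [c.domain_id, "A", c.label, c.method, c.score,
         ";".join(c.ties), c.confidence]
        for c in calls
    ] + [
        [c.domain_id, "C", c.subtype, "placement", c.score,
         ";".join(c.ties), c.confidence]
        for c in c_calls
    ] + [
        [t.domain_id, "TE", t.subtype, "placement", t.score, "",
         t.confidence]
        for t in te_calls
    ]
    pd.DataFrame(
        call_rows,
        columns=["domain_id", "kind", "label", "method", "score", "ties",
                 "confidence"],
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)

    report = {
        "coordinate_system": "0-based half-open",
        "n_proteins": len(line.proteins),
        "n_modules": line.n_modules,
        "te_tandem": line.te_tandem,
        "has_starter_c": line.has_starter_c,
        "diagnostics": list(line.diagnostics),
        "substrate_calls": [dataclasses.asdict(c) for c in calls],
        "c_domain_calls": [dataclasses.asdict(c) for c in c_calls],
        "te_calls": [dataclasses.asdict(t) for t in te_calls],
        "peptide": list(pred.sequence),
        "alternatives": [list(r.alternatives) for r in pred.residues],
        "stereo": list(pred.stereo),
        "stereo_caveat": pred.stereo_caveat,
        "cyclization_candidates": [
            {"donor": d, "ring_size": r}
            for d, r in pred.cyclization_candidates
        ],
        "congeners": [
            {
                "name": c.name,
                "formula": c.formula,
                "monoisotopic_mass": c.monoisotopic_mass,
                "mz_MH": c.mz_mh,
            }
            for c in congeners
        ],
    }
    with open(outdir / "calls.json", "w") as fh:
        json.dump(
            {"substrate_calls": report["substrate_calls"],
             "c_domain_calls": report["c_domain_calls"],
             "te_calls": report["te_calls"]},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    with open(outdir / "prediction.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": config.seed,
                "thresholds": {
                    "patristic": config.patristic_threshold,
                    "nn_floor": config.nn_floor,
                    "placement_delta": config.placement_delta,
                    "depsi_ppm": config.depsi_threshold_ppm,
                },
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")

    lines = [
        f"proteins: {len(line.proteins)}  modules: {line.n_modules}  "
        f"TE tandem: {line.te_tandem}",
        "peptide (1-based): " + "-".join(pred.sequence),
        "stereo:  " + " ".join(pred.stereo) + f"   [{pred.stereo_caveat}]",
        "cyclization candidates: "
        + (", ".join(
            f"donor {d} (ring {r})" for d, r in pred.cyclization_candidates
        ) or "none (linear product)"),
        f"congeners rendered: {len(congeners)}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    log.info("pipeline finished: %d modules, %d congeners",
             line.n_modules, len(congeners))
    return report
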