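"""End-to-end driver: simulate one line, emit files, run every analysis stage.

This is glue over the stage modules; it exists so the CLI, the tests and
the reproduction script exercise the same path, including the round trip
through the on-disk formats (VCF per caller per passage, force-call TSV,
growth TSV).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import clonality, consensus, io, pdtsim, sim, spectra
from .genome import SyntheticReference


def run_line(config: sim.CultureConfig, workdir, fixed_maf: float = 0.35,
             drift_maf: float = 0.02, gene_model: spectra.GeneModel | None = None,
             caller_a: sim.CallerModel = sim.DEFAULT_CALLER_A,
             caller_b: sim.CallerModel = sim.DEFAULT_CALLER_B) -> dict:
    """Simulate a culture line and run the SNV/indel + growth analyses.

    Returns a dict with the truth set, growth records, consensus MAF
    matrix, discovery labels, class summaries, clonality calls, per-class
    simulated PDT kinetics, spectra, and (when a gene model is given)
    location annotations with the intronic/intergenic enrichment test.
    """
    workdir = Path(workdir)
    truth, records = sim.simulate_culture(config)
    calls, forcecall = sim.emit_caller_outputs(truth, config, caller_a, caller_b)
    io.write_simulation(workdir, truth, calls=calls, forcecall=forcecall)

    obs = truth.observed_passages
    consensus_by_passage = {}
    for p in obs:
        read_a = io.read_vcf(workdir / f"{caller_a.name}_P{p}.vcf", p, caller_a.name)
        read_b = io.read_vcf(workdir / f"{caller_b.name}_P{p}.vcf", p, caller_b.name)
        consensus_by_passage[p] = consensus.intersect_callers(read_a, read_b)

    forcecall_rt = io.read_forcecall(workdir / "forcecall.tsv")
    matrix = consensus.build_maf_matrix(consensus_by_passage, forcecall_rt, obs)
    labels = consensus.assign_discovery_passage(matrix)
    summary = clonality.class_maf_summary(matrix)
    clonality_calls = clonality.classify_all(matrix, fixed_maf, drift_maf)

    growth_obs = [r for r in records if r.passage in obs]
    kinetics = pdtsim.class_kinetics(growth_obs, summary)

    snv_rows = [
        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
         "passage": int(labels[key].removeprefix("P"))}
        for key, v in matrix.variants.items()
        if v.is_snv
    ]
    snvs = pd.DataFrame(snv_rows, columns=["chrom", "pos", "ref", "alt", "passage"])
    spectrum = spectra.spectrum_fractions(snvs, passages=obs) if len(snvs) else None

    result = {
        "truth": truth,
        "records": records,
        "consensus": consensus_by_passage,
        "matrix": matrix,
        "labels": labels,
        "summary": summary,
        "clonality": clonality_calls,
        "kinetics": kinetics,
        "spectrum": spectrum,
        "annotation": None,
        "enrichment": None,
    }

    if gene_model is not None and len(snvs):
        reference = SyntheticReference(config.genome)
        annotated = spectra.annotate_variants(snvs, gene_model, reference)
        foot = spectra.genomic_footprints(gene_model, config.genome)
        n_i = int((annotated["location"] == "intronic").sum())
        n_g = int((annotated["location"] == "intergenic").sum())
        result["annotation"] = annotated
        if n_i + n_g:
            result["enrichment"] = spectra.intronic_intergenic_enrichment(
                n_i, n_g, foot["intronic"], foot["intergenic"]
            )
    return result
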