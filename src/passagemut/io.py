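"""Readers and writers for the pipeline's file formats.

VCF 4.2 is the interchange format for caller outputs (written with a
single sample carrying GT:AD:DP, read back through cyvcf2 with
multi-allelic records split).  Everything else is plain TSV/BED/JSON via
pandas and the standard library.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .genome import GenomeModel
from .growth import GrowthRecord

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=passagemut
{contigs}
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(path, calls, genome: GenomeModel, sample: str = "SAMPLE") -> None:
    """Write a list of VariantCall records as a single-sample VCF 4.2 file."""
    contigs = "\n".join(
        f"##contig=<ID={c},length={genome.chromosome_length}>" for c in genome.chromosomes
    )
    ordered = sorted(calls, key=lambda v: (genome.chrom_index(v.chrom), v.pos, v.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for v in ordered:
            ref_n = v.depth - v.alt_count
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t0/1:{ref_n},{v.alt_count}:{v.depth}\n"
            )


def read_vcf(path, passage: int, caller: str):
    """Read a single-sample VCF into VariantCall records.

    Multi-allelic records are split into one call per alternate allele,
    with that allele's AD; indel alleles are left-aligned/trimmed to their
    minimal representation on read.
    """
    from .consensus import VariantCall, normalize_variant

    out = []
    vcf = VCF(str(path))
    for record in vcf:
        depth = int(record.format("DP")[0][0]) if record.format("DP") is not None else 0
        ad = record.format("AD")
        for k, alt in enumerate(record.ALT):
            alt_count = int(ad[0][k + 1]) if ad is not None else 0
            chrom, pos, ref, alt_n = normalize_variant(record.CHROM, record.POS, record.REF, alt)
            out.append(VariantCall(chrom, pos, ref, alt_n, passage, caller, depth, alt_count))
    vcf.close()
    return out


def write_forcecall(path, forcecall: pd.DataFrame) -> None:
    forcecall.to_csv(path, sep="\t", index=False)


def read_forcecall(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def write_bins(path, bins: pd.DataFrame) -> None:
    bins.to_csv(path, sep="\t", index=False)


def read_bins(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_array_calls(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False, header=False)


def read_array_calls(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "direction"],
        dtype={"chrom": str, "direction": str},
    )


def write_growth(path, records: list[GrowthRecord]) -> None:
    pd.DataFrame(
        [(r.passage, r.seeded, r.harvested, r.hours) for r in records],
        columns=["passage", "seeded", "harvested", "hours"],
    ).to_csv(path, sep="\t", index=False)


def read_growth(path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        GrowthRecord(int(r.passage), float(r.seeded), float(r.harvested), float(r.hours))
        for r in df.itertuples()
    ]


def write_qpcr(path, wells: pd.DataFrame) -> None:
    wells.to_csv(path, sep="\t", index=False)


def read_qpcr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "amplicon": str})


def write_truth(path, truth) -> None:
    """Serialise a TruthSet to JSON (ground truth sidecar of a simulation)."""

    def mut_dict(m):
        d = dataclasses.asdict(m)
        d["fractions"] = {str(k): v for k, v in m.fractions.items()}
        return d

    payload = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(truth.config).items()
        },
        "mutations": [mut_dict(m) for m in truth.mutations],
        "cnas": [mut_dict(c) for c in truth.cnas],
        "records": [dataclasses.asdict(r) for r in truth.records],
        "telomere_mean": {str(k): v for k, v in truth.telomere_mean.items()},
        "senescent_fraction": {str(k): v for k, v in truth.senescent_fraction.items()},
        "senescence_onset": truth.senescence_onset,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path):
    from .sim import CnaEvent, CultureConfig, Mutation, TruthSet

    with open(path) as fh:
        payload = json.load(fh)
    cfg = dict(payload["config"])
    cfg["genome"] = GenomeModel(**cfg["genome"])
    cfg["observed_passages"] = tuple(cfg["observed_passages"])
    cfg["spectrum_early"] = tuple(cfg["spectrum_early"])
    cfg["spectrum_late"] = tuple(cfg["spectrum_late"])
    config = CultureConfig(**cfg)

    def fr(d):
        return {int(k): v for k, v in d.items()}

    mutations = [
        Mutation(
            m["mutation_id"], m["chrom"], m["pos"], m["ref"], m["alt"], m["vtype"],
            m["substitution_class"], m["origin_passage"], fr(m["fractions"]),
        )
        for m in payload["mutations"]
    ]
    cnas = [
        CnaEvent(
            c["cna_id"], c["chrom"], c["start"], c["end"], c["delta_copy"],
            c["origin_passage"], fr(c["fractions"]),
        )
        for c in payload["cnas"]
    ]
    records = [GrowthRecord(**r) for r in payload["records"]]
    return TruthSet(
        config=config,
        mutations=mutations,
        cnas=cnas,
        records=records,
        telomere_mean=fr(payload["telomere_mean"]),
        senescent_fraction=fr(payload["senescent_fraction"]),
        senescence_onset=payload["senescence_onset"],
    )


def read_variant_list(path) -> pd.DataFrame:
    """Read an externally supplied somatic-variant list (TSV).

    Expected columns: ``line`` (sample/line identifier), ``passage``
    (integer passage at which the variant was called), ``chrom``, ``pos``,
    ``ref``, ``alt``; an optional ``location`` column carries a functional
    category.  Used to feed published per-passage call lists through the
    discovery-assignment and counting stages when such a table is
    available; no such table ships with the package.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"line", "passage", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant list missing columns {sorted(missing)}")
    return df


def write_simulation(outdir, truth, calls=None, forcecall=None, depth_tables=None,
                     array_calls=None, qpcr=None) -> dict:
    """Write every emitted observation of one simulated line to ``outdir``.

    Returns a manifest mapping logical names to paths.  Any emission left
    as None is skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    write_growth(outdir / "growth.tsv", truth.records)
    manifest["growth"] = str(outdir / "growth.tsv")
    write_truth(outdir / "truth.json", truth)
    manifest["truth"] = str(outdir / "truth.json")

    if calls is not None:
        for caller, per_passage in calls.items():
            for p, call_list in per_passage.items():
                path = outdir / f"{caller}_P{p}.vcf"
                write_vcf(path, call_list, truth.genome, sample=f"MSC_P{p}")
                manifest[f"{caller}_P{p}"] = str(path)
    if forcecall is not None:
        write_forcecall(outdir / "forcecall.tsv", forcecall)
        manifest["forcecall"] = str(outdir / "forcecall.tsv")
    if depth_tables is not None:
        for p, bins in depth_tables.items():
            path = outdir / f"bins_P{p}.tsv"
            write_bins(path, bins)
            manifest[f"bins_P{p}"] = str(path)
    if array_calls is not None:
        for p, ac in array_calls.items():
            path = outdir / f"array_calls_P{p}.bed"
            write_array_calls(path, ac)
            manifest[f"array_P{p}"] = str(path)
    if qpcr is not None:
        write_qpcr(outdir / "qpcr.tsv", qpcr)
        manifest["qpcr"] = str(outdir / "qpcr.tsv")
    return manifest
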