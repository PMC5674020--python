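"""Substitution spectra and genomic-location annotation of variants.

SNVs are collapsed onto the six pyrimidine-reference substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G; a G>T on the sequenced strand is the same
event as C>A on the opposite strand).  Variant positions are annotated
against a gene model with a fixed precedence order and intronic versus
intergenic enrichment is tested with an exact binomial test against the
genomic footprint of the two categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .genome import COMPLEMENT, GenomeModel, SyntheticReference, revcomp
from .sim import SUBSTITUTION_CLASSES

LOCATION_CATEGORIES = (
    "exonic-missense",
    "exonic-silent",
    "exonic-nonsense",
    "splicing",
    "UTR",
    "intronic",
    "TSS-proximal",
    "ncRNA",
    "intergenic",
)
_PRECEDENCE = {c: i for i, c in enumerate(LOCATION_CATEGORIES)}


def substitution_class(ref: str, alt: str) -> str:
    """Six-class substitution label with purine references complemented."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"substitution must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_fractions(snvs: pd.DataFrame, passages=None) -> pd.DataFrame:
    """Per-passage six-class spectrum fractions.

    ``snvs`` needs columns ``passage``, ``ref``, ``alt``.  Each row of the
    result sums to 1; a requested passage with no SNVs is omitted with a
    warning.
    """
    classes = snvs.apply(lambda r: substitution_class(r["ref"], r["alt"]), axis=1)
    table = (
        pd.crosstab(snvs["passage"], classes)
        .reindex(columns=SUBSTITUTION_CLASSES, fill_value=0)
        .astype(float)
    )
    if passages is not None:
        missing = [p for p in passages if p not in table.index]
        for p in missing:
            warnings.warn(f"no SNVs at passage {p}; omitted from spectrum", stacklevel=2)
        table = table.reindex([p for p in passages if p in table.index])
    return table.div(table.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# gene model


@dataclass(frozen=True)
class Gene:
    """One transcript: span, exon blocks, CDS blocks, strand, TSS.

    Intervals are 0-based half-open genomic coordinates with exons (and
    CDS blocks) sorted and non-overlapping; the CDS is contained in the
    exons and its total length is a multiple of three for coding genes.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev = self.tx_start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.tx_end:
                raise ValueError(f"gene {self.name}: exons must be sorted, disjoint, in span")
            prev = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"gene {self.name}: CDS block outside exons")
        if self.cds and self.cds_length % 3:
            raise ValueError(f"gene {self.name}: CDS length not a multiple of 3")

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Transcription start (0-based position of the first transcribed base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class GeneModel:
    """A collection of non-overlapping-per-locus genes with lookup helpers."""

    def __init__(self, genes):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.tx_start)

    def __len__(self):
        return len(self.genes)

    def overlapping(self, chrom: str, pos0: int, pad: int = 0):
        """Genes whose [tx_start-pad, tx_end+pad) contains 0-based ``pos0``."""
        return [
            g
            for g in self._by_chrom.get(chrom, [])
            if g.tx_start - pad <= pos0 < g.tx_end + pad
        ]


def read_bed12(path) -> GeneModel:
    """Load a gene model from BED12 (blocks = exons, thick = CDS)."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom": str, "name": str})
    genes = []
    for r in df.itertuples():
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        exons = tuple((r.start + o, r.start + o + s) for o, s in zip(offsets, sizes))
        cds = []
        if r.thick_end > r.thick_start:
            for s, e in exons:
                cs, ce = max(s, r.thick_start), min(e, r.thick_end)
                if ce > cs:
                    cds.append((cs, ce))
        genes.append(
            Gene(str(r.name), str(r.chrom), str(r.strand), int(r.start), int(r.end),
                 exons, tuple(cds))
        )
    return GeneModel(genes)


def write_bed12(path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        for g in model.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            thick_s = min((s for s, _ in g.cds), default=g.tx_start)
            thick_e = max((e for _, e in g.cds), default=g.tx_start)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.name}\t0\t{g.strand}\t"
                f"{thick_s}\t{thick_e}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def random_gene_model(genome: GenomeModel, n_genes: int = 200, rng=None,
                      coding_fraction: float = 0.9) -> GeneModel:
    """Synthetic gene model: non-overlapping multi-exon genes on a grid.

    Used by tests and the end-to-end pipeline in place of a real
    annotation; gene sizes and exon counts are in the range of compact
    human protein-coding genes.
    """
    rng = np.random.default_rng(rng)
    per_chrom = max(1, n_genes // genome.n_chromosomes)
    slot = genome.chromosome_length // per_chrom
    genes = []
    for chrom in genome.chromosomes:
        for i in range(per_chrom):
            length = int(rng.integers(20_000, min(120_000, slot - 2_000)))
            start = i * slot + int(rng.integers(1_000, slot - length - 1_000))
            end = start + length
            n_exons = int(rng.integers(2, 9))
            cuts = np.sort(rng.choice(np.arange(1, length // 500), size=2 * n_exons, replace=False))
            blocks = [(start + 500 * a, start + 500 * b) for a, b in zip(cuts[::2], cuts[1::2])]
            blocks[0] = (start, blocks[0][1])
            blocks[-1] = (blocks[-1][0], end)
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() < coding_fraction
            cds = ()
            if coding:
                # trim whole-codon CDS from interior exon space, leaving UTRs
                exonic = sum(e - s for s, e in blocks)
                utr5 = min(200, (blocks[0][1] - blocks[0][0]) // 2)
                utr3 = min(200, (blocks[-1][1] - blocks[-1][0]) // 2)
                cds_blocks = _clip_blocks(blocks, blocks[0][0] + utr5, blocks[-1][1] - utr3)
                trim = sum(e - s for s, e in cds_blocks) % 3
                while trim and cds_blocks:
                    s, e = cds_blocks[-1]
                    take = min(trim, e - s)
                    cds_blocks[-1] = (s, e - take)
                    if cds_blocks[-1][1] <= cds_blocks[-1][0]:
                        cds_blocks.pop()
                    trim -= take
                cds = tuple(cds_blocks)
                if sum(e - s for s, e in cds) < 3 or exonic < 600:
                    cds = ()
            genes.append(Gene(f"{chrom}_g{i}", chrom, strand, start, end, tuple(blocks), cds))
    return GeneModel(genes)


def _clip_blocks(blocks, lo, hi):
    out = []
    for s, e in blocks:
        cs, ce = max(s, lo), min(e, hi)
        if ce > cs:
            out.append((cs, ce))
    return out


# ---------------------------------------------------------------------------
# annotation


def _coding_category(gene: Gene, pos0: int, alt: str, reference: SyntheticReference) -> str:
    """missense/silent/nonsense by comparing the reference and mutated codon."""
    cds_pos = 0
    hit = None
    for s, e in gene.cds:
        if s <= pos0 < e:
            hit = cds_pos + (pos0 - s)
        cds_pos += e - s
    assert hit is not None
    cds_seq = "".join(reference.fetch(gene.chrom, s, e) for s, e in gene.cds)
    mutated = cds_seq[:hit] + alt.upper() + cds_seq[hit + 1:]
    if gene.strand == "-":
        cds_seq, mutated = revcomp(cds_seq), revcomp(mutated)
        hit = len(cds_seq) - 1 - hit
    codon_i = hit // 3
    ref_aa = str(Seq(cds_seq[3 * codon_i: 3 * codon_i + 3]).translate())
    alt_aa = str(Seq(mutated[3 * codon_i: 3 * codon_i + 3]).translate())
    if alt_aa == ref_aa:
        return "exonic-silent"
    if alt_aa == "*":
        return "exonic-nonsense"
    return "exonic-missense"


def annotate_location(chrom: str, pos: int, ref: str, alt: str, model: GeneModel,
                      reference: SyntheticReference, tss_window: int = 1000,
                      splice_window: int = 2) -> str:
    """Single location category for a variant (1-based ``pos``).

    Precedence: exonic CDS (missense/silent/nonsense) > splicing > UTR >
    intronic > TSS-proximal > ncRNA > intergenic.  Intronic candidates
    come from coding genes; any position inside a non-coding transcript
    contributes an ncRNA candidate.  Raises if the position is off the
    genome model.
    """
    if not reference.genome.contains(chrom, pos):
        raise ValueError(f"variant {chrom}:{pos} off the genome model")
    if tss_window < 0 or splice_window < 0:
        raise ValueError("windows must be >= 0")
    pos0 = pos - 1
    candidates = []
    for gene in model.overlapping(chrom, pos0, pad=tss_window):
        in_span = gene.tx_start <= pos0 < gene.tx_end
        if in_span and gene.coding:
            if any(s <= pos0 < e for s, e in gene.cds):
                if len(ref) == 1 and len(alt) == 1:
                    candidates.append(_coding_category(gene, pos0, alt, reference))
                else:
                    candidates.append("exonic-missense")  # coding indel: nonsilent
            elif _near_splice(gene, pos0, splice_window):
                candidates.append("splicing")
            elif any(s <= pos0 < e for s, e in gene.exons):
                candidates.append("UTR")
            else:
                candidates.append("intronic")
        elif in_span and not gene.coding:
            candidates.append("ncRNA")
        if abs(pos0 - gene.tss) <= tss_window:
            candidates.append("TSS-proximal")
    if not candidates:
        return "intergenic"
    return min(candidates, key=_PRECEDENCE.__getitem__)


def _near_splice(gene: Gene, pos0: int, window: int) -> bool:
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 <= pos0 < min(e1 + window, s2) or max(s2 - window, e1) <= pos0 < s2:
            return True
    return False


def annotate_variants(variants: pd.DataFrame, model: GeneModel,
                      reference: SyntheticReference, tss_window: int = 1000,
                      splice_window: int = 2) -> pd.DataFrame:
    """Add ``location`` (and ``substitution_class`` for SNVs) columns."""
    out = variants.copy()
    out["location"] = [
        annotate_location(r.chrom, r.pos, r.ref, r.alt, model, reference, tss_window, splice_window)
        for r in variants.itertuples()
    ]
    out["substitution_class"] = [
        substitution_class(r.ref, r.alt) if len(r.ref) == 1 == len(r.alt) else None
        for r in variants.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    ratio: float
    p_value: float


def intronic_intergenic_enrichment(n_intronic: int, n_intergenic: int,
                                   footprint_intronic: float,
                                   footprint_intergenic: float) -> EnrichmentResult:
    """Footprint-normalised intronic/intergenic density ratio + exact test.

    ratio = (n_i/f_i)/(n_g/f_g); the p-value is a two-sided exact binomial
    test of n_i successes in n_i+n_g trials at p = f_i/(f_i+f_g), i.e. the
    null that mutations fall on the two compartments in proportion to
    their genomic footprints.
    """
    if footprint_intronic <= 0 or footprint_intergenic <= 0:
        raise ValueError("genomic footprints must be positive")
    n = n_intronic + n_intergenic
    if n <= 0:
        raise ValueError("no intronic or intergenic variants supplied")
    p0 = footprint_intronic / (footprint_intronic + footprint_intergenic)
    if n_intergenic == 0:
        ratio = float("inf")
    else:
        ratio = (n_intronic / footprint_intronic) / (n_intergenic / footprint_intergenic)
    test = stats.binomtest(n_intronic, n, p0, alternative="two-sided")
    return EnrichmentResult(ratio=ratio, p_value=float(test.pvalue))


def genomic_footprints(model: GeneModel, genome: GenomeModel) -> dict[str, float]:
    """Genome fractions of the exonic/intronic/genic/intergenic compartments."""
    genic = 0
    exonic = 0
    intronic = 0
    for chrom in genome.chromosomes:
        chrom_genes = model._by_chrom.get(chrom, [])
        spans = _merge([(g.tx_start, g.tx_end) for g in chrom_genes])
        exon_spans = _merge([blk for g in chrom_genes for blk in g.exons])
        g_bp = sum(e - s for s, e in spans)
        e_bp = sum(e - s for s, e in exon_spans)
        genic += g_bp
        exonic += e_bp
        intronic += g_bp - e_bp
    size = genome.size
    return {
        "genic": genic / size,
        "exonic": exonic / size,
        "intronic": intronic / size,
        "intergenic": (size - genic) / size,
    }


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
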