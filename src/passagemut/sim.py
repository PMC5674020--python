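"""Serial-passage clonal-evolution simulator for cultured stromal cells.

The generator emulates the dynamics of an MSC-like culture observed at odd
passages (P1, P3, ..., P9) at moderate sequencing depth: a fixed number of
cells is reseeded each passage (a population bottleneck), clones expand by
discrete doubling steps until a target harvest size, each clone carries a
finite telomere budget and stops dividing once it is exhausted, and new
point mutations arise during growth at a configurable per-cell-division
rate.  A late-passage mutational burst (rate multiplier plus a shifted,
C>A-heavy substitution spectrum) and a single-passage copy-number burst
reproduce the qualitative features the analysis stages are built to
detect.

The population is tracked at clone resolution, not cell resolution.  A new
mutation is assigned to a clone chosen with probability proportional to
its dividing cell count and is carried by the whole clone from then on;
subclonality arises from the spread of clone sizes (Dirichlet founder
fractions, bottleneck resampling, and per-clone senescence), not from
splitting clones at mutation events.  This keeps the simulation exact and
fast at realistic cell counts while producing the observed mixture of
low-frequency drifting mutations and late clonally fixed ones.

Everything downstream consumes only the emitted observations (VCFs,
force-call table, binned depths, array calls, growth and qPCR tables);
the ``TruthSet`` retains the generating ground truth for parameter
recovery checks.  All emissions are deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import COMPLEMENT, GenomeModel, SyntheticReference
from .growth import GrowthRecord

PassageRecord = GrowthRecord

#: Pyrimidine-reference substitution classes, canonical order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# alt base for each class when the reference shows the pyrimidine strand
_PYRIMIDINE_ALT = {"C>A": "A", "C>G": "G", "C>T": "T", "T>A": "A", "T>C": "C", "T>G": "G"}


def _u32(seed: int) -> int:
    return int(seed) % (2**32)


@dataclass(frozen=True)
class CultureConfig:
    """Parameters of one simulated culture line.

    Defaults describe the study conditions: 1e5 cells reseeded per passage,
    nine passages observed at the odd ones, ~30x mean depth, a P9 burst of
    C>A-shifted mutations, and telomere budgets that exhaust around P7-P9
    so the doubling time blows up late and a single long-telomere lineage
    comes to dominate the final passage.
    """

    n_passages: int = 9
    observed_passages: tuple[int, ...] = (1, 3, 5, 7, 9)
    seed_count: int = 100_000
    initial_population: int | None = None
    target_fold: float = 16.0
    max_steps_per_passage: int = 14

    n_founders: int = 12
    founder_alpha: float = 1.0
    founder_snv_mean: float = 3.0

    per_division_snv_rate: float = 2e-5
    per_division_indel_rate: float = 4e-6
    spectrum_early: tuple[float, ...] = (0.10, 0.10, 0.40, 0.05, 0.25, 0.10)
    spectrum_late: tuple[float, ...] = (0.60, 0.08, 0.12, 0.05, 0.10, 0.05)
    burst_passage: int = 9
    burst_factor: float = 20.0
    escape_bonus_divisions: float = 16.0

    cna_burst_passage: int | None = None
    cna_burst_segments: int = 29
    cna_burst_fraction: float = 0.6

    telomere_init: float = 32.0
    telomere_sd: float = 3.0
    telomere_loss_per_division: float = 1.0
    senescence_threshold: float = 0.0
    senescent_loss_rate: float = 0.15

    base_doubling_hours: float = 30.0
    doubling_slowdown_cap: float = 5.0

    mean_depth: float = 30.0
    seq_error_rate: float = 1e-3

    genome: GenomeModel = field(default_factory=GenomeModel)
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("spectrum_early", "spectrum_late"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (6,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a non-negative 6-vector summing to 1")
        if self.seed_count < 1:
            raise ValueError("seed_count must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.initial_population is not None and self.seed_count > self.initial_population:
            raise ValueError("seed_count exceeds initial population")
        if self.n_founders < 1:
            raise ValueError("need at least one founder clone")
        if not set(self.observed_passages) <= set(range(1, self.n_passages + 1)):
            raise ValueError("observed_passages must lie within 1..n_passages")


@dataclass
class CloneState:
    """One subpopulation: mutation/CNA content, size, and telomere budget."""

    clone_id: int
    mutation_ids: set[int]
    cell_count: int
    telomere_length: float
    cna_ids: set[int] = field(default_factory=set)


@dataclass(frozen=True)
class Mutation:
    mutation_id: int
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # "SNV" | "indel"
    substitution_class: str | None
    origin_passage: int
    fractions: dict[int, float]  # passage -> true cell fraction at harvest

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CnaEvent:
    cna_id: int
    chrom: str
    start: int  # 0-based half-open
    end: int
    delta_copy: int  # +1 gain, -1 loss
    origin_passage: int
    fractions: dict[int, float]

    @property
    def direction(self) -> str:
        return "gain" if self.delta_copy > 0 else "loss"


@dataclass
class TruthSet:
    """Ground truth of one simulated line, for parameter-recovery checks."""

    config: CultureConfig
    mutations: list[Mutation]
    cnas: list[CnaEvent]
    records: list[PassageRecord]
    telomere_mean: dict[int, float]
    senescent_fraction: dict[int, float]
    senescence_onset: int | None

    @property
    def genome(self) -> GenomeModel:
        return self.config.genome

    @property
    def observed_passages(self) -> tuple[int, ...]:
        """Observed passages actually reached before extinction."""
        last = self.records[-1].passage if self.records else 0
        return tuple(p for p in self.config.observed_passages if p <= last)

    def fraction_matrix(self) -> tuple[list[Mutation], np.ndarray]:
        """(mutations, n_mut x n_observed true cell fractions)."""
        obs = self.observed_passages
        mat = np.zeros((len(self.mutations), len(obs)))
        for i, m in enumerate(self.mutations):
            for j, p in enumerate(obs):
                mat[i, j] = m.fractions.get(p, 0.0)
        return list(self.mutations), mat

    def late_origin_fraction(self, late_passages, min_peak_fraction: float = 0.0) -> float:
        """Fraction of true mutations originating in ``late_passages``.

        ``min_peak_fraction`` restricts the denominator to mutations whose
        cell fraction reaches that level at some observed passage, i.e. to
        the mutations a sequencing assay could see at all.
        """
        late = set(late_passages)
        eligible = [
            m
            for m in self.mutations
            if max((m.fractions.get(p, 0.0) for p in self.observed_passages), default=0.0)
            >= min_peak_fraction
        ]
        if not eligible:
            raise ValueError("no eligible mutations in truth set")
        n_late = sum(m.origin_passage in late for m in eligible)
        return n_late / len(eligible)


def msc_line_preset(line: int) -> CultureConfig:
    """Configurations emulating the two cultured lines.

    Line 1: single late burst at P9, no CNA burst.  Line 2: an earlier
    senescence wall (shorter founder budgets) with a long-lived escape
    lineage, so the mutational burst starts at P7 and those mutations fix
    over the remaining passages; plus a 29-segment CNA burst at P3.
    """
    if line == 1:
        return CultureConfig(rng_seed=1)
    if line == 2:
        return CultureConfig(
            rng_seed=2,
            telomere_init=24.0,
            burst_passage=7,
            burst_factor=12.0,
            escape_bonus_divisions=28.0,
            cna_burst_passage=3,
        )
    raise ValueError("line must be 1 or 2")


# ---------------------------------------------------------------------------
# culture simulation


def _draw_snv(rng, reference, genome, spectrum, used, origin_passage, mut_id) -> Mutation:
    cls = SUBSTITUTION_CLASSES[rng.choice(6, p=spectrum)]
    pyr = cls[0]  # 'C' or 'T'
    want = {pyr, COMPLEMENT[pyr]}
    while True:
        (chrom, pos) = genome.random_sites(rng, 1)[0]
        if (chrom, pos) in used:
            continue
        ref = reference.base(chrom, pos)
        if ref in want:
            break
    alt = _PYRIMIDINE_ALT[cls]
    if ref != pyr:  # purine-strand site: report the complementary change
        alt = COMPLEMENT[alt]
    used.add((chrom, pos))
    return Mutation(mut_id, chrom, pos, ref, alt, "SNV", cls, origin_passage, {})


def _draw_indel(rng, reference, genome, used, origin_passage, mut_id) -> Mutation:
    while True:
        (chrom, pos) = genome.random_sites(rng, 1)[0]
        if (chrom, pos) in used or pos + 4 > genome.chromosome_length:
            continue
        break
    used.add((chrom, pos))
    anchor = reference.base(chrom, pos)
    length = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        ref, alt = anchor, anchor + ins
    else:  # deletion
        ref = anchor + reference.fetch(chrom, pos, pos + length)
        alt = anchor
    return Mutation(mut_id, chrom, pos, ref, alt, "indel", None, origin_passage, {})


def _nonoverlapping_spans(rng, genome, n, min_len=300_000, max_len=3_000_000,
                          min_gap=500_000):
    """Scattered genomic spans, separated by at least ``min_gap`` on a chromosome."""
    spans: list[tuple[str, int, int]] = []
    attempts = 0
    while len(spans) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place non-overlapping CNA spans")
        chrom = genome.chromosomes[rng.integers(0, genome.n_chromosomes)]
        length = int(rng.uniform(min_len, max_len))
        if length >= genome.chromosome_length:
            continue
        start = int(rng.integers(0, genome.chromosome_length - length))
        end = start + length
        if any(c == chrom and s - min_gap < end and start < e + min_gap for c, s, e in spans):
            continue
        spans.append((chrom, start, end))
    return spans


def simulate_culture(config: CultureConfig) -> tuple[TruthSet, list[PassageRecord]]:
    """Run one culture line and return its ground truth and growth records.

    Extinction (all clones senescent at the start of a passage) truncates
    the passage list rather than raising.
    """
    rng = np.random.default_rng([_u32(config.rng_seed), 0])
    genome = config.genome
    reference = SyntheticReference(genome)

    founder_fracs = rng.dirichlet(np.full(config.n_founders, config.founder_alpha))
    counts = rng.multinomial(config.seed_count, founder_fracs)
    telomeres = np.clip(
        rng.normal(config.telomere_init, config.telomere_sd, size=config.n_founders), 0.0, None
    )
    clones = [
        CloneState(i, set(), int(counts[i]), float(telomeres[i])) for i in range(config.n_founders)
    ]

    mutations: list[Mutation] = []
    cnas: list[CnaEvent] = []
    frac_acc: dict[int, dict[int, float]] = {}
    cna_frac_acc: dict[int, dict[int, float]] = {}
    used_sites: set[tuple[str, int]] = set()

    # pre-culture mutations carried by the founder clones (discovered at P1)
    for clone in clones:
        k = rng.poisson(config.founder_snv_mean)
        for _ in range(k):
            m = _draw_snv(
                rng, reference, genome, np.asarray(config.spectrum_early), used_sites, 0, len(mutations)
            )
            mutations.append(m)
            frac_acc[m.mutation_id] = {}
            clone.mutation_ids.add(m.mutation_id)

    records: list[PassageRecord] = []
    telomere_mean: dict[int, float] = {}
    senescent_fraction: dict[int, float] = {}
    onset: int | None = None
    next_clone_id = config.n_founders

    for p in range(1, config.n_passages + 1):
        if p > 1:
            total = sum(c.cell_count for c in clones)
            probs = np.array([c.cell_count / total for c in clones])
            reseeded = rng.multinomial(config.seed_count, probs)
            for c, n in zip(clones, reseeded):
                c.cell_count = int(n)
            clones = [c for c in clones if c.cell_count > 0]

        # The burst process (elevated rate, shifted spectrum) switches on with
        # the escape lineage one passage before the burst is observable, so a
        # burst "at P9" covers the unobserved P8-P9 interval it is discovered in.
        burst = p >= config.burst_passage - 1
        snv_rate = config.per_division_snv_rate * (config.burst_factor if burst else 1.0)
        indel_rate = config.per_division_indel_rate * (config.burst_factor if burst else 1.0)
        spectrum = np.asarray(config.spectrum_late if burst else config.spectrum_early)

        # The burst lineage escapes/delays replicative senescence: one clone,
        # chosen in proportion to its dividing cells, gains division budget
        # one passage ahead of the burst, so by the burst passage it is the
        # lineage still expanding while the rest of the culture senesces.
        if p == max(1, config.burst_passage - 1) and config.escape_bonus_divisions > 0:
            alive = [
                c for c in clones
                if c.telomere_length > config.senescence_threshold and c.cell_count > 0
            ]
            if alive:
                w = np.array([c.cell_count for c in alive], dtype=float)
                chosen = alive[int(rng.choice(len(alive), p=w / w.sum()))]
                chosen.telomere_length += config.escape_bonus_divisions

        target = config.seed_count * config.target_fold
        total = sum(c.cell_count for c in clones)
        hours = 0.0
        grew = False

        for _ in range(config.max_steps_per_passage):
            dividing = [
                c
                for c in clones
                if c.telomere_length > config.senescence_threshold and c.cell_count > 0
            ]
            if not dividing or total >= target:
                break
            grew = True
            div_cells = sum(c.cell_count for c in dividing)
            # contact inhibition: the dish holds `target` cells, so the final
            # doubling is partial — only the capacity's worth of cells divide
            q = min(1.0, (target - total) / div_cells)
            sen_frac = 1.0 - div_cells / total
            hours += q * config.base_doubling_hours * min(
                config.doubling_slowdown_cap, 1.0 / max(1e-9, 1.0 - sen_frac)
            )
            weights = np.array([c.cell_count for c in dividing], dtype=float) / div_cells
            n_snv = rng.poisson(snv_rate * div_cells * q)
            n_indel = rng.poisson(indel_rate * div_cells * q)
            if n_snv + n_indel:
                owners = rng.choice(len(dividing), size=n_snv + n_indel, p=weights)
                for k, owner in enumerate(owners):
                    if k < n_snv:
                        m = _draw_snv(rng, reference, genome, spectrum, used_sites, p, len(mutations))
                    else:
                        m = _draw_indel(rng, reference, genome, used_sites, p, len(mutations))
                    mutations.append(m)
                    frac_acc[m.mutation_id] = {}
                    dividing[owner].mutation_ids.add(m.mutation_id)
            dividing_ids = {id(c) for c in dividing}
            for c in clones:
                if id(c) in dividing_ids:
                    c.cell_count += int(round(q * c.cell_count))
                    c.telomere_length -= q * config.telomere_loss_per_division
                elif config.senescent_loss_rate > 0:
                    # senescent cells progressively detach and are lost
                    c.cell_count = int(round(c.cell_count * (1.0 - config.senescent_loss_rate)))
            total = sum(c.cell_count for c in clones)

        if not grew:
            break  # extinction: every clone senescent before any doubling

        # single-passage CNA burst: implant a subclone carrying many segments
        if config.cna_burst_passage == p:
            parent = max(clones, key=lambda c: c.cell_count)
            child_cells = int(round(config.cna_burst_fraction * total))
            scale = 1.0 - config.cna_burst_fraction
            for c in clones:
                c.cell_count = int(round(c.cell_count * scale))
            child = CloneState(
                next_clone_id,
                set(parent.mutation_ids),
                max(1, total - sum(c.cell_count for c in clones)),
                config.senescence_threshold,  # senescent from here on: it decays
            )
            next_clone_id += 1
            spans = _nonoverlapping_spans(rng, genome, config.cna_burst_segments)
            for (chrom, start, end) in spans:
                delta = 1 if rng.random() < 0.35 else -1
                cna = CnaEvent(len(cnas), chrom, start, end, delta, p, {})
                cnas.append(cna)
                cna_frac_acc[cna.cna_id] = {}
                child.cna_ids.add(cna.cna_id)
            clones.append(child)
            total = sum(c.cell_count for c in clones)
            if child_cells and abs(child.cell_count - child_cells) > child_cells:
                raise RuntimeError("CNA burst bookkeeping failed")

        records.append(PassageRecord(p, float(config.seed_count), float(total), hours))
        telomere_mean[p] = sum(c.cell_count * c.telomere_length for c in clones) / total
        sen_cells = sum(
            c.cell_count for c in clones if c.telomere_length <= config.senescence_threshold
        )
        senescent_fraction[p] = sen_cells / total
        if onset is None and senescent_fraction[p] > 0:
            onset = p

        for c in clones:
            f = c.cell_count / total
            for mid in c.mutation_ids:
                frac_acc[mid][p] = frac_acc[mid].get(p, 0.0) + f
            for cid in c.cna_ids:
                cna_frac_acc[cid][p] = cna_frac_acc[cid].get(p, 0.0) + f

    passages_seen = [r.passage for r in records]
    mutations = [
        replace(
            m,
            origin_passage=max(m.origin_passage, 1) if m.origin_passage == 0 else m.origin_passage,
            fractions={p: frac_acc[m.mutation_id].get(p, 0.0) for p in passages_seen},
        )
        for m in mutations
    ]
    cnas = [
        replace(c, fractions={p: cna_frac_acc[c.cna_id].get(p, 0.0) for p in passages_seen})
        for c in cnas
    ]

    truth = TruthSet(
        config=config,
        mutations=mutations,
        cnas=cnas,
        records=records,
        telomere_mean=telomere_mean,
        senescent_fraction=senescent_fraction,
        senescence_onset=onset,
    )
    return truth, records


# ---------------------------------------------------------------------------
# observation emitters


@dataclass(frozen=True)
class CallerModel:
    """Threshold model of one variant caller's detection behaviour."""

    name: str
    min_alt: int
    min_maf: float
    fp_rate: float = 5.0  # expected caller-specific false positives per passage


DEFAULT_CALLER_A = CallerModel("callerA", min_alt=3, min_maf=0.05)
DEFAULT_CALLER_B = CallerModel("callerB", min_alt=4, min_maf=0.08)


def emit_caller_outputs(
    truth: TruthSet,
    config: CultureConfig | None = None,
    caller_a: CallerModel = DEFAULT_CALLER_A,
    caller_b: CallerModel = DEFAULT_CALLER_B,
):
    """Emulate two variant callers plus a force-call allele-count table.

    Sequencing of a heterozygous mutation at true cell fraction ``f`` is
    modelled as depth ~ Poisson(mean_depth) and alt reads ~ Binomial(depth,
    f/2 + e/3) where ``e`` is the per-base sequencing error rate.  A caller
    reports a site when alt count and observed MAF clear its thresholds;
    each caller draws depth independently.  Caller-specific false positives
    are injected at disjoint sites so they vanish under intersection.  The
    force-call table re-counts every true and every called site at every
    observed passage with an independent depth draw.

    Returns ``(calls, forcecall)`` where ``calls`` maps caller name ->
    passage -> list of :class:`~passagemut.consensus.VariantCall` and
    ``forcecall`` is a DataFrame (chrom, pos, ref, alt, passage, depth,
    alt_count).
    """
    from .consensus import VariantCall

    config = config or truth.config
    rng = np.random.default_rng([_u32(config.rng_seed), 1])
    reference = SyntheticReference(truth.genome)
    obs = truth.observed_passages
    muts, fracs = truth.fraction_matrix()
    p_alt = np.clip(fracs / 2.0 + config.seq_error_rate / 3.0, 0.0, 1.0)

    calls: dict[str, dict[int, list]] = {}
    fp_sites: dict[str, list] = {}
    used_keys = {m.key[:2] for m in muts}

    for caller in (caller_a, caller_b):
        depths = rng.poisson(config.mean_depth, size=fracs.shape)
        alts = rng.binomial(depths, p_alt)
        called = (alts >= caller.min_alt) & (alts >= caller.min_maf * depths) & (depths > 0)
        per_passage: dict[int, list] = {p: [] for p in obs}
        for i, m in enumerate(muts):
            for j, p in enumerate(obs):
                if called[i, j]:
                    per_passage[p].append(
                        VariantCall(
                            m.chrom, m.pos, m.ref, m.alt, p, caller.name,
                            int(depths[i, j]), int(alts[i, j]),
                        )
                    )
        # caller-specific false positives, disjoint between callers by construction
        fps = []
        for p in obs:
            for _ in range(rng.poisson(caller.fp_rate)):
                while True:
                    (chrom, pos) = truth.genome.random_sites(rng, 1)[0]
                    if (chrom, pos) not in used_keys:
                        break
                used_keys.add((chrom, pos))
                ref = reference.base(chrom, pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                depth = max(int(rng.poisson(config.mean_depth)), caller.min_alt)
                alt_n = max(
                    caller.min_alt,
                    math.ceil(caller.min_maf * depth),
                    int(rng.binomial(depth, 0.15)),
                )
                vc = VariantCall(chrom, pos, ref, str(alt), p, caller.name, depth, min(alt_n, depth))
                per_passage[p].append(vc)
                fps.append(vc)
        for p in obs:
            per_passage[p].sort(key=lambda v: (truth.genome.chrom_index(v.chrom), v.pos, v.alt))
        calls[caller.name] = per_passage
        fp_sites[caller.name] = fps

    # force-call table over all true sites and all falsely called sites
    rows = []
    for i, m in enumerate(muts):
        for j, p in enumerate(obs):
            depth = int(rng.poisson(config.mean_depth))
            alt_n = int(rng.binomial(depth, p_alt[i, j])) if depth else 0
            rows.append((m.chrom, m.pos, m.ref, m.alt, p, depth, alt_n))
    fp_err = np.clip(config.seq_error_rate / 3.0, 0.0, 1.0)
    for fps in fp_sites.values():
        for vc in fps:
            for p in obs:
                depth = int(rng.poisson(config.mean_depth))
                alt_n = int(rng.binomial(depth, fp_err)) if depth else 0
                rows.append((vc.chrom, vc.pos, vc.ref, vc.alt, p, depth, alt_n))
    forcecall = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "passage", "depth", "alt_count"]
    )
    forcecall = forcecall.sort_values(["chrom", "pos", "alt", "passage"], kind="stable").reset_index(
        drop=True
    )
    return calls, forcecall


def emit_cna_observations(
    truth: TruthSet,
    bin_size: int = 100_000,
    probe_spacing: int = 5_000,
    noise_sd: float = 0.15,
    mean_bin_depth: float = 100.0,
    gc_bias: float = 1.0,
    array_sensitivity: float = 1.0,
    array_min_fraction: float = 0.2,
):
    """Binned case/control depths plus array-platform CNA calls per passage.

    Bins carry GC values drawn once per genome; a GC-dependent multiplier
    is applied identically to case and control so GC correction can remove
    it.  Within a true CNA at cell fraction ``f`` the expected case/control
    ratio is ``1 + f * delta_copy / 2``.  Array calls cover each true CNA
    whose fraction exceeds ``array_min_fraction`` with probability
    ``array_sensitivity`` and boundary jitter of at most one probe spacing.
    """
    genome = truth.genome
    if genome.chromosome_length % bin_size:
        raise ValueError("bin_size must divide the chromosome length evenly")
    rng = np.random.default_rng([_u32(truth.config.rng_seed), 2])

    per_chrom = genome.chromosome_length // bin_size
    chroms = np.repeat(genome.chromosomes, per_chrom)
    starts = np.tile(np.arange(per_chrom) * bin_size, genome.n_chromosomes)
    ends = starts + bin_size
    gc = np.clip(rng.normal(0.45, 0.06, size=chroms.size), 0.25, 0.65)
    bias = 1.0 + gc_bias * (gc - float(gc.mean()))
    mids = starts + bin_size // 2

    depth_tables: dict[int, pd.DataFrame] = {}
    array_calls: dict[int, pd.DataFrame] = {}
    for p in truth.observed_passages:
        ratio = np.ones(chroms.size)
        for cna in truth.cnas:
            f = cna.fractions.get(p, 0.0)
            if f <= 0:
                continue
            mask = (chroms == cna.chrom) & (mids >= cna.start) & (mids < cna.end)
            ratio[mask] *= 1.0 + f * cna.delta_copy / 2.0
        noise_case = 1.0 + rng.normal(0.0, noise_sd, size=chroms.size) if noise_sd else 1.0
        noise_ctrl = 1.0 + rng.normal(0.0, noise_sd, size=chroms.size) if noise_sd else 1.0
        depth_tables[p] = pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts,
                "end": ends,
                "gc": gc,
                "depth_case": np.clip(mean_bin_depth * bias * ratio * noise_case, 0.0, None),
                "depth_control": np.clip(mean_bin_depth * bias * noise_ctrl, 0.0, None),
            }
        )
        rows = []
        for cna in truth.cnas:
            if cna.fractions.get(p, 0.0) < array_min_fraction:
                continue
            if rng.random() > array_sensitivity:
                continue
            start = max(0, cna.start + int(rng.integers(-probe_spacing, probe_spacing + 1)))
            end = min(
                genome.chromosome_length,
                cna.end + int(rng.integers(-probe_spacing, probe_spacing + 1)),
            )
            rows.append((cna.chrom, start, end, cna.direction))
        array_calls[p] = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    return depth_tables, array_calls


def emit_qpcr_plate(
    truth: TruthSet,
    efficiency_t: float = 2.0,
    efficiency_s: float = 2.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    n_standards: int = 5,
    dilution_step: float = 4.0,
    intercept_t: float = 22.0,
    intercept_s: float = 26.0,
) -> pd.DataFrame:
    """qPCR well table: standard-curve dilution series plus per-passage samples.

    ``Cq = intercept - log10(amount) / log10(efficiency)`` plus Gaussian
    noise; the telomere amplicon amount is proportional to the passage's
    true mean telomere length, the single-copy amplicon amount is constant.
    Efficiencies are fold-amplification per cycle and must lie in (1, 2].
    """
    for eff in (efficiency_t, efficiency_s):
        if not 1.0 < eff <= 2.0:
            raise ValueError("amplification efficiency must be in (1, 2]")
    rng = np.random.default_rng([_u32(truth.config.rng_seed), 3])

    def cq(amount, intercept, eff):
        return intercept - math.log10(amount) / math.log10(eff) + (
            rng.normal(0.0, noise_sd) if noise_sd else 0.0
        )

    rows = []
    for amplicon, intercept, eff in (("T", intercept_t, efficiency_t), ("S", intercept_s, efficiency_s)):
        for i in range(n_standards):
            dilution = dilution_step**i
            for rep in range(1, n_replicates + 1):
                rows.append(("STD", amplicon, dilution, rep, cq(1.0 / dilution, intercept, eff)))

    obs = truth.observed_passages
    ref_len = truth.telomere_mean[obs[0]]
    for p in obs:
        amount_t = max(truth.telomere_mean[p], 1e-6) / max(ref_len, 1e-6)
        for rep in range(1, n_replicates + 1):
            rows.append((f"P{p}", "T", None, rep, cq(amount_t, intercept_t, efficiency_t)))
            rows.append((f"P{p}", "S", None, rep, cq(1.0, intercept_s, efficiency_s)))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "dilution", "replicate", "cq"])
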