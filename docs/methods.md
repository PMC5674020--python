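# Methods

This note describes the models behind `passagemut`: what the synthetic
serial-passage culture emulates and deliberately does not, the analysis
stages' numerical conventions, and the design choices made where no
published convention exists.

## The culture model

The simulator tracks a cultured cell population at **clone resolution**.
A clone is a set of cells sharing a mutation set, a CNA set and a
telomere budget. The state advances passage by passage:

1. **Bottleneck.** `seed_count` cells (default 10⁵, the per-dish
   reseeding count of standard MSC protocols) are drawn from the
   previous harvest by a multinomial over clone sizes.
2. **Growth.** Discrete doubling steps until the harvest target
   `seed_count × target_fold` (default 16×, i.e. four doublings to
   confluency) or `max_steps_per_passage` (default 14). The final
   doubling is partial — only as many cells divide as the dish's
   capacity admits (contact inhibition), so a healthy passage harvests
   exactly the target.
3. **Mutation.** Each step draws `Poisson(rate × dividing cells)` new
   SNVs and indels. `per_division_snv_rate` (default 2·10⁻⁵ per cell
   division) is calibrated so a line accumulates on the order of 10²–10³
   recorded mutations over nine passages, the scale reported for
   passage-series WGS of cultured MSC lines. Each new mutation is
   assigned to a clone with probability proportional to its dividing
   cells and is carried by the whole clone thereafter (see
   *resolution*, below). Substitution classes are drawn from
   `spectrum_early` (C>T/T>C-dominated, clock-like) or `spectrum_late`
   (C>A weight 0.6) with positions uniform over the genome; the
   reference base is taken from the deterministic synthetic reference so
   annotation and simulation agree.
4. **Senescence.** Each doubling decrements a clone's telomere budget;
   at or below `senescence_threshold` the clone stops dividing, and
   senescent cells detach at `senescent_loss_rate` (default 0.15 per
   step) — cultured senescent cells are observed to round up and detach.
   Founder budgets are Normal(`telomere_init` = 32, `telomere_sd` = 3)
   doublings: all founders divide freely until ~P7, the wall arrives at
   P8–P9, and the doubling time blows up there, reproducing the reported
   PDT pattern (flat ≈ 30 h early, rising sharply at the penultimate
   passage). Elapsed hours per step are
   `base_doubling_hours / (1 − senescent fraction)`, capped at
   `doubling_slowdown_cap`.
5. **The late burst and the escape lineage.** Observed cultures show an
   abrupt late-passage wave of mutations that are immediately clonally
   fixed. Neutral drift cannot fix a new mutation within one passage at
   these population sizes, and the hypothesis offered for the real
   phenomenon is that the mutation-accumulating lineage *escapes or
   delays replicative senescence*. The generator implements exactly
   that: one passage before `burst_passage`, one clone (chosen ∝
   dividing cells) gains `escape_bonus_divisions` of budget; from that
   same passage the mutation rate is multiplied by `burst_factor` and
   the spectrum switches to `spectrum_late`. As the background senesces,
   the escape lineage performs essentially all remaining divisions, so
   burst mutations land on it and surface at MAF ≈ 0.5. The burst
   window starts at `burst_passage − 1` because passages are observed at
   odd numbers: a burst "at P9" is a process active over the unobserved
   P8–P9 interval.
6. **CNA burst.** At `cna_burst_passage` a subclone carrying
   `cna_burst_segments` (default 29) scattered segments (0.3–3 Mb,
   ≥ 0.5 Mb apart, 65 % losses) is implanted at population fraction
   `cna_burst_fraction` (default 0.6) and immediately senesces, so its
   segments are strongly visible at that passage and decay geometrically
   afterwards — the punctuated, transient CNA wave. The implantation
   fraction is set directly rather than grown from a single cell: a
   one-cell clone cannot drift to a detectable fraction within one
   passage at these sizes, so the expansion that must have preceded the
   observable burst is collapsed into the implant.
7. **Extinction.** A passage at which no clone can divide truncates the
   record list; growth records never go below `harvested = seeded`
   silently.

**Resolution.** Carrying each new mutation on a whole existing clone
(rather than splitting off a one-cell subclone) keeps the simulation
exact at realistic cell counts. Consequences a user should know:
mutations sharing a clone share identical true-fraction trajectories;
subclonal structure comes from the founder Dirichlet spread, bottleneck
resampling and differential senescence, not from within-clone genealogy;
and a mutation's "origin passage" marks when its clone acquired it, with
the whole clone counted as carrying it from then on. These are
acceptable distortions for validating the analysis stages; they make the
simulator unsuitable for studying within-clone site-frequency spectra.

## Observation models

**Sequencing.** A mutation at true cell fraction `f` is heterozygous, so
reads carry it at `f/2`. Per passage and caller: depth ~
Poisson(`mean_depth` = 30), alt reads ~ Binomial(depth, `f/2 + e/3`)
with sequencing error `e` = 10⁻³ per base. The two emulated callers
differ only in thresholds (min alt reads 3 vs 4; min observed MAF 0.05
vs 0.08), draw depths independently, and each injects its own
Poisson-rate false positives at sites disjoint from truth and from the
other caller — so the two-caller intersection has precision 1.0 by
construction, which the tests assert. Caller internals are out of scope.
The force-call table re-counts every true and every called site at every
passage with an independent draw; zero-fraction sites therefore show
MAF 0 apart from sequencing error.

**Copy number.** Bins (default 100 kb; 25 kb in the recovery
experiments) carry GC drawn once per genome from a clipped
Normal(0.45, 0.06); a linear GC bias multiplies case and control
identically; within a CNA at fraction `f`, the expected case/control
ratio is `1 + f·Δcopy/2`; multiplicative Gaussian noise (`noise_sd`,
default 0.15) is applied per bin per sample. The array platform is
emulated as a call list covering each true CNA above
`array_min_fraction` with configurable sensitivity and boundary jitter
≤ one probe spacing (default 5 kb).

**qPCR.** `Cq = intercept − log10(amount)/log10(efficiency)` plus
Gaussian noise; the telomere amplicon amount is proportional to the
passage's true mean telomere length, the single-copy amplicon constant;
each plate carries a five-point, four-fold dilution series per amplicon.
Efficiencies are fold-per-cycle in (1, 2].

## Analysis conventions

- **Consensus.** Exact match on (chrom, pos, ref, alt) after splitting
  multi-allelic records and trimming indels to their left-aligned
  minimal representation; no published matching rule exists, so exact
  normalized matching is the declared convention. Depth/alt fields of
  consensus records come from caller A (fixed, arbitrary); MAF
  trajectories always come from the force-call table.
- **Discovery class** = earliest passage with a consensus call.
- **Clonality.** `fixed`: MAF ≥ `fixed_maf` at every passage from its
  post-discovery peak through the last; `drift`: above `drift_maf` at
  ≥ 2 passages without fixation; `transient`: the rest. `fixed_maf`
  defaults to 0.35 — between the subclonal band and the het ceiling of
  0.5 — and `drift_maf` to 0.02 (force-call noise floor); both are
  explicit conventions, configurable, since no numeric definition of
  "clonally fixed" is published. A variant observed only at the final
  passage can be `fixed`; the `terminal_only` flag carries the caveat.
  SE uses the sample SD (n − 1).
- **Spectra** use the pyrimidine-reference six-class convention (G>T
  counts as C>A). **Annotation precedence**: exonic CDS (codon
  comparison, strand-aware, standard genetic code) > splicing (≤ 2 bp
  into an intron) > UTR > intronic > TSS-proximal (± 1 kb) > ncRNA >
  intergenic; coding indels are labelled nonsilent (exonic-missense).
  The precedence order and windows are declared conventions.
  **Enrichment** is an exact two-sided binomial test of intronic counts
  against the intronic/(intronic+intergenic) footprint fraction; the
  published observation states the enrichment but no test.
- **CBS** is the classical recursive arc-statistic + permutation
  formulation with `s` = segment sample SD (making the statistic
  shift-invariant), permutation p = (exceed + 1)/(n_perm + 1), early
  exit once p can no longer fall below α, and post-hoc merging of
  segments shorter than `min_bins` (default 3) into the closer-mean
  neighbour. `min_abs_ratio` = 0.3 (≈ a one-copy change at 25 % cell
  fraction under the het model) and reciprocal overlap 0.5 are declared
  conventions for consensus calling. No hybrid/pruning acceleration:
  profiles here are ≤ a few hundred bins per chromosome.
- **PDT simulation** multiplies cell counts by MAF directly, following
  the quoted formulation; `diploid_fraction=True` switches to the
  biological alternative 2·MAF (the factor cancels in A whenever both
  passages scale together). Seeded mutants use the previous assayed
  passage's MAF (the seeded aliquot samples the previous harvest); the
  first assayed passage uses its own MAF. Class-level and per-variant
  modes are both implemented; which one the original figures used is
  not stated.

## Problem sizes and numerical notes

Default experiments run on a 10 chromosome × 10 Mb genome so that a full
line (simulate → emit → consensus → clonality → kinetics, with the VCF
round trip) takes ~2 s and the complete test suite a few minutes on one
CPU. Segment-recovery experiments use 25 kb bins (2 000 bins genome-wide)
and 200 permutations at α = 0.01, sizes at which a 12-bin segment at
log₂ ≈ 0.5 clears the permutation null comfortably. The permutation
count bounds the smallest attainable p at 1/201, adequate for α = 0.01.

Degenerate inputs: zero-depth force calls record MAF 0 with a flag;
zero-control bins are masked (never ±inf), with an error above 50 %
masked; chromosomes shorter than `2·min_bins` return one segment;
cultures whose clones all senesce truncate their passage list;
amplification of a class with zero seeded mutants is flagged missing,
as is any simulated PDT with A ≤ 1.

## What passing tests do and do not show

Parameter recovery on the generator demonstrates that the pipeline
recovers what the generator encodes — burst fraction to ± 0.05, the
late C>A weight to ± 0.05, 29 injected CNAs at ≥ 27/29, fixation calls
at ≥ 95 % sensitivity when counting depth is high. It does not
demonstrate performance on real data: the generator has no mapping
bias, no contamination, no multi-nucleotide events, no real caller
error modes, Poisson rather than overdispersed depths, and uniform
rather than chromatin-structured mutation placement. Two specific
bounds worth knowing: at 30× depth the binomial MAF noise (sd ≈ 0.09 at
MAF 0.45) crosses the 0.35 fixation threshold often enough to cap
fixation-call sensitivity near 0.9 — the ≥ 0.95 sensitivity property is
checked at 100× force-call depth where the noise premise holds; and
consecutive bulk PDT values jitter by 1–2 % from discrete-step hour
accounting, so PDT monotonicity after senescence onset is a trend (the
default configuration satisfies it exactly).

## Known limitations

Clone-level mutation carriage (above); no allele-specific copy number,
purity or ploidy estimation; no trinucleotide (96-class) signatures; no
phylogenetic subclone reconstruction; qPCR plate effects beyond a
shared intercept are not modelled; the synthetic reference is i.i.d.
uniform ACGT, so codon statistics (e.g. stop-gain rates) differ from a
real genome's; and the relative telomere mean can rise at the final
passage when the long-budget escape lineage takes over — a real feature
of the model worth remembering when reading T/S trajectories.
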