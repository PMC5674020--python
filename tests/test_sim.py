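"""Simulator contracts: growth arithmetic, mutation truth, emission models."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

import passagemut as pm
from passagemut import io
from passagemut.growth import pdt
from passagemut.sim import DEFAULT_CALLER_A, DEFAULT_CALLER_B


def zero_rate_config(**kw):
    base = dict(
        rng_seed=1, per_division_snv_rate=0.0, per_division_indel_rate=0.0,
        founder_snv_mean=0.0, telomere_loss_per_division=0.0, seq_error_rate=0.0,
    )
    base.update(kw)
    return pm.CultureConfig(**base)


class TestSimulateCulture:
    def test_no_mutation_no_senescence_limit(self):
        """All stochastic rates zero: no variants, identical folds, flat PDT."""
        truth, records = pm.simulate_culture(zero_rate_config())
        assert truth.mutations == [] and truth.cnas == []
        folds = {r.harvested / r.seeded for r in records}
        assert folds == {16.0}
        assert len({round(pdt(r), 9) for r in records}) == 1
        assert truth.senescence_onset is None

    def test_burst_passage_concentrates_origins(self):
        """With a strong late burst most emitted mutations originate late.

        The burst window covers the unobserved passage before the burst
        passage; binomial spread over 20 seeds stays well above 70%.
        """
        fracs = []
        for seed in range(20):
            cfg = pm.CultureConfig(rng_seed=seed, burst_passage=9, burst_factor=20.0)
            truth, _ = pm.simulate_culture(cfg)
            late = sum(m.origin_passage >= 8 for m in truth.mutations)
            fracs.append(late / len(truth.mutations))
        assert np.mean(fracs) >= 0.70

    def test_telomere_budget_arithmetic(self):
        """50 divisions at 10 doublings per passage: 5 passages, dead by P6."""
        cfg = zero_rate_config(
            telomere_init=50.0, telomere_sd=0.0, telomere_loss_per_division=1.0,
            senescence_threshold=0.0, target_fold=2.0**10, max_steps_per_passage=10,
            escape_bonus_divisions=0.0,
        )
        _, records = pm.simulate_culture(cfg)
        assert len(records) == 5

    def test_fractions_within_unit_interval(self, default_run):
        truth = default_run["truth"]
        _, fracs = truth.fraction_matrix()
        assert fracs.min() >= 0.0 and fracs.max() <= 1.0

    def test_seed_count_exceeding_initial_population_rejected(self):
        with pytest.raises(ValueError, match="initial population"):
            pm.CultureConfig(seed_count=1000, initial_population=10)

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError, match="spectrum"):
            pm.CultureConfig(spectrum_early=(0.5, 0.5, 0.1, 0, 0, 0))

    def test_pdt_non_decreasing_after_senescence_onset(self):
        """Without an escape lineage the PDT rises monotonically from onset."""
        for seed in (0, 1, 2):
            cfg = pm.CultureConfig(rng_seed=seed, escape_bonus_divisions=0.0)
            truth, records = pm.simulate_culture(cfg)
            onset = truth.senescence_onset
            assert onset is not None
            pdts = [pdt(r) for r in records if r.passage >= onset]
            finite = [v for v in pdts if not np.isnan(v)]
            # 5% slack: hours are a mean-field sum over discrete steps, so
            # consecutive PDTs can jitter slightly around the rising trend
            assert all(b >= 0.95 * a for a, b in zip(finite, finite[1:]))


class TestEmitCallerOutputs:
    def test_clonal_site_called_with_high_probability(self):
        """Het site at cell fraction 1: analytic call probability > 0.999.

        Depth ~ Poisson(30), alt ~ Binomial(depth, 0.5); both emulated
        callers clear their thresholds unless the depth draw collapses.
        """
        for min_alt, min_maf in ((3, 0.05), (4, 0.08)):
            p_call = 0.0
            for d in range(0, 200):
                need = max(min_alt, int(np.ceil(min_maf * d)))
                p_call += stats.poisson.pmf(d, 30) * stats.binom.sf(need - 1, d, 0.5)
            assert p_call > 0.999

    def test_zero_fraction_absent_from_callers_present_in_forcecall(self):
        cfg = zero_rate_config(founder_snv_mean=2.0)  # founder mutations only
        truth, _ = pm.simulate_culture(cfg)
        # make one mutation vanish: fractions to zero at late passages
        target = truth.mutations[0]
        object.__setattr__(target, "fractions", {p: (0.0 if p > 1 else target.fractions[p])
                                                 for p in target.fractions})
        calls, forcecall = pm.emit_caller_outputs(truth, cfg)
        for caller in calls.values():
            for p, lst in caller.items():
                if p > 1:
                    assert target.key not in {v.key for v in lst}
        fc = forcecall.set_index(["chrom", "pos", "ref", "alt", "passage"])
        for p in truth.observed_passages:
            if p > 1:
                row = fc.loc[target.key + (p,)]
                assert row["alt_count"] == 0

    def test_false_positives_vanish_under_intersection(self, default_run):
        """Caller-specific false positives are disjoint: consensus precision 1."""
        truth = default_run["truth"]
        truth_keys = {m.key for m in truth.mutations}
        matrix = default_run["matrix"]
        consensus_keys = {matrix.variants[k].key for k in matrix.maf.index}
        assert consensus_keys <= truth_keys

    def test_observed_maf_tracks_half_cell_fraction(self, default_run):
        """Force-call MAF ~ f/2 within 4 binomial standard errors at depth 30."""
        truth = default_run["truth"]
        matrix = default_run["matrix"]
        by_key = {m.key: m for m in truth.mutations}
        checked = 0
        for key in matrix.maf.index:
            v = matrix.variants[key]
            m = by_key.get(v.key)
            if m is None:
                continue
            for p in matrix.passages:
                f = m.fractions.get(p, 0.0)
                d = matrix.depth.loc[key, p]
                if f < 0.2 or d == 0:
                    continue
                se = np.sqrt((f / 2) * (1 - f / 2) / d)
                assert abs(matrix.maf.loc[key, p] - f / 2) < 4 * se + 0.02
                checked += 1
        assert checked > 100


class TestEmitCnaObservations:
    def test_null_genome_noiseless_ratios_are_zero(self, line2_truth):
        from dataclasses import replace

        truth = replace(line2_truth, cnas=[])
        bins, _ = pm.emit_cna_observations(truth, noise_sd=0.0)
        for p, table in bins.items():
            ratios = pm.log2_ratio(pm.gc_correct(table))
            assert np.allclose(ratios, 0.0, atol=1e-9)

    def test_clonal_single_copy_loss_hits_minus_one(self, line2_truth):
        from dataclasses import replace
        from passagemut.sim import CnaEvent

        loss = CnaEvent(0, "chr1", 2_000_000, 5_000_000, -1, 1,
                        {p: 1.0 for p in range(1, 10)})
        truth = replace(line2_truth, cnas=[loss])
        bins, _ = pm.emit_cna_observations(truth, noise_sd=0.0)
        table = bins[1]
        ratios = pm.log2_ratio(pm.gc_correct(table))
        mids = (table["start"] + table["end"]) // 2
        inside = (table["chrom"] == "chr1") & (mids >= loss.start) & (mids < loss.end)
        assert np.allclose(ratios[inside], -1.0, atol=0.01)

    def test_bin_size_must_divide_genome(self, line2_truth):
        with pytest.raises(ValueError, match="bin_size"):
            pm.emit_cna_observations(line2_truth, bin_size=333_333)

    def test_array_boundary_jitter_bounded(self, line2_truth):
        _, arr = pm.emit_cna_observations(line2_truth, probe_spacing=5_000)
        truth_spans = {(c.chrom, c.direction): (c.start, c.end) for c in line2_truth.cnas}
        p = line2_truth.cnas[0].origin_passage
        for call in arr[p].itertuples():
            matches = [
                (abs(call.start - c.start), abs(call.end - c.end))
                for c in line2_truth.cnas
                if c.chrom == call.chrom and c.direction == call.direction
            ]
            assert min(max(ds, de) for ds, de in matches) <= 5_000


class TestEmitQpcr:
    def test_perfect_efficiency_slope(self, line2_truth):
        wells = pm.emit_qpcr_plate(line2_truth, efficiency_t=2.0, noise_sd=0.0)
        std = wells[(wells["amplicon"] == "T") & wells["dilution"].notna()]
        by_dil = std.groupby("dilution")["cq"].mean().sort_index()
        diffs = np.diff(by_dil.to_numpy())  # 4-fold dilution steps
        assert np.allclose(diffs, 2.0, atol=1e-9)

    def test_efficiency_bounds(self, line2_truth):
        with pytest.raises(ValueError, match="efficiency"):
            pm.emit_qpcr_plate(line2_truth, efficiency_t=2.5)

    def test_ts_recovery_within_tolerance(self):
        """Monte-Carlo: noisy plates recover true telomere ratios (~15%)."""
        errs = []
        for seed in range(50):
            truth, _ = pm.simulate_culture(pm.CultureConfig(rng_seed=seed))
            wells = pm.emit_qpcr_plate(truth, noise_sd=0.1)
            ct = pm.fit_standard_curve(wells, "T")
            cs = pm.fit_standard_curve(wells, "S")
            ts = pm.ts_ratio(wells, ct, cs, "P1")
            true5 = truth.telomere_mean[5] / truth.telomere_mean[1]
            errs.append(abs(ts["P5"] - true5) / true5)
        assert np.mean(errs) <= 0.15


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = pm.CultureConfig(rng_seed=7)
        for sub in ("a", "b"):
            truth, _ = pm.simulate_culture(cfg)
            calls, fc = pm.emit_caller_outputs(truth, cfg)
            bins, arr = pm.emit_cna_observations(truth)
            qpcr = pm.emit_qpcr_plate(truth)
            io.write_simulation(tmp_path / sub, truth, calls=calls, forcecall=fc,
                                depth_tables=bins, array_calls=arr, qpcr=qpcr)
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names
        for name in names:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)


def test_truth_json_roundtrip(tmp_path, line2_truth):
    path = tmp_path / "truth.json"
    io.write_truth(path, line2_truth)
    back = io.read_truth(path)
    assert back.config == line2_truth.config
    assert back.mutations == line2_truth.mutations
    assert back.cnas == line2_truth.cnas
    assert back.records == line2_truth.records
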