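"""Simulated PDT of mutation-bearing subpopulations.

The count of cells carrying a mutation class at a passage is estimated by
multiplying the bulk cell count by the class MAF: harvested mutant cells
use that passage's MAF, seeded mutant cells use the previous assayed
passage's MAF (the seeded aliquot is a proportional sample of the
previous harvest).  The multiplication uses MAF directly; the biological
alternative of using the cell fraction (2 x MAF for heterozygous
mutations) is available behind ``diploid_fraction`` and cancels out of
the amplification ratio whenever the previous and current MAF are scaled
together.

Amplification capacity A = harvested mutants / seeded mutants converts to
a simulated doubling time hours * ln2 / ln A when A > 1; A <= 1 (a
shrinking subclone) and an undefined A (a de novo class with zero seeded
mutants) are flagged missing, not errors.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .growth import LN2, GrowthRecord


def mutant_counts(growth: list[GrowthRecord], class_maf: pd.Series,
                  diploid_fraction: bool = False) -> pd.DataFrame:
    """Per-passage seeded and harvested mutant-cell counts for one class.

    ``class_maf`` is indexed by the same passages as ``growth`` (in
    order).  The seeded count at the first assayed passage uses that
    passage's own MAF.
    """
    passages = [r.passage for r in growth]
    if list(class_maf.index) != passages:
        raise ValueError("growth records and MAF series cover different passages")
    maf = class_maf.to_numpy(dtype=float)
    if (maf < 0).any():
        raise ValueError("negative MAF")
    scale = 2.0 if diploid_fraction else 1.0
    prev_maf = np.concatenate([[maf[0]], maf[:-1]])
    rows = []
    for k, r in enumerate(growth):
        if r.seeded < 0 or r.harvested < 0:
            raise ValueError("negative cell counts")
        rows.append(
            {
                "passage": r.passage,
                "seeded_mutant": r.seeded * scale * prev_maf[k],
                "harvested_mutant": r.harvested * scale * maf[k],
                "hours": r.hours,
            }
        )
    return pd.DataFrame(rows).set_index("passage")


def amplification_capacity(seeded_mutant: float, harvested_mutant: float) -> float:
    """harvested / seeded mutant cells; NaN when the class had no seeded cells."""
    if seeded_mutant < 0 or harvested_mutant < 0:
        raise ValueError("negative mutant counts")
    if seeded_mutant == 0:
        return float("nan")  # de novo class at its origin passage
    return harvested_mutant / seeded_mutant


def simulated_pdt(a: float, hours: float) -> float:
    """hours * ln2 / ln A for A > 1; NaN (flagged missing) otherwise."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    if not a > 1.0:  # also covers NaN
        return float("nan")
    return hours * LN2 / math.log(a)


def class_kinetics(growth: list[GrowthRecord], summary: pd.DataFrame,
                   diploid_fraction: bool = False, mode: str = "class_mean",
                   maf_matrix=None) -> pd.DataFrame:
    """ClassKinetics table: mutant counts, amplification capacity, simulated PDT.

    ``summary`` is the per-(class, passage) MAF summary from
    :func:`passagemut.clonality.class_maf_summary`.  ``mode`` selects the
    class-mean trajectory ("class_mean") or per-variant computation
    averaged within class ("per_variant", requires ``maf_matrix``).
    """
    passages = [r.passage for r in growth]
    rows = []
    if mode == "class_mean":
        for label, block in summary.groupby("mutation_class"):
            maf = block.set_index("passage")["mean_maf"].reindex(passages)
            if maf.isna().any():
                raise ValueError(f"class {label} missing MAF at some passages")
            counts = mutant_counts(growth, maf, diploid_fraction)
            for p, r in counts.iterrows():
                a = amplification_capacity(r["seeded_mutant"], r["harvested_mutant"])
                rows.append(
                    {
                        "mutation_class": label,
                        "passage": p,
                        "seeded_mutant": r["seeded_mutant"],
                        "harvested_mutant": r["harvested_mutant"],
                        "amplification": a,
                        "simulated_pdt": simulated_pdt(a, r["hours"]),
                    }
                )
    elif mode == "per_variant":
        if maf_matrix is None or maf_matrix.labels is None:
            raise ValueError("per_variant mode needs a labelled MafMatrix")
        for label, block in maf_matrix.maf.groupby(maf_matrix.labels):
            per_variant = []
            for _, traj in block.iterrows():
                maf = traj.reindex(passages)
                counts = mutant_counts(growth, maf, diploid_fraction)
                a = counts["harvested_mutant"] / counts["seeded_mutant"].replace(0.0, np.nan)
                pdt_v = [
                    simulated_pdt(av, h) if not np.isnan(av) else float("nan")
                    for av, h in zip(a, counts["hours"])
                ]
                per_variant.append(pdt_v)
            stacked = np.array(per_variant, dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                mean_pdt = np.nanmean(stacked, axis=0)
            for p, v in zip(passages, mean_pdt):
                rows.append(
                    {
                        "mutation_class": label,
                        "passage": p,
                        "seeded_mutant": float("nan"),
                        "harvested_mutant": float("nan"),
                        "amplification": float("nan"),
                        "simulated_pdt": float(v),
                    }
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).sort_values(["mutation_class", "passage"]).reset_index(drop=True)


def expansion_fold(growth: list[GrowthRecord], from_passage: int, to_passage: int) -> float:
    """Cumulative expansion over consecutive passages: prod harvested/seeded."""
    covered = {r.passage: r for r in growth}
    wanted = range(from_passage, to_passage + 1)
    missing = [p for p in wanted if p not in covered]
    if missing:
        raise ValueError(f"gap in passage coverage: missing {missing}")
    fold = 1.0
    for p in wanted:
        r = covered[p]
        fold *= r.harvested / r.seeded
    return fold


def cross_line_expansion_ratio(growth_line1: list[GrowthRecord],
                               growth_line2: list[GrowthRecord],
                               from_passage: int, to_passage: int) -> float:
    """fold(line2) / fold(line1) over the matched passage range."""
    return expansion_fold(growth_line2, from_passage, to_passage) / expansion_fold(
        growth_line1, from_passage, to_passage
    )
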