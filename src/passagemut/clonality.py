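"""Per-class MAF summaries and clonality classification of trajectories.

Mutations are grouped by discovery-passage class (P1..P9) and summarised
as mean +/- standard error of MAF per passage.  Each trajectory is then
classified as clonally fixed (sustained high MAF from its post-discovery
peak to the last passage), subclonal drift (recurrently present but never
sustained high), or transient.  The thresholds have no published numeric
definition, so they are explicit, configurable conventions: ``fixed_maf``
defaults to 0.35 (between the subclonal band and the heterozygous ceiling
of 0.5) and ``drift_maf`` to 0.02 (the noise floor below which a
force-call MAF is treated as absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import MafMatrix


def class_maf_summary(matrix: MafMatrix) -> pd.DataFrame:
    """Mean and SE of MAF per (discovery class, passage).

    SE is sample SD (n-1 denominator) over sqrt(n); single-variant classes
    report SE 0.
    """
    if matrix.labels is None:
        raise ValueError("matrix has no discovery-passage labels")
    rows = []
    for label, block in matrix.maf.groupby(matrix.labels):
        for p in matrix.passages:
            vals = block[p].to_numpy()
            se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "mutation_class": label,
                    "passage": p,
                    "n": len(vals),
                    "mean_maf": float(vals.mean()),
                    "se_maf": se,
                }
            )
    return pd.DataFrame(rows).sort_values(["mutation_class", "passage"]).reset_index(drop=True)


@dataclass(frozen=True)
class ClonalityLabel:
    """Clonality call plus the statistics it was derived from."""

    label: str  # "fixed" | "drift" | "transient"
    max_maf_after_discovery: float
    min_maf_after_discovery: float
    terminal_only: bool  # fixed call rests on the final passage alone


def classify_clonality(trajectory, discovery_class: str, passages,
                       fixed_maf: float = 0.35, drift_maf: float = 0.02) -> ClonalityLabel:
    """Classify one MAF trajectory.

    fixed: MAF >= ``fixed_maf`` at every passage from its post-discovery
    peak through the last assayed passage (a variant observed only at the
    final passage can be fixed; the ``terminal_only`` flag records the
    caveat).  drift: above the ``drift_maf`` noise floor at >= 2 passages
    without sustained fixation.  transient: everything else.
    """
    traj = np.asarray(trajectory, dtype=float)
    passages = list(passages)
    if traj.shape != (len(passages),):
        raise ValueError("trajectory length does not match passage labels")
    if not 0 < drift_maf < fixed_maf <= 0.5:
        raise ValueError("need 0 < drift_maf < fixed_maf <= 0.5")
    disc = int(discovery_class.removeprefix("P"))
    if disc not in passages:
        raise ValueError(f"discovery passage {disc} not among assayed passages {passages}")
    d = passages.index(disc)

    after = traj[d:]
    peak = d + int(np.argmax(after))
    fixed = bool((traj[peak:] >= fixed_maf).all())
    label = "fixed" if fixed else ("drift" if (traj > drift_maf).sum() >= 2 else "transient")
    return ClonalityLabel(
        label=label,
        max_maf_after_discovery=float(after.max()),
        min_maf_after_discovery=float(after.min()),
        terminal_only=fixed and peak == len(passages) - 1 and d == len(passages) - 1,
    )


def classify_all(matrix: MafMatrix, fixed_maf: float = 0.35,
                 drift_maf: float = 0.02) -> pd.DataFrame:
    """Clonality table for every labelled variant in the matrix."""
    if matrix.labels is None:
        raise ValueError("matrix has no discovery-passage labels")
    rows = []
    for key in matrix.maf.index:
        lab = classify_clonality(
            matrix.maf.loc[key], matrix.labels[key], matrix.passages, fixed_maf, drift_maf
        )
        rows.append(
            {
                "variant": key,
                "mutation_class": matrix.labels[key],
                "clonality": lab.label,
                "max_maf_after_discovery": lab.max_maf_after_discovery,
                "min_maf_after_discovery": lab.min_maf_after_discovery,
                "terminal_only": lab.terminal_only,
            }
        )
    return pd.DataFrame(rows).set_index("variant")


def late_burst_fraction(labels, late_classes) -> float:
    """Fraction of variants whose discovery class is in ``late_classes``."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty variant set")
    late = set(late_classes)
    return sum(l in late for l in labels) / len(labels)
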