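"""Two-caller consensus variants and the MAF-by-passage matrix.

High-confidence somatic variants are defined as the exact-key overlap of
two callers' per-passage call sets.  The mutation allele frequency (MAF)
trajectory of each consensus variant is then read from a force-call
allele-count table that counts ref/alt reads at every site at every
passage regardless of caller status, separating "where was it called"
from "how frequent was it".  A variant's discovery class is the earliest
passage at which any caller pair reported it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VariantCall:
    """One caller's report of one variant at one passage."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    passage: int
    caller: str
    depth: int
    alt_count: int

    def __post_init__(self):
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def normalize_variant(chrom: str, pos: int, ref: str, alt: str):
    """Left-aligned minimal representation of a variant allele pair.

    Trims shared suffix bases, then shared prefix bases (advancing the
    position), always retaining at least one base on each allele — the
    VCF left-anchored convention for indels.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _keyed(calls, label):
    out = {}
    for c in calls:
        if c.key in out:
            raise ValueError(f"duplicate variant key {c.key} in caller {label!r} call set")
        out[c.key] = c
    return out


def intersect_callers(calls_a, calls_b) -> list[VariantCall]:
    """Variants reported by both callers at this passage.

    Depth and alt count of the returned records are taken from caller A
    (a fixed, arbitrary provenance choice; MAF trajectories come from the
    force-call table, not from these fields).  Output is sorted by
    (chrom, pos, alt).  Duplicate keys within one caller's list raise.
    """
    a = _keyed(calls_a, "A")
    b = _keyed(calls_b, "B")
    shared = set(a) & set(b)
    return sorted((a[k] for k in shared), key=lambda v: (v.chrom, v.pos, v.alt))


class MafMatrix:
    """Variants x passages MAF matrix with parallel depth and call masks.

    Attributes
    ----------
    maf, depth : DataFrame
        Rows are variant keys ("chrom:pos:ref>alt"), columns passages.
    zero_depth : DataFrame of bool
        True where force-call depth was 0 (MAF recorded as 0 there).
    called : DataFrame of bool
        True where the variant was in the consensus call set.
    labels : Series or None
        Discovery-passage class per variant, filled by
        :func:`assign_discovery_passage`.
    """

    def __init__(self, maf, depth, zero_depth, called, variants):
        self.maf = maf
        self.depth = depth
        self.zero_depth = zero_depth
        self.called = called
        self.variants = variants  # key -> representative VariantCall
        self.labels: pd.Series | None = None

    @property
    def passages(self) -> list[int]:
        return list(self.maf.columns)

    def is_snv(self, key: str) -> bool:
        return self.variants[key].is_snv

    def with_labels(self, labels: pd.Series) -> "MafMatrix":
        self.labels = labels
        return self


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def build_maf_matrix(consensus_by_passage: dict[int, list], forcecall: pd.DataFrame,
                     passages=None) -> MafMatrix:
    """Assemble the MAF matrix for the union of consensus variants.

    Every consensus site must be present in the force-call table at every
    passage (a missing entry raises, naming site and passage).  Bins with
    zero force-call depth get MAF 0 plus a zero-depth flag.
    """
    passages = sorted(consensus_by_passage) if passages is None else list(passages)
    lookup = {
        (r.chrom, r.pos, r.ref, r.alt, r.passage): (r.depth, r.alt_count)
        for r in forcecall.itertuples()
    }
    variants: dict[str, VariantCall] = {}
    called_at: dict[str, set[int]] = {}
    for p, calls in consensus_by_passage.items():
        for v in calls:
            k = variant_key(*v.key)
            variants.setdefault(k, v)
            called_at.setdefault(k, set()).add(p)

    order = sorted(variants, key=lambda k: (variants[k].chrom, variants[k].pos, variants[k].alt))
    maf = np.zeros((len(order), len(passages)))
    depth = np.zeros_like(maf, dtype=int)
    zero_depth = np.zeros_like(maf, dtype=bool)
    called = np.zeros_like(maf, dtype=bool)
    for i, k in enumerate(order):
        v = variants[k]
        for j, p in enumerate(passages):
            try:
                d, a = lookup[(v.chrom, v.pos, v.ref, v.alt, p)]
            except KeyError:
                raise KeyError(
                    f"force-call table has no entry for {k} at passage {p}"
                ) from None
            depth[i, j] = d
            if d == 0:
                zero_depth[i, j] = True
            else:
                maf[i, j] = a / d
            called[i, j] = p in called_at[k]

    def frame(arr, dtype=None):
        return pd.DataFrame(arr, index=order, columns=passages, dtype=dtype)

    return MafMatrix(frame(maf), frame(depth), frame(zero_depth), frame(called), variants)


def assign_discovery_passage(matrix: MafMatrix) -> pd.Series:
    """Label every variant with its earliest consensus-called passage (P1..P9).

    A variant identified at multiple passages is assigned to the earliest
    one; a variant called nowhere raises.
    """
    labels = {}
    for key, row in matrix.called.iterrows():
        called = [p for p in matrix.passages if row[p]]
        if not called:
            raise ValueError(f"variant {key} has an empty called-passage set")
        labels[key] = f"P{min(called)}"
    series = pd.Series(labels, name="mutation_class").reindex(matrix.maf.index)
    matrix.labels = series
    return series
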