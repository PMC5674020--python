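"""Copy-number pipeline: GC correction, log2 ratios, CBS, consensus calls.

Binned case/control read depths are GC-corrected per 1%-GC stratum,
turned into median-centred log2 ratios, and segmented with the classical
circular binary segmentation (CBS) recursion: for each ordered segment
find the arc (i, j] maximising the two-sample statistic

    T = |mean_in - mean_out| / (s * sqrt(1/n_in + 1/n_out))

and declare a change-point when a permutation test (shuffling bin order)
gives p < alpha, then recurse on the pieces.  ``s`` is the sample SD of
the segment, which makes T invariant to adding a constant to all ratios.
Segments shorter than ``min_bins`` are merged into the neighbour with the
closer mean.  This is the plain recursive formulation without hybrid or
pruning accelerations; desk-scale bin counts do not need them.

Sequencing-derived segments are then confirmed against an independent
array-platform call list: a segment is high-confidence when a
direction-matched array call covers it at a reciprocal overlap above
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CnaSegment:
    """A contiguous copy-number segment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    mean_ratio: float
    direction: str  # "gain" | "loss"
    n_bins: int
    source: str = "wgs"  # "wgs" | "array" | "consensus"
    track: dict | None = None  # optional per-passage mean ratio

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")


def _validate_bins(bins: pd.DataFrame) -> None:
    needed = {"chrom", "start", "end", "gc", "depth_case", "depth_control"}
    missing = needed - set(bins.columns)
    if missing:
        raise ValueError(f"bin table missing columns {sorted(missing)}")


def gc_correct(bins: pd.DataFrame, min_stratum_bins: int = 20) -> pd.DataFrame:
    """Divide each depth column by its 1%-GC stratum median over the global one.

    Strata with fewer than ``min_stratum_bins`` bins are merged with the
    neighbouring stratum (rightward sweep, remainder folded back into the
    last group); case and control are corrected independently.
    """
    _validate_bins(bins)
    out = bins.copy()
    strata = np.floor(out["gc"].to_numpy(dtype=float) * 100).astype(int)
    order = np.argsort(strata, kind="stable")
    groups: list[np.ndarray] = []
    current: list[int] = []
    for lvl in np.unique(strata):
        current.extend(np.flatnonzero(strata == lvl))
        if len(current) >= min_stratum_bins:
            groups.append(np.array(current))
            current = []
    if current:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(current)])
        else:
            groups.append(np.array(current))
    del order

    for col in ("depth_case", "depth_control"):
        depths = out[col].to_numpy(dtype=float)
        if not depths.any():
            raise ValueError(f"{col}: all depths are zero")
        global_med = np.median(depths)
        corrected = depths.copy()
        for idx in groups:
            med = np.median(depths[idx])
            if med > 0:
                corrected[idx] = depths[idx] / (med / global_med)
        out[col] = corrected
    return out


def log2_ratio(bins: pd.DataFrame, max_masked_fraction: float = 0.5) -> pd.Series:
    """Median-centred per-bin log2(case/control); zero-control bins are NaN.

    Raises when more than ``max_masked_fraction`` of the bins are masked.
    """
    _validate_bins(bins)
    case = bins["depth_case"].to_numpy(dtype=float)
    ctrl = bins["depth_control"].to_numpy(dtype=float)
    mask = (ctrl <= 0) | (case < 0)
    if mask.mean() > max_masked_fraction:
        raise ValueError(f"{mask.mean():.0%} of bins masked (control depth 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(np.where(case > 0, case, np.nan) / np.where(ctrl > 0, ctrl, np.nan))
    r[mask] = np.nan
    r = r - np.nanmedian(r)
    return pd.Series(r, index=bins.index, name="log2_ratio")


_PAIR_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _pairs(n: int):
    """Cached (i, j, width) arrays for all arcs (i, j] with non-empty complement."""
    cached = _PAIR_CACHE.get(n)
    if cached is None:
        i_idx, j_idx = np.triu_indices(n + 1, k=1)
        keep = (j_idx - i_idx) < n
        i_idx, j_idx = i_idx[keep], j_idx[keep]
        cached = (i_idx, j_idx, (j_idx - i_idx).astype(float))
        if len(_PAIR_CACHE) > 64:
            _PAIR_CACHE.clear()
        _PAIR_CACHE[n] = cached
    return cached


def _max_arc_stat(x: np.ndarray, s: float):
    """Best arc (i, j] and its T statistic for one ordered segment."""
    n = len(x)
    i_idx, j_idx, w = _pairs(n)
    S = np.concatenate([[0.0], np.cumsum(x)])
    sums = S[j_idx] - S[i_idx]
    t = np.abs(sums / w - (S[n] - sums) / (n - w)) / (s * np.sqrt(1.0 / w + 1.0 / (n - w)))
    k = int(np.argmax(t))
    return float(t[k]), (int(i_idx[k]), int(j_idx[k]))


def _max_arc_stat_batch(xs: np.ndarray, s: float) -> np.ndarray:
    """Row-wise max arc statistic for a block of permuted segments."""
    b, n = xs.shape
    i_idx, j_idx, w = _pairs(n)
    S = np.concatenate([np.zeros((b, 1)), np.cumsum(xs, axis=1)], axis=1)
    sums = S[:, j_idx] - S[:, i_idx]
    denom = s * np.sqrt(1.0 / w + 1.0 / (n - w))
    t = np.abs(sums / w - (S[:, [n]] - sums) / (n - w)) / denom
    return t.max(axis=1)


def _segment_indices(x: np.ndarray, alpha: float, n_perm: int, min_bins: int,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's ratio vector; returns [start, end) pairs."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_bins:
            out.append((lo, hi))
            return
        s = float(seg.std(ddof=1))
        if s <= 0:
            out.append((lo, hi))
            return
        t_obs, (i, j) = _max_arc_stat(seg, s)
        threshold = alpha * (n_perm + 1) - 1
        n_pairs = len(_pairs(n)[0])
        block = max(1, min(64, 20_000_000 // max(n_pairs, 1)))
        exceed = 0
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            xs = np.tile(seg, (b, 1))
            rng.permuted(xs, axis=1, out=xs)
            exceed += int(np.count_nonzero(_max_arc_stat_batch(xs, s) >= t_obs))
            done += b
            if exceed > threshold:
                break  # p cannot drop below alpha any more
        p = (exceed + 1) / (n_perm + 1)
        if p < alpha:
            for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b > a:
                    recurse(a, b)
        else:
            out.append((lo, hi))

    recurse(0, len(x))
    return sorted(out)


def _merge_short(bounds: list[tuple[int, int]], x: np.ndarray, min_bins: int):
    bounds = list(bounds)
    while len(bounds) > 1:
        lengths = [b - a for a, b in bounds]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_bins:
            break
        a, b = bounds[k]
        mean_seg = x[a:b].mean()
        left = k - 1 if k > 0 else None
        right = k + 1 if k < len(bounds) - 1 else None

        def dist(nb):
            la, lb = bounds[nb]
            return abs(x[la:lb].mean() - mean_seg)

        target = left if right is None or (left is not None and dist(left) <= dist(right)) else right
        if target < k:
            bounds[target] = (bounds[target][0], b)
        else:
            bounds[target] = (a, bounds[target][1])
        bounds.pop(k)
    return bounds


def cbs_segment(bins: pd.DataFrame, ratios: pd.Series, alpha: float = 0.01,
                n_perm: int = 1000, min_bins: int = 3,
                rng_seed: int = 0) -> list[CnaSegment]:
    """Segment median-centred log2 ratios chromosome by chromosome.

    NaN (masked) bins are dropped before segmentation; a chromosome with
    fewer than ``2 * min_bins`` usable bins comes back as one segment.
    Deterministic given ``rng_seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng_seed)
    segments: list[CnaSegment] = []
    for chrom, block in bins.groupby("chrom", sort=False):
        r = ratios.loc[block.index]
        keep = r.notna().to_numpy()
        if not keep.any():
            continue
        sub = block[keep]
        x = r.to_numpy(dtype=float)[keep]
        bounds = _segment_indices(x, alpha, n_perm, min_bins, rng)
        bounds = _merge_short(bounds, x, min_bins)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for a, b in bounds:
            mean = float(x[a:b].mean())
            segments.append(
                CnaSegment(
                    chrom=str(chrom),
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    mean_ratio=mean,
                    direction="gain" if mean >= 0 else "loss",
                    n_bins=b - a,
                )
            )
    return segments


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """min of the two mutual overlap fractions; 0 when disjoint."""
    inter = min(e1, e2) - max(s1, s2)
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1), inter / (e2 - s2))


def consensus_cna(wgs_segments: list[CnaSegment], array_calls: pd.DataFrame,
                  min_reciprocal_overlap: float = 0.5,
                  min_abs_ratio: float = 0.3) -> list[CnaSegment]:
    """Sequencing segments confirmed by a direction-matched array call.

    Keeps WGS segments with |mean ratio| >= ``min_abs_ratio`` that
    reciprocally overlap (>= threshold) at least one array call of the
    same direction; coordinates come from the WGS segment.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    kept = []
    for seg in wgs_segments:
        if abs(seg.mean_ratio) < min_abs_ratio:
            continue
        for call in array_calls.itertuples():
            if call.chrom != seg.chrom or call.direction != seg.direction:
                continue
            if reciprocal_overlap(seg.start, seg.end, int(call.start), int(call.end)) >= (
                min_reciprocal_overlap
            ):
                kept.append(replace(seg, source="consensus"))
                break
    return kept


def call_cnas(bins: pd.DataFrame, alpha: float = 0.01, n_perm: int = 1000,
              min_bins: int = 3, rng_seed: int = 0) -> list[CnaSegment]:
    """Convenience chain: GC-correct, log2-ratio, CBS on one bin table."""
    corrected = gc_correct(bins)
    ratios = log2_ratio(corrected)
    return cbs_segment(corrected, ratios, alpha, n_perm, min_bins, rng_seed)


def track_segment_ratio(segment: CnaSegment, bins_by_passage: dict[int, pd.DataFrame],
                        min_bins: int = 3, min_abs_ratio: float = 0.3) -> CnaSegment:
    """Mean centred log2 ratio of a segment at every passage, plus a clonality call.

    "clonal" when every passage clears |ratio| >= ``min_abs_ratio`` with a
    consistent sign, "passage_restricted" when only some do, "none" when
    the track never leaves the noise band.
    """
    track: dict[int, float] = {}
    for p, bins in sorted(bins_by_passage.items()):
        corrected = gc_correct(bins)
        ratios = log2_ratio(corrected)
        mids = (corrected["start"] + corrected["end"]) // 2
        inside = (
            (corrected["chrom"] == segment.chrom)
            & (mids >= segment.start)
            & (mids < segment.end)
            & ratios.notna()
        )
        if int(inside.sum()) < min_bins:
            raise ValueError(
                f"segment {segment.chrom}:{segment.start}-{segment.end} covers "
                f"{int(inside.sum())} bins at passage {p} (< {min_bins})"
            )
        track[p] = float(ratios[inside].mean())
    values = np.array(list(track.values()))
    above = np.abs(values) >= min_abs_ratio
    if above.all() and (np.sign(values) == np.sign(values[0])).all():
        label = "clonal"
    elif above.any():
        label = "passage_restricted"
    else:
        label = "none"
    tagged = replace(segment, track={"per_passage": track, "classification": label})
    return tagged
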