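"""Reduced synthetic genome model.

The analysis stages are genome-agnostic; everything here runs on a small
configurable genome (default 10 chromosomes x 10 Mb) so that end-to-end
simulations finish in seconds.  Coordinates follow the usual conventions:
1-based positions in VCF-like records, 0-based half-open intervals in
BED-like records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class GenomeModel:
    """A genome made of equally sized chromosomes.

    Parameters
    ----------
    n_chromosomes, chromosome_length
        Shape of the genome; total size is their product.
    reference_seed
        Seed of the deterministic reference sequence attached to this
        genome (see :class:`SyntheticReference`).  Part of the genome
        identity so simulator and annotator agree on base content.
    """

    n_chromosomes: int = 10
    chromosome_length: int = 10_000_000
    reference_seed: int = 7919

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("genome must have at least one chromosome of positive length")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def size(self) -> int:
        return self.n_chromosomes * self.chromosome_length

    def chrom_index(self, chrom: str) -> int:
        try:
            idx = int(chrom.removeprefix("chr")) - 1
        except ValueError as exc:
            raise ValueError(f"unknown chromosome {chrom!r}") from exc
        if not 0 <= idx < self.n_chromosomes:
            raise ValueError(f"chromosome {chrom!r} not in genome model")
        return idx

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` lies on ``chrom``."""
        try:
            self.chrom_index(chrom)
        except ValueError:
            return False
        return 1 <= pos <= self.chromosome_length

    def random_sites(self, rng: np.random.Generator, n: int) -> list[tuple[str, int]]:
        """Draw ``n`` positions uniformly over the genome (1-based)."""
        chroms = rng.integers(0, self.n_chromosomes, size=n)
        pos = rng.integers(1, self.chromosome_length + 1, size=n)
        names = self.chromosomes
        return [(names[c], int(p)) for c, p in zip(chroms, pos)]


class SyntheticReference:
    """Deterministic i.i.d. uniform ACGT reference for a :class:`GenomeModel`.

    Sequence content is a pure function of ``genome.reference_seed`` and
    the chromosome index, so any two holders of the same genome model see
    byte-identical sequence.  Chromosome arrays are materialised lazily.
    """

    def __init__(self, genome: GenomeModel):
        self.genome = genome
        self._chrom_cache: dict[int, np.ndarray] = {}

    def _chrom_array(self, idx: int) -> np.ndarray:
        arr = self._chrom_cache.get(idx)
        if arr is None:
            rng = np.random.default_rng([self.genome.reference_seed, idx])
            arr = rng.integers(0, 4, size=self.genome.chromosome_length, dtype=np.int8)
            self._chrom_cache[idx] = arr
        return arr

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end]`` (0-based half-open)."""
        if start < 0 or end > self.genome.chromosome_length or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} outside genome model")
        arr = self._chrom_array(self.genome.chrom_index(chrom))
        return "".join(BASES[i] for i in arr[start:end])

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        return self.fetch(chrom, pos - 1, pos)
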