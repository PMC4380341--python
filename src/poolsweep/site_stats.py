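"""Per-site statistics: allele counts, SNP calls, heterozygosity, subsampling.

These are the atoms every downstream statistic is built from.  Nucleotide
diversity at a site is the read-pair heterozygosity

    pi = n/(n-1) * (1 - sum_i p_i^2),   p_i = count_i / n,

i.e. the fraction of mismatching unordered read pairs, which generalises to
any number of alleles.  Reads are treated as sampled chromosomes ("read-based"
mode): double-sampling of the same pool chromosome is not corrected for, so a
small negative bias relative to the pool's true diversity is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigError, DataError
from .io_formats import PileupColumn

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SiteCounts:
    """Allele read counts at one genomic position of one pool."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    def __post_init__(self) -> None:
        self.counts = {b: int(self.counts.get(b, 0)) for b in BASES}
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[b] for b in BASES], dtype=np.int64)


@dataclass(frozen=True)
class SnpCallConfig:
    """Thresholds for SNP calling and site qualification.

    The window scan runs with (min_count=2, min_coverage=2, max_coverage=75,
    min_base_quality=25); the coding scan with (min_count=4, min_coverage=8,
    max_coverage=75).  max_coverage should be about twice the mean read depth
    to suppress SNP calls inside collapsed repeats.
    """

    min_count: int = 2
    min_coverage: int = 2
    max_coverage: int = 75
    min_base_quality: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ConfigError("require 0 < min_coverage <= max_coverage")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.min_base_quality < 0:
            raise ConfigError("min_base_quality must be >= 0")


def count_alleles(col: PileupColumn) -> SiteCounts:
    """Tally A/C/G/T in a decoded column; N carries no allelic information."""
    counts = {b: 0 for b in BASES}
    for b in col.bases:
        if b in counts:
            counts[b] += 1
    return SiteCounts(col.chrom, col.pos, col.ref_base, counts)


def is_snp(site: SiteCounts, cfg: SnpCallConfig) -> bool:
    """True iff coverage is in range and >= 2 alleles reach min_count."""
    cov = site.coverage
    if not (cfg.min_coverage <= cov <= cfg.max_coverage):
        return False
    return sum(1 for c in site.counts.values() if c >= cfg.min_count) >= 2


def pi_site(site: SiteCounts) -> float | None:
    """Read-pair heterozygosity; None (undefined) below 2 reads."""
    n = site.coverage
    if n < 2:
        return None
    same = sum(c * (c - 1) for c in site.counts.values())
    return 1.0 - same / (n * (n - 1))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def subsample_counts(site: SiteCounts, target: int, rng) -> SiteCounts | None:
    """Draw exactly ``target`` reads without replacement (hypergeometric).

    Returns None when coverage is below the target (site excluded).  ``rng``
    is a numpy Generator or a seed; the draw is deterministic given it.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if site.coverage < target:
        return None
    if site.coverage == target:
        return SiteCounts(site.chrom, site.pos, site.ref_base, dict(site.counts))
    colors = site.as_array()
    drawn = _as_rng(rng).multivariate_hypergeometric(colors, target)
    return SiteCounts(
        site.chrom, site.pos, site.ref_base, dict(zip(BASES, (int(x) for x in drawn)))
    )


@dataclass
class SiteMatrix:
    """Columnar per-chromosome site store: positions plus a (n, 4) count matrix.

    This is the vectorised counterpart of a stream of :class:`SiteCounts`;
    window scans and the simulator use it so chromosome-scale inputs stay
    cheap.  ``ref_codes`` maps each site's reference base to 0..3 (A,C,G,T)
    or -1 for N/unknown.
    """

    chrom: str
    positions: np.ndarray  # (n,) int64, 1-based, strictly increasing
    counts: np.ndarray  # (n, 4) integer, columns A,C,G,T
    ref_codes: np.ndarray | None = None  # (n,) int8 or None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.positions.size, 4):
            raise ValueError("counts must be (n_sites, 4)")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            bad = int(self.positions[np.argmin(np.diff(self.positions))])
            raise DataError(f"positions not strictly increasing near {self.chrom}:{bad}")

    def __len__(self) -> int:
        return self.positions.size

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def pi_values(self) -> np.ndarray:
        """Per-site read-pair heterozygosity; 0 where coverage < 2."""
        n = self.coverage.astype(np.float64)
        same = (self.counts * (self.counts - 1)).sum(axis=1).astype(np.float64)
        denom = n * (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = 1.0 - same / denom
        pi[denom <= 0] = 0.0
        return pi

    def qualifying_mask(self, cfg: SnpCallConfig) -> np.ndarray:
        cov = self.coverage
        return (cov >= cfg.min_coverage) & (cov <= cfg.max_coverage)

    def snp_mask(self, cfg: SnpCallConfig) -> np.ndarray:
        """Sites in coverage range where >= 2 alleles reach min_count."""
        second = np.partition(self.counts, 2, axis=1)[:, 2]
        return self.qualifying_mask(cfg) & (second >= cfg.min_count)

    def polymorphic_mask(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1) >= 2

    def slice_span(self, start0: int, end0: int) -> "SiteMatrix":
        """Sites whose (0-based) position falls in [start0, end0)."""
        lo = np.searchsorted(self.positions, start0 + 1)
        hi = np.searchsorted(self.positions, end0, side="right")
        return SiteMatrix(
            self.chrom,
            self.positions[lo:hi],
            self.counts[lo:hi],
            None if self.ref_codes is None else self.ref_codes[lo:hi],
        )

    def site(self, idx: int) -> SiteCounts:
        ref = "N"
        if self.ref_codes is not None and self.ref_codes[idx] >= 0:
            ref = BASES[int(self.ref_codes[idx])]
        return SiteCounts(
            self.chrom,
            int(self.positions[idx]),
            ref,
            dict(zip(BASES, (int(c) for c in self.counts[idx]))),
        )

    def iter_sites(self) -> Iterator[SiteCounts]:
        for i in range(len(self)):
            yield self.site(i)

    @classmethod
    def from_sites(cls, sites: Iterable[SiteCounts], chrom: str | None = None) -> "SiteMatrix":
        pos, rows, refs = [], [], []
        for s in sites:
            if chrom is None:
                chrom = s.chrom
            elif s.chrom != chrom:
                raise DataError(f"mixed chromosomes: {chrom} vs {s.chrom}")
            pos.append(s.pos)
            rows.append([s.counts[b] for b in BASES])
            refs.append(BASE_INDEX.get(s.ref_base, -1))
        if chrom is None:
            chrom = ""
        return cls(
            chrom,
            np.array(pos, dtype=np.int64),
            np.array(rows, dtype=np.int64).reshape(len(pos), 4),
            np.array(refs, dtype=np.int8),
        )


def matrices_from_pileup(columns: Iterable[PileupColumn]) -> dict[str, SiteMatrix]:
    """Group a decoded pileup stream into one SiteMatrix per chromosome."""
    acc: dict[str, tuple[list[int], list[tuple[int, int, int, int]], list[int]]] = {}
    for col in columns:
        pos, rows, refs = acc.setdefault(col.chrom, ([], [], []))
        b = col.bases
        pos.append(col.pos)
        rows.append((b.count("A"), b.count("C"), b.count("G"), b.count("T")))
        refs.append(BASE_INDEX.get(col.ref_base, -1))
    return {
        c: SiteMatrix(
            c,
            np.array(pos, dtype=np.int64),
            np.array(rows, dtype=np.int32).reshape(len(pos), 4),
            np.array(refs, dtype=np.int8),
        )
        for c, (pos, rows, refs) in acc.items()
    }
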