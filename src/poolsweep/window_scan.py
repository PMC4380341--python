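"""Sliding-window nucleotide diversity and Tajima's D along chromosome arms.

The scan walks fixed windows anchored at multiples of the step (default
geometry: 500-kb windows, 100-kb step).  Window pi is the mean per-site
read-pair heterozygosity over coverage-qualifying sites; only sites passing
the SNP rule (min_count validated alleles) contribute to the numerator, so
isolated sequencing-error reads do not inflate diversity.  Windows with no
SNPs, or with too little coverage, are reported as undefined ("na").

Tajima's D is computed per window after subsampling every usable site to a
uniform coverage n (default 30) without replacement, so the Tajima (1989)
constants apply at a single sample size:

    D = (pi_w - S/a1) / sqrt(e1*S + e2*S*(S-1))

with pi_w the window sum of per-site heterozygosity over the subsampled
sites and S the number of sites still polymorphic after subsampling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import DataError
from .io_formats import GeneModel
from .site_stats import SiteCounts, SiteMatrix, SnpCallConfig

DEFAULT_WINDOW = 500_000
DEFAULT_STEP = 100_000
DEFAULT_UNIFORM_N = 30
DEFAULT_MIN_COVERED_FRACTION = 0.6


@dataclass
class WindowStat:
    """One sliding-window record; ``value`` is None when reported "na"."""

    chrom: str
    start: int  # 0-based half-open span
    end: int
    snp_count: int
    covered_fraction: float
    value: float | None
    metric: str  # "pi" or "tajimas_d"


@dataclass(frozen=True)
class TajimaConstants:
    """The Tajima (1989) normalisation constants for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Evaluate the Tajima constants; n must be >= 4 for stable variance terms."""
    if n < 4:
        raise ValueError(f"Tajima constants need n >= 4, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d_from_summaries(pi_sum: float, s: int, consts: TajimaConstants) -> float | None:
    """D from a window's heterozygosity sum and segregating-site count."""
    if s == 0:
        return None
    var = consts.e1 * s + consts.e2 * s * (s - 1)
    return (pi_sum - s / consts.a1) / np.sqrt(var)


def _as_matrices(sites) -> dict[str, SiteMatrix]:
    if isinstance(sites, SiteMatrix):
        return {sites.chrom: sites}
    if isinstance(sites, Mapping):
        return dict(sites)
    acc: dict[str, list[SiteCounts]] = {}
    last: tuple[str, int] | None = None
    for s in sites:
        if last is not None and s.chrom == last[0] and s.pos <= last[1]:
            raise DataError(f"input sites not sorted at {s.chrom}:{s.pos}")
        last = (s.chrom, s.pos)
        acc.setdefault(s.chrom, []).append(s)
    return {c: SiteMatrix.from_sites(v, c) for c, v in acc.items()}


def window_grid(chrom_length: int, window: int, step: int) -> list[tuple[int, int]]:
    """0-based half-open windows anchored at multiples of the step."""
    if window < step:
        raise ValueError("window must be >= step")
    spans = []
    for start in range(0, max(chrom_length, 1), step):
        spans.append((start, min(start + window, chrom_length)))
    return spans


def _chrom_length(mat: SiteMatrix, chrom_lengths, window: int) -> int:
    if chrom_lengths and mat.chrom in chrom_lengths:
        return int(chrom_lengths[mat.chrom])
    if len(mat) == 0:
        return window
    return int(mat.positions[-1])


def scan_pi(
    sites,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    cfg: SnpCallConfig = SnpCallConfig(),
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[WindowStat]:
    """Sliding-window nucleotide diversity.

    ``sites`` is a SiteMatrix, a mapping chrom -> SiteMatrix, or a sorted
    iterable of SiteCounts.  Window value = sum of per-site pi over SNP
    sites / number of coverage-qualifying sites; covered_fraction =
    qualifying sites / window length.  Zero SNPs or covered_fraction below
    the floor -> "na".
    """
    mats = _as_matrices(sites)
    out: list[WindowStat] = []
    for chrom in sorted(mats):
        out.extend(
            _scan_pi_chrom(mats[chrom], window, step, cfg, min_covered_fraction, chrom_lengths)
        )
    return out


def _scan_pi_chrom(mat, window, step, cfg, min_covered_fraction, chrom_lengths):
    length = _chrom_length(mat, chrom_lengths, window)
    qual = mat.qualifying_mask(cfg)
    snp = mat.snp_mask(cfg)
    pi = mat.pi_values() * snp
    cum_qual = np.concatenate([[0], np.cumsum(qual)])
    cum_snp = np.concatenate([[0], np.cumsum(snp)])
    cum_pi = np.concatenate([[0.0], np.cumsum(pi)])
    out = []
    for start, end in window_grid(length, window, step):
        lo = np.searchsorted(mat.positions, start + 1)
        hi = np.searchsorted(mat.positions, end, side="right")
        n_qual = int(cum_qual[hi] - cum_qual[lo])
        n_snp = int(cum_snp[hi] - cum_snp[lo])
        pi_sum = float(cum_pi[hi] - cum_pi[lo])
        frac = n_qual / (end - start)
        if n_snp == 0 or frac < min_covered_fraction:
            value = None
        else:
            value = pi_sum / n_qual
        out.append(WindowStat(mat.chrom, start, end, n_snp, frac, value, "pi"))
    return out


def _window_rng(seed: int, chrom: str, index: int) -> np.random.Generator:
    # stable per-(chrom, window) stream: reruns are bit-identical, windows independent
    entropy = [int(seed), zlib.crc32(chrom.encode()), int(index)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _subsampled_window_summaries(
    counts: np.ndarray, uniform_n: int, rng: np.random.Generator
) -> tuple[float, int]:
    """Subsample each (polymorphic, coverage >= n) row to n; return (pi_w, S)."""
    pi_sum = 0.0
    s = 0
    scale = 1.0 / (uniform_n * (uniform_n - 1))
    for row in counts:
        sub = rng.multivariate_hypergeometric(row, uniform_n)
        if np.count_nonzero(sub) < 2:
            continue
        s += 1
        pi_sum += 1.0 - float((sub * (sub - 1)).sum()) * scale
    return pi_sum, s


def scan_tajimas_d(
    sites,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    cfg: SnpCallConfig = SnpCallConfig(),
    uniform_n: int = DEFAULT_UNIFORM_N,
    rng_seed: int = 0,
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[WindowStat]:
    """Sliding-window Tajima's D at uniform coverage ``uniform_n``.

    Usable sites have coverage within the config range and >= uniform_n;
    each is subsampled to uniform_n reads without replacement (seeded per
    chrom and window index from ``rng_seed``).  S counts sites polymorphic
    after subsampling; S == 0 -> "na".
    """
    consts = tajima_constants(uniform_n)
    mats = _as_matrices(sites)
    out: list[WindowStat] = []
    for chrom in sorted(mats):
        mat = mats[chrom]
        length = _chrom_length(mat, chrom_lengths, window)
        cov = mat.coverage
        usable = (
            (cov >= max(cfg.min_coverage, uniform_n)) & (cov <= cfg.max_coverage)
        )
        candidate = usable & mat.polymorphic_mask()
        cum_use = np.concatenate([[0], np.cumsum(usable)])
        for w_idx, (start, end) in enumerate(window_grid(length, window, step)):
            lo = np.searchsorted(mat.positions, start + 1)
            hi = np.searchsorted(mat.positions, end, side="right")
            n_use = int(cum_use[hi] - cum_use[lo])
            frac = n_use / (end - start)
            cand = np.flatnonzero(candidate[lo:hi]) + lo
            rng = _window_rng(rng_seed, chrom, w_idx)
            pi_w, s = _subsampled_window_summaries(mat.counts[cand], uniform_n, rng)
            if s == 0 or frac < min_covered_fraction:
                value = None
            else:
                value = float(tajimas_d_from_summaries(pi_w, s, consts))
            out.append(WindowStat(chrom, start, end, s, frac, value, "tajimas_d"))
    return out


def chrom_mean(stats: Iterable[WindowStat]) -> float | None:
    """Arithmetic mean of defined window values on a single chromosome."""
    stats = list(stats)
    if not stats:
        return None
    chroms = {w.chrom for w in stats}
    if len(chroms) > 1:
        raise DataError(f"chrom_mean over mixed chromosomes: {sorted(chroms)}")
    metrics = {w.metric for w in stats}
    if len(metrics) > 1:
        raise DataError(f"chrom_mean over mixed metrics: {sorted(metrics)}")
    values = [w.value for w in stats if w.value is not None]
    if not values:
        return None
    return float(np.mean(values))


def gene_d(
    sites,
    genes: Iterable[GeneModel],
    cfg: SnpCallConfig = SnpCallConfig(),
    uniform_n: int = DEFAULT_UNIFORM_N,
    rng_seed: int = 0,
) -> dict[str, float | None]:
    """Gene-by-gene Tajima's D over each gene's concatenated CDS.

    The gene's CDS plays the role of the window: usable CDS sites are
    subsampled to ``uniform_n`` and the window formula applies unchanged.
    Genes on chromosomes absent from ``sites``, or without polymorphism,
    map to None.
    """
    consts = tajima_constants(uniform_n)
    mats = _as_matrices(sites)
    out: dict[str, float | None] = {}
    for gene in genes:
        mat = mats.get(gene.chrom)
        if mat is None:
            out[gene.gene_id] = None
            continue
        cov = mat.coverage
        usable = (cov >= max(cfg.min_coverage, uniform_n)) & (cov <= cfg.max_coverage)
        candidate = usable & mat.polymorphic_mask()
        idx: list[np.ndarray] = []
        for s1, e1 in gene.cds_intervals:
            lo = np.searchsorted(mat.positions, s1)
            hi = np.searchsorted(mat.positions, e1, side="right")
            idx.append(np.flatnonzero(candidate[lo:hi]) + lo)
        rows = np.concatenate(idx) if idx else np.array([], dtype=int)
        rng = _window_rng(rng_seed, gene.gene_id, 0)
        pi_w, s = _subsampled_window_summaries(mat.counts[rows], uniform_n, rng)
        out[gene.gene_id] = (
            None if s == 0 else float(tajimas_d_from_summaries(pi_w, s, consts))
        )
    return out
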