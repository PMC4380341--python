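"""Ground-truthed synthetic Pool-seq inputs: reference, genes, two pooled pileups.

The generator emulates the data a pooled resequencing experiment produces
for two lines of common origin: a neutral control pool and a selected pool
carrying (a) contiguous sweep regions of strongly reduced diversity and
(b) genes with an implanted excess of nonsynonymous polymorphism.

The neutral model is intentionally site-independent: polymorphic sites are
placed i.i.d. with per-site probability theta * a1(pool_size) (the Watterson
expectation of segregation) and each site's allele frequency is drawn from
the neutral folded frequency spectrum P(i) proportional to 1/i + 1/(n-i).
Reads are then sampled binomially from the population frequency at
Poisson-distributed coverage, with a uniform base-error process.  Linkage,
demography and pool-chromosome resampling are deliberately absent; see the
methods note for what that implies for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .coding_selection import KIND_NONSYN, KIND_SYN, classify_codon_change, count_syn_nonsyn_sites
from .errors import ConfigError
from .io_formats import GeneModel, ReferenceGenome
from .site_stats import BASES, SiteMatrix

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {ord(b): i for i, b in enumerate(BASES)}


def harmonic(n: int) -> float:
    """a1(n) = sum_{i=1}^{n-1} 1/i, the Watterson normaliser."""
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class SiteVariant:
    """One polymorphic site of the truth: alternate-allele frequency and identity.

    ``alt_pick`` indexes the alternate among the 3 non-reference bases in
    A<C<G<T order, so the variant is meaningful for any reference base.
    """

    freq: float
    alt_pick: int

    def alt_code(self, ref_code: int) -> int:
        return self.alt_pick + (self.alt_pick >= ref_code)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults: two 5-Mbp chromosome arms at theta = 0.002 (inside the
    arm-level band seen in fly Pool-seq data), Poisson coverage with mean
    60, a pool of 100 chromosomes, and one 1-Mbp 200-fold sweep on 2L
    (wide enough that whole 500-kb scan windows sit inside it, as the
    flagged runs of real scans imply).  ``error_rate`` is the residual
    per-base substitution rate after quality filtering and strict mapping
    (5e-5); the rendered quality strings are drawn independently around
    ``qual_mean`` and are not coupled to the error process.  Genes are
    tiled on 2R, outside the sweep.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"2L": 5_000_000, "2R": 5_000_000}
    )
    theta: float = 0.002
    coverage_mean: float = 60.0
    coverage_dist: str = "poisson"
    pool_size: int = 100
    error_rate: float = 5e-5
    qual_mean: int = 38
    sweeps: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("2L", 2_000_000, 3_000_000, 200.0)]
    )
    selected_genes: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("g001", "nonsyn_excess"),
            ("g002", "nonsyn_excess"),
            ("g003", "nonsyn_excess"),
            ("g004", "nonsyn_excess"),
            ("g005", "syn_only"),
            ("g006", "syn_only"),
            ("g007", "syn_only"),
            ("g008", "syn_only"),
        ]
    )
    gene_count: int = 12
    gene_length: int = 900
    intergenic_gap: int = 5_100
    gene_chrom: str = "2R"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if not 0 <= self.error_rate < 0.01:
            raise ConfigError("error_rate must be in [0, 0.01)")
        if self.pool_size < 2:
            raise ConfigError("pool_size must be >= 2")
        if self.gene_length % 3 != 0:
            raise ConfigError("gene_length must be divisible by 3")
        for chrom, start, end, factor in self.sweeps:
            if factor < 1:
                raise ConfigError("sweep reduction_factor must be >= 1")
            if chrom in self.chrom_lengths and not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ConfigError(f"sweep region outside chromosome {chrom}")
        if self.coverage_dist != "poisson":
            raise ConfigError("only poisson coverage is supported")


@dataclass
class SimTruth:
    """Ground truth emitted with the simulated data."""

    sweeps: list[tuple[str, int, int, float]]  # chrom, start0, end0, factor
    gene_modes: dict[str, str]
    frequencies: dict[str, dict[str, dict[int, SiteVariant]]]  # pool -> chrom -> map


FreqMap = dict[int, SiteVariant]


def sample_site_frequencies(length: int, theta: float, pool_size: int, rng) -> FreqMap:
    """Place neutral polymorphic sites along ``length`` bp.

    Per-site segregation probability is theta * a1(pool_size); frequencies
    are i/pool_size with i drawn from weights 1/i + 1/(pool_size - i).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if theta == 0:
        return {}
    p_poly = theta * harmonic(pool_size)
    if p_poly >= 1:
        raise ConfigError("theta * a1(pool_size) must be < 1")
    n_poly = rng.binomial(length, p_poly)
    positions = rng.choice(length, size=n_poly, replace=False) + 1
    i = np.arange(1, pool_size)
    w = 1.0 / i + 1.0 / (pool_size - i)
    counts = rng.choice(i, size=n_poly, p=w / w.sum())
    picks = rng.integers(0, 3, size=n_poly)
    return {
        int(pos): SiteVariant(float(c) / pool_size, int(k))
        for pos, c, k in zip(positions, counts, picks)
    }


def implant_sweep(freqs: FreqMap, region: tuple[int, int], reduction_factor: float, rng) -> FreqMap:
    """Thin diversity inside a (0-based half-open) region by the given factor.

    Each polymorphic site is retained with probability 1/factor, otherwise
    fixed for its major allele: minor-frequency sites vanish, majority-
    alternate sites become monomorphic for the alternate (frequency 1.0),
    which is exactly the fixed-vs-segregating signal downstream detectors
    look for.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    start0, end0 = region
    out: FreqMap = {}
    keep_p = 1.0 / reduction_factor
    for pos, var in freqs.items():
        if not (start0 < pos <= end0):
            out[pos] = var
            continue
        if rng.random() < keep_p:
            out[pos] = var
        elif var.freq > 0.5:
            out[pos] = replace(var, freq=1.0)
        # else: fixed for the (reference) major allele -> drops out
    return out


def clear_region(freqs: FreqMap, intervals: list[tuple[int, int]]) -> FreqMap:
    """Remove polymorphism within 1-based inclusive intervals (gene CDS)."""
    out = dict(freqs)
    for s1, e1 in intervals:
        for pos in range(s1, e1 + 1):
            out.pop(pos, None)
    return out


def implant_gene_variants(
    freqs: FreqMap, gene: GeneModel, ref: ReferenceGenome, mode: str, rng
) -> FreqMap:
    """Constrain a gene's CDS polymorphism to a selection mode.

    ``nonsyn_excess`` clears background CDS variation and implants enough
    nonsynonymous SNPs (plus a few synonymous ones, so the ratio is defined)
    that piN/piS lands well above 1; ``syn_only`` implants synonymous SNPs
    only; ``neutral`` leaves the background untouched.  Implanted variants
    sit at population frequency 0.5 and are verified through the codon
    classifier at build time.
    """
    if mode == "neutral":
        return freqs
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = clear_region(freqs, gene.cds_intervals)
    syn_choices: list[tuple[int, int]] = []  # (pos, alt_code)
    nonsyn_choices: list[tuple[int, int]] = []
    for pos in gene.cds_positions():
        ref_code = _CODE_OF.get(ord(ref.base(gene.chrom, pos)))
        if ref_code is None:
            continue
        for alt_code in range(4):
            if alt_code == ref_code:
                continue
            kind = classify_codon_change(gene, ref, pos, BASES[alt_code]).kind
            if kind == KIND_SYN:
                syn_choices.append((pos, alt_code))
            elif kind == KIND_NONSYN:
                nonsyn_choices.append((pos, alt_code))
    n_sites, s_sites = count_syn_nonsyn_sites(gene, ref)
    if mode == "nonsyn_excess":
        k_syn = 3
        k_nonsyn = 6 * math.ceil(n_sites / max(s_sites, 1.0))
        picks = _pick_variants(syn_choices, k_syn, rng) + _pick_variants(
            nonsyn_choices, k_nonsyn, rng
        )
    elif mode == "syn_only":
        picks = _pick_variants(syn_choices, 3, rng)
    else:
        raise ConfigError(f"unknown gene selection mode {mode!r}")
    for pos, alt_code in picks:
        ref_code = _CODE_OF[ord(ref.base(gene.chrom, pos))]
        alt_pick = alt_code - (alt_code > ref_code)
        out[pos] = SiteVariant(0.5, int(alt_pick))
    return out


def _pick_variants(choices: list[tuple[int, int]], k: int, rng) -> list[tuple[int, int]]:
    # at most one variant per position
    by_pos: dict[int, list[int]] = {}
    for pos, alt in choices:
        by_pos.setdefault(pos, []).append(alt)
    positions = sorted(by_pos)
    if len(positions) < k:
        raise ConfigError(f"gene too short to implant {k} variants")
    chosen = rng.choice(len(positions), size=k, replace=False)
    out = []
    for ci in sorted(int(c) for c in chosen):
        pos = positions[ci]
        alts = by_pos[pos]
        out.append((pos, alts[int(rng.integers(0, len(alts)))]))
    return out


def reference_codes(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 codes (A,C,G,T), -1 for anything else."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(raw.size, -1, dtype=np.int8)
    for byte, code in _CODE_OF.items():
        codes[raw == byte] = code
    return codes


def build_reference(chrom_lengths: Mapping[str, int], rng) -> dict[str, str]:
    """Uniform-random A/C/G/T reference sequences."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for chrom in sorted(chrom_lengths):
        codes = rng.integers(0, 4, size=int(chrom_lengths[chrom]))
        out[chrom] = _BASE_BYTES[codes].tobytes().decode()
    return out


def _inject_errors(counts: np.ndarray, rng: np.random.Generator, error_rate: float) -> None:
    """Flip read bases to a uniform other base with prob error_rate, in place.

    Processed in rounds: each round picks at most one erroring read per
    affected site, with the source allele drawn proportionally to current
    counts, so counts never go negative.
    """
    cov = counts.sum(axis=1)
    rem = rng.binomial(cov, error_rate)
    while True:
        active = np.flatnonzero(rem > 0)
        if active.size == 0:
            return
        sub = counts[active].astype(np.float64)
        csum = np.cumsum(sub, axis=1)
        u = rng.random(active.size) * csum[:, -1]
        src = (u[:, None] >= csum).sum(axis=1)
        tgt = (src + rng.integers(1, 4, size=active.size)) % 4
        counts[active, src] -= 1
        counts[active, tgt] += 1
        rem[active] -= 1


def simulate_site_counts(
    freqs: FreqMap, ref_seq: str, chrom: str, cfg: SimConfig, rng
) -> SiteMatrix:
    """Sample pooled read counts for every position of one chromosome.

    Coverage is Poisson(coverage_mean); at polymorphic sites the alternate
    read count is Binomial(coverage, frequency) (reads treated as draws from
    the population frequency, i.e. the read-based estimator's model); the
    base-error process then flips individual reads.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    length = len(ref_seq)
    ref_codes = reference_codes(ref_seq)
    cov = rng.poisson(cfg.coverage_mean, size=length).astype(np.int32)
    counts = np.zeros((length, 4), dtype=np.int32)
    valid = ref_codes >= 0
    counts[np.flatnonzero(valid), ref_codes[valid]] = cov[valid]
    if freqs:
        pos = np.array(sorted(freqs), dtype=np.int64)
        idx = pos - 1
        keep = ref_codes[idx] >= 0  # variants on an N reference base are meaningless
        pos, idx = pos[keep], idx[keep]
        fr = np.array([freqs[int(p)].freq for p in pos])
        rcodes = ref_codes[idx]
        acodes = np.array(
            [freqs[int(p)].alt_code(int(r)) for p, r in zip(pos, rcodes)], dtype=np.int64
        )
        alt_reads = rng.binomial(cov[idx], fr).astype(np.int32)
        counts[idx, rcodes] -= alt_reads
        counts[idx, acodes] += alt_reads
    if cfg.error_rate > 0:
        _inject_errors(counts, rng, cfg.error_rate)
    return SiteMatrix(chrom, np.arange(1, length + 1), counts, ref_codes)


_QUAL_SD = 3.0


def render_pileup(matrix: SiteMatrix, ref_seq: str, cfg: SimConfig, rng):
    """Yield samtools-dialect pileup lines for a simulated count matrix.

    Reference-matching reads alternate '.'/',' (strands carry no signal
    here); alternate reads are uppercase letters; qualities are Phred+33
    from a clipped normal around qual_mean.  Zero-coverage positions are
    omitted, as mpileup omits them.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for i in range(len(matrix)):
        row = matrix.counts[i]
        depth = int(row.sum())
        if depth == 0:
            continue
        pos = int(matrix.positions[i])
        ref_base = ref_seq[pos - 1]
        ref_code = int(matrix.ref_codes[i]) if matrix.ref_codes is not None else -1
        parts = []
        for code in range(4):
            c = int(row[code])
            if c == 0:
                continue
            if code == ref_code:
                half = c // 2
                parts.append("." * (c - half) + "," * half)
            else:
                parts.append(BASES[code] * c)
        quals = np.clip(np.rint(rng.normal(cfg.qual_mean, _QUAL_SD, size=depth)), 2, 40)
        qual_str = (quals.astype(np.uint8) + 33).tobytes().decode("ascii")
        yield f"{matrix.chrom}\t{pos}\t{ref_base}\t{depth}\t{''.join(parts)}\t{qual_str}"


def simulate_pileup(freqs: FreqMap, ref_seq: str, chrom: str, cfg: SimConfig, rng):
    """Sample counts and render them as a pileup stream (see render_pileup)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    matrix = simulate_site_counts(freqs, ref_seq, chrom, cfg, rng)
    yield from render_pileup(matrix, ref_seq, cfg, rng)


def make_gene_models(cfg: SimConfig, ref: ReferenceGenome) -> tuple[str, list[GeneModel]]:
    """Tile non-overlapping two-exon genes with alternating strands.

    Returns the GTF text and the corresponding gene models.  Genes are named
    g001, g002, ... in coordinate order on ``cfg.gene_chrom``.
    """
    chrom = cfg.gene_chrom
    length = cfg.chrom_lengths[chrom]
    intron = 60
    first_start = 10_001
    pitch = cfg.gene_length + intron + cfg.intergenic_gap
    if cfg.gene_count > 0 and first_start + cfg.gene_count * pitch > length:
        raise ConfigError(
            f"cannot fit {cfg.gene_count} genes of pitch {pitch} on {chrom} ({length} bp)"
        )
    genes: list[GeneModel] = []
    rows: list[str] = []
    for k in range(cfg.gene_count):
        gid = f"g{k + 1:03d}"
        strand = "+" if k % 2 == 0 else "-"
        gstart = first_start + k * pitch
        if cfg.gene_length >= 600:
            e1 = (gstart, gstart + cfg.gene_length - 301)
            e2 = (e1[1] + intron + 1, e1[1] + intron + 300)
            ivals = [e1, e2]
        else:
            ivals = [(gstart, gstart + cfg.gene_length - 1)]
        genes.append(GeneModel(gid, chrom, strand, ivals))
        exons = ivals if strand == "+" else list(reversed(ivals))
        done = 0
        for s1, e1_ in exons:
            frame = (3 - done % 3) % 3
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            rows.append(
                f"{chrom}\tpoolsweep_sim\tCDS\t{s1}\t{e1_}\t.\t{strand}\t{frame}\t{attrs}"
            )
            done += e1_ - s1 + 1
    return "\n".join(rows) + ("\n" if rows else ""), genes


@dataclass
class SimResult:
    """Everything the simulator produced, in memory plus optional files."""

    config: SimConfig
    ref: ReferenceGenome
    gtf_text: str
    genes: list[GeneModel]
    selected: dict[str, SiteMatrix]
    control: dict[str, SiteMatrix]
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def generate(cfg: SimConfig, outdir=None) -> SimResult:
    """Run the full generator: reference, genes, truth, and both pools.

    Both pools share one ancestral frequency map per chromosome (common
    origin); the selected pool additionally carries the configured sweeps
    and per-gene selection modes.  Deterministic given ``cfg.seed``; when
    ``outdir`` is given, FASTA/GTF/pileup/truth files are also written.
    """
    ss = np.random.SeedSequence(cfg.seed)
    (ss_ref, ss_freq, ss_sweep, ss_gene, ss_sel, ss_con, ss_render) = ss.spawn(7)
    ref = ReferenceGenome(build_reference(cfg.chrom_lengths, np.random.default_rng(ss_ref)))
    gtf_text, genes = make_gene_models(cfg, ref)

    freq_rngs = {c: np.random.default_rng(s) for c, s in
                 zip(sorted(cfg.chrom_lengths), ss_freq.spawn(len(cfg.chrom_lengths)))}
    ancestral = {
        chrom: sample_site_frequencies(
            cfg.chrom_lengths[chrom], cfg.theta, cfg.pool_size, freq_rngs[chrom]
        )
        for chrom in sorted(cfg.chrom_lengths)
    }

    selected_freqs = {c: dict(m) for c, m in ancestral.items()}
    sweep_rng = np.random.default_rng(ss_sweep)
    for chrom, start0, end0, factor in cfg.sweeps:
        selected_freqs[chrom] = implant_sweep(
            selected_freqs[chrom], (start0, end0), factor, sweep_rng
        )
    gene_rng = np.random.default_rng(ss_gene)
    modes = dict(cfg.selected_genes)
    gene_by_id = {g.gene_id: g for g in genes}
    for gid, mode in sorted(modes.items()):
        if gid not in gene_by_id:
            raise ConfigError(f"selected gene {gid} not among simulated genes")
        gene = gene_by_id[gid]
        selected_freqs[gene.chrom] = implant_gene_variants(
            selected_freqs[gene.chrom], gene, ref, mode, gene_rng
        )

    truth = SimTruth(
        sweeps=list(cfg.sweeps),
        gene_modes={g.gene_id: modes.get(g.gene_id, "neutral") for g in genes},
        frequencies={"selected": selected_freqs, "control": ancestral},
    )

    pools = {}
    for name, freqs, pool_ss in (
        ("selected", selected_freqs, ss_sel),
        ("control", ancestral, ss_con),
    ):
        chrom_sss = pool_ss.spawn(len(cfg.chrom_lengths))
        pools[name] = {
            chrom: simulate_site_counts(
                freqs[chrom], ref.sequences[chrom], chrom, cfg, np.random.default_rng(s)
            )
            for chrom, s in zip(sorted(cfg.chrom_lengths), chrom_sss)
        }

    result = SimResult(cfg, ref, gtf_text, genes, pools["selected"], pools["control"], truth)
    if outdir is not None:
        result.paths = _write_outputs(result, Path(outdir), ss_render)
    return result


def _write_outputs(res: SimResult, outdir: Path, ss_render) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["ref"] = outdir / "ref.fa"
    with open(paths["ref"], "w") as fh:
        for chrom in sorted(res.ref.sequences):
            fh.write(f">{chrom}\n")
            seq = res.ref.sequences[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    paths["gtf"] = outdir / "genes.gtf"
    paths["gtf"].write_text(res.gtf_text)

    render_sss = ss_render.spawn(2)
    for (name, mats), s in zip((("selected", res.selected), ("control", res.control)), render_sss):
        path = outdir / f"{name}.pileup"
        rng = np.random.default_rng(s)
        with open(path, "w") as fh:
            for chrom in sorted(mats):
                for line in render_pileup(
                    mats[chrom], res.ref.sequences[chrom], res.config, rng
                ):
                    fh.write(line + "\n")
        paths[name] = path

    paths["truth_bed"] = outdir / "truth.bed"
    with open(paths["truth_bed"], "w") as fh:
        for chrom, start0, end0, factor in res.truth.sweeps:
            fh.write(f"{chrom}\t{start0}\t{end0}\tsweep_x{factor:g}\n")

    paths["truth_genes"] = outdir / "truth_genes.tsv"
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tmode\n")
        for g in res.genes:
            s1, e1 = g.span
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{s1}\t{e1}\t{g.strand}\t{res.truth.gene_modes[g.gene_id]}\n"
            )
    return paths
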