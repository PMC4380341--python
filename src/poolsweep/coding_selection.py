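"""Per-gene coding selection: piN/piS candidates and fixed-vs-segregating alleles.

Within-gene diversity is split into nonsynonymous (piN) and synonymous (piS)
components: each CDS SNP's per-site heterozygosity is routed by the codon
consequence of its alternate allele(s), and the two sums are normalised by
Nei-Gojobori fractional site counts (a codon position contributes f
synonymous sites, f = fraction of its 3 possible single-base changes that
leave the amino acid unchanged; changes creating a stop count as
nonsynonymous).  Genes lacking synonymous and/or nonsynonymous polymorphism
have an undefined ratio and are excluded; piN/piS > 1 flags a candidate
under directional selection.

Separately, positions monomorphic in the selected pool but still segregating
in the control pool ("fixed differences") are scanned inside sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from .errors import DataError
from .io_formats import GeneModel, ReferenceGenome
from .site_stats import BASES, SiteCounts, SiteMatrix, SnpCallConfig, is_snp, pi_site
from .sweep_calls import SweepInterval

_TABLE = CodonTable.unambiguous_dna_by_id[1]
# amino acid per codon, '*' for stops, over the full 64-codon standard code
GENETIC_CODE: dict[str, str] = {
    **_TABLE.forward_table,
    **{codon: "*" for codon in _TABLE.stop_codons},
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

KIND_SYN = "synonymous"
KIND_NONSYN = "nonsynonymous"
KIND_NONSENSE = "nonsense"
KIND_AMBIGUOUS = "ambiguous"


@dataclass
class CodonChange:
    """A single-base codon substitution and its coding consequence."""

    gene_id: str
    chrom: str
    pos: int  # 1-based genomic position of the changed base
    ref_codon: str
    alt_codon: str
    codon_index: int  # codon number within the concatenated CDS, 0-based
    kind: str


@dataclass
class GeneSelection:
    """Per-gene piN/piS summary; candidate iff the ratio is defined and > 1."""

    gene_id: str
    pi_n: float
    pi_s: float
    n_sites: float
    s_sites: float
    ratio: float | None
    candidate: bool
    n_snps_nonsyn: int = 0
    n_snps_syn: int = 0


@dataclass
class FixedDifference:
    """Allele fixed in the selected pool but segregating in the control pool."""

    chrom: str
    pos: int
    allele: str
    control_frequencies: dict[str, float]


def _cds_offset_index(gene: GeneModel) -> dict[int, int]:
    # cached on the gene: maps genomic pos -> offset in the concatenated CDS
    cache = getattr(gene, "_cds_offset_index", None)
    if cache is None:
        cache = {pos: i for i, pos in enumerate(gene.cds_positions())}
        gene._cds_offset_index = cache  # type: ignore[attr-defined]
    return cache


def classify_codon_change(
    gene: GeneModel, ref: ReferenceGenome, pos: int, alt_allele: str
) -> CodonChange:
    """Classify the codon consequence of ref->alt at a CDS position.

    The codon is read from the concatenated CDS in transcript orientation;
    for minus-strand genes both the codon and the alternate allele are
    complemented.  Codons containing N classify as ambiguous.
    """
    offsets = _cds_offset_index(gene)
    if pos not in offsets:
        raise DataError(f"position {gene.chrom}:{pos} outside CDS of {gene.gene_id}")
    if alt_allele not in "ACGT":
        raise ValueError(f"bad alternate allele {alt_allele!r}")
    ref_base = ref.base(gene.chrom, pos).upper()
    if alt_allele == ref_base:
        raise ValueError(f"alternate equals reference base at {gene.chrom}:{pos}")
    offset = offsets[pos]
    codon_index, within = divmod(offset, 3)
    cds = gene.cds_sequence(ref).upper()
    ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
    cds_alt = alt_allele if gene.strand == "+" else _COMPLEMENT[alt_allele]
    alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
    if "N" in ref_codon or cds_alt == "N":
        kind = KIND_AMBIGUOUS
    else:
        aa_ref = GENETIC_CODE[ref_codon]
        aa_alt = GENETIC_CODE[alt_codon]
        if aa_ref == aa_alt:
            kind = KIND_SYN
        elif aa_alt == "*" and aa_ref != "*":
            kind = KIND_NONSENSE
        else:
            kind = KIND_NONSYN
    return CodonChange(gene.gene_id, gene.chrom, pos, ref_codon, alt_codon, codon_index, kind)


def synonymous_fraction(codon: str, within: int) -> float:
    """Fraction of the 3 single-base changes at one codon position that are silent."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for b in BASES:
        if b == codon[within]:
            continue
        if GENETIC_CODE[codon[:within] + b + codon[within + 1 :]] == aa:
            syn += 1
    return syn / 3.0


def count_syn_nonsyn_sites(gene: GeneModel, ref: ReferenceGenome) -> tuple[float, float]:
    """Nei-Gojobori fractional site counts (n_sites, s_sites) for a gene.

    Codons containing N are skipped entirely; n_sites + s_sites equals
    3 x (number of counted codons) exactly.
    """
    cds = gene.cds_sequence(ref).upper()
    s_sites = 0.0
    n_codons = 0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        n_codons += 1
        s_sites += sum(synonymous_fraction(codon, k) for k in range(3))
    return 3.0 * n_codons - s_sites, s_sites


def _cds_snp_sites(gene: GeneModel, sites, cfg: SnpCallConfig) -> list[SiteCounts]:
    if isinstance(sites, SiteMatrix):
        mats: Mapping[str, SiteMatrix] = {sites.chrom: sites}
    elif isinstance(sites, Mapping):
        mats = sites
    else:
        mats = {}
        pool: dict[str, list[SiteCounts]] = {}
        for s in sites:
            pool.setdefault(s.chrom, []).append(s)
        mats = {c: SiteMatrix.from_sites(v, c) for c, v in pool.items()}
    mat = mats.get(gene.chrom)
    if mat is None:
        return []
    out: list[SiteCounts] = []
    for s1, e1 in gene.cds_intervals:
        sub = mat.slice_span(s1 - 1, e1)
        snp = sub.snp_mask(cfg)
        for i in np.flatnonzero(snp):
            out.append(sub.site(int(i)))
    return out


def gene_pi_n_pi_s(
    gene: GeneModel,
    ref: ReferenceGenome,
    sites,
    cfg: SnpCallConfig = SnpCallConfig(min_count=4, min_coverage=8, max_coverage=75),
) -> GeneSelection:
    """Per-gene piN and piS from the CDS SNPs of one pool.

    Each SNP's per-site heterozygosity is attributed to the synonymous or
    nonsynonymous accumulator by classifying its non-reference allele(s);
    multi-allelic sites split their heterozygosity across alternates in
    proportion to each alternate's pairwise-mismatch share, which conserves
    the total.  Nonsense changes accumulate with nonsynonymous; ambiguous
    ones are dropped.
    """
    n_sites, s_sites = count_syn_nonsyn_sites(gene, ref)
    sum_syn = sum_nonsyn = 0.0
    snps_syn = snps_nonsyn = 0
    for site in _cds_snp_sites(gene, sites, cfg):
        if not is_snp(site, cfg):
            continue
        ref_base = ref.base(gene.chrom, site.pos).upper()
        pi = pi_site(site)
        if pi is None or pi == 0.0:
            continue
        n = site.coverage
        alts = [
            b
            for b in BASES
            if b != ref_base and site.counts[b] >= cfg.min_count
        ]
        if not alts:
            continue
        weights = {b: site.counts[b] * (n - site.counts[b]) for b in alts}
        total_w = sum(weights.values())
        if total_w == 0:
            continue
        touched_syn = touched_nonsyn = False
        for b in alts:
            change = classify_codon_change(gene, ref, site.pos, b)
            share = pi * weights[b] / total_w
            if change.kind == KIND_SYN:
                sum_syn += share
                touched_syn = True
            elif change.kind in (KIND_NONSYN, KIND_NONSENSE):
                sum_nonsyn += share
                touched_nonsyn = True
        snps_syn += touched_syn
        snps_nonsyn += touched_nonsyn
    pi_n = sum_nonsyn / n_sites if n_sites > 0 else 0.0
    pi_s = sum_syn / s_sites if s_sites > 0 else 0.0
    if snps_syn >= 1 and snps_nonsyn >= 1 and pi_s > 0:
        ratio: float | None = pi_n / pi_s
    else:
        ratio = None
    return GeneSelection(
        gene.gene_id,
        pi_n,
        pi_s,
        n_sites,
        s_sites,
        ratio,
        candidate=ratio is not None and ratio > 1.0,
        n_snps_nonsyn=snps_nonsyn,
        n_snps_syn=snps_syn,
    )


def _is_monomorphic(row: np.ndarray, cfg: SnpCallConfig) -> bool:
    cov = int(row.sum())
    if not (cfg.min_coverage <= cov <= cfg.max_coverage):
        return False
    return int(np.count_nonzero(row)) == 1


def detect_fixed_differences(
    selected: SiteMatrix,
    control: SiteMatrix,
    region: tuple[str, int, int],
    cfg_selected: SnpCallConfig = SnpCallConfig(),
    cfg_control: SnpCallConfig = SnpCallConfig(min_count=4, min_coverage=8, max_coverage=75),
) -> list[FixedDifference]:
    """Scan a region for alleles fixed in the selected pool, variable in control.

    ``region`` is (chrom, start, end), 0-based half-open.  Positions covered
    in only one pool are skipped.  Emits the fixed allele and the control
    pool's allele-frequency map.
    """
    chrom, start0, end0 = region
    if selected.chrom != chrom or control.chrom != chrom:
        raise DataError(f"region chromosome {chrom} does not match site matrices")
    sel = selected.slice_span(start0, end0)
    con = control.slice_span(start0, end0)
    con_index = {int(p): i for i, p in enumerate(con.positions)}
    out: list[FixedDifference] = []
    for i, pos in enumerate(sel.positions):
        j = con_index.get(int(pos))
        if j is None:
            continue
        row = sel.counts[i]
        if not _is_monomorphic(row, cfg_selected):
            continue
        con_site = con.site(j)
        if not is_snp(con_site, cfg_control):
            continue
        allele = BASES[int(np.argmax(row))]
        cov = con_site.coverage
        freqs = {b: c / cov for b, c in con_site.counts.items() if c > 0}
        out.append(FixedDifference(chrom, int(pos), allele, freqs))
    return out


def genes_in_intervals(
    genes: Iterable[GeneModel], intervals: Iterable[SweepInterval]
) -> dict[int, list[str]]:
    """Assign genes to sweep intervals by >= 1 bp overlap of the CDS span.

    Returns interval id -> sorted gene ids; ids must be unique in the input
    (call per tier).  Every interval appears in the result, possibly empty.
    """
    intervals = list(intervals)
    ids = [iv.id for iv in intervals]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate interval ids; assign genes per tier")
    trees: dict[str, IntervalTree] = {}
    out: dict[int, list[str]] = {iv.id: [] for iv in intervals}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.id)
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        g_start, g_end = gene.span  # 1-based inclusive -> 0-based half-open
        for hit in tree.overlap(g_start - 1, g_end):
            out[hit.data].append(gene.gene_id)
    return {k: sorted(v) for k, v in out.items()}
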