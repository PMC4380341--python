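"""Readers and writers for the pipeline's boundary formats.

Inputs are the samtools 6-column text pileup (one pool per file), a reference
genome in FASTA, and gene models in GTF 2.2.  Outputs are plain TSV tables.
Genomic coordinates are 1-based in pileup/GTF files and converted to 0-based
half-open spans only inside window arithmetic; the types below keep the
1-based convention of their source format and say so per field.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import gffutils
import numpy as np
from Bio import SeqIO

from .errors import ConfigError, DataError, PileupParseError

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PileupColumn:
    """One decoded pileup column: the reads covering a single position.

    ``bases`` holds uppercase read bases (strand-merged, markers and indels
    stripped, deletion placeholders removed); ``quals`` the matching Phred
    base qualities.  ``len(bases) == len(quals)`` always.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals length mismatch")
        if self.pos < 1:
            raise ValueError("pileup positions are 1-based")


@dataclass
class GeneModel:
    """A gene's coding span: ordered, non-overlapping CDS intervals.

    ``cds_intervals`` are 1-based inclusive [start, end] spans in genomic
    order; minus-strand genes keep genomic coordinates and record the strand,
    so codon extraction walks the intervals in reverse and complements.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        ivals = sorted(self.cds_intervals)
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in gene {self.gene_id}")
        self.cds_intervals = ivals

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (1-based inclusive) from first to last CDS base."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic positions (1-based) of CDS bases in transcript 5'→3' order."""
        if self.strand == "+":
            return [p for s, e in self.cds_intervals for p in range(s, e + 1)]
        return [p for s, e in reversed(self.cds_intervals) for p in range(e, s - 1, -1)]

    def cds_sequence(self, ref: "ReferenceGenome") -> str:
        """Coding sequence in transcript orientation (minus strand: revcomp)."""
        parts = [ref.fetch(self.chrom, s - 1, e) for s, e in self.cds_intervals]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class ReferenceGenome:
    """In-memory reference: sequence per chromosome plus an analysis whitelist.

    The whitelist is the set of chromosomes the scan runs on; for the fly
    genome this excludes the Y chromosome, the mitochondrial genome and
    chromosome four.
    """

    sequences: dict[str, str]
    included_chroms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.included_chroms:
            self.included_chroms = frozenset(self.sequences)
        missing = self.included_chroms - set(self.sequences)
        if missing:
            raise ConfigError(f"whitelisted chroms absent from reference: {sorted(missing)}")

    @classmethod
    def from_fasta(cls, path, included_chroms: Iterable[str] | None = None) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        wl = frozenset(included_chroms) if included_chroms else frozenset(seqs)
        return cls(seqs, wl)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence of the 0-based half-open span [start0, end0)."""
        return self.sequences[chrom][start0:end0]

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


@dataclass
class ParseStats:
    """Counters filled while streaming a pileup file."""

    n_columns: int = 0
    n_skipped_chrom: int = 0
    n_malformed: int = 0


def decode_pileup_bases(ref_base: str, base_str: str) -> list[str]:
    """Decode an mpileup base string into one symbol per read.

    Returns uppercase bases; deletion/skip placeholders come back as '*' so
    the caller can pair every read with its quality character before
    dropping them.  Read-start markers ('^' plus the mapping-quality char),
    read-end markers ('$') and '+N/-N' indel suffixes are consumed in place;
    none of them carries a base quality.
    """
    ref = ref_base.upper()
    out: list[str] = []
    i, n = 0, len(base_str)
    while i < n:
        c = base_str[i]
        if c == "^":
            i += 2  # the char after '^' is a mapping quality, not a base
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and base_str[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"indel marker without length at offset {i}")
            i = j + int(base_str[i + 1 : j])
            continue
        if c in ".,":
            out.append(ref)
        elif c in "*#><":
            out.append("*")  # deletion or reference-skip placeholder
        else:
            u = c.upper()
            if u not in VALID_BASES:
                raise PileupParseError(f"unknown base code {c!r}")
            out.append(u)
        i += 1
    return out


def read_pileup(
    stream: TextIO | Iterable[str],
    min_base_quality: int = 0,
    whitelist: Iterable[str] | None = None,
    stats: ParseStats | None = None,
    strict: bool = True,
) -> Iterator[PileupColumn]:
    """Stream decoded, quality-filtered columns from a text pileup.

    Bases with Phred quality below ``min_base_quality`` are removed together
    with their quality; deletion placeholders are removed from coverage.
    Columns on chromosomes outside ``whitelist`` (when given) are skipped and
    counted.  A malformed column (declared depth disagreeing with the decoded
    read count) raises :class:`PileupParseError` naming chrom:pos, or is
    skipped and counted when ``strict`` is false.
    """
    wl = frozenset(whitelist) if whitelist is not None else None
    st = stats if stats is not None else ParseStats()
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        if len(fields) < 6:
            if strict:
                raise PileupParseError(f"short pileup line: {line[:60]!r}")
            st.n_malformed += 1
            continue
        chrom, pos_s, ref_base, depth_s, base_str, qual_str = fields[:6]
        if wl is not None and chrom not in wl:
            st.n_skipped_chrom += 1
            continue
        pos = int(pos_s)
        try:
            bases, quals = _decode_column(ref_base, base_str, qual_str, int(depth_s), min_base_quality)
        except PileupParseError as exc:
            if strict:
                raise PileupParseError(f"{chrom}:{pos}: {exc}") from None
            st.n_malformed += 1
            continue
        st.n_columns += 1
        yield PileupColumn(chrom, pos, ref_base.upper(), bases, quals)


_SPECIAL_RE = re.compile(r"[\^$+\-*#><]")
_NON_BASE = str.maketrans("", "", "ACGTN")


def _decode_column(
    ref_base: str, base_str: str, qual_str: str, depth: int, min_base_quality: int
) -> tuple[str, list[int]]:
    """Decode and quality-filter one column; the common marker-free case is fast."""
    ref = ref_base.upper()
    if _SPECIAL_RE.search(base_str) is None:
        decoded = base_str.upper().replace(".", ref).replace(",", ref)
        if decoded.translate(_NON_BASE):
            raise PileupParseError(f"unknown base code in {base_str[:30]!r}")
        symbols: str | list[str] = decoded
    else:
        symbols = decode_pileup_bases(ref_base, base_str)
    if len(symbols) != depth or len(symbols) != len(qual_str):
        raise PileupParseError(f"depth {depth} != decoded read count {len(symbols)}")
    quals = (np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(np.int64) - 33)
    keep_all = bool(quals.min(initial=64) >= min_base_quality) if min_base_quality else True
    if isinstance(symbols, str):
        if keep_all:
            return symbols, quals.tolist()
        keep = quals >= min_base_quality
        return (
            "".join(c for c, k in zip(symbols, keep) if k),
            quals[keep].tolist(),
        )
    bases: list[str] = []
    out_quals: list[int] = []
    for sym, q in zip(symbols, quals.tolist()):
        if sym == "*" or q < min_base_quality:
            continue
        bases.append(sym)
        out_quals.append(q)
    return "".join(bases), out_quals


def _cds_rows_by_transcript(db) -> dict[str, dict[str, list]]:
    per_gene: dict[str, dict[str, list]] = {}
    for feat in db.features_of_type("CDS"):
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes.get("transcript_id", [gid])[0]
        per_gene.setdefault(gid, {}).setdefault(tid, []).append(feat)
    return per_gene


def read_gtf(source: str | TextIO, whitelist: Iterable[str] | None = None) -> list[GeneModel]:
    """Parse CDS rows of a GTF into gene models, one transcript per gene.

    When a gene has several transcripts the one with the longest total CDS is
    kept (ties broken by transcript_id).  Genes whose CDS length is not a
    multiple of 3 are excluded with a warning, as are genes off the
    chromosome whitelist.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\t" not in text:  # a path, not GTF content
            with open(text) as fh:
                text = fh.read()
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        force=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    wl = frozenset(whitelist) if whitelist is not None else None
    genes: list[GeneModel] = []
    for gid, transcripts in sorted(_cds_rows_by_transcript(db).items()):
        tid = max(
            sorted(transcripts),
            key=lambda t: sum(f.end - f.start + 1 for f in transcripts[t]),
        )
        feats = transcripts[tid]
        chrom = feats[0].seqid
        strand = feats[0].strand
        if wl is not None and chrom not in wl:
            continue
        ivals = sorted((f.start, f.end) for f in feats)
        model = GeneModel(gid, chrom, strand, ivals)
        if model.cds_length % 3 != 0:
            warnings.warn(
                f"gene {gid}: CDS length {model.cds_length} not divisible by 3; "
                "excluded from coding analysis",
                stacklevel=2,
            )
            continue
        genes.append(model)
    return genes


WINDOW_TSV_COLUMNS = ("chrom", "window_start", "window_end", "snp_count", "covered_fraction", "value")


def write_window_tsv(records, path) -> None:
    """Write WindowStat records as TSV; undefined values print as "na"."""
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_TSV_COLUMNS) + "\n")
        for w in records:
            value = "na" if w.value is None else str(w.value)
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.snp_count}\t{w.covered_fraction!s}\t{value}\n"
            )


def read_window_tsv(path, metric: str = "pi"):
    """Round-trip reader for :func:`write_window_tsv` output."""
    from .window_scan import WindowStat  # local import: avoid cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != WINDOW_TSV_COLUMNS:
            raise DataError(f"unexpected window TSV header in {path}")
        for line in fh:
            chrom, start, end, snps, frac, value = line.rstrip("\n").split("\t")
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    snp_count=int(snps),
                    covered_fraction=float(frac),
                    value=None if value == "na" else float(value),
                    metric=metric,
                )
            )
    return out


def write_interval_tsv(intervals, path) -> None:
    """Write sweep intervals: id, chrom, start, end, tier, n_windows, min_pi."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\ttier\tn_windows\tmin_pi\n")
        for iv in intervals:
            pis = [p for _, p in iv.member_windows if p is not None]
            min_pi = str(min(pis)) if pis else "na"
            fh.write(
                f"{iv.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.tier}\t"
                f"{len(iv.member_windows)}\t{min_pi}\n"
            )


def write_interval_bed(intervals, path) -> None:
    """BED export of sweep intervals (0-based half-open, name=tier:id)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.tier}:{iv.id}\n")


def write_gene_selection_tsv(records, path) -> None:
    """Per-gene piN/piS table; undefined ratios print as "na"."""
    with open(path, "w") as fh:
        fh.write("gene_id\tpi_n\tpi_s\tn_sites\ts_sites\tratio\tcandidate\n")
        for g in records:
            ratio = "na" if g.ratio is None else str(g.ratio)
            fh.write(
                f"{g.gene_id}\t{g.pi_n!s}\t{g.pi_s!s}\t{g.n_sites!s}\t{g.s_sites!s}\t"
                f"{ratio}\t{int(g.candidate)}\n"
            )


def write_fixed_tsv(records, path) -> None:
    """Fixed-difference table: position, fixed allele, control frequencies."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele\tcontrol_frequencies\n")
        for r in records:
            freqs = ",".join(f"{b}:{f:.4f}" for b, f in sorted(r.control_frequencies.items()))
            fh.write(f"{r.chrom}\t{r.pos}\t{r.allele}\t{freqs}\n")


def open_text(source) -> TextIO:
    """Accept a path or an open text handle and return a text handle."""
    if hasattr(source, "read"):
        return source
    return open(source)


def as_lines(text: str) -> TextIO:
    return io.StringIO(text)
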