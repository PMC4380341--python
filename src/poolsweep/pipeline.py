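"""End-to-end orchestration: scan -> call -> genes-in-intervals -> piN/piS -> fixed.

A single RunConfig (loadable from YAML) drives the whole analysis with one
reproducibility seed; outputs are plain TSV files plus a run log and a JSON
manifest.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io_formats, sweep_calls, window_scan
from .coding_selection import detect_fixed_differences, gene_pi_n_pi_s, genes_in_intervals
from .errors import ConfigError, DataError
from .io_formats import ParseStats, ReferenceGenome, read_gtf, read_pileup
from .site_stats import SnpCallConfig, matrices_from_pileup

logger = logging.getLogger("poolsweep")

# chromosome names never analysed by default: sex-limited, organellar, dot
DEFAULT_EXCLUDE = frozenset(
    {"Y", "YHet", "4", "M", "MT", "mt", "chrM", "mitochondrion_genome",
     "dmel_mitochondrion_genome"}
)


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run (defaults overridable)."""

    selected_pileup: str = ""
    control_pileup: str = ""
    fasta: str = ""
    gtf: str = ""
    outdir: str = "poolsweep_out"
    # window scan
    window: int = 500_000
    step: int = 100_000
    min_cov: int = 2
    max_cov: int = 75
    min_qual: int = 25
    uniform_n: int = 30
    min_covered_fraction: float = window_scan.DEFAULT_MIN_COVERED_FRACTION
    # sweep calling
    major_fold: float = 100.0
    minor_fold: float = 90.0
    # coding (piN/piS and fixed-difference) scan
    pins_min_count: int = 4
    pins_min_cov: int = 8
    pins_max_cov: int = 75
    # chromosomes to analyse; None -> every FASTA chrom minus DEFAULT_EXCLUDE
    whitelist: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def scan_config(self) -> SnpCallConfig:
        return SnpCallConfig(2, self.min_cov, self.max_cov, self.min_qual)

    def pins_config(self) -> SnpCallConfig:
        return SnpCallConfig(
            self.pins_min_count, self.pins_min_cov, self.pins_max_cov, self.min_qual
        )


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed fan-out from the single run seed."""
    state = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(state.generate_state(1)[0])


def _resolve_whitelist(cfg: RunConfig, ref_chroms) -> frozenset[str]:
    if cfg.whitelist is not None:
        wl = frozenset(cfg.whitelist)
    else:
        wl = frozenset(ref_chroms) - DEFAULT_EXCLUDE
    if not wl:
        raise ConfigError("empty chromosome whitelist; nothing to analyse")
    return wl


def _load_pool(path, cfg: RunConfig, wl) -> dict:
    stats = ParseStats()
    with open(path) as fh:
        mats = matrices_from_pileup(
            read_pileup(fh, min_base_quality=cfg.min_qual, whitelist=wl, stats=stats)
        )
    logger.info(
        "loaded %s: %d columns, %d off-whitelist, %d malformed",
        path, stats.n_columns, stats.n_skipped_chrom, stats.n_malformed,
    )
    return mats


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns the manifest of written files."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, Path] = {"log": log_path}
    try:
        logger.info("parameters: %s", asdict(cfg))
        stage = "load reference"
        ref = ReferenceGenome.from_fasta(cfg.fasta)
        wl = _resolve_whitelist(cfg, ref.sequences)
        ref = ReferenceGenome(ref.sequences, wl)
        chrom_lengths = {c: len(ref.sequences[c]) for c in wl}

        stage = "load gene models"
        genes = read_gtf(cfg.gtf, whitelist=wl)
        logger.info("gene models kept: %d", len(genes))

        stage = "load pileups"
        pools = {
            "selected": _load_pool(cfg.selected_pileup, cfg, wl),
            "control": _load_pool(cfg.control_pileup, cfg, wl),
        }

        scan_cfg = cfg.scan_config()
        for pool, mats in pools.items():
            stage = f"pi scan ({pool})"
            pi_windows = window_scan.scan_pi(
                mats, cfg.window, cfg.step, scan_cfg,
                cfg.min_covered_fraction, chrom_lengths,
            )
            path = outdir / f"windows_pi_{pool}.tsv"
            io_formats.write_window_tsv(pi_windows, path)
            manifest[f"windows_pi_{pool}"] = path
            logger.info("%s: %d pi windows", pool, len(pi_windows))

            stage = f"tajimas_d scan ({pool})"
            d_windows = window_scan.scan_tajimas_d(
                mats, cfg.window, cfg.step, scan_cfg, cfg.uniform_n,
                derive_seed(cfg.seed, f"d_{pool}"),
                cfg.min_covered_fraction, chrom_lengths,
            )
            path = outdir / f"windows_d_{pool}.tsv"
            io_formats.write_window_tsv(d_windows, path)
            manifest[f"windows_d_{pool}"] = path

        stage = "sweep calling"
        pi_selected = io_formats.read_window_tsv(manifest["windows_pi_selected"])
        intervals = sweep_calls.call_sweeps(
            pi_selected, cfg.step, cfg.major_fold, cfg.minor_fold
        )
        path = outdir / "intervals.tsv"
        io_formats.write_interval_tsv(intervals, path)
        manifest["intervals"] = path
        io_formats.write_interval_bed(intervals, outdir / "intervals.bed")
        manifest["intervals_bed"] = outdir / "intervals.bed"
        logger.info(
            "intervals: %d major, %d minor",
            sum(iv.tier == "major" for iv in intervals),
            sum(iv.tier == "minor" for iv in intervals),
        )

        stage = "gene-interval assignment"
        path = outdir / "interval_genes.tsv"
        with open(path, "w") as fh:
            fh.write("tier\tinterval_id\tgene_id\n")
            for tier in ("major", "minor"):
                tier_ivs = [iv for iv in intervals if iv.tier == tier]
                for iv_id, gids in sorted(genes_in_intervals(genes, tier_ivs).items()):
                    for gid in gids:
                        fh.write(f"{tier}\t{iv_id}\t{gid}\n")
        manifest["interval_genes"] = path

        stage = "piN/piS"
        pins_cfg = cfg.pins_config()
        selections = [
            gene_pi_n_pi_s(g, ref, pools["selected"], pins_cfg) for g in genes
        ]
        path = outdir / "gene_selection.tsv"
        io_formats.write_gene_selection_tsv(selections, path)
        manifest["gene_selection"] = path
        logger.info("candidate genes: %d / %d", sum(s.candidate for s in selections), len(selections))

        stage = "fixed differences"
        fixed = []
        for iv in intervals:
            if iv.tier != "major":
                continue
            sel = pools["selected"].get(iv.chrom)
            con = pools["control"].get(iv.chrom)
            if sel is None or con is None:
                continue
            fixed.extend(
                detect_fixed_differences(
                    sel, con, (iv.chrom, iv.start, iv.end), pins_cfg, pins_cfg
                )
            )
        path = outdir / "fixed_differences.tsv"
        io_formats.write_fixed_tsv(fixed, path)
        manifest["fixed_differences"] = path
        logger.info("fixed differences: %d", len(fixed))

        stage = "manifest"
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps({k: str(v) for k, v in sorted(manifest.items())}, indent=2) + "\n"
        )
        manifest["manifest"] = manifest_path
    except (ConfigError,):
        raise
    except DataError as exc:
        raise DataError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
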