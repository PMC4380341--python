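"""Bundled example tables from a published genome scan.

Two small reference tables accompany the package, transcribed from a
published Pool-seq selective-sweep scan of the DDT-resistant *Drosophila
melanogaster* strain 91-R versus its susceptible control 91-C:

* the 100-kb window spans (with their window diversity) that passed the
  >= 100-fold reduction cutoff, and
* the chromosome-arm mean diversity of the selected strain.

They make the interval-merging and fold-reduction machinery runnable on
real published coordinates without any sequence download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sweep_calls import FlaggedWindow, TIER_MAJOR


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("poolsweep") / "examples" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_ddt_sweep_windows() -> pd.DataFrame:
    """Flagged 100-kb window spans with their diversity (columns chrom/start/end/pi)."""
    return _read("ddt_91R_sweep_windows.tsv")


def load_ddt_chrom_means() -> dict[str, float]:
    """Chromosome-arm mean nucleotide diversity of the selected strain."""
    df = _read("ddt_91R_chrom_mean_pi.tsv")
    return dict(zip(df["chrom"], df["mean_pi"]))


def ddt_flagged_windows() -> list[FlaggedWindow]:
    """The example windows as FlaggedWindow records, ready for merge_intervals."""
    df = load_ddt_sweep_windows()
    return [
        FlaggedWindow(r.chrom, int(r.start), int(r.end), TIER_MAJOR, float(r.pi))
        for r in df.itertuples()
    ]
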