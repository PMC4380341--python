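# poolsweep

Selective-sweep analysis of pooled resequencing (Pool-seq) data: sliding-window
nucleotide diversity (π) and Tajima's *D* from text pileups, fold-reduction
sweep calling against chromosome means, per-gene πN/πS candidate filtering,
fixed-vs-segregating allele detection, and a ground-truthed synthetic
pooled-data generator.

## The problem

Laboratory populations kept under strong, sustained selection — the motivating
case is a *Drosophila melanogaster* line maintained on DDT for decades beside
its untreated control — accumulate selective sweeps: genome tracts where a
beneficial allele and everything linked to it went to fixation, leaving almost
no polymorphism. With pooled sequencing of the two lines, those tracts are
visible as windows whose diversity collapses relative to the rest of the
chromosome arm, while the control line shows no such loss.

`poolsweep` implements that scan as a reusable, tested pipeline for anyone with
two pools of common origin (selected vs control): experimental-evolution and
resistance-monitoring studies in insects, or any Pool-seq contrast where
reduced heterozygosity is the signal of interest.

## The statistics

* **Per-site π** — read-pair heterozygosity
  `π = n/(n−1) · (1 − Σᵢ pᵢ²)`, the fraction of mismatching unordered read
  pairs at a site (`pᵢ` = allele read fraction, `n` = coverage).
* **Window scan** — 500-kb windows, 100-kb step: window π is the sum of
  per-site π over SNP sites divided by the coverage-qualifying site count;
  windows without SNPs report `na`.
* **Sweep calls** — fold reduction = arm-mean π / window π; ≥ 100-fold flags a
  *major* sweep window, ≥ 90- but < 100-fold a *minor* one; abutting flagged
  windows merge into numbered intervals.
* **Tajima's D** — every usable site subsampled without replacement to a
  uniform depth (default 30), then
  `D = (π_w − S/a₁) / √(e₁S + e₂S(S−1))` with the Tajima (1989) constants;
  computed per window and per gene CDS.
* **πN/πS** — per-gene nonsynonymous vs synonymous diversity with
  Nei–Gojobori fractional site counts; a defined ratio > 1 nominates a
  candidate gene inside a sweep.
* **Fixed differences** — positions monomorphic in the selected pool but still
  segregating in the control pool.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Simulate a two-pool study (5-Mbp arms, θ = 0.002, coverage 60, one 1-Mbp
200-fold sweep on 2L, selected genes on 2R), scan it, and call sweeps:

```python
from poolsweep import SimConfig, SnpCallConfig, generate, scan_pi, call_sweeps, chrom_mean

sim = generate(SimConfig(seed=0))
cfg = SnpCallConfig(min_count=2, min_coverage=2, max_coverage=75)
windows = scan_pi(sim.selected, cfg=cfg, chrom_lengths=sim.config.chrom_lengths)

arm = [w for w in windows if w.chrom == "2L"]
print(f"2L mean pi: {chrom_mean(arm):.6f}")
for iv in call_sweeps(windows, step=100_000):
    print(f"{iv.tier} sweep {iv.id}: {iv.chrom}:{iv.start:,}-{iv.end:,} "
          f"({len(iv.member_windows)} windows)")
```

```
2L mean pi: 0.001543
major sweep 1: 2L:2,000,000-2,600,000 (6 windows)
```

The arm mean (~0.0016) sits below θ because the swept tract drags it down;
the six flagged 100-kb window anchors span the start of the implanted
2.0–3.0 Mb sweep — only windows lying entirely inside the tract reach the
100-fold cutoff, so the reported interval is the detectable core, not the
full tract. The same scan on `sim.control` returns no intervals.

The same analysis runs from the shell over pileup/FASTA/GTF files:

```bash
poolsweep simulate --config sim.yaml --outdir sim/
poolsweep run --config run.yaml          # scan -> call -> piN/piS -> fixed
poolsweep scan --pileup sim/selected.pileup --metric pi --out windows.tsv
poolsweep call --windows windows.tsv --out intervals.tsv
```

`poolsweep run` writes window tables for both pools and both metrics, the
interval table with tiers, interval–gene assignments, the per-gene πN/πS
table, the fixed-difference table, and a JSON manifest; reruns with the same
config are byte-identical.

## Bundled example data

`poolsweep.datasets` ships two small tables transcribed from a published
Pool-seq sweep scan of the DDT-resistant fly strain 91-R: the 42 flagged
100-kb window spans with their window π, and the arm-level mean π values.
They let the interval-merging and fold-reduction machinery run on real
published coordinates with no download (the 42 spans merge into 13
intervals; the first 2L window sits 166-fold below its arm mean).

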