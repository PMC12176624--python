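# escapeatlas

Allele-specific detection of X-chromosome-inactivation (XCI) escape and
its aging dynamics, for skewed-XCI F1 hybrid mouse designs.

In female mammals one X chromosome is silenced (the Barr body), but some
X-linked genes *escape* inactivation and are expressed from both alleles.
In a BL6 ΔXist × CAST cross the maternal X is always active, so the
allelic ratio of a gene over its SNP-overlapping reads,

```
AR = maternal reads / (maternal + paternal reads),
```

measures escape directly: AR = 1 is complete silencing of the inactive X
(Xi), and a gene with median AR ≤ 0.9 across replicates — at least 10% of
its expression from the Xi — is called an escapee. `escapeatlas` takes
per-SNP allele count tables and turns them into:

- gene-level allelic ratios with informativeness filtering (per-SNP read
  floor, per-gene read cutoffs, replicate medians),
- escape / no-escape calls per organ and life stage, with male-sample and
  pseudoautosomal exclusions and percent-escape summaries,
- dynamic classifications across embryonic → young → adult → aged
  timepoints (age-specific, constitutive, gradual biallelic trend;
  ΔAR = AR_adult − AR_aged),
- positional statistics: escape-gene clusters, sliding-window enrichment
  of aged escapees (exact two-sided binomial), and the distal-region test
  (first 20 Mb + last 40 Mb of chrX),
- allele-specific ATAC analyses: union peak annotation, per-window
  aged-peak enrichment, allelic peak escape states, high-confidence
  Xi-opening shifts, regulatory-element assignment,
- single-cell XCI status (active-X assignment from chromosome-wide AR)
  with pseudobulk escape calling restricted by active-X strain,
- a synthetic-data generator that emulates all three designs with planted
  ground truth, so the whole pipeline is testable without sequencing data.

It is aimed at researchers analyzing allele-specific RNA-seq/ATAC-seq
from hybrid crosses, and at anyone who needs a tested reference
implementation of escape calling rules.

## Worked example

```python
import escapeatlas as ea

sim = ea.simulate_bulk(ea.SimConfig(seed=7))          # 7 organs, 4 stages
cfg = ea.AnalysisConfig()
counts = ea.aggregate_gene_counts(sim.snp_counts, sim.genes, cfg.minread)
summary = ea.summarize_allelic(counts, sim.meta, cfg.total_read_cutoff_bulk)
calls, groups = ea.call_table(summary[summary.sex == "female"],
                              summary[summary.sex == "male"], cfg)
print(groups[groups.timepoint.isin(["adult", "aged"])]
      .pivot(index="group", columns="timepoint", values="percent_escape")
      .round(1))
dyn = ea.classify_dynamics(calls, cfg)
print("age-specific escapees:",
      dyn.loc[dyn.classification == "age_specific", "gene_id"].nunique())
pos = sim.genes.set_index("gene_id")["start"]
age_specific = dyn.loc[dyn.classification == "age_specific", "gene_id"].unique()
res = ea.distal_fraction(pos.reindex(age_specific).dropna().astype(int),
                         cfg.chrom_length, cfg.distal_head, cfg.distal_tail)
print(f"distal fraction {res.fraction:.2f} (null {res.null_probability:.2f}), "
      f"p = {res.p_value:.2e}")
```

prints

```
timepoint  adult  aged
group
brain        3.2   7.0
heart        3.5   6.8
kidney       3.8   6.8
liver        3.8   7.5
lung         4.0   6.5
muscle       4.0   7.2
spleen       4.5   6.8
age-specific escapees: 33
distal fraction 0.76 (null 0.35), p = 2.86e-06
```

Reading the output: every organ's escape rate roughly doubles from adult
(~3–4% of informative X-linked genes) to aged (~7%); 33 genes escape only
in aged samples; and those age-specific escapees concentrate in the
distal chromosome regions (76% observed vs 35% expected under uniform
placement, exact binomial p ≈ 3e-6) — the planted structure of the
simulated study, recovered end to end by the pipeline.

## Command line

The same steps are available as subcommands on generated or real tables:

```bash
escapeatlas simulate --seed 7 --out-dir sim/
escapeatlas ar   --snp-counts sim/snp_counts.tsv --genes sim/genes.bed \
                 --meta sim/meta.tsv --out ar.tsv
escapeatlas call --ar ar.tsv --out calls.tsv --cutoff-sweep
escapeatlas dynamics --calls calls.tsv --out dynamics.tsv
escapeatlas windows  --calls calls.tsv --dynamics dynamics.tsv \
                     --genes sim/genes.bed --out windows.tsv
escapeatlas atac  --peaks-dir peaks/ --allele-counts atac_counts.tsv --out atac.tsv
escapeatlas cells --cell-counts cells.tsv --gene-counts gene_counts.tsv --out-dir sc/
```

All thresholds live in one config file (`--config cfg.yaml`, YAML or
JSON); unknown keys are rejected. See `docs/methods.md` for the model,
conventions and the generator's assumptions.

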