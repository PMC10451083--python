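# pedsweep

Pedigree-breeding genome analysis for two-parent inbred panels, exercisable
end-to-end on a synthetic breeding simulator with known ground truth:

- **`pedsweep.synthetic_data`** — forward simulator: two fully inbred
  founders, descendant inbred lines bred by repeated DH extraction plus
  truncation selection at chosen loci, a DH mapping population, and additive
  multi-environment phenotypes. Ground truth (parent-of-origin paths,
  crossovers, QTLs) is recorded for recovery tests.
- **`pedsweep.ibd_icr`** — parent-of-origin tracing by allele match with
  LOD scoring (detection LOD 3, end trimming 2.5, allele error 1e-4),
  minimum-recombination gap attribution, IBD-conserved-region (ICR) calling
  at a retention threshold, parental genome fractions and retention ratios.
- **`pedsweep.sweep_scan`** — per-10-kb-window π, Watterson's θ and
  Tajima's D, a composite-likelihood-ratio sweep scan against the
  genome-wide background SFS, 100-kb aggregation, top-10 % selection with
  adjacent-window merging into sweep regions, plus MAF/PIC panel
  diagnostics.
- **`pedsweep.qtl_map`** — inclusive composite interval mapping for DH
  populations (stepwise cofactor selection at P = 0.001, cofactor-adjusted
  0.5-cM interval scan via Kosambi recombination fractions, LOD 2.5
  threshold), moisture correction to 13 % water content, stable-QTL and
  QTL-cluster calling, per-line cumulative additive effects.
- **`pedsweep.coloc`** — interval algebra (union/intersect/lengths on
  0-based half-open coordinates), ICR–sweep co-localization percentages,
  QTL in-or-near classification, cM↔bp interpolation, genes-in-regions.
- **`pedsweep.cli`** — `pedsweep` command-line pipeline with deterministic
  seeding.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: statistic oracles
against brute-force enumeration, CLR sweep-recovery and neutral calibration,
IBD/ICR recovery against simulator truth, QTL detection/permutation-null
checks, interval-algebra oracles, closed-form spot checks, and a timed,
byte-reproducible end-to-end demo.

## Run

One-command demo (simulate → ibd → sweep → qtl → coloc, summary JSON):

```sh
pedsweep all --config configs/demo.yaml --out out/ --seed 1
```

Individual stages:

```sh
pedsweep simulate --config configs/demo.yaml --out sim/ --seed 1
pedsweep ibd   --vcf sim/panel.vcf --parents sim/parents.txt --map sim/map.tsv --out ibd/
pedsweep sweep --vcf sim/panel.vcf --parents sim/parents.txt --out sweep/
pedsweep qtl   --geno sim/dh.vcf --map sim/map.tsv --pheno sim/phenotypes.tsv --out qtl/
pedsweep validate --panel-vcf sim/panel.vcf --parents sim/parents.txt
```

Outputs are plain text: VCF v4.2 (GT-only), TSV tables, BED intervals and
JSON summaries. Within a fixed `--seed`, the full pipeline is
byte-reproducible.

## Conventions and caveats

- Inbred lines are treated as one haplotype each; heterozygous calls are
  rejected on input.
- The VCF reference allele is parent 1's allele and doubles as the ancestral
  allele for the unfolded SFS.
- Simulation generates crossovers as a Poisson process on the cM scale (no
  interference); mapping uses the Kosambi convention. The mismatch is
  deliberate: map functions are analysis conventions, not generative truth.
- Segment LOD scoring defaults to the balanced biparental null (either
  parent with probability 0.5). Scoring against observed panel allele
  frequencies (`null_freq="panel"`) is available but removes evidence
  exactly where selection fixed one parent's allele.
- Sweep-statistic ranking uses the sweep-evidence direction (lowest π,
  lowest Tajima's D, highest CLR); direction is configurable per statistic.
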