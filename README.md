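# snpqc

Quality-assurance / quality-control toolkit for SNP genotype data from
clonally propagated polyploid crops — built around the workflow used to
fingerprint sweetpotato (*Ipomoea batatas*, autohexaploid) breeding
material with "diploidized" biallelic markers.

Breeding programs that move clones between labs, screenhouses and fields
accumulate labeling errors that silently erode genetic gains. `snpqc`
provides the pieces needed to detect and manage them:

- **Genotype I/O** — loci × samples matrices of diploidized calls
  (`0` = homozygous reference AA, `1` = homozygous alternative BB,
  `2` = heterozygous AB, `-` = missing), in a simple CSV dialect or the
  one-row genotyping-platform export, plus population, replicate-map and
  trait-marker companion tables (TSV).
- **Locus QC** — call rate, genotype-class frequencies, minor allele
  frequency (MAF) and polymorphic information content
  (PIC = 1 − p² − q², max 0.5), with composable filter recipes.
- **Distances and trees** — allele-sharing distance (ASD: per locus 0 if
  genotypes match, 1 for opposite homozygotes, 0.5 if exactly one is
  heterozygous; averaged over shared loci), Saitou–Nei neighbor joining
  with deterministic tie-breaking, newick I/O, and strict
  bipartition-based tree comparison.
- **Population genetics** — Nei's per-population inbreeding coefficient
  F_IS = 1 − H_obs/H_exp; Weir–Cockerham (1984) variance-component
  estimators of F (≈F_IT), θ (≈F_ST) and f (≈F_IS), overall and pairwise;
  phase-free LD r² (dosage correlation); Mantel permutation tests.
- **Replicate concordance** — given a map of clone → per-stage samples,
  flag clones whose replicates do not cluster together (a tree-clade rule
  or a distance-only exclusive-cluster rule) and quantify stage-to-stage
  agreement by Mantel correlation of per-stage distance matrices.
- **Panel selection** — reduce a filtered marker set to a low-density
  diagnostic panel (k markers per chromosome by maximal physical spread,
  with a fallback rescue for marker-poor chromosomes), append
  trait-associated markers, and evaluate the panel against the full set.
  The published 36-marker reference panel (30 fingerprinting + 6 trait
  SNPs) ships with the package (`snpqc.panel.published_panel()`).
- **Synthetic data** — a Balding–Nichols generator of structured
  populations with hexaploid sampling, diploidization, missingness,
  genotyping error and injected mislabeling, with full ground truth, so
  the whole pipeline is testable end to end.

## Worked example

```python
import snpqc

# simulate a replicated progeny population with known mislabeling
cfg = snpqc.SimConfig(
    populations=(("MDP", 94),), target_fst=0.2, missing_rate=0.02,
    genotype_error_rate=0.01, mislabel_fraction=0.28, seed=2,
)
base, _ = snpqc.simulate_parents(cfg)
gm, truth = snpqc.simulate_replicates(base, cfg)

report = snpqc.replicate_concordance(gm, truth.replicate_map, method="tree_clade")
print(f"injected  {100 * len(truth.mislabeled_genotypes) / 94:.1f}%")
print(f"recovered {report.mislabeling_pct:.1f}% "
      f"({report.n_discordant}/{report.n_tested})")
```

prints

```
injected  27.7%
recovered 27.7% (26/94)
```

i.e. the concordance rule recovers exactly the 26 clones whose stage
copies were swapped. The same objects feed the rest of the pipeline:
`snpqc.asd_matrix(gm)` gives the distance matrix,
`snpqc.neighbor_joining(...)` the tree, and
`snpqc.stage_matrix_correlation(gm, truth.replicate_map)` the Mantel
agreement between the in-vitro, screenhouse and field distance matrices.

The same API is exposed as a CLI:

```sh
snpqc simulate --preset mdp --seed 2 -o sim/
snpqc concordance sim/genotypes.csv --map sim/replicates.tsv -o report.json
snpqc qc in.csv --max-missing 0.25 --min-pic 0.25 --min-maf 0.10 -o filtered.csv
```

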