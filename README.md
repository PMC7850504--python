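# poolkin

Population genetics for **pooled-DNA (bulk) allele-frequency panels** —
collections of crop landraces or other populations genotyped as a single
DNA pool of many individuals each, so that the data are per-population SNP
allele frequencies rather than individual genotypes.

Bulk genotyping makes it affordable to characterise hundreds of
open-pollinated landraces at tens of thousands of SNPs, at the cost of
individual-level information (no F_IS, no genotype-based software). poolkin
re-casts the standard population-genetics workflow so that every statistic
is computed directly from frequency vectors:

- **Diversity** — per-landrace gene diversity He = mean over loci of
  2p(1−p), allelic richness Ar = 1 + proportion of polymorphic loci, group
  He from averaged frequencies, and rarefied group Ar by resampling g
  landraces without replacement (with exact enumeration of all C(n, g)
  subsets when feasible).
- **Differentiation and distance** — modified Rogers distance
  d = sqrt(Σ_l Σ_a (p₁ − p₂)² / 2L), Nei's multilocus
  G_ST = (H_T − H_S)/H_T as a ratio of sums with a landrace-permutation
  test, Rousset's F_ST/(1−F_ST) linearization, and great-circle distances
  by the spherical law of cosines.
- **Ordination and trees** — PCoA (Gower double-centering), PCA with
  supplementary-row projection (project extra populations onto axes fitted
  to a reference set), and Saitou–Nei neighbor joining with Newick export.
- **Structure inference** — one SNP per genetic-map window to limit LD,
  pseudo-haploid genotypes drawn from the frequencies under
  Hardy–Weinberg, the K-cluster admixture likelihood
  log L = Σᵢ Σ_l log(Σ_k q_ik [g_il p_kl + (1−g_il)(1−p_kl)])
  maximised by EM, Evanno ΔK model choice over replicate runs, and
  majority-cluster assignment with a purity cutoff.
- **Admixture tests** — the three-population statistic
  f3(X; Y, W) = mean over loci of (x−y)(x−w) with a block jackknife over
  contiguous map-ordered loci; Z = f3/sd with Z < −2 flagging the focal
  group as a mixture of relatives of the two references; plus a scan over
  all focal × reference-pair scenarios.
- **Spatial analysis** — Mantel matrix-correlation tests, multiple
  regression on distance matrices (MRM) with joint row/column response
  permutation, ordination-axis vs longitude/latitude clines, and a
  climatic distance from PC1 of twelve growing-season variables.
- **Synthetic data** — seeded Balding–Nichols generators (hierarchical
  reference groups, a longitudinal admixture gradient with climate
  covariates, admixed focal groups, binomial bulk-sampling noise) so the
  entire pipeline can be verified end-to-end on data of known truth.

## Worked example

Three reference groups are simulated from a shared ancestral pool with
15-plant bulk noise, a focal group `ESWF` is created as a 50/50 blend of
`NFA` and `CAR`, and the f3 scan is asked which pair of references
explains it:

```python
import numpy as np
from poolkin import *
from poolkin.f3 import group_frequencies

cfg = SimConfig(
    n_loci=5000,
    groups=[GroupSpec("NFA", 12, 0.2, 0.02),
            GroupSpec("CAR", 12, 0.12, 0.02),
            GroupSpec("AND", 12, 0.15, 0.02)],
    bulk_size=15, seed=7)
fm, passport, markers = generate_reference_panel(cfg)
groups = passport.groups()

focal = generate_admixed_focal(
    group_frequencies(fm, groups["NFA"]),
    group_frequencies(fm, groups["CAR"]),
    alpha=0.5, drift_F=0.01, n_landraces=10, seed=8, label="ESWF")

combined = FrequencyMatrix(fm.landrace_ids + focal.landrace_ids,
                           markers.locus_ids,
                           np.vstack([fm.values, focal.values]))
membership = dict(groups, ESWF=focal.landrace_ids)

rec = landrace_stats(combined.row("ESWF_000"), "ESWF_000")
print(f"ESWF_000: He = {rec.He:.3f}, Ar = {rec.Ar:.3f}")

res, p = fst_permutation_test(combined, groups["NFA"], groups["CAR"],
                              n_perm=999, seed=9)
print(f"NFA vs CAR: Fst = {res.Fst:.4f} (permutation p = {p:.3g})")

scan = scan_admixture_scenarios(combined, membership, ["ESWF"],
                                ["NFA", "CAR", "AND"], 500, panel=markers)
print(scan[["focal", "ref1", "ref2", "f3", "sd", "Z", "significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:.5f}"))
```

Output:

```
ESWF_000: He = 0.329, Ar = 1.994
NFA vs CAR: Fst = 0.0877 (permutation p = 0.001)
focal ref1 ref2       f3      sd         Z  significant
 ESWF  NFA  CAR -0.01440 0.00024 -59.84873         True
 ESWF  NFA  AND -0.00365 0.00041  -8.93430         True
 ESWF  CAR  AND  0.00403 0.00039  10.26929        False
```

The true parental pair (NFA, CAR) gives by far the most negative Z. The
(NFA, AND) scenario is also flagged — AND shares ancestry with CAR, so it
partially proxies for the true tropical parent — which is exactly the
ambiguity such scans show on real panels; ranking by Z identifies the
best-supported scenario. The (CAR, AND) pair, which omits the NFA parent,
is positive and rejected. Fst between the simulated reference groups is
significantly positive by the landrace-permutation test.

A full pipeline run (filter → diversity → structure → distances → PCoA/NJ
→ f3 → Mantel/MRM) is driven by one YAML config:

```
poolkin simulate --preset swf-panel --scale 0.2 --seed 1 --out data/
poolkin run --config run.yaml
```

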