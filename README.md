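# oribatrait

Comparative-phylogenetics toolkit for functional traits of soil mites
(Oribatida) — or any clade with a dated phylogeny, continuous traits, and
stable-isotope trophic data.

Soil microarthropod lineages have been evolving in place for hundreds of
millions of years, and their extant traits carry that history. This
package implements the analysis chain used to read it: phylogenetic
signal statistics for body size, body form and trophic level; detection
of significant trait shifts on the tree; a stable-isotope trophic-level
scoring scheme; and branching-time profiles aligned against dated floral
events.

## What it computes

Given a rooted ultrametric tree with branch lengths in my (tips at the
present), let C be the phylogenetic covariance matrix, `C[i,j]` = shared
root-to-MRCA path length of tips i, j.

- **Blomberg's K** — with GLS root estimate â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x,

      K = [MSE₀/MSE]_obs / [MSE₀/MSE]_BM,
      MSE₀ = Σ(xᵢ−â)²/(n−1),  MSE = (x−â1)ᵀC⁻¹(x−â1)/(n−1),
      [MSE₀/MSE]_BM = [tr(C) − n/(1ᵀC⁻¹1)]/(n−1).

  K = 1 under Brownian motion; significance by permuting trait values
  across tips (one-sided, add-one smoothing).
- **Pagel's λ** — maximum-likelihood multiplier on the off-diagonal of C
  over [0, 1], profile likelihood in closed form, likelihood-ratio test
  against λ = 0 on χ²₁.
- **Independent contrasts** (Felsenstein's pruning recursion) and
  permutation-based detection of nodes whose standardized contrast is
  larger than expected — the "significant trait shift" arrows of a
  comparative study, with node ages attached.
- **Trophic levels from stable isotopes** — per habitat,
  baseline-normalized mean δ¹⁵N is binned into four groups spaced 3.4 ‰
  apart (0 lichen specialists … 3 predators/scavengers); scores span
  [0.0, 3.99] with the decimal encoding within-group position; species
  measured in several habitats get the mean score.
- **Branching-time profiles** — internal-node ages in 5-my bins, interval
  fractions, and a "gap / rise / typical" overlay of dated events
  (vascular plants 425 mya, Devonian–Mississippian 359, Mississippian–
  Pennsylvanian 318, Kasimovian 303–307, first angiosperm fossils 124).

A synthetic-data module generates Yule trees, Brownian/λ traits, clade
shifts and multi-habitat isotope communities with exactly the structure
the statistics assume, so every stage is testable end to end.

## Worked example

```sh
oribatrait simulate --n-tips 110 --root-age 400 --seed 42 --out-dir demo
oribatrait run --config demo/config.yaml   # config lists the three files above
cat demo/out/signal.tsv
```

with `demo/config.yaml`:

```yaml
tree: demo/tree.nwk
traits: demo/traits.tsv
isotopes: demo/isotopes.tsv
output_dir: demo/out
seed: 42
n_replicates: 9999
```

prints (abridged):

```
trait          n_species  K      P_K     lambda  P_lambda
body_size      110        0.301  0.0002  0.983   2.9e-11
body_ratio     110        0.999  0.0001  1.000   1.6e-38
trophic_level  70         0.342  0.265   0.077   0.478
```

Body size and form evolve on the tree in this bundle, so both carry
significant phylogenetic signal (small P for K and λ). Trophic levels are
assigned to species independently of the phylogeny, and the statistics
correctly find no signal — the same contrast between conserved morphology
and phylogeny-free trophic structure that motivates this kind of analysis.
The run also writes `shifts.tsv` / `shift_times.tsv` (flagged nodes with
their ages; 16 flags here), `trophic_scores.tsv` (scores in [0.0, 3.99]
with group labels), `branching_histogram.tsv` and `event_overlay.tsv`.

The library surface mirrors the CLI: `read_newick`, `simulate_yule`,
`simulate_bm`, `blomberg_K`, `k_permutation_test`, `pagel_lambda`, `pic`,
`detect_shifts`, `score_isotope_table`, `branching_histogram`,
`event_overlay`, `run_pipeline`, …

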