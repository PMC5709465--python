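# atpmod — modular evolution of the F1Fo ATP synthase

The F-type ATP synthase couples proton flow to ATP synthesis through two
machines bolted together: the soluble catalytic head F1 (α₃β₃γδε) and the
membrane-embedded Fo (a, b₂, c-ring), joined by central and peripheral
stalks.  Did this enzyme evolve as one unit, or was it assembled from
pre-existing modules?  `atpmod` implements two complementary,
desk-reproducible analyses that bear on that question, for researchers in
molecular evolution and comparative genomics:

1. **Phylogenetic-profile clustering.**  Each subunit gene is a binary
   presence/absence vector `X ∈ {0,1}^n` across a panel of `n` genomes
   spanning Archaea, Bacteria and Eukaryota.  Genes gained and lost
   together are candidate co-evolving modules.  Six distances quantify
   profile similarity — Minkowski `L₁`/`L₂`, Jaccard, mutual information
   `d = 1 − I(X;Y)`, Kendall tau rank distance, and Pearson absolute
   anti-correlation `d = 1 − |cor(X,Y)|` — and hierarchical cuts at group
   numbers 5..50, PCA grouping, and a cross-method co-clustering consensus
   identify the modules that every measure agrees on: the α₃β₃ hexamer,
   the c-ring, and the remaining F1 and Fo subunits.

2. **Bacterial transcription-unit (TU) analysis.**  Across bacterial
   genomes the synthase genes keep a constant order, the standard complete
   unit **ε-β-γ-α-δ-b-c-a**.  Fragmented TU predictions are merged
   (same strand, no intervening gene), tandem homologs collapsed
   (b-b′ → b), direction discarded, and every unit mapped to one of the
   C(9,2) = 36 contiguous modules of the standard order.  A module is
   non-random when its frequency exceeds the binomial upper bound
   `CI_up = p + Z_α √(p(1−p)/N)` with `p = 1/36`, `α = 0.05` — the
   recurrent splits (F1 + Fo, ε-β + the rest, the triple split, …) all
   clear it, and δ/b Rosetta-stone fusion proteins independently tie the
   peripheral stalk to its neighbors.

Because the original inputs are database snapshots, both tracks run on
synthetic data from generators that encode realistic study conditions (panel
sizes, noise, the recurrent TU pattern mixture) and return the planted
truth beside each dataset; see `docs/methods.md`.

## Worked example

```python
from atpmod import simulate, distances, clustering, canonical, tustats

# profile track: plant the four synthase modules, recover them
spec = simulate.atp_profile_spec(n_species=400, flip_noise=0.05, seed=4)
profiles, truth = simulate.simulate_profiles(spec)
dm = distances.distance_matrix(profiles, "euclidean")
groups = clustering.hierarchical_cluster(dm, "average", k=4)

# TU track: simulate a bacterial panel, canonicalize, test significance
ann, _ = simulate.simulate_genomes(simulate.GenomeSimSpec(n_genomes=2000, seed=0))
units = canonical.canonical_units(ann)
freqs = tustats.module_frequencies(units)
flagged = tustats.flag_significant(freqs)
sig = tustats.module_significance(freqs.n_units)
print(f"N = {freqs.n_units}, CI_up = {sig.ci_up:.4f}")
print(flagged[flagged.significant].sort_values("frequency", ascending=False)
      [["pattern", "frequency"]].head(5))
```

which prints

```
N = 3186, CI_up = 0.0326
                pattern  frequency
module
0-8     ε-β-γ-α-δ-b-c-a   0.347144
0-2                 ε-β   0.105148
5-8               b-c-a   0.102950
0-6         ε-β-γ-α-δ-b   0.085374
0-5           ε-β-γ-α-δ   0.068110
```

The full unit dominates (~35% of all units), and the recurrent fragments —
the Fo module b-c-a, the F1 module ε-β-γ-α-δ, ε-β, ε-β-γ-α-δ-b — each
exceed the 0.03 cutoff line: the synthase's parts travel as modules.

## Analysis drivers

The full analysis is reproduced by five numbered scripts (each writes under
`results/` and prints what it found):

```sh
python analysis/01_simulate_data.py        # profile matrix + two TU panels
python analysis/02_profile_clustering.py   # 6 distances, cuts 5..50, PCA, consensus
python analysis/03_tu_canonicalize.py      # merge, collapse, canonicalize, classify
python analysis/04_tu_statistics.py        # frequencies, CI_up, flags, fusion calls
python analysis/05_class_patterns.py       # dominant pattern per bacterial class + tree
```

A thin CLI exposes the same stages for ad-hoc files
(`atpmod simulate-genomes`, `atpmod tu-classify`, `atpmod tu-stats`,
`atpmod distances`, `atpmod cluster`, `atpmod consensus`,
`atpmod tree-annotate`, `atpmod run-all`, …).

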