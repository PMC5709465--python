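#!/usr/bin/env python
"""Generate the two synthetic study datasets.

Writes, under results/data/:
  * a phylogenetic profile matrix for a scaled-down mitochondrial protein
    complement (4 planted synthase modules among 46 background modules,
    759 species: 82 Archaea / 614 Bacteria / 63 Eukaryota) plus its truth;
  * gene annotation tables for two bacterial panels — a pooled 2000-genome
    panel with the default transcription-unit pattern mixture, and a
    2248-genome panel structured into classes/phyla with per-class
    mixtures — plus their truths.
"""

from pathlib import Path

from atpmod import profiles, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20171124


def main() -> None:
    spec = simulate.mito_complement_spec(seed=SEED)
    mat, truth = simulate.simulate_profiles(spec)
    profiles.write_profile_matrix(mat, OUT / "profiles.tsv")
    simulate.write_truth(truth, OUT / "profiles_truth.json")
    print(
        f"profiles: {len(mat)} genes x {len(mat.columns)} species, "
        f"{len(set(truth.values()))} planted modules"
    )

    pooled = simulate.GenomeSimSpec(n_genomes=2000, seed=SEED)
    ann, tu_truth = simulate.simulate_genomes(pooled)
    simulate.write_annotations(ann, OUT / "annotations_pooled.tsv")
    simulate.write_truth(tu_truth, OUT / "annotations_pooled_truth.json")
    print(f"pooled TU panel: {ann['genome'].nunique()} genomes, {len(ann)} gene records")

    by_class = simulate.GenomeSimSpec(
        n_genomes=2248, taxon_mixtures=simulate.default_taxon_mixtures(), seed=SEED + 1
    )
    ann2, truth2 = simulate.simulate_genomes(by_class)
    simulate.write_annotations(ann2, OUT / "annotations_by_class.tsv")
    simulate.write_truth(truth2, OUT / "annotations_by_class_truth.json")
    n_taxa = len({t["taxon"] for t in truth2.values()})
    print(f"class-structured TU panel: {ann2['genome'].nunique()} genomes in {n_taxa} classes")


if __name__ == "__main__":
    main()
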