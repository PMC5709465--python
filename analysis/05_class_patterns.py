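#!/usr/bin/env python
"""TU track, step 3: dominant unit combinations per bacterial class.

Summarizes the class-structured panel from 01: for each class/phylum, the
modal per-genome combination of canonical units and its share, written as
a table and as an annotated Newick tree of the classes.  Outputs land in
results/tu_track/.
"""

import json
from pathlib import Path

import dendropy

from atpmod import canonical, simulate, tustats

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "tu_track"
OUT.mkdir(parents=True, exist_ok=True)

# simple class/phylum topology for display; Epsilonproteobacteria placed
# basal among the proteobacterial classes
CLASS_TREE = (
    "((((Gammaproteobacteria,Betaproteobacteria),Alphaproteobacteria,"
    "Deltaproteobacteria),Epsilonproteobacteria),"
    "(Actinobacteria,Bacilli),(Bacteroidetes,Cyanobacteria),OtherPhyla);"
)


def main() -> None:
    ann = simulate.read_annotations(ROOT / "data" / "annotations_by_class.tsv")
    truth = json.loads((ROOT / "data" / "annotations_by_class_truth.json").read_text())
    units = canonical.canonical_units(ann)
    taxa = {g: t["taxon"] for g, t in truth.items()}
    summaries = tustats.dominant_patterns(units, taxa)
    tustats.summaries_frame(summaries).to_csv(
        OUT / "taxon_summaries.tsv", sep="\t", index=False, float_format="%.4f"
    )

    tree = dendropy.Tree.get(data=CLASS_TREE, schema="newick")
    tree, unmatched = tustats.annotate_tree(tree, summaries)
    tustats.write_tree(tree, OUT / "class_tree_annotated.nwk")

    print(f"{len(summaries)} classes/phyla summarized; unmatched: {unmatched or 'none'}")
    for s in summaries:
        sig = " + ".join(s.dominant_signature)
        print(f"  {s.taxon:<24} {100 * s.dominant_share:5.1f}%  {sig}  (n={s.genome_count})")


if __name__ == "__main__":
    main()
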