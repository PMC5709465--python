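#!/usr/bin/env python
"""TU track, step 1: merge, collapse, canonicalize, classify.

Reads the pooled annotation panel from 01, reconstructs merged
transcription units, normalizes them against the standard order
ε-β-γ-α-δ-b-c-a, and writes the canonical unit table plus a breakdown by
classification kind.  Also runs the parallel analysis on the raw
(unmerged) units for comparison.  Outputs land in results/tu_track/.
"""

from pathlib import Path

from atpmod import canonical, simulate

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "tu_track"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    ann = simulate.read_annotations(ROOT / "data" / "annotations_pooled.tsv")
    records = canonical.records_from_frame(ann)

    units = canonical.canonical_units(records)
    units.to_csv(OUT / "canonical_units.tsv", sep="\t", index=False)
    raw_units = canonical.canonical_units(records, merge=False)
    raw_units.to_csv(OUT / "canonical_units_raw.tsv", sep="\t", index=False)

    print(f"{ann['genome'].nunique()} genomes, {len(ann)} gene records")
    print(f"merged units: {len(units)}  (raw, unmerged: {len(raw_units)})")
    print("classification of merged units:")
    for kind, n in units["kind"].value_counts().items():
        print(f"  {kind}: {n} ({100 * n / len(units):.1f}%)")
    collapsed = int(units["collapsed"].sum())
    print(f"units with tandem-homolog collapse (e.g. b-b' -> b): {collapsed}")


if __name__ == "__main__":
    main()
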