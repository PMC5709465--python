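"""Transcription-unit reconstruction, canonicalization and classification.

Raw transcription-unit predictions for bacterial genomes are frequently
fragmented, so adjacent units on the same strand with no gene between them
are merged (transitively) into one unit.  Unit strings are then normalized:
tandem homolog runs collapse to a single gene (b and b' are one label), δ/b
fusion genes expand to their two motifs in reading order, and transcription
direction is ignored by reducing each string to the direction-free canonical
representative.  Every canonical string is classified against the standard
order ε-β-γ-α-δ-b-c-a:

* ``standard_module`` — equals a contiguous run of the standard order, and
  carries its cut-point pair (i, j) among the 9 cut positions;
* ``minor_ctu`` — contains all eight subunits in a non-standard order;
* ``chimera`` — two or more (but not all) subunits in an order matching no
  contiguous run;
* ``other`` — anything else, e.g. units containing foreign genes.

Units consisting only of foreign ("other") genes are dropped before
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .subunits import (
    FUSION_LABEL,
    OTHER_LABEL,
    STANDARD_ORDER,
    VALID_LABELS,
    canonical_form,
    format_pattern,
    module_lookup,
    normalize_label,
)


@dataclass(frozen=True)
class GeneRecord:
    genome: str
    replicon: str
    gene_id: str
    position: int
    strand: str
    tu_id: str
    label: str  # normalized subunit label

    @property
    def motifs(self) -> frozenset[str]:
        """Subunit motifs carried by the protein (two for a δ/b fusion)."""
        if self.label == FUSION_LABEL:
            return frozenset({"delta", "b"})
        if self.label == OTHER_LABEL:
            return frozenset()
        return frozenset({self.label})


@dataclass(frozen=True)
class TranscriptionUnit:
    genome: str
    replicon: str
    labels: tuple[str, ...]  # in ascending-position order
    strand: str
    source: str  # "raw" or "merged"
    gene_ids: tuple[str, ...] = ()
    start: int = 0
    end: int = 0
    collapsed: bool = False


@dataclass(frozen=True)
class CanonicalPattern:
    genome: str
    replicon: str
    labels: tuple[str, ...]  # canonical (direction-free) form
    collapsed: bool
    source: str = "merged"

    @property
    def text(self) -> str:
        return format_pattern(self.labels)


@dataclass(frozen=True)
class Classification:
    kind: str  # standard_module | minor_ctu | chimera | other
    cuts: tuple[int, int] | None = None


def records_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    """Build normalized gene records from an annotation table."""
    required = {"genome", "replicon", "gene_id", "position", "strand", "tu_id", "subunit_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    records = [
        GeneRecord(
            genome=str(r.genome),
            replicon=str(r.replicon),
            gene_id=str(r.gene_id),
            position=int(r.position),
            strand=str(r.strand),
            tu_id=str(r.tu_id),
            label=normalize_label(str(r.subunit_label)),
        )
        for r in df.itertuples(index=False)
    ]
    seen: dict[tuple[str, str, int], str] = {}
    for rec in records:
        key = (rec.genome, rec.replicon, rec.position)
        if key in seen:
            raise ValueError(
                f"duplicate position {rec.position} on {rec.genome}/{rec.replicon} "
                f"({seen[key]} vs {rec.gene_id})"
            )
        seen[key] = rec.gene_id
    return records


def _raw_units(records: list[GeneRecord]) -> list[TranscriptionUnit]:
    by_tu: dict[tuple[str, str, str], list[GeneRecord]] = {}
    for rec in records:
        by_tu.setdefault((rec.genome, rec.replicon, rec.tu_id), []).append(rec)
    units = []
    for (genome, replicon, tu_id), recs in by_tu.items():
        recs.sort(key=lambda r: r.position)
        strands = {r.strand for r in recs}
        if len(strands) > 1:
            raise ValueError(f"inconsistent strand within raw TU {tu_id} of {genome}")
        units.append(
            TranscriptionUnit(
                genome=genome,
                replicon=replicon,
                labels=tuple(r.label for r in recs),
                strand=recs[0].strand,
                source="raw",
                gene_ids=tuple(r.gene_id for r in recs),
                start=recs[0].position,
                end=recs[-1].position,
            )
        )
    units.sort(key=lambda u: (u.genome, u.replicon, u.start))
    return units


def merge_adjacent_tus(records: list[GeneRecord]) -> list[TranscriptionUnit]:
    """Merge adjacent raw units transcribed in the same direction.

    Two raw units on one replicon merge iff they share the strand and no
    gene lies between them — i.e. their position indices are consecutive
    (an index gap means unrecorded genes sit in between).  A unit made of
    foreign genes only is an interrupting gene run, never a merge partner.
    Merging is transitive; every returned unit has source "merged".
    """

    def foreign(u: TranscriptionUnit) -> bool:
        return set(u.labels) <= {OTHER_LABEL}

    merged: list[TranscriptionUnit] = []
    for unit in _raw_units(records):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and not foreign(prev)
            and not foreign(unit)
            and prev.genome == unit.genome
            and prev.replicon == unit.replicon
            and prev.strand == unit.strand
            and unit.start == prev.end + 1
        ):
            merged[-1] = replace(
                prev,
                labels=prev.labels + unit.labels,
                gene_ids=prev.gene_ids + unit.gene_ids,
                end=unit.end,
            )
        else:
            merged.append(replace(unit))
    return [replace(u, source="merged") for u in merged]


def expand_fusions(tu: TranscriptionUnit) -> TranscriptionUnit:
    """Expand δ/b fusion genes to their two motifs in reading order.

    Labels are stored in ascending-position order, so on the minus strand
    the fused protein's motifs appear reversed (b, δ) in genomic order.
    """
    if FUSION_LABEL not in tu.labels:
        return tu
    motifs = ("b", "delta") if tu.strand == "-" else ("delta", "b")
    out: list[str] = []
    for lab in tu.labels:
        out.extend(motifs if lab == FUSION_LABEL else (lab,))
    return replace(tu, labels=tuple(out))


def collapse_tandem_homologs(tu: TranscriptionUnit) -> TranscriptionUnit:
    """Reduce maximal runs of identical subunit labels to one occurrence.

    b and b' are already one label after normalization, so e.g.
    ε-β-γ-α-δ-b-b' becomes ε-β-γ-α-δ-b.  Sets ``collapsed`` when any
    reduction occurred.
    """
    if not tu.labels:
        raise ValueError("transcription unit is empty")
    out = [tu.labels[0]]
    for lab in tu.labels[1:]:
        if lab != out[-1]:
            out.append(lab)
    return replace(tu, labels=tuple(out), collapsed=len(out) != len(tu.labels))


def canonicalize(tu: TranscriptionUnit) -> CanonicalPattern:
    """Direction-free canonical pattern of a (collapsed) unit.

    Fusion expansion and tandem collapse are applied defensively so the
    operation is idempotent regardless of input state.
    """
    prepped = collapse_tandem_homologs(expand_fusions(tu))
    return CanonicalPattern(
        genome=tu.genome,
        replicon=tu.replicon,
        labels=canonical_form(prepped.labels),
        collapsed=prepped.collapsed or tu.collapsed,
        source=tu.source,
    )


def classify_pattern(cp: CanonicalPattern) -> Classification:
    """Classify a canonical unit against the standard gene order."""
    for lab in cp.labels:
        if lab not in VALID_LABELS:
            raise ValueError(f"unknown subunit label in unit: {lab!r}")
    if OTHER_LABEL in cp.labels or FUSION_LABEL in cp.labels:
        # fusions are expanded before classification; a remaining fusion or
        # foreign gene leaves the unit outside the standard-order vocabulary
        return Classification("other")
    cuts = module_lookup().get(cp.labels)
    if cuts is not None:
        return Classification("standard_module", cuts)
    present = set(cp.labels)
    if present == set(STANDARD_ORDER):
        return Classification("minor_ctu")
    if len(present) >= 2:
        return Classification("chimera")
    return Classification("other")


def canonical_units(
    records: list[GeneRecord] | pd.DataFrame,
    *,
    merge: bool = True,
) -> pd.DataFrame:
    """Full normalization pipeline: merge -> collapse -> canonicalize -> classify.

    Accepts gene records or an annotation DataFrame; returns one row per
    analyzed unit with its canonical string and classification.  Units made
    of foreign genes only are dropped.  ``merge=False`` analyzes the raw
    units instead (the parallel track on unmerged predictions).
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    units = merge_adjacent_tus(records) if merge else _raw_units(records)
    rows = []
    for tu in units:
        if set(tu.labels) <= {OTHER_LABEL}:
            continue
        cp = canonicalize(tu)
        cls = classify_pattern(cp)
        rows.append(
            {
                "genome": cp.genome,
                "replicon": cp.replicon,
                "pattern": cp.text,
                "n_genes": len(tu.labels),
                "kind": cls.kind,
                "cut_i": cls.cuts[0] if cls.cuts else pd.NA,
                "cut_j": cls.cuts[1] if cls.cuts else pd.NA,
                "collapsed": cp.collapsed,
                "source": cp.source,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome", "replicon", "pattern", "n_genes", "kind",
            "cut_i", "cut_j", "collapsed", "source",
        ],
    )
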