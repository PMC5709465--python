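"""Frequency and significance analysis of canonical transcription units.

Each canonical unit counts once.  Units classifying as a standard module
fall into one of the 36 cut-point bins of the standard order; minor complete
units, chimeras and anything else share an "other" bin that participates in
the total N but is never significance-tested.  A module is significant when
its observed frequency strictly exceeds the one-sided binomial upper bound

    CI_up = p + Z_alpha * sqrt(p (1 - p) / N),

with p = 1/36 the probability of drawing its cut-point pair at random,
Z_alpha the standard normal quantile (one-sided by default, configurable to
two-sided) and N the total unit count.

Rosetta-stone fusion detection flags any gene whose protein carries two or
more distinct subunit motifs (δ/b being the case of interest), and per-taxon
summaries report the modal per-genome combination of canonical units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .canonical import GeneRecord
from .subunits import format_pattern, null_module_probability, standard_modules

OTHER_BIN = "other"


@dataclass
class ModuleFrequencyTable:
    """Counts and frequencies per standard module plus the other-bin."""

    table: pd.DataFrame  # index: "i-j" keys + "other"; columns: pattern, count, frequency
    n_units: int


@dataclass
class ModuleSignificance:
    p: float
    alpha: float
    z: float
    n_units: int
    ci_up: float


@dataclass(frozen=True)
class FusionCall:
    genome: str
    gene_id: str
    motifs: frozenset[str]
    flanking: tuple[str, ...]
    is_delta_b: bool


@dataclass
class TaxonSummary:
    taxon: str
    dominant_signature: tuple[str, ...]
    dominant_share: float
    genome_count: int
    signature_counts: Counter


def module_frequencies(units: pd.DataFrame) -> ModuleFrequencyTable:
    """Bin canonical units (output of ``canonical_units``) and normalize.

    Every unit contributes one count to exactly one bin; frequencies sum
    to 1 over the 36 module bins plus the other-bin.
    """
    if len(units) == 0:
        raise ValueError("no canonical units to count")
    n = len(units)
    rows = []
    std = units[units["kind"] == "standard_module"]
    counts = Counter(zip(std["cut_i"].astype(int), std["cut_j"].astype(int)))
    for (i, j), run in sorted(standard_modules().items()):
        c = counts.get((i, j), 0)
        rows.append(
            {
                "module": f"{i}-{j}",
                "pattern": format_pattern(run),
                "count": c,
                "frequency": c / n,
            }
        )
    other = n - len(std)
    rows.append({"module": OTHER_BIN, "pattern": OTHER_BIN, "count": other, "frequency": other / n})
    table = pd.DataFrame(rows).set_index("module")
    assert int(table["count"].sum()) == n
    return ModuleFrequencyTable(table, n)


def ci_upper(p: float, alpha: float, n_units: int, *, two_sided: bool = False) -> float:
    """Binomial upper confidence bound p + Z_alpha * sqrt(p(1-p)/N)."""
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_units < 1:
        raise ValueError("N must be >= 1")
    z = norm.ppf(1 - alpha / 2) if two_sided else norm.ppf(1 - alpha)
    return p + z * np.sqrt(p * (1 - p) / n_units)


def module_significance(
    n_units: int,
    alpha: float = 0.05,
    p: float | None = None,
    *,
    two_sided: bool = False,
) -> ModuleSignificance:
    p = null_module_probability() if p is None else p
    z = norm.ppf(1 - alpha / 2) if two_sided else norm.ppf(1 - alpha)
    return ModuleSignificance(p, alpha, float(z), n_units, ci_upper(p, alpha, n_units, two_sided=two_sided))


def flag_significant(
    freqs: ModuleFrequencyTable,
    sig: ModuleSignificance | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach the CI bound and significance flags to a frequency table.

    A module is flagged iff its frequency strictly exceeds CI_up; the
    other-bin has no null probability and is never flagged.
    """
    if sig is None:
        sig = module_significance(freqs.n_units, alpha)
    if sig.n_units != freqs.n_units:
        raise ValueError("significance bound and frequency table disagree on N")
    out = freqs.table.copy()
    out["ci_up"] = sig.ci_up
    out["significant"] = (out["frequency"] > sig.ci_up) & (out.index != OTHER_BIN)
    return out


def detect_fusions(records: list[GeneRecord]) -> list[FusionCall]:
    """One call per gene whose motif set holds >= 2 distinct subunit motifs."""
    by_tu: dict[tuple[str, str, str], list[GeneRecord]] = {}
    for rec in records:
        by_tu.setdefault((rec.genome, rec.replicon, rec.tu_id), []).append(rec)
    calls = []
    for recs in by_tu.values():
        recs.sort(key=lambda r: r.position)
        for idx, rec in enumerate(recs):
            if len(rec.motifs) >= 2:
                flanking = tuple(
                    recs[i].label for i in (idx - 1, idx + 1) if 0 <= i < len(recs)
                )
                calls.append(
                    FusionCall(
                        genome=rec.genome,
                        gene_id=rec.gene_id,
                        motifs=rec.motifs,
                        flanking=flanking,
                        is_delta_b={"delta", "b"} <= rec.motifs,
                    )
                )
    calls.sort(key=lambda c: (c.genome, c.gene_id))
    return calls


def genome_signatures(units: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """Per-genome signature: the sorted multiset of canonical unit strings."""
    return {
        genome: tuple(sorted(grp["pattern"]))
        for genome, grp in units.groupby("genome")
    }


def dominant_patterns(
    units: pd.DataFrame,
    genome_taxa: dict[str, str],
) -> list[TaxonSummary]:
    """Modal per-genome unit combination within each taxon.

    Ties break toward the lexicographically smallest signature so summaries
    are deterministic.
    """
    signatures = genome_signatures(units)
    missing = sorted(set(signatures) - set(genome_taxa))
    if missing:
        raise ValueError(f"genomes missing from taxon map: {missing[:5]}")
    by_taxon: dict[str, Counter] = {}
    for genome, sig in signatures.items():
        by_taxon.setdefault(genome_taxa[genome], Counter())[sig] += 1
    summaries = []
    for taxon in sorted(by_taxon):
        counts = by_taxon[taxon]
        total = sum(counts.values())
        best = max(counts.items(), key=lambda kv: (kv[1], tuple(reversed(kv[0]))))
        dominant = min(
            (sig for sig, c in counts.items() if c == best[1]),
        )
        summaries.append(
            TaxonSummary(
                taxon=taxon,
                dominant_signature=dominant,
                dominant_share=counts[dominant] / total,
                genome_count=total,
                signature_counts=counts,
            )
        )
    return summaries


def summaries_frame(summaries: list[TaxonSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": s.taxon,
            "dominant_signature": " + ".join(s.dominant_signature),
            "dominant_share": s.dominant_share,
            "genome_count": s.genome_count,
        }
        for s in summaries
    )


def annotate_tree(
    tree: dendropy.Tree | str,
    summaries: list[TaxonSummary],
) -> tuple[dendropy.Tree, list[str]]:
    """Attach dominant signatures and shares to matching tree nodes.

    Taxa are matched against leaf labels and internal node labels; topology
    is untouched.  Returns the annotated tree and the list of taxa with no
    matching node.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    by_label: dict[str, dendropy.Node] = {}
    for node in tree:
        label = node.taxon.label if node.taxon is not None else node.label
        if label:
            by_label[label] = node
    warnings: list[str] = []
    for summary in summaries:
        node = by_label.get(summary.taxon)
        if node is None:
            warnings.append(summary.taxon)
            continue
        node.annotations.add_new("dominant_pattern", " + ".join(summary.dominant_signature))
        node.annotations.add_new("dominant_share", round(summary.dominant_share, 4))
        node.annotations.add_new("genome_count", summary.genome_count)
    return tree, warnings


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_annotations=False)
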