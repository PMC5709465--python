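"""Reading homology tables and binarizing them into phylogenetic profiles.

A phylogenetic profile records, for one query gene, the presence (1) or
absence (0) of a detectable homolog in each genome of a species panel.
Presence is called from the best BLASTP hit per (gene, species): an E-value
strictly below the chosen threshold (default 1e-3) counts as presence.
Profiles at a larger threshold are therefore supersets of those at a smaller
one (nestedness is property-tested).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

#: the four E-value thresholds used across the analyses
DEFAULT_THRESHOLD = 1e-3
ALTERNATE_THRESHOLDS = (0.1, 0.01, 1e-3, 1e-4)

DOMAINS = ("Archaea", "Bacteria", "Eukaryota")

_BLAST_COLUMNS = 12  # outfmt-6 dialect


@dataclass
class EvalueTable:
    """Best-hit E-values per (gene, species) pair.

    ``entries`` maps (gene_id, species_id) -> (evalue, bitscore); after
    best-hit reduction at most one entry exists per pair.  Gene and species
    orders follow first occurrence in the source file unless given.
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    gene_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)
    species_domains: dict[str, str] = field(default_factory=dict)

    def add_hit(self, gene: str, species: str, evalue: float, bitscore: float) -> None:
        """Keep the minimum-E-value hit; ties broken by maximum bitscore,
        then by first occurrence."""
        if evalue < 0:
            raise ValueError(f"negative E-value {evalue} for ({gene}, {species})")
        if gene not in self.gene_ids:
            self.gene_ids.append(gene)
        if species not in self.species_ids:
            self.species_ids.append(species)
        key = (gene, species)
        best = self.entries.get(key)
        if best is None or evalue < best[0] or (evalue == best[0] and bitscore > best[1]):
            self.entries[key] = (evalue, bitscore)


def read_blast_tabular(
    path,
    species_of,
    *,
    on_unmapped: str = "error",
) -> EvalueTable:
    """Parse a 12-column BLAST tabular file into an :class:`EvalueTable`.

    Parameters
    ----------
    species_of
        Mapping or callable taking the subject id (column 2) to a species
        id.  Query ids (column 1) are the gene ids.
    on_unmapped
        ``"error"`` (default) raises on a subject id with no species;
        ``"skip"`` drops the row with a warning.
    """
    if on_unmapped not in ("error", "skip"):
        raise ValueError("on_unmapped must be 'error' or 'skip'")
    mapper = species_of.get if hasattr(species_of, "get") else species_of
    table = EvalueTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_BLAST_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            gene, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if not math.isfinite(evalue) or evalue < 0:
                raise ValueError(f"{path}: line {lineno}: bad E-value {fields[10]!r}")
            species = mapper(subject)
            if species is None:
                if on_unmapped == "error":
                    raise ValueError(
                        f"{path}: line {lineno}: subject id {subject!r} maps to no species"
                    )
                warnings.warn(f"skipping unmappable subject id {subject!r}")
                continue
            table.add_hit(gene, species, evalue, bitscore)
    return table


def binarize(
    table: EvalueTable,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    reference_species: str | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix (genes x species) at an E-value threshold.

    Presence requires an entry with E-value strictly below the threshold
    ("smaller than"); a missing pair is absence.  The reference species'
    own genes are present in its column by definition when given.
    """
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    species = list(table.species_ids)
    if reference_species is not None and reference_species not in species:
        species.append(reference_species)
    mat = pd.DataFrame(0, index=list(table.gene_ids), columns=species, dtype="int8")
    for (gene, sp), (evalue, _bits) in table.entries.items():
        if evalue < threshold:
            mat.loc[gene, sp] = 1
    if reference_species is not None:
        mat.loc[:, reference_species] = 1
    return mat


def write_profile_matrix(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index_label="gene")


def read_profile_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype("int8")


def read_species_domains(path) -> dict[str, str]:
    """Two-column TSV: species id, domain (Archaea/Bacteria/Eukaryota)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "domain"])
    bad = set(df["domain"]) - set(DOMAINS)
    if bad:
        raise ValueError(f"unknown domains in {path}: {sorted(bad)}")
    return dict(zip(df["species"], df["domain"]))
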