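"""End-to-end orchestration of the two analysis tracks.

``run_profile_track`` goes from a profile matrix (simulated or read from
disk) to distance matrices for every configured method, hierarchical cut
series, PCA grouping, the gene correlation matrix and the cross-method
consensus modules.  ``run_tu_track`` goes from genome annotations to merged
canonical units, the module frequency table with significance flags, fusion
calls, per-taxon dominant patterns and an annotated taxon tree.  Every run
writes a manifest (config, seeds, input digests) sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from . import canonical, clustering, distances, simulate, tustats
from .profiles import write_profile_matrix


@dataclass
class PipelineConfig:
    evalue_thresholds: tuple[float, ...] = (1e-3,)
    distance_methods: tuple[str, ...] = distances.METHODS
    linkage: str = "average"
    group_numbers: tuple[int, ...] = clustering.DEFAULT_GROUP_NUMBERS
    pca_components: int = 2
    pca_k: int = 4
    consensus_f: float = 0.8
    alpha: float = 0.05
    two_sided_z: bool = False
    seed: int = 0
    # profile simulation
    n_species: int = 759
    flip_noise: float = 0.05
    n_background_modules: int = 46
    # genome simulation
    n_genomes: int = 2000
    use_taxon_mixtures: bool = False
    # optional inputs
    profile_matrix: str | None = None
    annotations: str | None = None
    taxon_tree: str | None = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.evalue_thresholds):
            raise ValueError("E-value thresholds must be positive")
        unknown = set(self.distance_methods) - set(distances.METHODS)
        if unknown:
            raise ValueError(f"unknown distance methods: {sorted(unknown)}")
        if self.linkage not in clustering.LINKAGES:
            raise ValueError(f"linkage must be one of {clustering.LINKAGES}")
        if not (0 < self.consensus_f <= 1):
            raise ValueError("consensus_f must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("evalue_thresholds", "distance_methods", "group_numbers"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(out_dir: Path, config: PipelineConfig, inputs: dict[str, Path]) -> None:
    manifest = {
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _digest(p)} for name, p in inputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_profile_track(config: PipelineConfig, out_dir) -> dict:
    """Run the phylogenetic-profiling track; returns a small report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {}

    if config.profile_matrix:
        profiles = pd.read_csv(config.profile_matrix, sep="\t", index_col=0).astype("int8")
        truth = None
        inputs["profile_matrix"] = Path(config.profile_matrix)
    else:
        spec = simulate.mito_complement_spec(
            n_species=config.n_species,
            n_background_modules=config.n_background_modules,
            flip_noise=config.flip_noise,
            seed=config.seed,
        )
        profiles, truth = _stage("simulate_profiles")(simulate.simulate_profiles)(spec)
        write_profile_matrix(profiles, out / "profiles.tsv")
        simulate.write_truth(truth, out / "profiles_truth.json")
        inputs["profiles"] = out / "profiles.tsv"

    results = []
    for method in config.distance_methods:
        dm = _stage(f"distances[{method}]")(distances.distance_matrix)(profiles, method)
        distances.write_distance_matrix(dm, out / f"distance_{method}.tsv")
        series = _stage(f"cluster[{method}]")(clustering.cut_series)(
            dm, config.linkage, list(config.group_numbers)
        )
        results.extend(series)
        pd.DataFrame(
            {f"k{r.k}": pd.Series(r.assignment) for r in series}
        ).to_csv(out / f"clusters_{method}.tsv", sep="\t", index_label="gene")

    consensus_sets, cmatrix = _stage("consensus")(clustering.consensus_modules)(
        results, config.consensus_f
    )
    with open(out / "consensus_modules.tsv", "w") as fh:
        fh.write("module\tgenes\n")
        for i, genes in enumerate(consensus_sets, 1):
            fh.write(f"consensus_{i:03d}\t{','.join(sorted(genes))}\n")
    cmatrix.to_frame().to_csv(out / "consensus_matrix.tsv", sep="\t", float_format="%.10g")

    atp_genes = [g for m in simulate.atp_synthase_modules() for g in m.genes]
    cor_genes = [g for g in atp_genes if g in profiles.index] or list(profiles.index[:17])
    cor, constant = _stage("correlation")(clustering.correlation_matrix)(profiles, cor_genes)
    cor.to_csv(out / "correlation_matrix.tsv", sep="\t", float_format="%.10g")

    pca = _stage("pca")(clustering.pca_groups)(
        profiles.loc[cor_genes], config.pca_k, config.pca_components, config.seed
    )
    pd.Series(pca.assignment, name="group").to_csv(
        out / "pca_groups.tsv", sep="\t", index_label="gene"
    )

    _manifest(out, config, inputs)
    return {
        "n_genes": len(profiles.index),
        "n_species": len(profiles.columns),
        "n_runs": len(results),
        "n_consensus_modules": len(consensus_sets),
        "truth": truth,
        "consensus_sets": consensus_sets,
    }


def _taxon_star_tree(taxa: list[str]) -> dendropy.Tree:
    newick = "(" + ",".join(sorted(taxa)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def run_tu_track(config: PipelineConfig, out_dir) -> dict:
    """Run the transcription-unit track; returns a small report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {}

    if config.annotations:
        ann = simulate.read_annotations(config.annotations)
        truth = None
        inputs["annotations"] = Path(config.annotations)
    else:
        spec = simulate.GenomeSimSpec(
            n_genomes=config.n_genomes,
            taxon_mixtures=simulate.default_taxon_mixtures()
            if config.use_taxon_mixtures
            else None,
            seed=config.seed,
        )
        ann, truth = _stage("simulate_genomes")(simulate.simulate_genomes)(spec)
        simulate.write_annotations(ann, out / "annotations.tsv")
        simulate.write_truth(truth, out / "annotations_truth.json")
        inputs["annotations"] = out / "annotations.tsv"

    records = _stage("records")(canonical.records_from_frame)(ann)
    units = _stage("canonicalize")(canonical.canonical_units)(records)
    units.to_csv(out / "canonical_units.tsv", sep="\t", index=False)

    freqs = _stage("frequencies")(tustats.module_frequencies)(units)
    sig = tustats.module_significance(freqs.n_units, config.alpha, two_sided=config.two_sided_z)
    flagged = _stage("significance")(tustats.flag_significant)(freqs, sig)
    flagged.to_csv(out / "module_frequencies.tsv", sep="\t", float_format="%.10g")

    calls = _stage("fusions")(tustats.detect_fusions)(records)
    pd.DataFrame(
        {
            "genome": c.genome,
            "gene_id": c.gene_id,
            "motifs": "+".join(sorted(c.motifs)),
            "is_delta_b": c.is_delta_b,
            "flanking": "|".join(c.flanking),
        }
        for c in calls
    ).to_csv(out / "fusion_calls.tsv", sep="\t", index=False)

    report = {
        "n_genomes": ann["genome"].nunique(),
        "n_units": freqs.n_units,
        "ci_up": sig.ci_up,
        "n_significant": int(flagged["significant"].sum()),
        "n_fusions": len(calls),
        "truth": truth,
        "frequencies": flagged,
    }

    # taxon summaries need a genome -> taxon map; with simulated input it
    # comes from the planted truth, otherwise a sidecar column if present
    if truth is not None:
        taxa_map = {g: t["taxon"] for g, t in truth.items()}
    elif "taxon" in ann.columns:
        taxa_map = dict(zip(ann["genome"], ann["taxon"]))
    else:
        taxa_map = {g: "Bacteria" for g in ann["genome"].unique()}
    summaries = _stage("dominant_patterns")(tustats.dominant_patterns)(units, taxa_map)
    tustats.summaries_frame(summaries).to_csv(
        out / "taxon_summaries.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if config.taxon_tree:
        tree = dendropy.Tree.get(path=config.taxon_tree, schema="newick")
        inputs["taxon_tree"] = Path(config.taxon_tree)
    else:
        tree = _taxon_star_tree([s.taxon for s in summaries])
    tree, unmatched = _stage("annotate_tree")(tustats.annotate_tree)(tree, summaries)
    tustats.write_tree(tree, out / "annotated_tree.nwk")
    report["summaries"] = summaries
    report["unmatched_taxa"] = unmatched

    _manifest(out, config, inputs)
    return report
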