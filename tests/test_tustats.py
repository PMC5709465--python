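"""Module frequencies, binomial significance, fusion calls, taxon summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from atpmod import canonical as can
from atpmod import simulate as sim
from atpmod import tustats as ts


def _units_frame(patterns_with_cuts):
    """patterns_with_cuts: list of (pattern, kind, cuts|None, genome)"""
    rows = []
    for pattern, kind, cuts, genome in patterns_with_cuts:
        rows.append(
            {
                "genome": genome,
                "replicon": "chr",
                "pattern": pattern,
                "n_genes": pattern.count("-") + 1,
                "kind": kind,
                "cut_i": cuts[0] if cuts else pd.NA,
                "cut_j": cuts[1] if cuts else pd.NA,
                "collapsed": False,
                "source": "merged",
            }
        )
    return pd.DataFrame(rows)


class TestModuleFrequencies:
    def test_all_standard_ctu(self):
        units = _units_frame(
            [("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), f"g{i}") for i in range(5)]
        )
        table = ts.module_frequencies(units)
        assert table.n_units == 5
        assert table.table.loc["0-8", "frequency"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, small_genome_sim):
        ann, _ = small_genome_sim
        units = can.canonical_units(ann)
        table = ts.module_frequencies(units)
        assert table.table["frequency"].sum() == pytest.approx(1.0)
        assert table.table["count"].sum() == table.n_units

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no canonical units"):
            ts.module_frequencies(_units_frame([]))

    def test_planted_mixture_frequencies(self):
        """Two-pattern mixture: bin shares land within 3 binomial SEs."""
        mix = {"standard_ctu": 0.4, "f1_plus_fo": 0.6}
        spec = sim.GenomeSimSpec(n_genomes=2000, pattern_mixture=mix, seed=17)
        ann, _ = sim.simulate_genomes(spec)
        table = ts.module_frequencies(can.canonical_units(ann))
        # expected unit shares: std 0.4/1.6, F1 and Fo 0.6/1.6 each
        for key, expected in (("0-8", 0.25), ("0-5", 0.375), ("5-8", 0.375)):
            se = np.sqrt(expected * (1 - expected) / table.n_units)
            assert abs(table.table.loc[key, "frequency"] - expected) < 3 * se


class TestCIUpper:
    def test_formula(self):
        # direct evaluation: p + z * sqrt(p(1-p)/N)
        val = ts.ci_upper(1 / 36, 0.05, 10_000)
        z = norm.ppf(0.95)
        assert z == pytest.approx(1.6449, abs=1e-4)
        assert val == pytest.approx(1 / 36 + z * np.sqrt((1 / 36) * (35 / 36) / 10_000))
        assert val == pytest.approx(0.0305, abs=5e-5)

    def test_limit_as_n_grows(self):
        assert ts.ci_upper(1 / 36, 0.05, 10**12) == pytest.approx(1 / 36, abs=1e-4)

    def test_monotone_in_n_and_alpha(self):
        vals = [ts.ci_upper(0.1, 0.05, n) for n in (10, 100, 1000, 10000)]
        assert vals == sorted(vals, reverse=True)
        assert ts.ci_upper(0.1, 0.01, 100) > ts.ci_upper(0.1, 0.05, 100)

    @pytest.mark.parametrize("p,alpha,n", [(0, 0.05, 10), (1, 0.05, 10), (0.5, 0, 10), (0.5, 1.5, 10), (0.5, 0.05, 0)])
    def test_domain_violations(self, p, alpha, n):
        with pytest.raises(ValueError):
            ts.ci_upper(p, alpha, n)


class TestFlagSignificant:
    def test_strict_boundary(self):
        """frequency == CI_up exactly -> not flagged."""
        units = _units_frame(
            [("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), f"g{i}") for i in range(10)]
            + [("b-c-a", "standard_module", (5, 8), f"h{i}") for i in range(10)]
        )
        freqs = ts.module_frequencies(units)
        sig = ts.ModuleSignificance(p=1 / 36, alpha=0.05, z=1.6449, n_units=20, ci_up=0.5)
        flagged = ts.flag_significant(freqs, sig)
        assert not flagged.loc["0-8", "significant"]  # 0.5 == 0.5, strict
        assert not flagged.loc["other", "significant"]

    def test_zero_frequency_never_flagged(self, small_genome_sim):
        ann, _ = small_genome_sim
        flagged = ts.flag_significant(ts.module_frequencies(can.canonical_units(ann)))
        zero = flagged[flagged["count"] == 0]
        assert not zero["significant"].any()

    def test_adding_copies_keeps_module_flagged(self):
        base = [("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), f"g{i}") for i in range(40)]
        rest = [("β-ε-a-c-b-α-γ", "chimera", None, f"x{i}") for i in range(60)]
        freqs1 = ts.module_frequencies(_units_frame(base + rest))
        f1 = ts.flag_significant(freqs1)
        assert f1.loc["0-8", "significant"]
        freqs2 = ts.module_frequencies(_units_frame(base * 2 + rest))
        f2 = ts.flag_significant(freqs2)
        assert f2.loc["0-8", "significant"]

    def test_power_against_planted_enrichment(self):
        """A module at true frequency 0.10 is flagged in >=99/100 replicates."""
        rng = np.random.default_rng(5)
        n, p0 = 5000, 1 / 36
        hits = 0
        reps = 100
        for _ in range(reps):
            count = rng.binomial(n, 0.10)
            freq = count / n
            hits += freq > ts.ci_upper(p0, 0.05, n)
        assert hits >= 99

    def test_uniform_null_error_control(self):
        """Uniform draws over the 36 modules: per-module flag rate <= alpha + 3 SE."""
        rng = np.random.default_rng(11)
        reps, n, alpha = 200, 1000, 0.05
        ci = ts.ci_upper(1 / 36, alpha, n)
        flags = np.zeros(36)
        for _ in range(reps):
            counts = rng.multinomial(n, np.full(36, 1 / 36))
            flags += (counts / n) > ci
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert (flags / reps <= bound).all()


class TestFusions:
    def test_delta_b_call(self):
        recs = [
            can.GeneRecord("g", "chr", "x1", 1, "+", "t", "alpha"),
            can.GeneRecord("g", "chr", "x2", 2, "+", "t", "delta/b"),
            can.GeneRecord("g", "chr", "x3", 3, "+", "t", "b"),
        ]
        calls = ts.detect_fusions(recs)
        assert len(calls) == 1
        call = calls[0]
        assert call.is_delta_b and call.motifs == {"delta", "b"}
        assert call.flanking == ("alpha", "b")

    def test_single_motif_no_call(self):
        recs = [can.GeneRecord("g", "chr", "x1", 1, "+", "t", "b")]
        assert ts.detect_fusions(recs) == []

    def test_recall_precision_on_planted_fusions(self):
        spec = sim.GenomeSimSpec(n_genomes=500, p_fusion=0.2, seed=23)
        ann, truth = sim.simulate_genomes(spec)
        calls = ts.detect_fusions(can.records_from_frame(ann))
        called = {(c.genome, c.gene_id) for c in calls}
        planted = {
            (g, gid) for g, t in truth.items() for gid in t["fusion_genes"]
        }
        assert planted, "simulation should plant fusions at p_fusion=0.2"
        assert called == planted  # recall 1.0 and precision 1.0


class TestDominantPatterns:
    def test_unanimous_taxon(self):
        units = _units_frame(
            [("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), f"g{i}") for i in range(4)]
        )
        summaries = ts.dominant_patterns(units, {f"g{i}": "T" for i in range(4)})
        assert summaries[0].dominant_share == 1.0
        assert summaries[0].genome_count == 4

    def test_two_to_one_majority(self):
        units = _units_frame(
            [
                ("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), "g1"),
                ("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8), "g2"),
                ("b-c-a", "standard_module", (5, 8), "g3"),
            ]
        )
        (summary,) = ts.dominant_patterns(units, {"g1": "T", "g2": "T", "g3": "T"})
        assert summary.dominant_signature == ("ε-β-γ-α-δ-b-c-a",)
        assert summary.dominant_share == pytest.approx(2 / 3)

    def test_missing_genome_named(self):
        units = _units_frame([("b-c-a", "standard_module", (5, 8), "g1")])
        with pytest.raises(ValueError, match="g1"):
            ts.dominant_patterns(units, {})

    def test_planted_taxon_modes_recovered(self):
        spec = sim.GenomeSimSpec(
            n_genomes=1500, taxon_mixtures=sim.default_taxon_mixtures(), seed=31
        )
        ann, truth = sim.simulate_genomes(spec)
        units = can.canonical_units(ann)
        taxa = {g: t["taxon"] for g, t in truth.items()}
        summaries = {s.taxon: s for s in ts.dominant_patterns(units, taxa)}
        for taxon, (weight, mixture) in sim.default_taxon_mixtures().items():
            expected_share = max(mixture.values())
            s = summaries[taxon]
            se = np.sqrt(expected_share * (1 - expected_share) / s.genome_count)
            assert abs(s.dominant_share - expected_share) < 3 * se + 1e-9, taxon
            best_pattern = max(mixture, key=mixture.get)
            assert s.dominant_signature == sim.pattern_signature(best_pattern)


class TestAnnotateTree:
    def test_empty_summaries_round_trip(self):
        import dendropy

        newick = "((A:1,B:1):1,C:2);"
        tree, warnings = ts.annotate_tree(newick, [])
        assert warnings == []
        out = tree.as_string(schema="newick")
        back = dendropy.Tree.get(data=out, schema="newick")
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"A", "B", "C"}

    def test_single_match_and_warning(self, tmp_path):
        summaries = [
            ts.TaxonSummary("A", ("b-c-a",), 0.9, 10, None),
            ts.TaxonSummary("Zed", ("c",), 1.0, 3, None),
        ]
        tree, warnings = ts.annotate_tree("((A:1,B:1):1,C:2);", summaries)
        assert warnings == ["Zed"]
        path = tmp_path / "t.nwk"
        ts.write_tree(tree, path)
        text = path.read_text()
        assert "dominant_pattern" in text and "b-c-a" in text

    def test_simulated_taxa_annotations_parse_on_reread(self, tmp_path):
        import dendropy

        spec = sim.GenomeSimSpec(
            n_genomes=200, taxon_mixtures=sim.default_taxon_mixtures(), seed=41
        )
        ann, truth = sim.simulate_genomes(spec)
        units = can.canonical_units(ann)
        taxa = {g: t["taxon"] for g, t in truth.items()}
        summaries = ts.dominant_patterns(units, taxa)
        newick = "(" + ",".join(s.taxon for s in summaries) + ");"
        tree, warnings = ts.annotate_tree(newick, summaries)
        assert warnings == []
        path = tmp_path / "t.nwk"
        ts.write_tree(tree, path)
        back = dendropy.Tree.get(
            path=str(path), schema="newick", extract_comment_metadata=True
        )
        annotated = [
            n for n in back if n.annotations.get_value("dominant_share") is not None
        ]
        assert len(annotated) == len(summaries)
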