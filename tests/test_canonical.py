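"""Transcription-unit merging, collapsing, canonicalization, classification."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from atpmod import canonical as can
from atpmod import subunits as su


def _records(rows):
    """rows: (genome, replicon, gene, pos, strand, tu, label)"""
    return [can.GeneRecord(*r[:6], su.normalize_label(r[6])) for r in rows]


def _unit(pattern: str, **kw) -> can.TranscriptionUnit:
    defaults = dict(genome="g", replicon="chr", strand="+", source="merged")
    defaults.update(kw)
    return can.TranscriptionUnit(labels=su.parse_pattern(pattern), **defaults)


labels_strategy = st.lists(
    st.sampled_from(su.STANDARD_ORDER), min_size=1, max_size=10
).map(tuple)


# ---------------------------------------------------------------------------
# standard order bookkeeping
# ---------------------------------------------------------------------------


def test_standard_module_enumeration():
    mods = su.standard_modules()
    assert len(mods) == 36  # C(9, 2) cut-point pairs
    assert mods[(0, 8)] == su.STANDARD_ORDER
    assert su.null_module_probability() == pytest.approx(1 / 36)
    # reversal-distinct: 36 distinct canonical forms
    assert len(su.module_lookup()) == 36


def test_label_normalization():
    assert su.normalize_label("ε") == "epsilon"
    assert su.normalize_label("b'") == "b"
    assert su.normalize_label("b′") == "b"
    assert su.normalize_label("δ/b") == su.FUSION_LABEL
    with pytest.raises(ValueError, match="unknown subunit label"):
        su.normalize_label("zeta")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_merge_adjacent_same_strand():
    """F1 unit + Fo unit at consecutive positions on one strand merge to the cTU."""
    rows = [("g", "chr", f"x{i}", i + 1, "+", "tu1", lab) for i, lab in enumerate(su.parse_pattern("ε-β-γ-α-δ"))]
    rows += [("g", "chr", f"y{i}", i + 6, "+", "tu2", lab) for i, lab in enumerate(su.parse_pattern("b-c-a"))]
    units = can.merge_adjacent_tus(_records(rows))
    assert len(units) == 1
    assert units[0].labels == su.STANDARD_ORDER
    assert units[0].source == "merged"


def test_no_merge_across_strands():
    rows = [("g", "chr", f"x{i}", i + 1, "+", "tu1", lab) for i, lab in enumerate(su.parse_pattern("ε-β-γ-α-δ"))]
    rows += [("g", "chr", f"y{i}", i + 6, "-", "tu2", lab) for i, lab in enumerate(su.parse_pattern("a-c-b"))]
    assert len(can.merge_adjacent_tus(_records(rows))) == 2


def test_no_merge_with_interrupting_gene():
    rows = [("g", "chr", f"x{i}", i + 1, "+", "tu1", lab) for i, lab in enumerate(su.parse_pattern("ε-β-γ-α-δ"))]
    rows += [("g", "chr", "foreign", 6, "+", "tu_other", "other")]
    rows += [("g", "chr", f"y{i}", i + 7, "+", "tu2", lab) for i, lab in enumerate(su.parse_pattern("b-c-a"))]
    units = can.merge_adjacent_tus(_records(rows))
    atp_units = [u for u in units if set(u.labels) != {"other"}]
    assert len(atp_units) == 2


def test_no_merge_across_position_gap():
    """An index gap implies unrecorded genes in between: no merge."""
    rows = [("g", "chr", "x1", 1, "+", "tu1", "epsilon"), ("g", "chr", "x2", 2, "+", "tu1", "beta")]
    rows += [("g", "chr", "y1", 10, "+", "tu2", "gamma")]
    assert len(can.merge_adjacent_tus(_records(rows))) == 2


def test_merge_is_transitive():
    rows = [
        ("g", "chr", "x1", 1, "+", "tu1", "epsilon"),
        ("g", "chr", "x2", 2, "+", "tu2", "beta"),
        ("g", "chr", "x3", 3, "+", "tu3", "gamma"),
    ]
    units = can.merge_adjacent_tus(_records(rows))
    assert len(units) == 1
    assert units[0].labels == ("epsilon", "beta", "gamma")


def test_mixed_strand_raw_tu_rejected():
    rows = [
        ("g", "chr", "x1", 1, "+", "tu1", "epsilon"),
        ("g", "chr", "x2", 2, "-", "tu1", "beta"),
    ]
    with pytest.raises(ValueError, match="tu1"):
        can.merge_adjacent_tus(_records(rows))


def test_no_merge_across_replicons():
    rows = [
        ("g", "chrA", "x1", 1, "+", "tu1", "epsilon"),
        ("g", "chrB", "x2", 2, "+", "tu2", "beta"),
    ]
    assert len(can.merge_adjacent_tus(_records(rows))) == 2


# ---------------------------------------------------------------------------
# collapsing and canonicalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "before,after,flag",
    [
        ("ε-β-γ-α-δ-b-b'", "ε-β-γ-α-δ-b", True),
        ("ε-β-γ-α-δ", "ε-β-γ-α-δ", False),
        ("b-b-b", "b", True),
    ],
)
def test_collapse_tandem_homologs(before, after, flag):
    out = can.collapse_tandem_homologs(_unit(before))
    assert out.labels == su.parse_pattern(after)
    assert out.collapsed is flag


def test_reversal_gives_same_canonical_form():
    a = can.canonicalize(_unit("δ-α-γ-β-ε"))
    b = can.canonicalize(_unit("ε-β-γ-α-δ"))
    assert a.labels == b.labels


def test_single_gene_unit_is_palindrome():
    assert can.canonicalize(_unit("c")).labels == ("c",)


@given(labels_strategy)
def test_canonicalization_reversal_invariant(labels):
    fwd = can.canonicalize(can.TranscriptionUnit("g", "chr", labels, "+", "merged"))
    rev = can.canonicalize(
        can.TranscriptionUnit("g", "chr", tuple(reversed(labels)), "-", "merged")
    )
    assert fwd.labels == rev.labels
    assert can.classify_pattern(fwd) == can.classify_pattern(rev)


@given(labels_strategy)
def test_canonical_form_idempotent(labels):
    once = su.canonical_form(labels)
    assert su.canonical_form(once) == once


def test_fusion_expansion_in_reading_order():
    """A δ/b fusion occupies one position but reads as δ-b for ordering."""
    cp = can.canonicalize(_unit("ε-β-γ-α-δ/b-c-a"))
    assert cp.labels == su.STANDARD_ORDER
    assert can.classify_pattern(cp) == can.Classification("standard_module", (0, 8))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pattern,kind,cuts",
    [
        ("ε-β-γ-α-δ-b-c-a", "standard_module", (0, 8)),  # the standard cTU
        ("b-c-a", "standard_module", (5, 8)),  # the Fo module
        ("ε-β-γ-α-δ", "standard_module", (0, 5)),  # the F1 module
        ("a-c-b", "standard_module", (5, 8)),  # reversed Fo reads the same
        ("c", "standard_module", (6, 7)),  # width-1 module
        ("β-ε-a-c-b-δ-α-γ", "minor_ctu", None),  # all 8, non-standard order
        ("ε-β-γ-α-δ-b-a-c", "minor_ctu", None),
        ("β-ε-a-c-b-α-γ", "chimera", None),  # N-ATPase-like subset
        ("ε-β-γ-α-b-c-a", "chimera", None),
    ],
)
def test_classification_worked_examples(pattern, kind, cuts):
    cls = can.classify_pattern(can.canonicalize(_unit(pattern)))
    assert cls.kind == kind
    assert cls.cuts == (tuple(cuts) if cuts else None)


def test_all_36_modules_classify_to_their_cuts():
    for cuts, run in su.standard_modules().items():
        for seq in (run, tuple(reversed(run))):
            cls = can.classify_pattern(can.canonicalize(_unit("-".join(seq))))
            assert cls == can.Classification("standard_module", cuts)


def test_unit_with_foreign_gene_classifies_other():
    cp = can.canonicalize(_unit("ε-other-β"))
    assert can.classify_pattern(cp).kind == "other"


# ---------------------------------------------------------------------------
# full pipeline on simulated annotations
# ---------------------------------------------------------------------------


def test_simulator_round_trip_recovers_planted_patterns(small_genome_sim):
    """merge -> collapse -> canonicalize maps every genome to its planted pattern."""
    from atpmod.simulate import signature_lookup
    from atpmod.tustats import genome_signatures

    ann, truth = small_genome_sim
    units = can.canonical_units(ann)
    lookup = signature_lookup()
    for genome, sig in genome_signatures(units).items():
        assert lookup[sig] == truth[genome]["pattern"], genome


def test_duplicate_positions_rejected():
    df = pd.DataFrame(
        {
            "genome": ["g", "g"],
            "replicon": ["chr", "chr"],
            "gene_id": ["x", "y"],
            "position": [1, 1],
            "strand": ["+", "+"],
            "tu_id": ["t", "t"],
            "subunit_label": ["epsilon", "beta"],
        }
    )
    with pytest.raises(ValueError, match="duplicate position"):
        can.records_from_frame(df)
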