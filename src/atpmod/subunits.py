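"""Subunit alphabet and the standard bacterial atp-operon gene order.

The eight genes of the bacterial F-type ATP synthase operon are written here
with ASCII names (``epsilon, beta, gamma, alpha, delta, b, c, a``); Greek
one-letter spellings are accepted on input and used for display.  The
consensus order ``ε-β-γ-α-δ-b-c-a`` defines nine cut positions (0..8); every
contiguous sub-run between two distinct cuts is a *standard module*, of which
there are exactly C(9,2) = 36.  Unit strings are compared without regard to
transcription direction, so each string is reduced to a canonical
representative of {string, reversed string}.
"""

from __future__ import annotations

from functools import lru_cache

#: consensus gene order of the complete transcription unit (cTU)
STANDARD_ORDER: tuple[str, ...] = (
    "epsilon", "beta", "gamma", "alpha", "delta", "b", "c", "a",
)

N_CUTS = len(STANDARD_ORDER) + 1  # 9 cut positions, indexed 0..8

#: δ/b Rosetta-stone fusion gene: one coding sequence carrying both motifs
FUSION_LABEL = "delta/b"
#: any gene that is not an ATP synthase subunit
OTHER_LABEL = "other"

_GREEK = {
    "ε": "epsilon", "β": "beta", "γ": "gamma", "α": "alpha", "δ": "delta",
}
_TO_GREEK = {v: k for k, v in _GREEK.items()}

_ALIASES = {
    **_GREEK,
    "b'": "b",       # b and b′ are one label throughout
    "b′": "b",
    "b_prime": "b",
    "δ/b": FUSION_LABEL,
    "delta/b": FUSION_LABEL,
    "d/b": FUSION_LABEL,
}

VALID_LABELS = frozenset(STANDARD_ORDER) | {FUSION_LABEL, OTHER_LABEL}

# canonical-form tie-break ranks: ε < β < γ < α < δ < b < c < a, then fusion/other
_RANK = {lab: i for i, lab in enumerate(STANDARD_ORDER)}
_RANK[FUSION_LABEL] = len(STANDARD_ORDER)
_RANK[OTHER_LABEL] = len(STANDARD_ORDER) + 1


def normalize_label(label: str) -> str:
    """Map a raw annotation label onto the internal alphabet.

    Greek letters, ``b'``/``b′`` and δ/b fusion spellings are accepted.
    Unknown labels raise ``ValueError``.
    """
    lab = label.strip()
    lab = _ALIASES.get(lab, lab)
    if lab not in VALID_LABELS:
        raise ValueError(f"unknown subunit label: {label!r}")
    return lab


def parse_pattern(text: str) -> tuple[str, ...]:
    """Parse a dash-joined unit string such as ``"ε-β-γ-α-δ-b-c-a"``."""
    return tuple(normalize_label(tok) for tok in text.split("-") if tok)


def format_pattern(labels: tuple[str, ...], greek: bool = True) -> str:
    """Render labels as a dash-joined string, Greek by default."""
    if greek:
        return "-".join(_TO_GREEK.get(lab, lab) for lab in labels)
    return "-".join(labels)


def reverse_pattern(labels: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(reversed(labels))


def canonical_form(labels: tuple[str, ...]) -> tuple[str, ...]:
    """Direction-free representative of a unit string.

    Transcription direction is ignored, so a string and its reversal denote
    the same unit; the representative is the one that is lexicographically
    smaller under the subunit rank ε<β<γ<α<δ<b<c<a.  Idempotent by
    construction.
    """
    fwd = tuple(labels)
    rev = tuple(reversed(fwd))
    return min(fwd, rev, key=lambda seq: tuple(_RANK[lab] for lab in seq))


@lru_cache(maxsize=1)
def standard_modules() -> dict[tuple[int, int], tuple[str, ...]]:
    """All contiguous sub-runs of the standard order, keyed by cut pair (i, j)."""
    return {
        (i, j): STANDARD_ORDER[i:j]
        for i in range(N_CUTS)
        for j in range(i + 1, N_CUTS)
    }


@lru_cache(maxsize=1)
def module_lookup() -> dict[tuple[str, ...], tuple[int, int]]:
    """Canonical unit string -> cut pair, for all 36 standard modules."""
    table: dict[tuple[str, ...], tuple[int, int]] = {}
    for cuts, run in standard_modules().items():
        key = canonical_form(run)
        if key in table:  # pragma: no cover - structural impossibility
            raise RuntimeError("standard modules are not reversal-distinct")
        table[key] = cuts
    return table


def null_module_probability() -> float:
    """Probability of one module under uniform choice of a cut-point pair."""
    return 1.0 / len(standard_modules())
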