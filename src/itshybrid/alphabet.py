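"""IUPAC nucleotide alphabet tables shared across the package.

Sequences are stored as DNA (U is folded into T on input); structure-aware
code treats T as U when printing RNA. Coordinates are 1-based inclusive
throughout the package.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC code for every non-empty subset of {A,C,G,T}.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

GAP = "-"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_iupac(ch: str) -> bool:
    return ch in ALPHABET


def expand(base: str, *, permissive_n: bool = True) -> frozenset[str]:
    """Expand one IUPAC character to its set of canonical bases.

    Gap always expands to the empty set. ``N`` expands to all four bases when
    ``permissive_n`` is true, to the empty set otherwise (callers that treat N
    as missing data pass ``permissive_n=False``).
    """
    if base == GAP:
        return frozenset()
    if base == "N" and not permissive_n:
        return frozenset()
    try:
        return IUPAC_SETS[base]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {base!r}") from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of canonical bases."""
    key = frozenset(bases)
    try:
        return SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"cannot encode base set {sorted(bases)}") from None


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T (canonical bases only)."""
    return a != b and ((a in PURINES) == (b in PURINES))
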