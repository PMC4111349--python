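"""Polymorphic-site detection with IUPAC semantics, ITS region annotation,
GC content, hybrid additivity classification and consensus calling.

A direct Sanger read of a multi-copy rDNA template reports intragenomic
variation as IUPAC ambiguity codes, so a *single* ambiguous base at a column
already marks that column as polymorphic: polymorphism is defined on the
union of expanded IUPAC states, with gaps and N excluded (columns that vary
only by gaps are not polymorphic).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from . import alphabet
from .alphabet import GAP
from .types import AlignedSet, RegionAnnotation, SequenceRecord, StructureTemplate


class AdditivityClass(str, Enum):
    ADDITIVE_COMBINATION = "additive_combination"
    PARENTAL_SHARED = "parental_shared"
    MATERNAL_ONLY = "maternal_only"
    PATERNAL_ONLY = "paternal_only"
    NOVEL = "novel"


@dataclass(frozen=True)
class PolymorphicSite:
    column: int  # 1-based alignment column
    region: str | None
    states_per_group: dict[str, frozenset[str]]
    additivity_class: AdditivityClass | None = None

    @property
    def states(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.states_per_group.values():
            out |= s
        return frozenset(out)


def expand_ambiguity(base: str, *, permissive_n: bool = True) -> frozenset[str]:
    """Expand an IUPAC character; gap -> empty set, N per ``permissive_n``."""
    return alphabet.expand(base, permissive_n=permissive_n)


# ---------------------------------------------------------------------------
# region annotation

#: Conserved-motif anchors used when explicit spans are not supplied.
#: The 5.8S is delimited by its first (M1) and last (M3) conserved blocks;
#: ITS1 is everything upstream, ITS2 everything downstream.
DEFAULT_MOTIF_ANCHORS = {"m1_58s_start": "CGATGAAGAACGYAGC", "m3_58s_end": "TTTGAAYGCA"}


def _iupac_window_mismatches(seq: str, pattern: str, offset: int) -> int:
    n = 0
    for k, pch in enumerate(pattern):
        sset = alphabet.expand(seq[offset + k])
        pset = alphabet.expand(pch)
        if not sset or not sset <= pset:
            n += 1
    return n


def find_motif(seq: str, pattern: str, max_mismatches: int = 0) -> tuple[int, int]:
    """Best IUPAC-aware match of ``pattern`` in ``seq``.

    Returns ``(1-based start, n_mismatches)`` of the best window; raises if
    the best window exceeds ``max_mismatches``.
    """
    best = (None, len(pattern) + 1)
    for off in range(len(seq) - len(pattern) + 1):
        mm = _iupac_window_mismatches(seq, pattern, off)
        if mm < best[1]:
            best = (off, mm)
            if mm == 0:
                break
    if best[0] is None or best[1] > max_mismatches:
        hit = "" if best[0] is None else seq[best[0] : best[0] + len(pattern)]
        raise ValueError(
            f"motif {pattern!r} not found within {max_mismatches} mismatches; "
            f"best hit {hit!r} with {best[1]} mismatches"
        )
    return best[0] + 1, best[1]


def annotate_regions(
    aln: AlignedSet,
    template: StructureTemplate | dict | None = None,
    *,
    motif_anchors: dict[str, str] | None = None,
    max_mismatches: int = 1,
) -> RegionAnnotation:
    """Annotate ITS1 / 5.8S / ITS2 spans on the alignment columns.

    Explicit spans (a dict, or a template carrying ``region_spans``) are
    passed through verbatim. Otherwise the 5.8S is anchored by locating its
    first and last conserved motifs (M1/M3) in the first sequence, allowing
    up to ``max_mismatches`` per motif.
    """
    if isinstance(template, dict) and template:
        return RegionAnnotation(dict(template))
    if isinstance(template, StructureTemplate) and template.region_spans:
        return RegionAnnotation(dict(template.region_spans))
    anchors = motif_anchors or DEFAULT_MOTIF_ANCHORS
    seq = aln.records[0].seq.replace(GAP, "")
    if len(seq) != aln.L:
        # motif anchoring needs gap-free coordinates equal to column numbers
        seq = aln.records[0].seq
    m1_start, _ = find_motif(seq, anchors["m1_58s_start"], max_mismatches)
    m3_start, _ = find_motif(seq, anchors["m3_58s_end"], max_mismatches)
    s58_start = m1_start
    s58_end = m3_start + len(anchors["m3_58s_end"]) - 1
    if not (1 < s58_start <= s58_end < aln.L):
        raise ValueError(
            f"anchored 5.8S span ({s58_start},{s58_end}) leaves no room for ITS1/ITS2"
        )
    return RegionAnnotation(
        {
            "ITS1": (1, s58_start - 1),
            "5.8S": (s58_start, s58_end),
            "ITS2": (s58_end + 1, aln.L),
        }
    )


# ---------------------------------------------------------------------------
# GC content


def gc_content(seq: SequenceRecord | str, region: RegionAnnotation | None = None,
               which: str | None = None) -> float:
    """GC fraction over a region (or the whole sequence).

    Ambiguity codes contribute their expected GC fraction (R -> 0.5); gaps
    and N are excluded from the denominator.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if region is not None and which is not None:
        start, end = region.spans[which]
        if end > len(s):
            raise ValueError(f"region {which} span ({start},{end}) exceeds sequence length {len(s)}")
        s = s[start - 1 : end]
    num = den = 0.0
    for ch in s:
        states = alphabet.expand(ch, permissive_n=False)
        if not states:
            continue
        num += len(states & frozenset("GC")) / len(states)
        den += 1
    if den == 0:
        raise ValueError("all-gap (or all-N) region: GC content undefined")
    return num / den


# ---------------------------------------------------------------------------
# polymorphic sites


def column_states(
    aln: AlignedSet, col: int, groups=None
) -> dict[str, frozenset[str]]:
    """Expanded base states per group at a column (gaps and N excluded)."""
    out: dict[str, set[str]] = {}
    for rec in aln.records:
        g = rec.group or ""
        if groups is not None and g not in groups:
            continue
        states = alphabet.expand(rec.seq[col - 1], permissive_n=False)
        if states:
            out.setdefault(g, set()).update(states)
    return {g: frozenset(s) for g, s in out.items()}


def find_polymorphic_sites(
    aln: AlignedSet,
    groups=None,
    region: RegionAnnotation | None = None,
) -> list[PolymorphicSite]:
    """Columns whose union of expanded states (over the selected sequences)
    contains two or more bases; a single ambiguous base suffices."""
    if groups is not None:
        groups = set(groups)
        if not any((r.group or "") in groups for r in aln.records):
            raise ValueError(f"no sequences in the selected groups {sorted(groups)}")
    sites: list[PolymorphicSite] = []
    for col in range(1, aln.L + 1):
        per_group = column_states(aln, col, groups)
        union: set[str] = set()
        for s in per_group.values():
            union |= s
        if len(union) >= 2:
            reg = region.region_of(col) if region else None
            sites.append(PolymorphicSite(col, reg, per_group))
    return sites


def classify_additivity(
    site: PolymorphicSite, maternal: str, paternal: str, hybrid: str
) -> AdditivityClass:
    """Classify a polymorphic site by how the hybrid's states relate to the
    parental state sets.

    additive_combination: the hybrid unites a maternal-specific with a
    paternal-specific state; parental_shared: the hybrid repeats a
    polymorphism already present within one parent; maternal_only /
    paternal_only: the hybrid matches one parent exclusively; novel: the
    hybrid carries a state absent from both parents.
    """
    try:
        H = site.states_per_group[hybrid]
    except KeyError:
        raise ValueError(f"hybrid group {hybrid!r} has no states at column {site.column}") from None
    M = site.states_per_group.get(maternal, frozenset())
    P = site.states_per_group.get(paternal, frozenset())
    if not M or not P:
        raise ValueError(
            f"column {site.column}: both parental groups must be present "
            f"(maternal={sorted(M)}, paternal={sorted(P)})"
        )
    if H - (M | P):
        return AdditivityClass.NOVEL
    if (H & (M - P)) and (H & (P - M)):
        return AdditivityClass.ADDITIVE_COMBINATION
    if len(H) >= 2 and (H == M or H == P):
        return AdditivityClass.PARENTAL_SHARED
    if H <= M and not H <= P:
        return AdditivityClass.MATERNAL_ONLY
    if H <= P and not H <= M:
        return AdditivityClass.PATERNAL_ONLY
    # hybrid states lie inside both parents' shared states
    return AdditivityClass.PARENTAL_SHARED


def classify_sites_additivity(
    sites, maternal: str, paternal: str, hybrid: str
) -> list[PolymorphicSite]:
    out = []
    for s in sites:
        if hybrid not in s.states_per_group:
            continue
        if maternal not in s.states_per_group or paternal not in s.states_per_group:
            continue
        klass = classify_additivity(s, maternal, paternal, hybrid)
        out.append(PolymorphicSite(s.column, s.region, s.states_per_group, klass))
    return out


# ---------------------------------------------------------------------------
# consensus calling (emulates direct Sanger sequencing of a copy mixture)


def call_consensus(
    copies, minor_threshold: float = 0.25, record_id: str = "consensus"
) -> SequenceRecord:
    """Collapse aligned copies into one record with IUPAC ambiguity calls.

    Per column, every base whose frequency among non-gap copies reaches
    ``minor_threshold`` enters the call; the call is the minimal IUPAC code
    covering those bases. Below-threshold variants vanish, which is exactly
    how direct sequencing under-reports rare intragenomic variants. The
    default threshold 0.25 mimics the smallest secondary peak a Sanger trace
    is typically scored at.
    """
    copies = list(copies)
    if not copies:
        raise ValueError("no copies to call a consensus from")
    if not 0 < minor_threshold < 0.5:
        raise ValueError(f"minor_threshold must be in (0, 0.5), got {minor_threshold}")
    L = len(copies[0])
    if any(len(c) != L for c in copies):
        raise ValueError("copies are not aligned (unequal lengths)")
    out: list[str] = []
    for col in range(L):
        freq: dict[str, float] = {}
        n = 0
        for c in copies:
            states = alphabet.expand(c.seq[col], permissive_n=False)
            if not states:
                continue
            n += 1
            for b in states:
                freq[b] = freq.get(b, 0.0) + 1.0 / len(states)
        if n == 0:
            out.append(GAP)
            continue
        called = {b for b, f in freq.items() if f / n >= minor_threshold}
        if not called:
            called = {max(freq, key=freq.get)}
        out.append(alphabet.code_for(called))
    return SequenceRecord(record_id, "".join(out))


# ---------------------------------------------------------------------------
# tabular outputs


def site_frequency_table(aln: AlignedSet, groups=None) -> pd.DataFrame:
    """Per-column fractional base counts after ambiguity expansion.

    Counts at a column sum to the number of non-gap, non-N sequences there
    (each ambiguous base contributes fractionally to its expansions).
    """
    rows = []
    for col in range(1, aln.L + 1):
        counts = {b: 0.0 for b in "ACGT"}
        for rec in aln.records:
            if groups is not None and (rec.group or "") not in groups:
                continue
            states = alphabet.expand(rec.seq[col - 1], permissive_n=False)
            for b in states:
                counts[b] += 1.0 / len(states)
        rows.append({"column": col, **counts})
    return pd.DataFrame(rows).set_index("column")


def polymorphism_table(sites, region: RegionAnnotation | None = None) -> pd.DataFrame:
    """TSV-ready table of polymorphic sites: column, region, local column,
    per-group states and (when classified) additivity class."""
    rows = []
    for s in sites:
        local = region.local_coordinate(s.column) if region else None
        rows.append(
            {
                "column": s.column,
                "region": s.region or (local[0] if local else ""),
                "local_column": local[1] if local else "",
                "states": "/".join(sorted(s.states)),
                **{
                    f"states[{g}]": "".join(sorted(v))
                    for g, v in sorted(s.states_per_group.items())
                },
                "additivity_class": s.additivity_class.value if s.additivity_class else "",
            }
        )
    return pd.DataFrame(rows)
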