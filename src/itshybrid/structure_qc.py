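"""Secondary-structure-aware substitution classification (CBC / hemi-CBC /
non-compensatory / unpaired), conserved-motif checks, pseudogene screening
of cloned rDNA copies, and a maximum chi-square chimera scan.

The bond set on the RNA transcript is {A-U, G-C, G-U} (both orientations);
G·U wobble counts as a bond by default, switchable off. A CBC changes both
partners of a paired site and retains the bond; a hemi-CBC changes one
partner and retains the bond; a non-compensatory change leaves the new pair
outside the bond set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import alphabet
from .alphabet import GAP
from .polymorphism import find_motif, gc_content
from .types import AlignedSet, RegionAnnotation, SequenceRecord, StructureTemplate


class ChangeClass(str, Enum):
    CBC = "CBC"
    HCBC = "hCBC"
    NON_COMPENSATORY = "non_compensatory"
    UNPAIRED = "unpaired"
    SILENT = "silent"


#: Severity used when one site shows several state transitions.
SEVERITY = {
    ChangeClass.CBC: 4,
    ChangeClass.NON_COMPENSATORY: 3,
    ChangeClass.HCBC: 2,
    ChangeClass.UNPAIRED: 1,
    ChangeClass.SILENT: 0,
}

_WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def is_bond(pair: tuple[str, str], wobble: bool = True) -> bool:
    """True if the (5', 3') base pair bonds on the transcript (T read as U)."""
    return pair in _WATSON_CRICK or (wobble and pair in _WOBBLE)


@dataclass(frozen=True)
class BaseChangeClass:
    column: int
    partner: int | None
    from_pair: tuple[str, ...]
    to_pair: tuple[str, ...]
    klass: ChangeClass


def classify_base_change(
    template: StructureTemplate,
    column: int,
    from_base: str,
    to_base: str,
    partner_state: str | tuple[str, str] | None = None,
    wobble: bool = True,
) -> BaseChangeClass:
    """Classify one substitution at a template column.

    ``partner_state`` describes the partner position: a single base if the
    partner did not change, a ``(from, to)`` tuple if it did, or None to use
    the template base. Supplying a partner state at an unpaired column is an
    error. The pair is always evaluated once, from the pair's own
    perspective, so a changed partner is not double counted.
    """
    if not 1 <= column <= template.L:
        raise ValueError(f"column {column} outside template of length {template.L}")
    for b in (from_base, to_base):
        if b not in "ACGT":
            raise ValueError(f"bases must be canonical ACGT, got {b!r}")
    partner = template.partner_of(column)
    if partner is None:
        if partner_state is not None:
            raise ValueError(f"column {column} is unpaired but a partner state was supplied")
        klass = ChangeClass.SILENT if from_base == to_base else ChangeClass.UNPAIRED
        return BaseChangeClass(column, None, (from_base,), (to_base,), klass)
    if partner_state is None:
        pf = pt = template.seq[partner - 1]
    elif isinstance(partner_state, tuple):
        pf, pt = partner_state
    else:
        pf = pt = partner_state
    # orient the pair 5' -> 3'
    if column < partner:
        old, new = (from_base, pf), (to_base, pt)
    else:
        old, new = (pf, from_base), (pt, to_base)
    if old == new:
        klass = ChangeClass.SILENT
    else:
        changed = int(from_base != to_base) + int(pf != pt)
        if is_bond(new, wobble):
            klass = ChangeClass.CBC if changed == 2 else ChangeClass.HCBC
        else:
            klass = ChangeClass.NON_COMPENSATORY
    return BaseChangeClass(column, partner, old, new, klass)


def classify_site(
    template: StructureTemplate,
    column: int,
    observed_states,
    wobble: bool = True,
) -> ChangeClass:
    """Class of a polymorphic site: the maximal-severity class over the
    substitutions from the template base to each observed alternative state
    (partner held at its template base)."""
    ref = template.seq[column - 1]
    best = ChangeClass.SILENT
    for alt in observed_states:
        if alt == ref or alt not in "ACGT":
            continue
        c = classify_base_change(template, column, ref, alt, None, wobble)
        if SEVERITY[c.klass] > SEVERITY[best]:
            best = c.klass
    return best


def summarize_change_classes(
    sites, template: StructureTemplate, region: RegionAnnotation | None = None,
    wobble: bool = True,
) -> pd.DataFrame:
    """Counts of site classes per region.

    Every site contributes exactly one class (its maximal-severity class, so
    the counts partition the site list). Site columns must already be in
    template coordinates.
    """
    rows = []
    for site in sites:
        if not 1 <= site.column <= template.L:
            raise ValueError(f"site column {site.column} not mapped to the template")
        klass = classify_site(template, site.column, site.states, wobble)
        reg = site.region or (region.region_of(site.column) if region else None)
        rows.append({"column": site.column, "region": reg or "", "klass": klass.value})
    classes = [c.value for c in ChangeClass]
    if not rows:
        return pd.DataFrame(0, index=pd.Index([], name="region"), columns=classes)
    df = pd.DataFrame(rows)
    table = df.pivot_table(index="region", columns="klass", aggfunc="size", fill_value=0)
    for c in classes:
        if c not in table.columns:
            table[c] = 0
    return table[classes]


# ---------------------------------------------------------------------------
# conserved motifs

#: Default motif table. The ITS1 angiosperm motif and the M3 5.8S motif are
#: canonical published patterns; M1/M2 are conserved angiosperm 5.8S blocks.
#: ``spacer`` marks a variable-length insert scanned over the given range.
DEFAULT_MOTIFS: dict[str, dict] = {
    "ITS1_angiosperm": {
        "region": "ITS1",
        "head": "GGCRY",
        "spacer": (4, 7),
        "tail": "GYGYCAAGGAA",
    },
    "M1": {"region": "5.8S", "pattern": "CGATGAAGAACGYAGC"},
    "M2": {"region": "5.8S", "pattern": "GAATTGCAGAATCC"},
    "M3": {"region": "5.8S", "pattern": "TTTGAAYGCA"},
}


@dataclass(frozen=True)
class MotifCheck:
    motif_id: str
    expected: str
    observed: str
    n_mismatches: int

    @property
    def passed(self) -> bool:
        return self.n_mismatches == 0


def _best_match(seq: str, pattern: str) -> tuple[str, int]:
    try:
        start, mm = find_motif(seq, pattern, max_mismatches=len(pattern))
    except ValueError:
        return "", len(pattern)
    return seq[start - 1 : start - 1 + len(pattern)], mm


def check_motifs(
    seq: SequenceRecord, regions: RegionAnnotation, motifs: dict | None = None
) -> list[MotifCheck]:
    """Check each conserved motif within its region (IUPAC-aware; a pattern
    R matches observed A or G). Variable-length spacers are scanned over all
    admissible lengths and the best window kept. A missing region yields a
    failed check, not an error."""
    motifs = motifs or DEFAULT_MOTIFS
    out = []
    for mid, spec in motifs.items():
        span = regions.spans.get(spec["region"])
        if span is None or span[1] < span[0]:
            expected = spec.get("pattern") or (spec["head"] + "..." + spec["tail"])
            out.append(MotifCheck(mid, expected, "", len(expected)))
            continue
        sub = seq.seq[span[0] - 1 : span[1]].replace(GAP, "")
        if "spacer" in spec:
            lo, hi = spec["spacer"]
            best: MotifCheck | None = None
            for k in range(lo, hi + 1):
                pattern = spec["head"] + "N" * k + spec["tail"]
                obs, mm = _best_match(sub, pattern)
                mm_fixed = mm  # N spacer never mismatches, only fixed positions count
                cand = MotifCheck(mid, pattern, obs, mm_fixed)
                if best is None or cand.n_mismatches < best.n_mismatches:
                    best = cand
            out.append(best)
        else:
            obs, mm = _best_match(sub, spec["pattern"])
            out.append(MotifCheck(mid, spec["pattern"], obs, mm))
    return out


# ---------------------------------------------------------------------------
# pseudogene screening


class Verdict(str, Enum):
    OK = "ok"
    PUTATIVE_NONFUNCTIONAL = "putative_nonfunctional"
    PUTATIVE_ARTIFACT = "putative_artifact"


@dataclass
class QCConfig:
    gc_z: float = -3.0  # per-region GC z-score cutoff (against the library)
    wobble: bool = True
    motifs: dict | None = None


@dataclass
class CloneQCReport:
    clone_id: str
    motif_checks: list[MotifCheck]
    n_58S_substitutions: int
    substitution_columns: tuple[int, ...]
    gc_by_region: dict[str, float]
    gc_z_by_region: dict[str, float]
    n_methylation_type_subs: int
    is_singleton_variant: bool
    verdict: Verdict = Verdict.OK
    notes: list[str] = field(default_factory=list)


def _substitution_columns(clone: SequenceRecord, consensus: SequenceRecord):
    """Columns where the clone's base is not covered by the consensus call."""
    out = []
    for col, (c, k) in enumerate(zip(clone.seq, consensus.seq), start=1):
        sc = alphabet.expand(c, permissive_n=False)
        sk = alphabet.expand(k, permissive_n=False)
        if sc and sk and not sc <= sk:
            out.append(col)
    return out


def screen_pseudogenes(
    library: AlignedSet,
    consensus: SequenceRecord,
    regions: RegionAnnotation,
    cfg: QCConfig | None = None,
    template: StructureTemplate | None = None,
) -> list[CloneQCReport]:
    """Per-clone QC against the direct-sequencing (or majority) consensus.

    A clone is ``putative_nonfunctional`` if it carries any 5.8S
    substitution, fails a conserved motif, or has a region GC z-score below
    ``cfg.gc_z``. A clone whose private (singleton) variants are exclusively
    non-compensatory (template required) is flagged ``putative_artifact`` —
    single-clone bond-breaking variants are the typical PCR/cloning error
    signature.
    """
    cfg = cfg or QCConfig()
    if "5.8S" not in regions.spans:
        raise ValueError("5.8S span missing from region annotation")
    s58 = regions.spans["5.8S"]
    if s58[1] < s58[0]:
        raise ValueError("5.8S span is empty; screening needs the 5.8S region")
    if len(consensus) != library.L:
        raise ValueError("consensus length does not match the library alignment")

    # per-clone substitution lists and library-wide variant multiplicities
    subs = {r.id: _substitution_columns(r, consensus) for r in library.records}
    variant_count: dict[tuple[int, str], int] = {}
    for r in library.records:
        for col in subs[r.id]:
            variant_count[(col, r.seq[col - 1])] = variant_count.get((col, r.seq[col - 1]), 0) + 1

    gc = {
        r.id: {reg: gc_content(r, regions, reg) for reg in regions.spans if regions.spans[reg][1] >= regions.spans[reg][0]}
        for r in library.records
    }
    gc_stats = {}
    for reg in next(iter(gc.values())):
        vals = np.array([gc[r.id][reg] for r in library.records])
        gc_stats[reg] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)

    reports = []
    for r in library.records:
        cols = subs[r.id]
        n58 = sum(1 for c in cols if s58[0] <= c <= s58[1])
        checks = check_motifs(r, regions, cfg.motifs)
        zscores = {}
        for reg, val in gc[r.id].items():
            mean, sd = gc_stats[reg]
            zscores[reg] = (val - mean) / sd if sd > 0 else 0.0
        n_meth = 0
        for c in cols:
            frm, to = consensus.seq[c - 1], r.seq[c - 1]
            if (frm, to) in (("C", "T"), ("G", "A")):
                n_meth += 1
        singleton = bool(cols) and all(
            variant_count[(c, r.seq[c - 1])] == 1 for c in cols
        )
        rep = CloneQCReport(
            clone_id=r.id,
            motif_checks=checks,
            n_58S_substitutions=n58,
            substitution_columns=tuple(cols),
            gc_by_region=gc[r.id],
            gc_z_by_region=zscores,
            n_methylation_type_subs=n_meth,
            is_singleton_variant=singleton,
        )
        failed_motifs = [m.motif_id for m in checks if not m.passed]
        low_gc = [reg for reg, z in zscores.items() if z < cfg.gc_z]
        if n58 > 0 or failed_motifs or low_gc:
            rep.verdict = Verdict.PUTATIVE_NONFUNCTIONAL
            if n58:
                rep.notes.append(f"{n58} substitution(s) in 5.8S")
            if failed_motifs:
                rep.notes.append("failed motifs: " + ",".join(failed_motifs))
            if low_gc:
                rep.notes.append("GC outlier in " + ",".join(low_gc))
        elif singleton and template is not None:
            klasses = {
                classify_site(template, c, {r.seq[c - 1]}, cfg.wobble) for c in cols
            }
            if klasses and klasses <= {ChangeClass.NON_COMPENSATORY}:
                rep.verdict = Verdict.PUTATIVE_ARTIFACT
                rep.notes.append("singleton non-compensatory variant(s) only")
        reports.append(rep)
    return reports


def qc_table(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "clone": r.clone_id,
            "n_58S_substitutions": r.n_58S_substitutions,
            "n_methylation_type_subs": r.n_methylation_type_subs,
            "is_singleton_variant": r.is_singleton_variant,
            "failed_motifs": ",".join(m.motif_id for m in r.motif_checks if not m.passed),
            "verdict": r.verdict.value,
        }
        for reg, val in r.gc_by_region.items():
            row[f"gc[{reg}]"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chimera scan (maximum chi-square)


@dataclass(frozen=True)
class BreakpointReport:
    position: int  # alignment column of the last informative site before the breakpoint
    chi_square: float
    p_value: float
    n_informative: int


def _max_chisq(assign: np.ndarray) -> tuple[float, int]:
    """Maximum 2x2 chi-square over all breakpoints of a binary parent
    assignment vector; returns (chi2, split index) with the breakpoint after
    element ``index``."""
    n = len(assign)
    cum = np.cumsum(assign)
    total_a = int(cum[-1])
    best = (0.0, 0)
    for k in range(1, n):
        la = int(cum[k - 1])
        lb = k - la
        ra = total_a - la
        rb = (n - k) - ra
        row1, row2 = la + lb, ra + rb
        col1, col2 = la + ra, lb + rb
        if 0 in (row1, row2, col1, col2):
            continue
        exp = np.array(
            [
                [row1 * col1, row1 * col2],
                [row2 * col1, row2 * col2],
            ]
        ) / n
        obs = np.array([[la, lb], [ra, rb]])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        if chi2 > best[0]:
            best = (chi2, k)
    return best


def chimera_scan(
    query: SequenceRecord,
    parent_a: SequenceRecord,
    parent_b: SequenceRecord,
    *,
    reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    min_informative: int = 4,
) -> BreakpointReport | None:
    """Maximum chi-square scan of a query against two candidate parents.

    At informative sites (parents unambiguous and different, query matching
    one of them) the query is assigned to parent A or B; the breakpoint
    maximizing the 2x2 left/right-by-parent chi-square is tested against a
    permutation null (shuffling the assignment vector, ``reps`` permutations
    with a fixed seed). Returns a report when p <= alpha, None otherwise.
    Fewer than ``min_informative`` sites yields None with a warning;
    identical parents are an error.
    """
    if not (len(query) == len(parent_a) == len(parent_b)):
        raise ValueError("query and parents must be aligned to equal lengths")
    cols = []
    assign = []
    n_diff = 0
    for col, (q, a, b) in enumerate(zip(query.seq, parent_a.seq, parent_b.seq), start=1):
        if a not in "ACGT" or b not in "ACGT" or a == b:
            continue
        n_diff += 1
        if q == a:
            cols.append(col)
            assign.append(1)
        elif q == b:
            cols.append(col)
            assign.append(0)
    if n_diff == 0:
        raise ValueError("no informative sites: the parents are identical")
    if len(cols) < min_informative:
        warnings.warn(
            f"only {len(cols)} informative sites (<{min_informative}); chimera scan skipped",
            stacklevel=2,
        )
        return None
    vec = np.array(assign)
    if vec.min() == vec.max():  # query matches a single parent throughout
        return None
    obs_chi2, obs_k = _max_chisq(vec)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(reps):
        perm = rng.permutation(vec)
        chi2, _ = _max_chisq(perm)
        if chi2 >= obs_chi2:
            exceed += 1
    p = (exceed + 1) / (reps + 1)
    if p > alpha:
        return None
    return BreakpointReport(cols[obs_k - 1], obs_chi2, p, len(cols))
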