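"""Readers/writers for the formats the pipeline touches.

FASTA (sequences, via Biopython), CT and Vienna dot-bracket (structure
templates), TPS (2D landmarks), NEXUS (distance and splits blocks,
SplitsTree-compatible), and the TSV sidecar label table. Group/role labels
live in the sidecar table rather than FASTA headers, because GenBank headers
are unstructured.
"""

from __future__ import annotations

import csv
import io
import re
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import ALPHABET
from .types import LandmarkConfiguration, Role, SequenceRecord, StructureTemplate

# ---------------------------------------------------------------------------
# labels (TSV sidecar: id, taxon/group, role[, library])


def read_labels(path) -> dict[str, dict]:
    """Read a TSV label table: columns ``id``, ``group`` (or ``taxon``),
    optional ``role`` and ``library``."""
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty label table")
        for row in reader:
            rid = row.get("id")
            if not rid:
                raise ValueError(f"{path}: row without id: {row}")
            group = row.get("group") or row.get("taxon")
            role = row.get("role")
            out[rid] = {
                "group": group,
                "role": Role(role) if role else None,
                "library": row.get("library"),
            }
    return out


def _match_label(rid: str, labels: dict[str, dict]) -> dict | None:
    """Exact id match, else the longest key that is a prefix of the id."""
    if rid in labels:
        return labels[rid]
    best = None
    for key in labels:
        if rid.startswith(key) and (best is None or len(key) > len(best)):
            best = key
    return labels[best] if best is not None else None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, labels: dict[str, dict] | None = None) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Characters are upper-cased and U folded to T; a non-IUPAC character is an
    error naming its record and position. ``labels`` (see :func:`read_labels`)
    are merged by exact-or-prefix id match.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: record {entry.id!r} is empty")
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{path}: record {entry.id!r}: non-IUPAC character {ch!r} "
                    f"at position {pos}"
                )
        group = role = None
        if labels:
            hit = _match_label(entry.id, labels)
            if hit:
                group, role = hit.get("group"), hit.get("role")
        records.append(SequenceRecord(entry.id, seq, group, role or Role.UNKNOWN))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# structure templates

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def _parse_dotbracket(text: str) -> StructureTemplate:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith((">", "#"))]
    if len(lines) < 2:
        raise ValueError("dot-bracket input needs a sequence line and a structure line")
    seq, struct = lines[0].upper().replace("U", "T"), lines[1]
    if len(seq) != len(struct):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(struct, start=1):
        if ch in _BRACKETS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at structure position {pos}")
            i = stack.pop()
            pairs.add((i, pos))
        elif ch not in ".-,:_":
            raise ValueError(f"unexpected structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced {opener!r} at structure position {stack[-1]}")
    return StructureTemplate(seq, frozenset(pairs))


def _parse_ct(text: str) -> StructureTemplate:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise ValueError(f"CT header does not start with a length: {lines[0]!r}") from None
    rows = lines[1 : 1 + n]
    if len(rows) != n:
        raise ValueError(f"CT file declares {n} rows but has {len(rows)}")
    seq_chars: list[str] = []
    partner: dict[int, int] = {}
    for row in rows:
        fields = row.split()
        if len(fields) < 6:
            raise ValueError(f"CT row has fewer than 6 columns: {row!r}")
        idx, base, p = int(fields[0]), fields[1].upper().replace("U", "T"), int(fields[4])
        seq_chars.append(base)
        if p:
            if not 1 <= p <= n:
                raise ValueError(f"CT position {idx}: partner {p} out of range 1..{n}")
            partner[idx] = p
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if partner.get(j) not in (i, None):
            raise ValueError(f"CT pairing not symmetric at positions {i}/{j}")
        pairs.add((min(i, j), max(i, j)))
    return StructureTemplate("".join(seq_chars), frozenset(pairs))


def read_structure(path, dialect: str = "dotbracket") -> StructureTemplate:
    """Parse a CT (6-column) or Vienna dot-bracket structure file.

    Pseudoknot bracket families ``[] {} <>`` are accepted in dot-bracket and
    parsed as ordinary pairs.
    """
    text = Path(path).read_text()
    if dialect == "ct":
        return _parse_ct(text)
    if dialect == "dotbracket":
        return _parse_dotbracket(text)
    raise ValueError(f"unknown structure dialect {dialect!r}")


# ---------------------------------------------------------------------------
# TPS landmarks


def read_tps(path, strict: bool = True, expected_landmarks: int = 14) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (LM=, coordinate lines, ID=/IMAGE=/SCALE=).

    SCALE is applied multiplicatively when present. With ``strict`` (default)
    every configuration must have ``expected_landmarks`` landmarks.
    """
    configs: list[LandmarkConfiguration] = []
    lm: int | None = None
    coords: list[tuple[float, float]] = []
    meta: dict[str, str] = {}

    def flush(line_no: int) -> None:
        nonlocal lm, coords, meta
        if lm is None:
            return
        if len(coords) != lm:
            raise ValueError(
                f"{path}:{line_no}: LM={lm} but {len(coords)} coordinate lines"
            )
        if strict and lm != expected_landmarks:
            raise ValueError(
                f"{path}:{line_no}: expected {expected_landmarks} landmarks, got {lm}"
            )
        arr = np.asarray(coords, dtype=float)
        if "SCALE" in meta:
            arr = arr * float(meta["SCALE"])
        cid = meta.get("ID") or meta.get("IMAGE") or f"specimen_{len(configs) + 1}"
        configs.append(LandmarkConfiguration(cid, meta.get("GROUP", ""), arr))
        lm, coords, meta = None, [], {}

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = re.match(r"^([A-Za-z]+)\s*=\s*(.*)$", line)
            if m:
                key, value = m.group(1).upper(), m.group(2).strip()
                if key == "LM":
                    flush(line_no)
                    lm = int(value)
                else:
                    meta[key] = value
            else:
                if lm is None:
                    raise ValueError(f"{path}:{line_no}: coordinates before any LM= line")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: expected 'x y', got {line!r}")
                coords.append((float(parts[0]), float(parts[1])))
    flush(-1)
    if not configs:
        raise ValueError(f"{path}: no landmark configurations (missing LM= line?)")
    return configs


def write_tps(configs, path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.n_landmarks}\n")
            for x, y in c.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={c.id}\n")
            if c.group:
                fh.write(f"GROUP={c.group}\n")


# ---------------------------------------------------------------------------
# NEXUS splits / distances (SplitsTree-compatible)


def write_nexus_splits(splits, taxa, path, supports: bool = False) -> None:
    """Write a weighted split set as a NEXUS TAXA+SPLITS file.

    ``splits`` is an iterable of ``(side, weight)`` or ``(side, weight,
    support)`` where ``side`` is a collection of taxon names (one side of the
    bipartition). Round-trips through :func:`read_nexus_splits`.
    """
    taxa = list(taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    rows = []
    for entry in splits:
        side, weight = entry[0], float(entry[1])
        support = float(entry[2]) if supports and len(entry) > 2 and entry[2] is not None else None
        if weight < 0:
            raise ValueError(f"negative split weight {weight}")
        unknown = [t for t in side if t not in index]
        if unknown:
            raise ValueError(f"split references unknown taxa: {unknown}")
        rows.append((sorted(index[t] for t in side), weight, support))
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)};\nTAXLABELS\n")
        for t in taxa:
            fh.write(f"\t'{t}'\n")
        fh.write(";\nEND;\n\nBEGIN SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(rows)};\n")
        fmt = "FORMAT LABELS=NO WEIGHTS=YES"
        if supports:
            fmt += " CONFIDENCES=YES"
        fh.write(fmt + ";\nMATRIX\n")
        for k, (members, weight, support) in enumerate(rows, start=1):
            cells = [f"[{k}]", f"{weight:.10g}"]
            if supports:
                cells.append("" if support is None else f"{support:.10g}")
            cells.append(" ".join(str(m) for m in members))
            fh.write("\t" + "\t".join(cells) + ",\n")
        fh.write(";\nEND;\n")


def read_nexus_splits(path):
    """Read back a TAXA+SPLITS NEXUS file written by :func:`write_nexus_splits`.

    Returns ``(taxa, [(frozenset side, weight, support-or-None), ...])``.
    """
    text = Path(path).read_text()
    taxa_block = re.search(r"TAXLABELS(.*?);", text, re.S | re.I)
    if not taxa_block:
        raise ValueError(f"{path}: no TAXLABELS found")
    taxa = re.findall(r"'([^']*)'|(\S+)", taxa_block.group(1))
    taxa = [a or b for a, b in taxa]
    matrix = re.search(r"BEGIN SPLITS;.*?MATRIX(.*?);", text, re.S | re.I)
    if not matrix:
        raise ValueError(f"{path}: no SPLITS matrix found")
    has_conf = re.search(r"CONFIDENCES\s*=\s*YES", text, re.I) is not None
    splits = []
    for line in matrix.group(1).splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        line = re.sub(r"^\[\d+\]\s*", "", line)
        fields = line.split("\t") if "\t" in line else line.split(None, 2 if has_conf else 1)
        fields = [f for f in fields if f != ""]
        weight = float(fields[0])
        if has_conf:
            support, members = float(fields[1]), fields[2]
        else:
            support, members = None, fields[1]
        side = frozenset(taxa[int(m) - 1] for m in members.split())
        splits.append((side, weight, support))
    return taxa, splits


def write_nexus_distances(taxa, matrix, path) -> None:
    """Write a NEXUS DISTANCES block (full, labelled matrix)."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)};\nTAXLABELS\n")
        for t in taxa:
            fh.write(f"\t'{t}'\n")
        fh.write(";\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\nMATRIX\n")
        for t, row in zip(taxa, matrix):
            fh.write(f"'{t}'\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
        fh.write(";\nEND;\n")


# ---------------------------------------------------------------------------
# optional GenBank fetch (network; off by default in the CLI)


def fetch_genbank(accessions, email: str, out_fasta=None) -> list[SequenceRecord]:
    """Fetch nucleotide accessions from GenBank via Entrez (requires network).

    ``accessions`` may contain ranges like ``KF671968-KF672114``.
    """
    from Bio import Entrez

    acc_list: list[str] = []
    for item in accessions:
        m = re.match(r"^([A-Za-z]+)(\d+)-([A-Za-z]+)?(\d+)$", item)
        if m and (m.group(3) is None or m.group(3) == m.group(1)):
            prefix, lo, hi = m.group(1), int(m.group(2)), int(m.group(4))
            width = len(m.group(2))
            acc_list.extend(f"{prefix}{n:0{width}d}" for n in range(lo, hi + 1))
        else:
            acc_list.append(item)
    Entrez.email = email
    Entrez.max_tries = 1
    handle = Entrez.efetch(
        db="nucleotide", id=",".join(acc_list), rettype="fasta", retmode="text"
    )
    data = handle.read()
    handle.close()
    records = []
    for entry in SeqIO.parse(io.StringIO(data), "fasta"):
        seq = str(entry.seq).upper().replace("U", "T")
        records.append(SequenceRecord(entry.id.split(".")[0], seq))
    if out_fasta:
        write_fasta(records, out_fasta)
    return records
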