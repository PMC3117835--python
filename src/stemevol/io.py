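"""Readers and writers for structural alignments and tabular matrices.

Two alignment dialects are supported:

* ``bracket`` — aligned FASTA records followed by one ``#structure`` line
  whose string uses round/square/curly/angle brackets plus paired
  uppercase/lowercase letters (Aa, Bb, ...) for pseudoknotted helices;
* ``stockholm-like`` — a Stockholm file whose ``#=GC SS_cons`` line carries
  the consensus structure in WUSS symbols, mapped onto the same classes.

Rows are normalized on input: T -> U, '.' -> '-', everything uppercased.
Lowercase input characters (used by curated alignments to flag mutated,
non-pairing bases) are preserved as per-sequence column metadata, and ``~``
(region not sequenced) is kept distinct from the gap character ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .alphabet import VALID_ROW_CHARS, normalize_char
from .errors import FormatError, StructureError, ValidationError
from .stems import parse_structure_pairs

_WUSS_UNPAIRED = set(".,:_-~")


@dataclass
class StructuralAlignment:
    """A gapped multiple alignment plus one consensus structure string."""

    ids: list[str]
    rows: list[str]
    consensus_structure: str
    family_label: str = ""
    #: per-id 0-based columns that were lowercase in the source file
    lowercase: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def n_columns(self) -> int:
        return len(self.consensus_structure)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def validate(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("number of ids and rows differ")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dupes}")
        L = len(self.consensus_structure)
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise FormatError(
                    f"row {sid!r} has length {len(row)}, expected {L}"
                )
            bad = set(row) - VALID_ROW_CHARS
            if bad:
                raise FormatError(
                    f"row {sid!r} contains invalid characters {sorted(bad)}"
                )
        parse_structure_pairs(self.consensus_structure)  # may raise StructureError

    def subset(self, keep_ids) -> "StructuralAlignment":
        """Alignment restricted to ``keep_ids`` (original order kept)."""
        keep = set(keep_ids)
        idx = [k for k, sid in enumerate(self.ids) if sid in keep]
        return StructuralAlignment(
            ids=[self.ids[k] for k in idx],
            rows=[self.rows[k] for k in idx],
            consensus_structure=self.consensus_structure,
            family_label=self.family_label,
            lowercase={
                sid: cols for sid, cols in self.lowercase.items() if sid in keep
            },
        )


def _normalize_row(sid: str, raw: str) -> tuple[str, tuple[int, ...]]:
    lower_cols = tuple(i for i, ch in enumerate(raw) if ch.isalpha() and ch.islower())
    normalized = "".join(normalize_char(ch) for ch in raw)
    bad = set(normalized) - VALID_ROW_CHARS
    if bad:
        raise FormatError(f"row {sid!r} contains invalid characters {sorted(bad)}")
    return normalized, lower_cols


def _read_bracket(path) -> StructuralAlignment:
    ids: list[str] = []
    chunks: dict[str, list[str]] = {}
    structure_parts: list[str] = []
    family = ""
    current: str | None = None
    in_structure = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#structure"):
                in_structure = True
                rest = line[len("#structure"):].strip()
                if rest:
                    structure_parts.append(rest)
                current = None
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("family:"):
                    family = body.split(":", 1)[1].strip()
                continue
            if line.startswith(">"):
                in_structure = False
                current = line[1:].split()[0]
                if current in chunks:
                    raise ValidationError(f"duplicate sequence ids: [{current!r}]")
                ids.append(current)
                chunks[current] = []
                continue
            if in_structure:
                structure_parts.append(line.strip())
            elif current is not None:
                chunks[current].append(line.strip())
            else:
                raise FormatError(f"unexpected line outside any record: {line!r}")
    if not structure_parts:
        raise FormatError(f"{path}: no #structure line found")
    if not ids:
        raise FormatError(f"{path}: no sequence records found")
    structure = "".join(structure_parts)
    rows, lowercase = [], {}
    for sid in ids:
        row, lower = _normalize_row(sid, "".join(chunks[sid]))
        rows.append(row)
        if lower:
            lowercase[sid] = lower
    return StructuralAlignment(
        ids=ids,
        rows=rows,
        consensus_structure=structure,
        family_label=family,
        lowercase=lowercase,
    )


def _read_stockholm(path) -> StructuralAlignment:
    aln = AlignIO.read(path, "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise FormatError(f"{path}: Stockholm file lacks a #=GC SS_cons line")
    structure = "".join("." if ch in _WUSS_UNPAIRED else ch for ch in ss)
    ids, rows, lowercase = [], [], {}
    for rec in aln:
        ids.append(rec.id)
        row, lower = _normalize_row(rec.id, str(rec.seq))
        rows.append(row)
        if lower:
            lowercase[rec.id] = lower
    return StructuralAlignment(
        ids=ids, rows=rows, consensus_structure=structure, family_label=""
    )


def read_structural_alignment(path, dialect: str = "bracket") -> StructuralAlignment:
    """Read a structural alignment in the given dialect.

    ``dialect`` is ``"bracket"`` (aligned FASTA + ``#structure`` line) or
    ``"stockholm-like"`` (Stockholm with ``#=GC SS_cons``).
    """
    if dialect == "bracket":
        return _read_bracket(path)
    if dialect in ("stockholm-like", "stockholm"):
        return _read_stockholm(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structural_alignment(aln: StructuralAlignment, path) -> None:
    """Write the bracket dialect; lowercase metadata is restored in the rows."""
    with open(path, "w") as fh:
        if aln.family_label:
            fh.write(f"# family: {aln.family_label}\n")
        for sid, row in zip(aln.ids, aln.rows):
            chars = list(row)
            for c in aln.lowercase.get(sid, ()):
                chars[c] = chars[c].lower()
            fh.write(f">{sid}\n{''.join(chars)}\n")
        fh.write(f"#structure {aln.consensus_structure}\n")


def write_matrix_tsv(matrix, path) -> None:
    """Serialize a counts or log-odds matrix as a labeled TSV grid.

    Accepts any object with ``states`` and either integer ``counts`` or real
    ``values`` (NaN written as ``NA``, reals to 2 decimals), or a plain
    DataFrame.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        data = matrix.to_numpy()
        integral = np.issubdtype(data.dtype, np.integer)
        row_labels = [str(r) for r in matrix.index]
    else:
        labels = ["".join(s) if isinstance(s, tuple) else s for s in matrix.states]
        row_labels = labels
        if hasattr(matrix, "values") and matrix.values is not None:
            data = np.asarray(matrix.values, dtype=float)
            integral = False
        else:
            data = np.asarray(matrix.counts)
            integral = True
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for r, rl in enumerate(row_labels):
            cells = []
            for v in data[r]:
                if not integral and (v != v):  # NaN -> undefined cell
                    cells.append("NA")
                elif integral:
                    cells.append(str(int(v)))
                else:
                    cells.append(f"{v:.2f}")
            fh.write(rl + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix_tsv`; NA -> NaN."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
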