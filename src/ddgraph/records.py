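"""Mutation records: parsing, edit algebra, antisymmetric augmentation, filtering.

The central object is a :class:`MutationRecord` — a wild-type/mutant sequence
pair with a measured or predicted stability change ddG (kcal/mol).  Mutations
of any type are represented as ordered lists of :class:`Edit` (substitutions,
insertions, deletions) on wild-type coordinates, so a single record can
describe single-point, multi-point and indel variants uniformly.

Stability is a state function, so the inverse mutation (mutant -> wild) has
ddG_inverse = -ddG_direct.  :func:`augment_antisymmetric` merges every record
with its inversion, which balances stabilising against destabilising examples
and lets a regressor learn the antisymmetry from data.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: default CSV column mapping; override per input schema
DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "wild_seq": "wt_seq",
    "mut_seq": "mut_seq",
    "edits": "mutation",
    "ddg": "ddG",
    "reliable": "reliable",
    "direction": "direction",
}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


class EditError(ValueError):
    """Raised for invalid edit notation or inapplicable edits."""


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - _AA_SET
    if bad:
        raise EditError(f"{what} contains non-standard letters: {sorted(bad)}")


@dataclass(frozen=True)
class Edit:
    """One local sequence change on 0-based wild-type coordinates.

    Substitution: ``wild_span`` and ``mut_span`` are single letters.
    Deletion: ``mut_span`` is empty; ``wild_span`` is the removed segment
    starting at ``position``.
    Insertion: ``wild_span`` is empty; ``mut_span`` is inserted immediately
    *after* ``position`` (``position = -1`` prepends at the N-terminus).
    """

    kind: str
    position: int
    wild_span: str = ""
    mut_span: str = ""

    def __post_init__(self) -> None:
        if self.kind == SUBSTITUTION:
            if len(self.wild_span) != 1 or len(self.mut_span) != 1:
                raise EditError("substitution spans must be single letters")
        elif self.kind == INSERTION:
            if self.wild_span or not self.mut_span:
                raise EditError("insertion needs empty wild_span, non-empty mut_span")
        elif self.kind == DELETION:
            if self.mut_span or not self.wild_span:
                raise EditError("deletion needs empty mut_span, non-empty wild_span")
        else:
            raise EditError(f"unknown edit kind {self.kind!r}")
        _check_alphabet(self.wild_span + self.mut_span, "edit span")
        min_pos = -1 if self.kind == INSERTION else 0
        if self.position < min_pos:
            raise EditError(f"position {self.position} out of range for {self.kind}")

    @property
    def wild_end(self) -> int:
        """First wild index after the span this edit consumes."""
        if self.kind == INSERTION:
            return self.position + 1
        return self.position + len(self.wild_span)


_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RE = re.compile(r"^([A-Z])(\d+)del$")
_DEL_SPAN_RE = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)del$")
_INS_RE = re.compile(r"^(\d+)ins([A-Z]+)$")


def parse_edit_notation(s: str, wild_seq: str) -> list[Edit]:
    """Parse colon-separated edit notation into validated :class:`Edit` objects.

    Grammar (positions 1-based): ``A2G`` substitution, ``C2del`` single
    deletion, ``C2_D4del`` span deletion, ``2insGG`` insertion after position
    2 (``0insGG`` prepends).  Multi-point mutations join tokens with ``:``.
    """
    edits: list[Edit] = []
    for token in s.split(":"):
        token = token.strip()
        if not token:
            continue
        if m := _SUB_RE.match(token):
            wt, pos, mt = m.group(1), int(m.group(2)) - 1, m.group(3)
            _require_wild(wild_seq, pos, wt, token)
            edits.append(Edit(SUBSTITUTION, pos, wt, mt))
        elif m := _DEL_RE.match(token):
            wt, pos = m.group(1), int(m.group(2)) - 1
            _require_wild(wild_seq, pos, wt, token)
            edits.append(Edit(DELETION, pos, wild_span=wt))
        elif m := _DEL_SPAN_RE.match(token):
            w1, p1, w2, p2 = m.group(1), int(m.group(2)) - 1, m.group(3), int(m.group(4)) - 1
            if p2 < p1:
                raise EditError(f"{token!r}: span end before start")
            _require_wild(wild_seq, p1, w1, token)
            _require_wild(wild_seq, p2, w2, token)
            edits.append(Edit(DELETION, p1, wild_span=wild_seq[p1 : p2 + 1]))
        elif m := _INS_RE.match(token):
            pos, seq = int(m.group(1)) - 1, m.group(2)
            if pos >= len(wild_seq):
                raise EditError(f"{token!r}: insertion anchor beyond sequence end")
            edits.append(Edit(INSERTION, pos, mut_span=seq))
        else:
            raise EditError(f"unrecognised edit token {token!r}")
    edits.sort(key=lambda e: (e.position, 1 if e.kind == INSERTION else 0))
    _check_disjoint(edits)
    return edits


def _require_wild(wild_seq: str, pos: int, letter: str, token: str) -> None:
    if not 0 <= pos < len(wild_seq):
        raise EditError(f"{token!r}: position {pos + 1} outside sequence of length {len(wild_seq)}")
    if wild_seq[pos] != letter:
        raise EditError(
            f"{token!r}: wild-type letter mismatch at position {pos + 1} "
            f"(sequence has {wild_seq[pos]!r})"
        )


def _check_disjoint(edits: Sequence[Edit]) -> None:
    # insertions occupy the inter-residue slot after `position`; spans must not overlap
    prev_end = 0
    for e in edits:
        start = e.position + 1 if e.kind == INSERTION else e.position
        if start < prev_end:
            raise EditError(f"overlapping edits at wild position {e.position}")
        prev_end = max(prev_end, e.wild_end)


def apply_edits(wild_seq: str, edits: Sequence[Edit]) -> str:
    """Apply sorted, non-overlapping edits to a wild-type sequence.

    Output length is ``len(wild) + sum(len(mut_span) - len(wild_span))``.
    """
    _check_alphabet(wild_seq, "wild sequence")
    ordered = sorted(edits, key=lambda e: (e.position, 1 if e.kind == INSERTION else 0))
    _check_disjoint(ordered)
    out: list[str] = []
    cursor = 0
    for e in ordered:
        if e.kind == INSERTION:
            keep_to = e.position + 1
        else:
            keep_to = e.position
        if keep_to < cursor or e.wild_end > len(wild_seq):
            raise EditError(f"edit at position {e.position} out of range or overlapping")
        out.append(wild_seq[cursor:keep_to])
        if e.kind == SUBSTITUTION:
            if wild_seq[e.position] != e.wild_span:
                raise EditError(f"wild letter mismatch at {e.position}")
            out.append(e.mut_span)
            cursor = e.position + 1
        elif e.kind == DELETION:
            if wild_seq[e.position : e.wild_end] != e.wild_span:
                raise EditError(f"wild span mismatch at {e.position}")
            cursor = e.wild_end
        else:  # insertion
            out.append(e.mut_span)
            cursor = e.position + 1
    out.append(wild_seq[cursor:])
    return "".join(out)


def invert_edits(edits: Sequence[Edit]) -> list[Edit]:
    """Re-express edits on mutant coordinates: the inverse mutation.

    Substitutions swap spans; insertions become deletions of the inserted
    span and vice versa.  Positions are shifted by the cumulative length
    change of all preceding edits.
    """
    inverted: list[Edit] = []
    offset = 0
    for e in sorted(edits, key=lambda x: (x.position, 1 if x.kind == INSERTION else 0)):
        if e.kind == SUBSTITUTION:
            inverted.append(Edit(SUBSTITUTION, e.position + offset, e.mut_span, e.wild_span))
        elif e.kind == DELETION:
            # deleted span is absent from the mutant: re-insert after the
            # residue preceding the deletion site
            inverted.append(Edit(INSERTION, e.position + offset - 1, mut_span=e.wild_span))
            offset -= len(e.wild_span)
        else:  # insertion -> deletion of the inserted span in mutant coords
            inverted.append(Edit(DELETION, e.position + offset + 1, wild_span=e.mut_span))
            offset += len(e.mut_span)
    return inverted


def edits_to_notation(edits: Sequence[Edit]) -> str:
    """Serialise edits back to the 1-based colon-separated notation."""
    tokens = []
    for e in sorted(edits, key=lambda x: (x.position, 1 if x.kind == INSERTION else 0)):
        if e.kind == SUBSTITUTION:
            tokens.append(f"{e.wild_span}{e.position + 1}{e.mut_span}")
        elif e.kind == DELETION:
            if len(e.wild_span) == 1:
                tokens.append(f"{e.wild_span}{e.position + 1}del")
            else:
                end = e.position + len(e.wild_span) - 1
                tokens.append(f"{e.wild_span[0]}{e.position + 1}_{e.wild_span[-1]}{end + 1}del")
        else:
            tokens.append(f"{e.position + 1}ins{e.mut_span}")
    return ":".join(tokens)


@dataclass
class MutationRecord:
    protein_id: str
    wild_seq: str
    mut_seq: str
    ddg: float
    reliable: bool = True
    direction: str = "direct"
    edits: list[Edit] | None = None

    def __post_init__(self) -> None:
        if not self.wild_seq or not self.mut_seq:
            raise ValueError("sequences must be non-empty")
        if self.direction not in ("direct", "inverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.edits is not None:
            produced = apply_edits(self.wild_seq, self.edits)
            if produced != self.mut_seq:
                raise EditError(
                    f"edits applied to wild_seq give {produced!r}, not mut_seq"
                )

    def validate_alphabet(self) -> bool:
        return set(self.wild_seq) <= _AA_SET and set(self.mut_seq) <= _AA_SET


def invert_record(r: MutationRecord) -> MutationRecord:
    """The inverse mutation: sequences swapped, ddG negated, edits re-derived."""
    return MutationRecord(
        protein_id=r.protein_id,
        wild_seq=r.mut_seq,
        mut_seq=r.wild_seq,
        ddg=-r.ddg,
        reliable=r.reliable,
        direction="inverse" if r.direction == "direct" else "direct",
        edits=invert_edits(r.edits) if r.edits is not None else None,
    )


@dataclass
class Dataset:
    records: list[MutationRecord] = field(default_factory=list)
    provenance: str = ""
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": r.protein_id,
                "wt_seq": r.wild_seq,
                "mut_seq": r.mut_seq,
                "ddG": r.ddg,
                "reliable": r.reliable,
                "direction": r.direction,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["protein_id", "wt_seq", "mut_seq", "ddG", "reliable", "direction"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def _parse_reliable(v) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unparseable reliability flag {v!r}")


def parse_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited mutation table into a :class:`Dataset`.

    ``column_map`` maps the logical fields {protein_id, wild_seq, mut_seq,
    edits, ddg, reliable} to column names in the file; the mutant sequence
    may be given explicitly (``mut_seq``) or as edit notation (``edits``) —
    an explicit mutant column takes precedence.  Rows that fail to parse are
    collected in ``Dataset.row_errors`` as (row number, message), never
    silently dropped.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for key in ("protein_id", "wild_seq", "ddg"):
        if cols[key] not in df.columns:
            raise KeyError(f"required column {cols[key]!r} (for {key}) missing from {path.name}")
    has_mut = cols["mut_seq"] in df.columns
    has_edits = cols["edits"] in df.columns
    if not has_mut and not has_edits:
        raise KeyError(
            f"need a mutant column: neither {cols['mut_seq']!r} nor {cols['edits']!r} present"
        )
    has_rel = cols["reliable"] in df.columns
    has_dir = cols["direction"] in df.columns

    records: list[MutationRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header line
        row = dict(zip(df.columns, row))
        try:
            wild = row[cols["wild_seq"]].strip().upper()
            edits = None
            mut = None
            if has_edits and row[cols["edits"]].strip():
                edits = parse_edit_notation(row[cols["edits"]].strip(), wild)
            if has_mut and row[cols["mut_seq"]].strip():
                mut = row[cols["mut_seq"]].strip().upper()
            if mut is None:
                if edits is None:
                    raise ValueError("no mutant sequence or edit notation")
                mut = apply_edits(wild, edits)
            elif edits is not None and apply_edits(wild, edits) != mut:
                # the explicit mutant column is authoritative; stale notation
                # is surfaced as a row error rather than silently ignored
                raise ValueError("edit notation inconsistent with explicit mutant sequence")
            try:
                ddg = float(row[cols["ddg"]])
            except ValueError:
                raise ValueError(f"unparseable ddG value {row[cols['ddg']]!r}") from None
            reliable = _parse_reliable(row[cols["reliable"]]) if has_rel else True
            direction = row[cols["direction"]].strip() if has_dir else "direct"
            records.append(
                MutationRecord(
                    protein_id=row[cols["protein_id"]].strip(),
                    wild_seq=wild,
                    mut_seq=mut,
                    ddg=ddg,
                    reliable=reliable,
                    direction=direction or "direct",
                    edits=edits,
                )
            )
        except (ValueError, EditError, KeyError) as exc:
            errors.append((i, str(exc)))
    return Dataset(records=records, provenance=str(path), row_errors=errors)


def augment_antisymmetric(d: Dataset) -> Dataset:
    """Merge every direct record with its inversion (2n records, ddG sum 0)."""
    for r in d.records:
        if r.direction != "direct":
            raise ValueError("augment_antisymmetric expects direct records only")
    out = list(d.records) + [invert_record(r) for r in d.records]
    seen: set[tuple[str, str]] = set()
    dups = 0
    for r in out:
        key = (r.wild_seq, r.mut_seq)
        if key in seen:
            dups += 1
        seen.add(key)
    if dups:
        warnings.warn(f"{dups} duplicate (wild, mutant) pairs after antisymmetric merge; kept")
    return Dataset(records=out, provenance=d.provenance + "+inverse")


def filter_records(
    d: Dataset,
    drop_unreliable: bool = True,
    drop_nonstandard: bool = True,
    max_length: int | None = None,
) -> tuple[Dataset, dict[str, int]]:
    """Apply the curation rules; returns (filtered dataset, removal counts).

    Rules: drop records flagged unreliable; drop records whose sequences
    contain non-standard amino-acid letters; optionally drop records whose
    wild or mutant sequence exceeds ``max_length`` residues.
    """
    report = {"unreliable": 0, "nonstandard": 0, "too_long": 0}
    kept: list[MutationRecord] = []
    for r in d.records:
        if drop_unreliable and not r.reliable:
            report["unreliable"] += 1
            continue
        if drop_nonstandard and not r.validate_alphabet():
            report["nonstandard"] += 1
            continue
        if max_length is not None and max(len(r.wild_seq), len(r.mut_seq)) > max_length:
            report["too_long"] += 1
            continue
        kept.append(r)
    return Dataset(records=kept, provenance=d.provenance), report


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def sequence_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment.

    Scoring: match 1, mismatch 0, affine gaps (open -10, extend -0.5);
    identity = 100 * identical columns / alignment length (gaps included).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    c = aln.counts()
    return 100.0 * c.identities / (c.gaps + c.identities + c.mismatches)


def split_by_identity(train: Dataset, test: Dataset, threshold: float = 25.0) -> Dataset:
    """Subset of ``test`` whose wild sequences stay below ``threshold`` %
    identity against every training wild sequence (leakage control)."""
    if not 0.0 < threshold < 100.0 and threshold != 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    train_seqs = sorted({r.wild_seq for r in train.records})
    cache: dict[str, float] = {}
    kept = []
    for r in test.records:
        if r.wild_seq not in cache:
            cache[r.wild_seq] = max(
                (sequence_identity(r.wild_seq, t) for t in train_seqs), default=0.0
            )
        if cache[r.wild_seq] < threshold:
            kept.append(r)
    return Dataset(records=kept, provenance=test.provenance + f"+id<{threshold:g}%")


def filter_report_json(report: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
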