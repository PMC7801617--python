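"""COSMIC-style mutation catalog parsing and validation.

Coordinates are protein-level, 1-based and inclusive throughout. Both
one-letter ("L2509P", optionally "p."-prefixed) and three-letter
("p.Leu2509Pro") substitution dialects are accepted and normalized to the
canonical one-letter id.
"""
from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

from .errors import (
    CatalogFileError,
    MalformedTokenError,
    NonStandardResidueError,
    SynonymousSubstitutionError,
)

log = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_THREE_TO_ONE = {k.upper(): v.upper() for k, v in protein_letters_3to1.items()}

_TOKEN_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{3}|[A-Za-z])(\d+)([A-Za-z]{3}|[A-Za-z*])$", re.IGNORECASE
)
# crude classifiers for rows that are dropped (not missense)
_NONSENSE_RE = re.compile(r"(\*|Ter)$", re.IGNORECASE)
_FS_INDEL_RE = re.compile(r"(fs|del|ins|dup)", re.IGNORECASE)


@dataclass(frozen=True)
class MutationRecord:
    """One protein-level missense substitution with catalog metadata."""

    wt_aa: str
    position: int
    mut_aa: str
    recurrence: int = 0
    tissue: str = ""
    histology: str = ""

    def __post_init__(self):
        if self.wt_aa not in STANDARD_AA or self.mut_aa not in STANDARD_AA:
            raise NonStandardResidueError(
                f"non-standard amino acid in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise SynonymousSubstitutionError(
                f"synonymous substitution {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise MalformedTokenError(f"position must be >= 1, got {self.position}")
        if self.recurrence < 0:
            raise MalformedTokenError("recurrence must be non-negative")

    @property
    def id(self) -> str:
        """Canonical "WT + position + MUT" identifier, e.g. ``L2509P``."""
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ReferenceSequence:
    """A named protein sequence, addressed with 1-based residue indices."""

    name: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty reference sequence")
        bad = set(self.residues.upper()) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard letters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1].upper()


def _normalize_letter(letter: str) -> str:
    """Map a one- or three-letter residue code to upper-case one-letter form."""
    if len(letter) == 3:
        code = _THREE_TO_ONE.get(letter.upper())
        if code is None:
            raise NonStandardResidueError(f"unknown three-letter code {letter!r}")
        return code
    return letter.upper()


def parse_substitution(token: str) -> MutationRecord:
    """Parse a protein substitution token into a (wt, position, mut) record.

    Accepts ``L2509P``, ``p.L2509P`` and ``p.Leu2509Pro``; case-insensitive.
    Raises :class:`MalformedTokenError`, :class:`SynonymousSubstitutionError`
    or :class:`NonStandardResidueError` as distinct failure classes.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise MalformedTokenError(f"cannot parse substitution token {token!r}")
    wt_raw, pos, mut_raw = m.groups()
    wt = _normalize_letter(wt_raw)
    mut = _normalize_letter(mut_raw) if mut_raw != "*" else "*"
    if wt not in STANDARD_AA:
        raise NonStandardResidueError(f"non-standard wild-type letter in {token!r}")
    if mut not in STANDARD_AA:
        raise NonStandardResidueError(f"non-standard mutant letter in {token!r}")
    if wt == mut:
        raise SynonymousSubstitutionError(f"synonymous substitution {token!r}")
    return MutationRecord(wt_aa=wt, position=int(pos), mut_aa=mut)


def classify_token(token: str) -> str:
    """Classify a mutation token: missense / nonsense / frameshift_or_indel /
    synonymous / malformed. Used to tally dropped catalog rows."""
    t = token.strip()
    if _FS_INDEL_RE.search(t):
        return "frameshift_or_indel"
    if _NONSENSE_RE.search(t):
        return "nonsense"
    try:
        parse_substitution(t)
        return "missense"
    except SynonymousSubstitutionError:
        return "synonymous"
    except CatalogParseErrorTuple:  # pragma: no cover - see alias below
        return "malformed"
    except Exception:
        return "malformed"


# alias so classify_token's except clause reads clearly
CatalogParseErrorTuple = (MalformedTokenError, NonStandardResidueError)


@dataclass(frozen=True)
class CatalogDialect:
    """Column naming and separator for delimited catalog files."""

    mutation: str = "mutation"
    recurrence: str = "recurrence"
    tissue: str = "tissue"
    histology: str = "histology"
    sep: str = "\t"


@dataclass
class CatalogLoad:
    """Result of :func:`load_catalog`: retained records plus a drop tally."""

    records: list[MutationRecord]
    dropped: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def load_catalog(path: str | Path, dialect: CatalogDialect | None = None) -> CatalogLoad:
    """Load a delimited mutation catalog, keeping missense rows only.

    Non-missense rows (nonsense, frameshift/indel, synonymous, malformed) are
    counted per class in the returned tally and logged. Duplicate ids are
    merged by summing recurrence (first row's metadata wins); input row order
    is otherwise preserved.
    """
    dialect = dialect or CatalogDialect()
    path = Path(path)
    if not path.exists():
        raise CatalogFileError(f"catalog file not found: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.sep, dtype=str, comment="#")
    except Exception as exc:
        raise CatalogFileError(f"unreadable catalog file {path}: {exc}") from exc
    if dialect.mutation not in df.columns:
        raise CatalogFileError(
            f"missing mandatory column {dialect.mutation!r} in {path} "
            f"(found {list(df.columns)})"
        )

    by_id: dict[str, MutationRecord] = {}
    order: list[str] = []
    dropped: Counter = Counter()
    for _, row in df.iterrows():
        token = str(row[dialect.mutation])
        kind = classify_token(token)
        if kind != "missense":
            dropped[kind] += 1
            continue
        rec = parse_substitution(token)
        recurrence = 0
        if dialect.recurrence in df.columns and pd.notna(row.get(dialect.recurrence)):
            recurrence = int(float(row[dialect.recurrence]))
        rec = replace(
            rec,
            recurrence=recurrence,
            tissue=str(row.get(dialect.tissue, "") or "") if dialect.tissue in df.columns else "",
            histology=str(row.get(dialect.histology, "") or "")
            if dialect.histology in df.columns
            else "",
        )
        if rec.id in by_id:
            prev = by_id[rec.id]
            by_id[rec.id] = replace(prev, recurrence=prev.recurrence + rec.recurrence)
        else:
            by_id[rec.id] = rec
            order.append(rec.id)
    if dropped:
        log.info("dropped non-missense rows: %s", dict(dropped))
    return CatalogLoad(records=[by_id[i] for i in order], dropped=dropped)


@dataclass(frozen=True)
class ValidationIssue:
    id: str
    failure_class: str  # out_of_range | wt_mismatch
    detail: str


@dataclass
class CatalogValidation:
    records: list[MutationRecord]
    report: list[ValidationIssue]


def validate_catalog(
    records: list[MutationRecord] | CatalogLoad, ref: ReferenceSequence
) -> CatalogValidation:
    """Check every record against the reference sequence.

    Records whose position exceeds the sequence or whose wild-type letter
    disagrees with the reference are collected into the validation report
    (with both letters) rather than silently dropped.
    """
    if isinstance(records, CatalogLoad):
        records = records.records
    kept: list[MutationRecord] = []
    issues: list[ValidationIssue] = []
    for rec in records:
        if rec.position > len(ref):
            issues.append(
                ValidationIssue(rec.id, "out_of_range", f"position {rec.position} > {len(ref)}")
            )
            continue
        expected = ref.residue(rec.position)
        if expected != rec.wt_aa:
            issues.append(
                ValidationIssue(
                    rec.id,
                    "wt_mismatch",
                    f"catalog says {rec.wt_aa}, reference has {expected} at {rec.position}",
                )
            )
            continue
        kept.append(rec)
    return CatalogValidation(records=kept, report=issues)


def load_reference(path: str | Path, name: str | None = None) -> ReferenceSequence:
    """Read the first record of a FASTA file as the reference sequence."""
    path = Path(path)
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise CatalogFileError(f"no FASTA record in {path}")
    return ReferenceSequence(name=name or record.id, residues=str(record.seq).upper())


def write_catalog(records: list[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "mutation": r.id,
                "recurrence": r.recurrence,
                "tissue": r.tissue,
                "histology": r.histology,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_validation_report(report: list[ValidationIssue], path: str | Path) -> None:
    pd.DataFrame([i.__dict__ for i in report], columns=["id", "failure_class", "detail"]).to_csv(
        path, sep="\t", index=False
    )
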