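"""Substitution-matrix penalties and polarity-transition classes.

Two normalization schemes coexist:

``row_range``
    A computable default. For a substitution wt→mut under matrix M the
    penalty is ``(M[wt,wt] − M[wt,mut]) / (M[wt,wt] − min_x M[wt,x])``,
    clamped to [0, 1]: 0 at identity, 1 for the worst substitution of that
    wild-type row.

``fixture``
    A verbatim lookup in a supplied normalized-score table (TSV: wt, mut,
    matrix, value). This is how externally normalized scores — including
    published per-mutation values — enter the pipeline unaltered; values may
    be negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Align import substitution_matrices

from .catalog import STANDARD_AA
from .errors import MatrixError

AA20 = tuple(sorted(STANDARD_AA))


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid substitution score table."""

    name: str
    scores: dict[tuple[str, str], float]

    def __post_init__(self):
        for a in AA20:
            for b in AA20:
                if (a, b) not in self.scores:
                    raise MatrixError(f"{self.name}: pair ({a},{b}) undefined")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise MatrixError(f"{self.name}: asymmetric at ({a},{b})")

    def score(self, wt: str, mut: str) -> float:
        key = (wt.upper(), mut.upper())
        if key not in self.scores:
            raise MatrixError(f"{self.name}: letter pair {key} absent")
        return self.scores[key]

    def row_min(self, wt: str) -> float:
        wt = wt.upper()
        if wt not in STANDARD_AA:
            raise MatrixError(f"{self.name}: letter {wt!r} absent")
        return min(self.scores[(wt, x)] for x in AA20)


def blosum62() -> SubstitutionMatrix:
    """The canonical BLOSUM62 matrix (via Biopython), restricted to the 20
    standard amino acids."""
    m = substitution_matrices.load("BLOSUM62")
    scores = {(a, b): float(m[a, b]) for a in AA20 for b in AA20}
    return SubstitutionMatrix(name="BLOSUM62", scores=scores)


def load_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Read an NCBI-style square substitution-matrix text file."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    scores: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0].upper()
        for col, val in zip(header, parts[1:]):
            scores[(row, col.upper())] = float(val)
    scores = {k: v for k, v in scores.items() if k[0] in STANDARD_AA and k[1] in STANDARD_AA}
    return SubstitutionMatrix(name=name or path.stem, scores=scores)


def write_matrix(matrix: SubstitutionMatrix, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("  " + " ".join(AA20) + "\n")
        for a in AA20:
            fh.write(a + " " + " ".join(f"{matrix.scores[(a, b)]:g}" for b in AA20) + "\n")


def matrix_score(wt: str, mut: str, matrix: SubstitutionMatrix) -> float:
    """Exact table lookup of the raw substitution score."""
    return matrix.score(wt, mut)


@dataclass(frozen=True)
class NormalizedScoreTable:
    """Fixture table of externally normalized substitution scores, keyed by
    (wt, mut, matrix name)."""

    values: dict[tuple[str, str, str], float]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizedScoreTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in ("wt", "mut", "matrix", "value"):
            if col not in df.columns:
                raise MatrixError(f"normalized-score table {path} lacks column {col!r}")
        values = {
            (str(r.wt).upper(), str(r.mut).upper(), str(r.matrix)): float(r.value)
            for r in df.itertuples()
        }
        return cls(values=values)

    def lookup(self, wt: str, mut: str, matrix_name: str) -> float:
        key = (wt.upper(), mut.upper(), matrix_name)
        if key not in self.values:
            raise MatrixError(f"no fixture normalized score for {key}")
        return self.values[key]


def normalize_substitution(
    wt: str,
    mut: str,
    matrix: SubstitutionMatrix,
    scheme: str = "row_range",
    fixture: NormalizedScoreTable | None = None,
) -> float:
    """Normalized substitution penalty.

    ``row_range``: 0 at identity, 1 at the wild-type row minimum, clamped to
    [0, 1]. ``fixture``: verbatim lookup in the supplied table (may be
    negative).
    """
    if scheme == "row_range":
        diag = matrix.score(wt, wt)
        raw = matrix.score(wt, mut)
        denom = diag - matrix.row_min(wt)
        if denom == 0:  # degenerate flat row
            return 0.0
        val = (diag - raw) / denom
        return min(1.0, max(0.0, val))
    if scheme == "fixture":
        if fixture is None:
            raise MatrixError("fixture scheme requires a NormalizedScoreTable")
        return fixture.lookup(wt, mut, matrix.name)
    raise MatrixError(f"unknown normalization scheme {scheme!r}")


# --- polarity ---------------------------------------------------------------

HYDROPHOBIC = "hydrophobic"
POLAR = "polar-uncharged"
POSITIVE = "charged-positive"
NEGATIVE = "charged-negative"

#: Transition classes emitted by :func:`polarity_transition`.
TRANSITION_NONE = "none"
TRANSITIONS = (
    TRANSITION_NONE,
    "hydrophobic->polar",
    "hydrophobic->charged",
    "polar->hydrophobic",
    "charge_change",
    "other",
)


def _default_classes() -> dict[str, str]:
    classes = {}
    for aa in "AVLIMFWCPG":
        classes[aa] = HYDROPHOBIC
    for aa in "STNQYH":
        classes[aa] = POLAR
    for aa in "DE":
        classes[aa] = NEGATIVE
    for aa in "KR":
        classes[aa] = POSITIVE
    return classes


@dataclass(frozen=True)
class PolarityScheme:
    """Total map amino acid → polarity class (config-replaceable default)."""

    class_of: dict[str, str] = field(default_factory=_default_classes)

    def __post_init__(self):
        missing = STANDARD_AA - set(self.class_of)
        if missing:
            raise MatrixError(f"polarity scheme incomplete, missing {sorted(missing)}")


def polarity_transition(wt: str, mut: str, scheme: PolarityScheme | None = None) -> str:
    """Deterministic transition class for the ordered polarity-class pair.

    "none" iff both residues share a class; hydrophilic→hydrophilic swaps
    across charge signs report "charge_change"; everything else that crosses
    class boundaries without a dedicated label is "other".
    """
    scheme = scheme or PolarityScheme()
    a = scheme.class_of[wt.upper()]
    b = scheme.class_of[mut.upper()]
    if a == b:
        return TRANSITION_NONE
    charged = (POSITIVE, NEGATIVE)
    if a == HYDROPHOBIC and b == POLAR:
        return "hydrophobic->polar"
    if a == HYDROPHOBIC and b in charged:
        return "hydrophobic->charged"
    if a == POLAR and b == HYDROPHOBIC:
        return "polar->hydrophobic"
    if a in charged and b in charged:
        return "charge_change"
    return "other"
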