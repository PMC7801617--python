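"""Ingestion of external predictor evidence.

Two kinds of evidence enter the pipeline as delimited files, never via live
web queries: a per-mutation pathogenicity probability (PON-P2 style, in
[0, 1]) and a per-residue evolutionary-conservation profile (ConSurf style,
either integer grades 1–9 or continuous scores).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import EvidenceError, MissingEvidenceError

log = logging.getLogger(__name__)

CONSERVATION_MODES = ("grade", "continuous", "fixture")


@dataclass(frozen=True)
class PathogenicityEvidence:
    mutation_id: str
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise EvidenceError(
                f"{self.mutation_id}: probability {self.probability} outside [0,1]"
            )


def load_pathogenicity(
    path: str | Path, id_col: str = "mutation", prob_col: str = "probability", sep: str = "\t"
) -> dict[str, PathogenicityEvidence]:
    """Load per-mutation pathogenicity probabilities.

    Identical duplicate rows collapse silently; duplicates with conflicting
    probabilities are an error.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in (id_col, prob_col):
        if col not in df.columns:
            raise EvidenceError(f"pathogenicity file {path} lacks column {col!r}")
    out: dict[str, PathogenicityEvidence] = {}
    for row in df.itertuples():
        mid = str(getattr(row, id_col))
        prob = float(getattr(row, prob_col))
        ev = PathogenicityEvidence(mid, prob)
        if mid in out and out[mid].probability != prob:
            raise EvidenceError(
                f"conflicting probabilities for {mid}: {out[mid].probability} vs {prob}"
            )
        out[mid] = ev
    return out


def write_pathogenicity(
    evidence: dict[str, PathogenicityEvidence], path: str | Path
) -> None:
    pd.DataFrame(
        [{"mutation": e.mutation_id, "probability": e.probability} for e in evidence.values()]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ConservationProfile:
    """position → raw conservation value, plus the normalization mode.

    Modes: ``grade`` (integer 1–9, mapped to (g−1)/8), ``continuous``
    (min–max over the profile), ``fixture`` (verbatim passthrough of already
    normalized values, range-checked to [−1, 1] and logged if outside [0, 1]).
    """

    values: dict[int, float]
    mode: str = "grade"

    def __post_init__(self):
        if self.mode not in CONSERVATION_MODES:
            raise EvidenceError(f"unknown conservation mode {self.mode!r}")
        if self.mode == "grade":
            for pos, v in self.values.items():
                if not (float(v).is_integer() and 1 <= v <= 9):
                    raise EvidenceError(f"grade {v} at position {pos} not an integer in 1..9")


def load_conservation(
    path: str | Path, mode: str = "grade", value_col: str | None = None
) -> ConservationProfile:
    """Read a conservation table (``position`` + value column), tolerant of
    ``#`` comment headers. The value column defaults to ``grade`` in grade
    mode and to the first of ``score``/``value`` otherwise."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in df.columns:
        raise EvidenceError(f"conservation file {path} lacks 'position' column")
    if value_col is None:
        candidates = ("grade",) if mode == "grade" else ("score", "value")
        value_col = next((c for c in candidates if c in df.columns), None)
        if value_col is None:
            raise EvidenceError(
                f"conservation file {path} lacks a value column among {candidates}"
            )
    values = {int(r.position): float(getattr(r, value_col)) for r in df.itertuples()}
    return ConservationProfile(values=values, mode=mode)


def write_conservation(profile: ConservationProfile, path: str | Path) -> None:
    col = "grade" if profile.mode == "grade" else "score"
    pd.DataFrame(
        [{"position": p, col: v} for p, v in sorted(profile.values.items())]
    ).to_csv(path, sep="\t", index=False)


def normalize_conservation(profile: ConservationProfile, position: int) -> float:
    """Normalized conservation at ``position``.

    A missing position raises :class:`MissingEvidenceError` — never a silent
    zero; the missing-evidence policy lives with the caller.
    """
    if position not in profile.values:
        raise MissingEvidenceError(f"no conservation value for position {position}")
    raw = profile.values[position]
    if profile.mode == "grade":
        return (raw - 1.0) / 8.0
    if profile.mode == "continuous":
        lo = min(profile.values.values())
        hi = max(profile.values.values())
        if hi == lo:
            return 0.0
        return (raw - lo) / (hi - lo)
    # fixture: verbatim passthrough
    if not -1.0 <= raw <= 1.0:
        raise EvidenceError(f"fixture conservation {raw} at {position} outside [-1,1]")
    if not 0.0 <= raw <= 1.0:
        log.warning("fixture conservation %s at %s outside [0,1]", raw, position)
    return raw
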