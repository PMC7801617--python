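"""Bundled reference data: the talin-1 fixture bundle and matrices.

The bundled catalog of eleven talin-1 missense mutations, their predictor
evidence and the calibration final scores are the package's reference case.
Two bundled objects are synthetic stand-ins and say so in their names: the
reference sequence (``talin1_reference.synthetic.fasta``, real human talin-1
wild-type letters fixed only at the catalog positions) and the CBSM60-slot
matrix (:func:`cbsm60_synthetic`). The externally normalized penalties the
talin pipeline actually consumes ship in ``talin1_normalized_scores.tsv``.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..annotation import ProteinAnnotation, load_annotation
from ..catalog import CatalogLoad, ReferenceSequence, load_catalog, load_reference
from ..evidence import (
    ConservationProfile,
    PathogenicityEvidence,
    load_conservation,
    load_pathogenicity,
)
from ..substitution import AA20, NormalizedScoreTable, SubstitutionMatrix, blosum62


def _path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def talin1_reference() -> ReferenceSequence:
    """The bundled synthetic stand-in for the 2541-residue talin-1 sequence."""
    return load_reference(_path("talin1_reference.synthetic.fasta"), name="TLN1")


def talin1_annotation() -> ProteinAnnotation:
    """Talin-1 domain map, binding-site registry and residue environment."""
    return load_annotation(
        _path("talin1_annotation.yaml"),
        environment_table=_path("talin1_environment.tsv"),
    )


def talin1_catalog() -> CatalogLoad:
    return load_catalog(_path("talin1_catalog.tsv"))


def talin1_pathogenicity() -> dict[str, PathogenicityEvidence]:
    return load_pathogenicity(_path("talin1_pathogenicity.tsv"))


def talin1_conservation() -> ConservationProfile:
    return load_conservation(_path("talin1_conservation.tsv"), mode="fixture")


def talin1_normalized_scores() -> NormalizedScoreTable:
    return NormalizedScoreTable.from_tsv(_path("talin1_normalized_scores.tsv"))


def talin1_final_scores() -> dict[str, float]:
    df = pd.read_csv(_path("talin1_final_scores.tsv"), sep="\t", comment="#")
    return {str(r.mutation): float(r.final_score) for r in df.itertuples()}


# Kyte-Doolittle hydropathy, side-chain volume (A^3) and a coarse polarity
# code; only used to build the synthetic CBSM60-slot stand-in.
_PROPS = {
    "A": (1.8, 88.6, 0), "R": (-4.5, 173.4, 2), "N": (-3.5, 114.1, 1),
    "D": (-3.5, 111.1, 2), "C": (2.5, 108.5, 0), "Q": (-3.5, 143.8, 1),
    "E": (-3.5, 138.4, 2), "G": (-0.4, 60.1, 0), "H": (-3.2, 153.2, 1),
    "I": (4.5, 166.7, 0), "L": (3.8, 166.7, 0), "K": (-3.9, 168.6, 2),
    "M": (1.9, 162.9, 0), "F": (2.8, 189.9, 0), "P": (-1.6, 112.7, 0),
    "S": (-0.8, 89.0, 1), "T": (-0.7, 116.1, 1), "W": (-0.9, 227.8, 0),
    "Y": (-1.3, 193.6, 1), "V": (4.2, 140.0, 0),
}


def cbsm60_synthetic() -> SubstitutionMatrix:
    """Synthetic symmetric stand-in occupying the CBSM60 matrix slot.

    Built deterministically from standardized physicochemical property
    distances (hydropathy, volume, polarity): score = round(10 - 14*d) with
    d the pairwise distance scaled by its maximum. Not the published CBSM60
    table; the bundled fixture normalization table carries the published
    per-substitution normalized values instead.
    """
    P = np.array([_PROPS[a] for a in AA20], dtype=float)
    Z = (P - P.mean(axis=0)) / P.std(axis=0)
    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
    D /= D.max()
    S = np.round(10.0 - 14.0 * D)
    scores = {
        (a, b): float(S[i, j]) for i, a in enumerate(AA20) for j, b in enumerate(AA20)
    }
    return SubstitutionMatrix(name="CBSM60", scores=scores)


def default_matrices() -> dict[str, SubstitutionMatrix]:
    return {"BLOSUM62": blosum62(), "CBSM60": cbsm60_synthetic()}


@dataclass
class Talin1Bundle:
    """Everything needed to run the pipeline on the bundled talin-1 case."""

    reference: ReferenceSequence
    annotation: ProteinAnnotation
    catalog: CatalogLoad
    pathogenicity: dict[str, PathogenicityEvidence]
    conservation: ConservationProfile
    normalized_scores: NormalizedScoreTable
    final_scores: dict[str, float]
    matrices: dict[str, SubstitutionMatrix]


def talin1_bundle() -> Talin1Bundle:
    return Talin1Bundle(
        reference=talin1_reference(),
        annotation=talin1_annotation(),
        catalog=talin1_catalog(),
        pathogenicity=talin1_pathogenicity(),
        conservation=talin1_conservation(),
        normalized_scores=talin1_normalized_scores(),
        final_scores=talin1_final_scores(),
        matrices=default_matrices(),
    )
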