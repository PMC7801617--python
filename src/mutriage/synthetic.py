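"""Self-contained synthetic mutation studies with known ground truth.

The generator emits the full input bundle the real loaders read — reference
FASTA, annotation YAML, environment TSV, catalog TSV, two evidence TSVs and
a truth TSV — so every pipeline stage is testable without any download.

Ground truth: each mutation carries a pathogenic/benign label drawn with the
configured prevalence; pathogenic mutations preferentially hit conserved,
buried positions with heavily penalized substitutions, benign ones the
opposite. The true final score applies the configured effect weights to the
noiseless features; the simulated pathogenicity probability is a logistic
readout of that score (its own weight is therefore fixed at zero when
building truth), and evidence files add clamped Gaussian noise of standard
deviation ``noise_sd`` on top of the noiseless values.

A single integer seed drives one named numpy Generator; the same seed and
config reproduce byte-identical output files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .annotation import (
    BindingSite,
    DomainInterval,
    ProteinAnnotation,
    ResidueEnvironment,
    write_annotation,
)
from .catalog import MutationRecord, ReferenceSequence, write_catalog
from .evidence import ConservationProfile, PathogenicityEvidence, write_pathogenicity
from .scoring import FEATURE_FIELDS, PipelineConfig, ScoreWeights
from .substitution import (
    AA20,
    SubstitutionMatrix,
    TRANSITION_NONE,
    normalize_substitution,
    polarity_transition,
)
from . import data as _data

_TISSUES = ("Skin", "Liver", "Breast", "Pancreas", "Large intestine", "Lung")
_HISTOLOGIES = ("Carcinoma", "Malignant melanoma", "Glioma", "Adenoma")


def default_effect_weights() -> ScoreWeights:
    """Ground-truth composite weights on the ~6–9 scale of the bundled
    reference scores.

    The pathogenicity-probability coefficient is zero because in the
    generative model that probability is a readout of the score, not one of
    its causes.
    """
    return ScoreWeights(
        intercept=5.0,
        coefficients={
            "pon_p2": 0.0,
            "blosum_norm": 1.0,
            "cbsm_norm": 1.0,
            "consurf_norm": 1.0,
            "buried": 0.5,
            "between_helices": 0.25,
            "polarity_changed": 0.5,
            "site_proximal": 0.5,
        },
        provenance="user",
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic screen.

    Defaults emulate the bundled reference case: a talin-sized protein
    (2541 residues, 19 tiled domains) and a COSMIC-scale missense catalog
    (258 mutations).
    """

    protein_length: int = 2541
    n_domains: int = 19
    buried_fraction: float = 0.5
    n_mutations: int = 258
    pathogenic_fraction: float = 0.2
    effect_weights: ScoreWeights = field(default_factory=default_effect_weights)
    noise_sd: float = 0.05
    seed: int = 0
    # logistic readout mapping true score -> pathogenicity probability
    pon_midpoint: float = 7.0
    pon_scale: float = 0.8
    proximity_window: int = 10

    def __post_init__(self):
        for name in ("buried_fraction", "pathogenic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.protein_length < 20 or self.n_mutations < 1 or self.n_domains < 1:
            raise ValueError("counts must be positive (and protein length >= 20)")
        if self.protein_length < 3 * self.n_domains:
            raise ValueError("protein too short to tile the requested domains")
        if self.n_mutations > 19 * self.protein_length:
            raise ValueError(
                f"infeasible: {self.n_mutations} mutations exceed the "
                f"{19 * self.protein_length} distinct substitutions available"
            )


@dataclass
class SyntheticStudy:
    """In-memory result of one generated study (plus file paths if written)."""

    config: SyntheticConfig
    reference: ReferenceSequence
    annotation: ProteinAnnotation
    catalog: list[MutationRecord]
    truth: pd.DataFrame  # id, position, label, true_score, all feature columns
    pathogenicity: dict[str, PathogenicityEvidence]
    conservation: ConservationProfile
    paths: dict[str, Path] = field(default_factory=dict)


def _tile_domains(rng: np.random.Generator, length: int, n: int) -> list[DomainInterval]:
    min_w = max(3, length // (4 * n))
    widths = rng.multinomial(length - min_w * n, np.full(n, 1.0 / n)) + min_w
    out, start = [], 1
    for i, w in enumerate(widths):
        out.append(DomainInterval(name=f"D{i + 1:02d}", segments=((start, start + int(w) - 1),)))
        start += int(w)
    return out


def _worst_and_mildest(matrix: SubstitutionMatrix) -> tuple[dict, dict]:
    """Per wild type: the 3 lowest- and 3 highest-scoring alternatives."""
    worst, mildest = {}, {}
    for wt in AA20:
        alts = sorted(
            (a for a in AA20 if a != wt), key=lambda a: matrix.score(wt, a)
        )
        worst[wt] = alts[:3]
        mildest[wt] = alts[-3:]
    return worst, mildest


def generate_synthetic_study(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> SyntheticStudy:
    """Generate one seeded synthetic study; optionally write the file bundle.

    Emitted files (in ``outdir``): ``reference.fasta``, ``annotation.yaml``,
    ``environment.tsv``, ``catalog.tsv``, ``pathogenicity.tsv``,
    ``conservation.tsv``, ``truth.tsv`` — all in the dialects the real
    loaders read.
    """
    rng = np.random.default_rng(config.seed)
    L = config.protein_length

    seq = "".join(rng.choice(list(AA20), size=L))
    reference = ReferenceSequence(name=f"synthetic_{config.seed}", residues=seq)

    domains = _tile_domains(rng, L, config.n_domains)
    n_sites = max(1, config.n_domains // 5)
    site_domains = rng.choice(len(domains), size=n_sites, replace=False)
    sites = []
    for k, di in enumerate(sorted(site_domains)):
        s, e = domains[di].segments[0]
        width = int(rng.integers(3, 9))
        lo = int(rng.integers(s, max(s + 1, e - width)))
        sites.append(
            BindingSite(
                name=f"site{k + 1}",
                residues=frozenset(range(lo, min(lo + width, e) + 1)),
                host_domain=domains[di].name,
            )
        )

    # residue environment: buried flag, then RSA from two disjoint regimes so
    # thresholding at 0.2 reproduces the flag exactly
    buried = rng.random(L) < config.buried_fraction
    rsa = np.where(
        buried,
        np.clip(0.2 * rng.beta(2.0, 2.0, size=L), 1e-4, 0.1999),
        np.clip(0.2 + 0.8 * rng.beta(2.0, 2.0, size=L), 0.2001, 0.9999),
    )
    bh = buried & (rng.random(L) < 0.3)
    environment = {
        i + 1: ResidueEnvironment(
            i + 1,
            "buried" if buried[i] else "surface",
            between_helices=bool(bh[i]),
            rsa=float(rsa[i]),
        )
        for i in range(L)
    }

    conservation_true = rng.beta(2.0, 2.0, size=L)

    annotation = ProteinAnnotation(
        protein=reference.name,
        length=L,
        domains=domains,
        binding_sites=sites,
        environment=environment,
        rsa={i + 1: float(rsa[i]) for i in range(L)},
    )

    matrices = _data.default_matrices()
    worst_b, mild_b = _worst_and_mildest(matrices["BLOSUM62"])

    labels = rng.random(config.n_mutations) < config.pathogenic_fraction
    w_path = np.exp(2.0 * conservation_true + 1.5 * buried)
    w_ben = np.exp(-2.0 * conservation_true - 1.5 * buried)
    w_path /= w_path.sum()
    w_ben /= w_ben.sum()

    records: list[MutationRecord] = []
    seen: set[tuple[int, str]] = set()
    truth_rows = []
    for label in labels:
        for _ in range(1000):
            pos = int(rng.choice(L, p=w_path if label else w_ben)) + 1
            wt = reference.residue(pos)
            pool = worst_b[wt] if label else mild_b[wt]
            mut = str(rng.choice(pool))
            if (pos, mut) not in seen:
                seen.add((pos, mut))
                break
        else:  # pragma: no cover - only reachable near saturation
            raise RuntimeError("could not place a unique mutation")
        rec = MutationRecord(
            wt_aa=wt,
            position=pos,
            mut_aa=mut,
            recurrence=1 + int(rng.poisson(0.3)),
            tissue=str(rng.choice(_TISSUES)),
            histology=str(rng.choice(_HISTOLOGIES)),
        )
        records.append(rec)

        # noiseless true features; the pipeline recomputes the matrix terms
        # with the same row_range scheme, so they are exact by construction
        fv_wo_pon = {
            "blosum_norm": normalize_substitution(wt, mut, matrices["BLOSUM62"]),
            "cbsm_norm": normalize_substitution(wt, mut, matrices["CBSM60"]),
            "consurf_norm": float(conservation_true[pos - 1]),
            "buried": int(buried[pos - 1]),
            "between_helices": int(bh[pos - 1]),
            "polarity_changed": int(polarity_transition(wt, mut) != TRANSITION_NONE),
            "site_proximal": int(
                annotation.binding_site_proximity(pos, config.proximity_window).is_proximal
            ),
        }
        w = config.effect_weights
        score = w.intercept + sum(
            w.coefficients[f] * v for f, v in fv_wo_pon.items()
        )
        pon = float(1.0 / (1.0 + np.exp(-(score - config.pon_midpoint) / config.pon_scale)))
        truth_rows.append(
            {
                "id": rec.id,
                "position": pos,
                "label": int(label),
                "true_score": score,
                "pon_p2": pon,
                **fv_wo_pon,
            }
        )

    truth = pd.DataFrame(truth_rows)[
        ["id", "position", "label", "true_score", *FEATURE_FIELDS]
    ]

    # noisy evidence files (clamped additive Gaussian noise)
    pon_noisy = np.clip(
        truth["pon_p2"].to_numpy() + rng.normal(0.0, config.noise_sd, len(truth)), 0.0, 1.0
    )
    pathogenicity = {
        rec.id: PathogenicityEvidence(rec.id, float(p))
        for rec, p in zip(records, pon_noisy)
    }
    cons_noisy = np.clip(
        conservation_true + rng.normal(0.0, config.noise_sd, L), 0.0, 1.0
    )
    conservation = ConservationProfile(
        values={i + 1: float(cons_noisy[i]) for i in range(L)}, mode="fixture"
    )

    study = SyntheticStudy(
        config=config,
        reference=reference,
        annotation=annotation,
        catalog=records,
        truth=truth,
        pathogenicity=pathogenicity,
        conservation=conservation,
    )
    if outdir is not None:
        study.paths = _write_bundle(study, Path(outdir))
    return study


def _write_bundle(study: SyntheticStudy, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.{ext}" for k, ext in (
        ("reference", "fasta"),
        ("annotation", "yaml"),
        ("environment", "tsv"),
        ("catalog", "tsv"),
        ("pathogenicity", "tsv"),
        ("conservation", "tsv"),
        ("truth", "tsv"),
    )}
    seq = study.reference.residues
    with open(paths["reference"], "w") as fh:
        fh.write(f">{study.reference.name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    write_annotation(study.annotation, paths["annotation"])
    env = study.annotation.environment
    pd.DataFrame(
        [
            {
                "position": p,
                "location_class": e.location_class,
                "rsa": round(e.rsa, 6),
                "bh": int(e.between_helices),
            }
            for p, e in sorted(env.items())
        ]
    ).to_csv(paths["environment"], sep="\t", index=False)
    write_catalog(study.catalog, paths["catalog"])
    write_pathogenicity(study.pathogenicity, paths["pathogenicity"])
    pd.DataFrame(
        [{"position": p, "score": v} for p, v in sorted(study.conservation.values.items())]
    ).to_csv(paths["conservation"], sep="\t", index=False)
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def pipeline_config_for(study: SyntheticStudy) -> PipelineConfig:
    """The scoring config matching the generator's conventions."""
    return PipelineConfig(
        scheme="row_range",
        proximity_window=study.config.proximity_window,
        threshold=study.config.pon_midpoint,
    )


def ranking_auc(scores, labels) -> float:
    """ROC-AUC of a score ranking against binary ground-truth labels."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))
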