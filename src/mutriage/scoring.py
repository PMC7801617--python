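"""Feature composition, weighted final score, calibration and ranking.

The final score is a linear composite of eight normalized evidence features:

    score = b0 + w·(pon_p2, blosum_norm, cbsm_norm, consurf_norm,
                    buried, between_helices, polarity_changed, site_proximal)

Weights are either user-supplied or calibrated by ordinary least squares
against reference final scores (rank-deficient designs fall back to the
minimum-norm pseudo-inverse solution, with the design rank reported).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    DEFAULT_PROXIMITY_WINDOW,
    MissingLocationError,
    ProteinAnnotation,
)
from .catalog import (
    CatalogLoad,
    MutationRecord,
    ReferenceSequence,
    load_catalog,
    validate_catalog,
)
from .errors import MissingEvidenceError, PipelineStageError, ScoringError
from .evidence import ConservationProfile, PathogenicityEvidence, normalize_conservation
from .substitution import (
    NormalizedScoreTable,
    PolarityScheme,
    SubstitutionMatrix,
    TRANSITION_NONE,
    normalize_substitution,
    polarity_transition,
)

log = logging.getLogger(__name__)

#: Field order of the feature vector; fixed, also the report column order.
FEATURE_FIELDS = (
    "pon_p2",
    "blosum_norm",
    "cbsm_norm",
    "consurf_norm",
    "buried",
    "between_helices",
    "polarity_changed",
    "site_proximal",
)

REPORT_COLUMNS = (
    "id",
    "recurrence",
    "tissue",
    "histology",
    "domain",
    "location",
    *FEATURE_FIELDS,
    "provenance",
    "final_score",
    "selected",
    "selection_reason",
)


@dataclass(frozen=True)
class FeatureVector:
    """Normalized evidence values entering the final score for one mutation."""

    pon_p2: float
    blosum_norm: float
    cbsm_norm: float
    consurf_norm: float
    buried: int
    between_helices: int
    polarity_changed: int
    site_proximal: int

    def __post_init__(self):
        for name in ("buried", "between_helices", "polarity_changed", "site_proximal"):
            if getattr(self, name) not in (0, 1):
                raise ScoringError(f"indicator {name} must be 0/1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_FIELDS], dtype=float)


@dataclass(frozen=True)
class ScoreWeights:
    """Intercept + one coefficient per feature field."""

    intercept: float
    coefficients: dict[str, float]
    provenance: str = "user"  # "user" | "fitted"

    def __post_init__(self):
        missing = set(FEATURE_FIELDS) - set(self.coefficients)
        if missing:
            raise ScoringError(f"weights missing coefficients for {sorted(missing)}")
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ScoringError("weights must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept] + [self.coefficients[f] for f in FEATURE_FIELDS], dtype=float
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreWeights":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            intercept=float(doc["intercept"]),
            coefficients={k: float(v) for k, v in doc["coefficients"].items()},
            provenance=str(doc.get("provenance", "user")),
        )

    @classmethod
    def from_array(cls, beta: np.ndarray, provenance: str = "fitted") -> "ScoreWeights":
        return cls(
            intercept=float(beta[0]),
            coefficients={f: float(b) for f, b in zip(FEATURE_FIELDS, beta[1:])},
            provenance=provenance,
        )


MISSING_POLICIES = ("fail", "drop", "impute")


@dataclass
class PipelineConfig:
    """Knobs of the scoring pipeline (all mirrored by CLI flags)."""

    scheme: str = "row_range"  # substitution normalization: row_range | fixture
    proximity_window: int = DEFAULT_PROXIMITY_WINDOW
    rsa_threshold: float | None = None  # None -> annotation default
    threshold: float = 7.4
    manual_includes: tuple[str, ...] = ()
    missing_policy: str = "fail"  # fail | drop | impute
    imputed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.missing_policy not in MISSING_POLICIES:
            raise ScoringError(f"unknown missing-evidence policy {self.missing_policy!r}")


@dataclass
class EvidenceBundle:
    """All external evidence needed to score a catalog."""

    pathogenicity: dict[str, PathogenicityEvidence]
    conservation: ConservationProfile
    normalized_table: NormalizedScoreTable | None = None


def compose_features(
    record: MutationRecord,
    annotation: ProteinAnnotation,
    matrices: dict[str, SubstitutionMatrix],
    evidence: EvidenceBundle,
    config: PipelineConfig | None = None,
    polarity_scheme: PolarityScheme | None = None,
) -> tuple[FeatureVector, dict[str, str]]:
    """Assemble the feature vector for one mutation.

    Returns the vector together with a per-feature provenance map
    (``fixture`` vs ``computed`` vs ``file``). Missing evidence raises
    :class:`MissingEvidenceError`; policy handling happens in
    :func:`run_pipeline`.
    """
    config = config or PipelineConfig()
    prov: dict[str, str] = {}

    if record.id not in evidence.pathogenicity:
        raise MissingEvidenceError(f"no pathogenicity probability for {record.id}")
    pon = evidence.pathogenicity[record.id].probability
    prov["pon_p2"] = "file"

    norms: dict[str, float] = {}
    for key, mat_name in (("blosum_norm", "BLOSUM62"), ("cbsm_norm", "CBSM60")):
        matrix = matrices[mat_name]
        norms[key] = normalize_substitution(
            record.wt_aa,
            record.mut_aa,
            matrix,
            scheme=config.scheme,
            fixture=evidence.normalized_table,
        )
        prov[key] = "fixture" if config.scheme == "fixture" else "computed"

    consurf = normalize_conservation(evidence.conservation, record.position)
    prov["consurf_norm"] = (
        "fixture" if evidence.conservation.mode == "fixture" else "file"
    )

    try:
        env = annotation.classify_location(record.position, config.rsa_threshold)
    except MissingLocationError as exc:
        raise MissingEvidenceError(
            f"no location class or RSA for {record.id} (position {record.position})"
        ) from exc
    buried = 1 if env.location_class == "buried" else 0
    bh = 1 if env.between_helices else 0
    prov["buried"] = prov["between_helices"] = (
        "table" if record.position in annotation.environment else "computed"
    )

    transition = polarity_transition(record.wt_aa, record.mut_aa, polarity_scheme)
    polarity_changed = 0 if transition == TRANSITION_NONE else 1
    prov["polarity_changed"] = "computed"

    prox = annotation.binding_site_proximity(record.position, config.proximity_window)
    prov["site_proximal"] = "computed"

    vec = FeatureVector(
        pon_p2=pon,
        blosum_norm=norms["blosum_norm"],
        cbsm_norm=norms["cbsm_norm"],
        consurf_norm=consurf,
        buried=buried,
        between_helices=bh,
        polarity_changed=polarity_changed,
        site_proximal=1 if prox.is_proximal else 0,
    )
    return vec, prov


def final_score(features: FeatureVector, weights: ScoreWeights) -> float:
    """Intercept plus dot product; linear, hence monotone in every feature
    for non-negative coefficients."""
    x = np.concatenate(([1.0], features.as_array()))
    return float(x @ weights.as_array())


@dataclass
class FitReport:
    rank: int
    residuals: list[float]  # fitted - target, per row in input order
    rmse: float


def fit_weights(
    rows: list[tuple[FeatureVector, float]], method: str = "ols"
) -> tuple[ScoreWeights, FitReport]:
    """Calibrate weights against reference final scores by least squares.

    Full-rank designs give the unique OLS solution; rank-deficient designs
    the minimum-norm pseudo-inverse solution (rank is reported and logged).
    """
    if method != "ols":
        raise ScoringError(f"unknown fitting method {method!r}")
    if len(rows) < 2:
        raise ScoringError("need at least 2 rows to fit weights")
    X = np.column_stack(
        [np.ones(len(rows)), np.vstack([fv.as_array() for fv, _ in rows])]
    )
    y = np.array([t for _, t in rows], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ScoringError("non-finite target score")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        log.info("rank-deficient design: rank %d < %d, minimum-norm solution", rank, X.shape[1])
    fitted = X @ beta
    resid = fitted - y
    report = FitReport(
        rank=int(rank),
        residuals=[float(r) for r in resid],
        rmse=float(np.sqrt(np.mean(resid**2))),
    )
    return ScoreWeights.from_array(beta, provenance="fitted"), report


@dataclass
class RankedCandidate:
    record: MutationRecord
    features: FeatureVector
    final_score: float
    selected: bool
    selection_reason: str  # above_threshold | manual_include | below_threshold
    domain: str = ""
    location: str = ""
    provenance: dict[str, str] = field(default_factory=dict)


def select_candidates(
    scored: list[tuple[MutationRecord, FeatureVector, float]],
    threshold: float,
    manual_includes: tuple[str, ...] | list[str] = (),
) -> list[RankedCandidate]:
    """Select score >= threshold plus explicit manual includes; sort by score
    descending with ties broken by catalog order."""
    ids = {rec.id for rec, _, _ in scored}
    for mid in manual_includes:
        if mid not in ids:
            raise ScoringError(f"manual include {mid!r} absent from catalog")
    manual = set(manual_includes)
    out: list[RankedCandidate] = []
    for rec, fv, score in scored:
        if score >= threshold:
            reason, sel = "above_threshold", True
        elif rec.id in manual:
            reason, sel = "manual_include", True
        else:
            reason, sel = "below_threshold", False
        out.append(RankedCandidate(rec, fv, score, sel, reason))
    out.sort(key=lambda c: -c.final_score)  # stable: ties keep catalog order
    return out


@dataclass
class PipelineResult:
    candidates: list[RankedCandidate]
    weights: ScoreWeights
    fit_report: FitReport | None
    report: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)
    validation_issues: list = field(default_factory=list)

    def write_report(self, path: str | Path) -> None:
        self.report.to_csv(path, sep="\t", index=False)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    catalog: str | Path | CatalogLoad | list[MutationRecord],
    reference: ReferenceSequence,
    annotation: ProteinAnnotation,
    matrices: dict[str, SubstitutionMatrix],
    evidence: EvidenceBundle,
    weights: ScoreWeights | None = None,
    calibration_rows: list[tuple[str, float]] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end: parse → validate → features → score → rank → select.

    ``weights`` and ``calibration_rows`` are alternatives: pass fixed weights,
    or pass (mutation id, reference score) pairs to calibrate against. Fully
    deterministic given inputs and config.
    """
    config = config or PipelineConfig()
    if weights is None and calibration_rows is None:
        raise ScoringError("provide either weights or calibration_rows")

    with _stage("parse"):
        if isinstance(catalog, (str, Path)):
            loaded = load_catalog(catalog)
            records, dropped = loaded.records, dict(loaded.dropped)
        elif isinstance(catalog, CatalogLoad):
            records, dropped = catalog.records, dict(catalog.dropped)
        else:
            records, dropped = list(catalog), {}

    with _stage("validate"):
        validation = validate_catalog(records, reference)
        records = validation.records

    with _stage("features"):
        rows: list[tuple[MutationRecord, FeatureVector, dict]] = []
        for rec in records:
            try:
                fv, prov = compose_features(
                    rec, annotation, matrices, evidence, config
                )
            except MissingEvidenceError:
                if config.missing_policy == "fail":
                    raise
                if config.missing_policy == "drop":
                    log.warning("dropping %s: missing evidence", rec.id)
                    continue
                fv, prov = _compose_with_imputation(
                    rec, annotation, matrices, evidence, config
                )
            rows.append((rec, fv, prov))

    with _stage("calibrate"):
        fit_report = None
        if weights is None:
            by_id = {rec.id: fv for rec, fv, _ in rows}
            fit_rows = []
            for mid, target in calibration_rows:
                if mid not in by_id:
                    raise ScoringError(f"calibration id {mid!r} not in scored catalog")
                fit_rows.append((by_id[mid], target))
            weights, fit_report = fit_weights(fit_rows)

    with _stage("score"):
        scored = [(rec, fv, final_score(fv, weights)) for rec, fv, _ in rows]

    with _stage("select"):
        candidates = select_candidates(scored, config.threshold, config.manual_includes)

    with _stage("report"):
        prov_by_id = {rec.id: prov for rec, _, prov in rows}
        for cand in candidates:
            cand.domain = annotation.locate_domain(cand.record.position)
            env = annotation.classify_location(cand.record.position, config.rsa_threshold)
            cand.location = env.location_class
            cand.provenance = prov_by_id[cand.record.id]
        report = pd.DataFrame(
            [
                {
                    "id": c.record.id,
                    "recurrence": c.record.recurrence,
                    "tissue": c.record.tissue,
                    "histology": c.record.histology,
                    "domain": c.domain,
                    "location": c.location,
                    **{f: getattr(c.features, f) for f in FEATURE_FIELDS},
                    "provenance": ";".join(
                        f"{k}={v}" for k, v in sorted(c.provenance.items())
                    ),
                    "final_score": c.final_score,
                    "selected": c.selected,
                    "selection_reason": c.selection_reason,
                }
                for c in candidates
            ],
            columns=list(REPORT_COLUMNS),
        )

    return PipelineResult(
        candidates=candidates,
        weights=weights,
        fit_report=fit_report,
        report=report,
        dropped=dropped,
        validation_issues=validation.report,
    )


def _compose_with_imputation(rec, annotation, matrices, evidence, config):
    """Retry composition filling missing pathogenicity/conservation with the
    configured neutral values."""
    ev = EvidenceBundle(
        pathogenicity=dict(evidence.pathogenicity),
        conservation=ConservationProfile(
            values=dict(evidence.conservation.values), mode=evidence.conservation.mode
        ),
        normalized_table=evidence.normalized_table,
    )
    if rec.id not in ev.pathogenicity:
        ev.pathogenicity[rec.id] = PathogenicityEvidence(
            rec.id, float(config.imputed.get("pon_p2", 0.5))
        )
    if rec.position not in ev.conservation.values:
        neutral = float(config.imputed.get("consurf_norm", 0.5))
        if ev.conservation.mode == "grade":
            neutral = float(config.imputed.get("consurf_grade", 5))
        ev.conservation.values[rec.position] = neutral
    fv, prov = compose_features(rec, annotation, matrices, ev, config)
    prov = {**prov, "imputed": "true"}
    return fv, prov
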