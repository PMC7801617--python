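"""Feature composition, linear scoring, OLS calibration, selection."""
import numpy as np
import pytest

from mutriage.catalog import MutationRecord
from mutriage.errors import MissingEvidenceError, ScoringError
from mutriage.scoring import (
    FEATURE_FIELDS,
    EvidenceBundle,
    FeatureVector,
    PipelineConfig,
    ScoreWeights,
    compose_features,
    final_score,
    fit_weights,
    run_pipeline,
    select_candidates,
)

FIXTURE_CFG = PipelineConfig(scheme="fixture", threshold=7.4, manual_includes=("E1770Q",))


def _vec(**overrides) -> FeatureVector:
    base = dict(pon_p2=0.5, blosum_norm=0.5, cbsm_norm=0.0, consurf_norm=0.0,
                buried=1, between_helices=0, polarity_changed=0, site_proximal=0)
    base.update(overrides)
    return FeatureVector(**base)


def _weights(intercept=0.0, **coefs) -> ScoreWeights:
    full = {f: 0.0 for f in FEATURE_FIELDS}
    full.update(coefs)
    return ScoreWeights(intercept=intercept, coefficients=full)


def _evidence(bundle):
    return EvidenceBundle(bundle.pathogenicity, bundle.conservation,
                          bundle.normalized_scores)


def test_compose_features_reference_row(bundle):
    rec = next(r for r in bundle.catalog if r.id == "I392N")
    fv, prov = compose_features(rec, bundle.annotation, bundle.matrices,
                                _evidence(bundle), FIXTURE_CFG)
    assert fv == FeatureVector(pon_p2=0.86, blosum_norm=1.0, cbsm_norm=0.83,
                               consurf_norm=1.0, buried=1, between_helices=0,
                               polarity_changed=1, site_proximal=1)
    assert prov["blosum_norm"] == "fixture" and prov["pon_p2"] == "file"


def test_compose_features_missing_evidence_fails(bundle):
    rec = MutationRecord("P", 600, "L")  # unannotated position, no evidence
    with pytest.raises(MissingEvidenceError):
        compose_features(rec, bundle.annotation, bundle.matrices,
                         _evidence(bundle), FIXTURE_CFG)


def test_final_score_arithmetic():
    assert final_score(_vec(), _weights(intercept=7.0)) == 7.0
    unit = ScoreWeights(intercept=0.0, coefficients={f: 1.0 for f in FEATURE_FIELDS})
    assert final_score(_vec(), unit) == 2.0


def test_final_score_monotone_for_nonnegative_weights():
    w = ScoreWeights(intercept=1.0, coefficients={f: 0.5 for f in FEATURE_FIELDS})
    base = _vec()
    s0 = final_score(base, w)
    for f in FEATURE_FIELDS:
        cur = getattr(base, f)
        if cur in (0, 0.0):
            bumped = FeatureVector(**{**base.__dict__, f: 1 if isinstance(cur, int) else 0.9})
            assert final_score(bumped, w) >= s0


def test_fit_weights_exact_recovery():
    rng = np.random.default_rng(3)
    true = ScoreWeights(
        intercept=2.0,
        coefficients={f: w for f, w in zip(FEATURE_FIELDS, rng.normal(size=8))},
    )
    rows = []
    for _ in range(40):
        fv = FeatureVector(
            pon_p2=rng.random(), blosum_norm=rng.random(), cbsm_norm=rng.random(),
            consurf_norm=rng.random(), buried=int(rng.integers(2)),
            between_helices=int(rng.integers(2)), polarity_changed=int(rng.integers(2)),
            site_proximal=int(rng.integers(2)),
        )
        rows.append((fv, final_score(fv, true)))
    fitted, report = fit_weights(rows)
    assert np.abs(fitted.as_array() - true.as_array()).max() <= 1e-8
    assert report.rank == 9


def test_fit_weights_minimum_norm_when_rank_deficient():
    """3 rows, 9 parameters: zero residual, rank equals the row count."""
    rng = np.random.default_rng(4)
    rows = []
    for _ in range(3):
        fv = FeatureVector(
            pon_p2=rng.random(), blosum_norm=rng.random(), cbsm_norm=rng.random(),
            consurf_norm=rng.random(), buried=int(rng.integers(2)),
            between_helices=int(rng.integers(2)), polarity_changed=int(rng.integers(2)),
            site_proximal=int(rng.integers(2)),
        )
        rows.append((fv, rng.normal()))
    fitted, report = fit_weights(rows)
    assert report.rank == 3
    # verify zero residual by direct multiplication
    for fv, target in rows:
        assert final_score(fv, fitted) == pytest.approx(target, abs=1e-10)


def test_fit_weights_input_validation():
    with pytest.raises(ScoringError):
        fit_weights([(_vec(), 1.0)])
    with pytest.raises(ScoringError):
        fit_weights([(_vec(), np.nan), (_vec(buried=0), 1.0)])


def test_select_candidates_threshold_and_manual(bundle, reference_rows):
    scored = [
        (rec, _vec(), reference_rows[rec.id][-1]) for rec in bundle.catalog
    ]
    out = select_candidates(scored, threshold=7.4, manual_includes=("E1770Q",))
    assert sum(c.selected for c in out) == 11
    reasons = {c.record.id: c.selection_reason for c in out}
    assert reasons["E1770Q"] == "manual_include"
    assert all(v == "above_threshold" for k, v in reasons.items() if k != "E1770Q")
    scores = [c.final_score for c in out]
    assert scores == sorted(scores, reverse=True)


def test_select_candidates_edges(bundle):
    scored = [(rec, _vec(), 1.0) for rec in bundle.catalog]
    assert all(c.selected for c in select_candidates(scored, threshold=0.0))
    assert select_candidates([], threshold=0.0) == []
    with pytest.raises(ScoringError):
        select_candidates(scored, threshold=0.0, manual_includes=("Z9Z",))


def test_pipeline_deterministic_reports(bundle, tmp_path):
    def run():
        res = run_pipeline(bundle.catalog, bundle.reference, bundle.annotation,
                           bundle.matrices, _evidence(bundle),
                           calibration_rows=sorted(bundle.final_scores.items()),
                           config=FIXTURE_CFG)
        p = tmp_path / "report.tsv"
        res.write_report(p)
        return p.read_bytes()

    assert run() == run()


def test_pipeline_score_invariant_to_catalog_order(bundle):
    ev = _evidence(bundle)
    weights = _weights(intercept=1.0, pon_p2=2.0, consurf_norm=1.0)
    fwd = run_pipeline(bundle.catalog, bundle.reference, bundle.annotation,
                       bundle.matrices, ev, weights=weights, config=FIXTURE_CFG)
    rev = run_pipeline(list(reversed(bundle.catalog.records)), bundle.reference,
                       bundle.annotation, bundle.matrices, ev, weights=weights,
                       config=FIXTURE_CFG)
    a = fwd.report.set_index("id")["final_score"]
    b = rev.report.set_index("id")["final_score"]
    assert (a.sort_index() == b.sort_index()).all()


def test_pipeline_missing_policy_drop_and_impute(bundle):
    ev = _evidence(bundle)
    weights = _weights(intercept=5.0, pon_p2=1.0)

    # unannotated position (no environment row, no evidence): dropped
    wt600 = bundle.reference.residue(600)
    unannotated = MutationRecord(wt600, 600, "L" if wt600 != "L" else "P")
    cfg_drop = PipelineConfig(scheme="fixture", threshold=0.0, missing_policy="drop")
    res = run_pipeline(bundle.catalog.records + [unannotated], bundle.reference,
                       bundle.annotation, bundle.matrices, ev, weights=weights,
                       config=cfg_drop)
    assert unannotated.id not in set(res.report["id"])
    assert len(res.report) == 11

    # annotated position but no pathogenicity entry: imputed neutral value
    novel = MutationRecord("I", 392, "V")  # same residue as I392N, new substitution
    cfg_imp = PipelineConfig(scheme="row_range", threshold=0.0,
                             missing_policy="impute", imputed={"pon_p2": 0.5})
    res2 = run_pipeline(bundle.catalog.records + [novel], bundle.reference,
                        bundle.annotation, bundle.matrices,
                        EvidenceBundle(bundle.pathogenicity, bundle.conservation),
                        weights=weights, config=cfg_imp)
    row = res2.report.set_index("id").loc["I392V"]
    assert row["pon_p2"] == 0.5 and "imputed=true" in row["provenance"]


def test_weights_yaml_roundtrip(tmp_path):
    w = _weights(intercept=3.5, pon_p2=1.25, buried=0.5)
    p = tmp_path / "w.yaml"
    w.to_yaml(p)
    back = ScoreWeights.from_yaml(p)
    assert back.intercept == w.intercept and back.coefficients == w.coefficients
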