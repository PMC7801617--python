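# mutriage

Evidence-based triage of missense mutations in multidomain proteins.

Large somatic-mutation catalogs (COSMIC-style exports) list far more
protein-level substitutions than any lab can characterise. `mutriage`
implements the screening stage of that funnel for a single annotated
protein: it parses and validates the catalog against the reference
sequence, assembles per-mutation evidence — substitution-matrix penalties,
evolutionary conservation, an external pathogenicity probability,
buried/surface location, polarity change, and proximity to known
ligand-binding sites — normalizes each component, combines them with
calibrated linear weights into a final score, and ranks the catalog so that
a tractable candidate subset can be selected for experiments. The bundled
reference case is talin-1, the ~2541-residue focal-adhesion scaffold
(FERM head F0–F3, ~80-aa linker, rod domains R1–R13, dimerisation domain
DD), with its eleven-candidate screening table as the calibration target.

## The score

For mutation *i* with feature vector

x<sub>i</sub> = (PON-P2 probability, normalized BLOSUM62 penalty, normalized
CBSM60 penalty, normalized conservation, buried, between-helices,
polarity-changed, site-proximal)

the final score is the linear composite

  s<sub>i</sub> = β₀ + βᵀ x<sub>i</sub>

The four numeric components lie in [−1, 1]; the last four are 0/1
indicators. Weights (β₀, β) are either supplied or calibrated by ordinary
least squares against reference scores; rank-deficient designs fall back to
the minimum-norm pseudo-inverse solution with the design rank reported.
Candidates with s ≥ threshold (default 7.4) are selected, plus any explicit
manual includes. Substitution penalties come from BLOSUM62 (via Biopython)
and a CBSM60-slot conformation-specific matrix, normalized either by the
computable `row_range` scheme (0 at identity, 1 at the wild-type row
minimum) or verbatim from a supplied `fixture` table of externally
normalized values.

## Worked example

```python
import mutriage as mt
from mutriage import data

bundle = data.talin1_bundle()
evidence = mt.EvidenceBundle(bundle.pathogenicity, bundle.conservation,
                             bundle.normalized_scores)
config = mt.PipelineConfig(scheme="fixture", threshold=7.4,
                           manual_includes=("E1770Q",))
result = mt.run_pipeline(bundle.catalog, bundle.reference, bundle.annotation,
                         bundle.matrices, evidence,
                         calibration_rows=sorted(bundle.final_scores.items()),
                         config=config)
print(result.report[["id", "domain", "location", "final_score",
                     "selection_reason"]].to_string(index=False))
```

prints the ranked catalog:

```
    id domain location  final_score selection_reason
 I392N     F3   buried     8.962310  above_threshold
L1539P     R8   buried     8.548153  above_threshold
 V577D     R1   buried     8.419371  above_threshold
Y1389C     R7   buried     8.349683  above_threshold
 P229L     F2   buried     8.268247  above_threshold
R1368W     R7  surface     7.822156  above_threshold
D2086V    R11  surface     7.748307  above_threshold
S1750F     R9   buried     7.640483  above_threshold
 A893E     R3   buried     7.561753  above_threshold
L2509P     DD  surface     7.293600  below_threshold
E1770Q     R9  surface     6.065937   manual_include
```

The final scores are the least-squares calibration against the bundled
reference scores (maximum absolute residual 0.23, so every fitted score is
within ±0.3 of its published value); `E1770Q` scores below threshold but is
kept through the manual-include mechanism, mirroring its selection for
sitting in the talin autoinhibition site. The same pipeline is available
from the shell: `mutriage score`, `mutriage fit`, `mutriage select`,
`mutriage simulate` (see `mutriage --help`).

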