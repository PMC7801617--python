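# Methods

## Problem and model

`mutriage` ranks protein-level missense substitutions in one annotated
multidomain protein by a linear composite of normalized evidence. The model
is deliberately simple: each evidence channel is mapped to a common scale
where values near 1 predict damage to protein function, and the final score
is an intercept plus a weighted sum. Linearity makes the score monotone in
every feature for non-negative weights, trivially auditable per component,
and calibratable from a handful of reference rows by least squares.

The eight features, in fixed order:

| feature | range | source |
|---|---|---|
| `pon_p2` | [0, 1] | external pathogenicity predictor, ingested from file |
| `blosum_norm` | [−1, 1] | BLOSUM62 penalty, `row_range` or fixture scheme |
| `cbsm_norm` | [−1, 1] | conformation-specific matrix penalty, same schemes |
| `consurf_norm` | [0, 1] | per-residue conservation (grades, continuous or fixture) |
| `buried` | 0/1 | residue environment table, or RSA < threshold |
| `between_helices` | 0/1 | annotation-supplied flag |
| `polarity_changed` | 0/1 | polarity-class transition ≠ none |
| `site_proximal` | 0/1 | sequence distance to nearest binding site ≤ window |

## Normalization choices

**Substitution penalties.** The computable `row_range` scheme maps a
substitution wt→mut under matrix M to
`(M[wt,wt] − M[wt,mut]) / (M[wt,wt] − min_x M[wt,x])`, clamped to [0, 1]:
zero at identity, one at the worst substitution of that wild-type row.
Normalizations published for specific catalogs do not always follow a
recoverable closed form, so a second `fixture` scheme passes externally
normalized values through verbatim from a TSV keyed by (wt, mut, matrix);
the bundled talin-1 case uses this scheme, and its fixture table carries
the published per-substitution values (which may be negative, e.g. −0.33
for E→Q under the conformation-specific matrix).

**Conservation.** Grade mode maps ConSurf-style grades g ∈ 1..9 to
(g−1)/8; continuous mode min–max scales over the loaded profile; fixture
mode passes already-normalized values through, range-checked to [−1, 1]
and logged when outside [0, 1]. A position absent from the profile raises
an explicit missing-evidence error — never a silent zero. The
missing-evidence policy is configurable: `fail` (default, matching a
screen that scores only fully-evidenced mutations), `drop` with a logged
tally, or `impute` with configured neutral values.

**Location.** An explicit per-residue table is authoritative when present;
otherwise buried ⇔ RSA < 0.20, the common buried/surface convention. The
between-helices flag is annotation-supplied, not computed: it encodes
curated structural knowledge for which no general sequence-level rule
exists.

**Binding-site proximity.** Distance is the minimum absolute sequence
separation to any registered site residue (0 inside a site); a mutation is
proximal when the distance is at most the window, default 10 residues —
"close to a binding site" is inherently a judgement call, so the window is
a named configuration knob rather than a constant.

## The talin-1 reference case

The bundled annotation freezes the talin-1 architecture from published
structure-fragment and construct boundaries: F2 208–308 and F3 309–405
(the F2–F3 and F3 fragments), the head ending at 405, the rod starting at
482 (the 1–481 construct boundary), R1 487–656 extended back to 482, R3
796–909, R7 discontinuous (1352–1457 and 1585–1659) wrapping the inserted
R8 (1458–1584), R9 1655–1822 trimmed to 1660 to avoid overlapping R7's
second segment, R11 1975–2140, R13 starting at 2300 (the R13–DD construct)
and DD 2494–2541. Gaps between anchors are closed by extending the earlier
domain to the next domain's start−1; the inventory is 19 entries
(F0–F3, linker, R1–R13, DD). The binding-site registry anchors four sites
with published residue-level support: the integrin/membrane interface
helix 385–405 in F3, the DLC-1 contacts K1530/K1544 in R8, the R9
autoinhibition surface (≈1762–1772, around E1770), and the C-terminal
actin-binding site ABS3 spanning R13–DD (2300–2541; it spans two domains,
so no single host domain is declared and containment is checked against
the sequence only).

Two bundled objects are synthetic stand-ins and are labelled as such. The
reference sequence is a deterministic pseudo-random 2541-mer with the
catalog wild-type residues (plus K1530, K1544, C1392) fixed at their true
letters, sufficient for every validation and annotation query the package
performs; it is not the biological talin-1 sequence. The CBSM60-slot
matrix is a symmetric score table built from standardized physicochemical
property distances (hydropathy, side-chain volume, polarity); the talin
pipeline never consults its raw values because the bundled case runs the
fixture normalization scheme, which carries the published normalized
penalties directly.

## Calibration and selection

Weights are fitted by ordinary least squares of reference final scores on
the intercept-augmented feature matrix (`numpy.linalg.lstsq`). Full-rank
designs give the unique OLS solution; rank-deficient designs the
minimum-norm pseudo-inverse solution, with the rank logged and reported.
On the bundled 11-row case the design has full rank 9 and the fitted
scores reproduce the published final-score column with maximum absolute
residual 0.23 (RMSE 0.10) — consistent with the published weights having
been tuned by hand rather than by least squares, while confirming the
feature encoding explains the published ranking. Selection keeps
score ≥ threshold (default 7.4, which on the published scores separates
the ten high scorers from E1770Q) union an explicit manual-include list;
output is sorted by score descending, ties broken stably by catalog order
for reproducibility.

## Synthetic studies

The generator emits a complete, loader-compatible input bundle with known
ground truth. Design, in draw order from a single seeded numpy Generator:
a uniform random sequence; domains tiling the protein with
multinomial-perturbed widths; a few binding sites placed inside random
domains; per-residue buried flags (Bernoulli with the configured buried
fraction) with RSA drawn from two disjoint Beta-shaped regimes
(0.2·Beta(2,2) clipped below 0.2 for buried, 0.2+0.8·Beta(2,2) above for
surface) so thresholding reproduces the flags exactly; per-residue true
conservation Beta(2,2); then mutations: each carries a pathogenic label
drawn at the configured prevalence, pathogenic mutations sample positions
with weight ∝ exp(2·conservation + 1.5·buried) and one of the three
lowest-scoring BLOSUM62 substitutions, benign mutations the opposite. The
true score applies the configured effect weights to the noiseless
features; the simulated pathogenicity probability is a logistic readout of
that score (midpoint 7.0, scale 0.8 on the ~5–9.75 score scale), which is
why the ground-truth weight on `pon_p2` is zero — in the generative model
the probability is a consequence of damage, not a cause. Evidence files
add clamped Gaussian noise (sd `noise_sd`) to the probability and the
conservation values.

Defaults emulate the bundled reference screen: a talin-sized protein
(2541 residues, 19 domains), a 258-mutation catalog, buried fraction 0.5,
pathogenic fraction 0.2 (the catalog-wide prevalence is not knowable from
a screening table, so a moderate enrichment typical of somatic hotspot
catalogs was chosen once), noise sd 0.05.

What the generator does not emulate: real substitution spectra, codon
structure, tissue-specific recurrence patterns, structural correlation
between neighbouring residues, or predictor biases that correlate across
tools. Passing tests therefore demonstrate internal consistency of the
pipeline — exact zero-noise feature passthrough, exact weight recovery,
ranking that tracks planted labels under noise — not accuracy on real
cancer catalogs.

## Numerical choices and degenerate inputs

- OLS via `lstsq` with machine-precision `rcond`; zero-noise end-to-end
  recovery is asserted to 1e−6 and measures ~1e−14 in practice.
- `row_range` returns 0 for a degenerate flat matrix row (denominator 0).
- Continuous conservation min–max returns 0 for a constant profile.
- Ranking sorts are stable; equal scores keep catalog order.
- Duplicate catalog ids merge by summing recurrence (first row's metadata
  wins), matching single-recurrence-per-mutant catalog conventions.
- An empty binding-site registry yields distance ∞ and `proximal = false`.
- Problem sizes in the test and acceptance runs (catalogs of 120–1000
  mutations on proteins of 800–2541 residues) keep the whole suite in a
  few seconds while leaving every statistical check well-powered.

## Known limitations

- The score is a screening heuristic: no significance statements attach to
  it, and weights fitted to eleven rows with nine parameters are heavily
  constrained by the encoding, not by data volume.
- The bundled location table covers only the catalog positions; scoring
  new talin mutations requires supplying RSA values or an extended table.
- Sequence-distance proximity ignores 3D contacts; a mutation spatially
  adjacent to a site but distant in sequence scores `proximal = 0`.
- The fixture normalization scheme can only score substitutions present in
  its table; novel substitutions need the `row_range` scheme.
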