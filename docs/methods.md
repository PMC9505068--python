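# Methods

`pknet` implements the quantitative core of a herb–drug disposition study:
does a co-administered herbal extract change the pharmacokinetics of an
intravenously dosed drug, and are the herb's component targets even in the
network vicinity of the drug's disposition machinery? The package covers
five statistical engines (network separation, enrichment, noncompartmental
PK, bioanalytical validation, group statistics), the seeded generators that
emulate the study's data, and the orchestration around them.

## Network module separation

Drug-disposition enzymes and compound targets are treated as *modules*:
node subsets of a background protein–protein interactome, modelled as an
undirected simple graph over opaque, case-sensitive identifiers. The
separation of modules A and B is

S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2

with the nearest-neighbour convention: ⟨d_AA⟩ averages, over members of A,
the shortest-path distance to the closest *other* member of A (singleton
modules have internal distance 0); ⟨d_AB⟩ averages, over members of both
modules, the distance to the nearest member of the opposite module, so a
protein shared by both modules contributes 0. S_AB < 0 means overlapping
network neighbourhoods; S_AB ≥ 0 means topological separation (the
boundary 0 is classified as separated).

Numerical/convention choices:

* All separation analyses run on the largest connected component (LCC) of
  the loaded network, which guarantees finite distances; ties between
  equally large components break on the lexicographically smallest member.
  Distance queries outside one component raise an error that points at the
  LCC restriction rather than returning infinities.
* Distances are exact unweighted BFS; cross-distances use one multi-source
  BFS per module (O(E) each) so genome-scale networks (≈18k nodes / 270k
  edges) are handled in seconds; internal distances use early-stopped BFS
  per member.
* Self-loops and duplicate (including reversed) edge rows are dropped at
  load time and counted in a load report, because published PPI files
  routinely contain both.
* No degree-preserving permutation significance is attached to S_AB; the
  score is reported raw, at full precision (rounding is display-only).

The test suite checks S_AB against a brute-force recomputation from a
test-local Floyd–Warshall all-pairs matrix (independent of both the
implementation and networkx) to 1e-12 on random graphs.

## Over-representation analysis

Enrichment of a query protein set against a gene-set collection uses the
upper-tail hypergeometric probability P(X ≥ k) with universe N, set size
K, query size n, overlap k, adjusted by Benjamini–Hochberg over *all*
sets in the collection — zero-overlap sets are excluded from the output
table but counted in the hypothesis number m, so the correction does not
depend on outcomes. The recommended universe is the intersection of the
background network's nodes with the collection's membership, which avoids
inflating significance with never-observable proteins. Venn-region
decomposition of 2–3 enrichment tables at a q threshold (default 0.01)
summarises cross-drug pathway overlap.

## Noncompartmental pharmacokinetics

Profiles are single-dose IV-bolus concentration–time series sampled from
t = 0 (the 0, 0.083, …, 48 h schedule is the generator default). The
engine uses the linear trapezoidal rule for the zeroth, first and second
moment integrals (log-down integration is out of scope), an OLS fit of
ln C on t for the terminal slope λz, and analytic tail extrapolation from
the predicted last concentration. Derived parameters (14 in total):
AUC and AUMC to t_last and infinity, MRT = AUMC/AUC, VRT = M2/AUC − MRT²
(the residence-time variance, defined via the second statistical moment),
λz, C_last predicted, t½ = ln2/λz, CL = Dose/AUC_0–∞, V = CL/λz, and the
maximum observed concentration. The identities t½·λz = ln 2,
CL·AUC_0–∞ = Dose and V = CL/λz hold exactly by construction and are
asserted for every accepted fit.

Terminal-fit policy: candidate points are quantifiable (not below LOQ),
positive, and strictly after C_max; `auto` selection maximises adjusted
r² over terminal suffixes of ≥ 3 candidates. A non-negative slope in
every window is rejected as "no terminal decline"; batch runs flag such
subjects and keep going. The observed t = 0 concentration is used as-is
(no back-extrapolation of C0). With ~5 usable terminal points over
6–48 h and 10% proportional noise, the OLS slope carries an irreducible
sampling error of order 10–15% relative; the recovery tests assert the
15% median bound that this design supports, and < 5% for AUC_0–t.

## Bioanalytical validation

Calibration is weighted least squares of response on nominal
concentration with weights 1, 1/x or 1/x² (default 1/x², the common
choice for assays spanning 2–3 orders of magnitude); r² is reported on
the weighted fit. Accuracy is 100·mean(measured)/nominal; precision is
the RSD with the sample (n−1) standard deviation. Acceptance rules:
accuracy/precision requires accuracy within 80–120% and RSD < 20% at the
LLOQ, 85–115% and RSD < 15% elsewhere (accuracy bounds inclusive, RSD
strict, following "less than" phrasing); the matrix-effect rule checks
only the 85–115% ratio band; the stability rule uses 85–115% and an
*inclusive* RSD ≤ 15%. Recovery and matrix effect share one statistic:
the percent ratio of mean test to mean reference signal. Chromatographic
peak handling and raw-noise S/N estimation are out of scope; S/N-based
limits are accepted as inputs.

## Group statistics

Two-group comparisons are classical equal-variance Student t-tests
(df = n₁+n₂−2), two-sided, with a 0.05 significance default and no
multiplicity correction across the 14 parameters — the convention of the
study design this mirrors. Degenerate zero-variance cases are defined:
equal means give (t=0, p=1), unequal means are an error. PCA runs on
z-scored columns because the parameters span ~5 orders of magnitude;
zero-variance columns are dropped with a warning, and component signs are
fixed by making each component's largest-magnitude loading positive, so
score plots are reproducible run to run.

## Synthetic data: what it emulates, and what it does not

* **Plasma profiles**: C(t) = (A e^{−αt} + B e^{−βt})·ε with ε lognormal,
  mean 1, CV 10% by default, independent per sample. Defaults A = 1470
  µg/L, α = 3.0 h⁻¹, B = 25 µg/L, β = ln2/31.5 h⁻¹, dose 5000 µg/kg,
  n = 7 per group, two groups with no planted effect. These were chosen
  once so that C_max ≈ 1500 µg/L, AUC_0–48 ≈ 1250 µg/L·h, terminal t½ =
  31.5 h and CL ≈ 3 L/h/kg — the magnitudes typical of doxorubicin in
  the rat; the fast phase fully decays within ~4 h, as observed for
  drugs with rapid, extensive tissue distribution. A faster α was
  preferred over a slower one because a slow distribution phase is
  incompatible with the target C_max/AUC pair.
* **Tissue panels**: per-tissue lognormal draws (σ = 0.2 on the log
  scale) around geometric means ordered kidney ≈ spleen ≈ heart > liver >
  lung ≈ muscle; the treated group multiplies the liver mean by 0.70 and
  the other tissues by 0.95, emulating a liver-only significant decrease.
* **Planted networks**: a connected small-world (or scale-free)
  background; module A is densely wired (spanning path + random edges at
  density 0.6) and anchored to the background; module B either shares
  members with A (overlap construction → negative S_AB) or hangs off a
  spacer path that is its only route to the rest of the graph, fixing the
  nearest cross-distance at the planted value (distance ≥ 3 → positive
  S_AB by construction).
* **Calibration/QC**: 8 geometric levels over each matrix's validated
  range, proportional (heteroscedastic) response noise, 4 QC levels × 5
  replicates × 3 days with an optional fractional bias.
* **Gene sets**: uniform random sets over a synthetic universe with one
  optionally planted set overlapping a query.

Seeding: each generator call derives one child stream per subject /
replicate from the top-level seed (`numpy` `SeedSequence.spawn`), so
outputs are bit-reproducible and stable under partial regeneration.

What the generators deliberately do **not** reproduce: between-subject
PK random effects beyond sampling noise (a per-point error model only),
metabolite kinetics, assay carryover, correlated tissue uptake, the
degree distribution or literature bias of a curated human interactome,
and any real pathway database. Passing the planted-truth tests therefore
demonstrates that the estimators recover what the simulation puts in —
correctness of the machinery, calibration of the tests at the study's
n — not that the biological conclusions transfer to any particular real
dataset.

## Problem sizes

Default verification scales, chosen as a desk-check budget: 500
replicate profiles for recovery error, 100 replicate studies for the
half-life envelope and the null false-positive rate, 200 seeded tissue
panels for power/specificity, 2 × 100 planted networks (150-node
background) for sign recovery, 100 QC batches. The whole acceptance
script runs in well under a minute on one CPU; reproducing the published
network numbers instead requires the external interactome download
described in the README and a few minutes of BFS.

## Known limitations

* Linear trapezoid only; log-linear ("log-down") integration is not
  offered, so AUC is slightly biased upward on steeply declining
  segments at sparse spacing.
* The `auto` λz rule (best adjusted r², ≥ 3 points) can select short
  windows under noise; a fixed `last_n` or manual time window is
  available when reproducibility against other NCA software matters.
* No proximity z-scores against degree-preserving null networks; S_AB is
  reported without a significance measure.
* Identifier namespaces are not translated; modules must already use the
  background network's vocabulary.
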