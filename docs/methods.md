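# Methods

This note documents the models, conventions and numerical choices behind
`hepafroc`, in the spirit of the methods documentation of statistical
simulation packages: what is computed, under which assumptions, and what
the synthetic data do and do not establish.

## Matching rule

A mark is a candidate true positive for lesion *g* when the 3D Euclidean
distance between the mark and the lesion centre is within a
diameter-scaled threshold. Reader-study conventions in this area state two
clauses — "within 3/4 of the lesion diameter" and "within 3 mm" — without
an unambiguous connective. Read as a conjunction (`combine="and"`), the
3 mm clause caps every threshold, so a 74 mm lesion would demand 3 mm
click accuracy; read as a floor (`combine="max"`, the default), 3 mm is
the minimum tolerance granted to tiny lesions and the threshold scales
with size, `T(g) = max(0.75·d_g, 3 mm)`. Both are implemented; the default
follows the scaling reading because it preserves the detectability of
large lesions under realistic click placement. Candidate pairs are
resolved one-to-one, greedily by ascending distance with deterministic
ties (lesion identifier, then mark order). Additional marks falling inside
the threshold of an already-claimed lesion are, by default, absorbed as
duplicate detections of that lesion rather than counted as false
positives; a flag (`absorb_duplicates=False`) counts them as FPs instead.

## Figure of merit and significance testing

The JAFROC1 statistic compares every lesion's localization rating against
every case's highest false-positive rating:

θ = (1 / N_C·N_L) Σ_c Σ_l ψ(NL_c, LL_l),  ψ(a,b) = 1 if b > a, ½ if b = a
(both finite), 0 otherwise.

JAFROC1 rather than the lesion-case-restricted variant is used because in
an enriched study with no lesion-free cases the latter has no
normal-case pool to draw from. Unmarked entries carry −∞; the tie
ψ(−∞, −∞) scores **0** by default, so a reader who marks nothing scores 0
rather than being credited for silence in an all-abnormal dataset. The
0.5 tie convention is available (`neg_inf_tie=0.5`). θ is invariant under
any strictly increasing transform of the finite ratings. All lesions are
weighted equally.

Jackknife pseudovalues are `Y_c = N·θ − (N−1)·θ₍₋c₎`, where θ₍₋c₎ removes
case *c*'s NL entry and all its lesions' LL entries; pseudovalues are
centred so their mean equals θ (centring shifts every case equally and
leaves all ANOVA contrasts unchanged). The Dorfman–Berbaum–Metz test runs
a three-way crossed ANOVA (modality fixed; readers and cases random) on
the pseudovalues. The default *F* statistic uses the Hillis denominator
`MS(TR) + max(MS(TC) − MS(TRC), 0)` with denominator degrees of freedom
`[denominator]²·(I−1)(J−1)/MS(TR)²`; the classic quasi-*F* with
Satterthwaite degrees of freedom is selectable. With a single reader the
test reduces exactly to the square of the paired *t* statistic on
pseudovalue case means, which the test suite asserts. A numerically-zero
treatment mean square (identical pseudovalue blocks) is reported as
F = 0, p = 1 rather than 0/0.

Per-reader LLF differences are compared with the standard two-sided
paired *t* test; zero-variance differences raise a documented
degenerate-statistic error rather than silently returning p = 1.

## Reader sample size

The sample-size routine targets the Wilcoxon signed-rank test on paired
per-reader differences via the asymptotic-relative-efficiency method:
the Wilcoxon test at *n* pairs is evaluated as a paired *t* test at the
reduced effective size n′ = ARE·n, using the exact noncentral-*t* power
(df = n′ − 1, noncentrality dz·√n′), and the smallest *n* reaching the
target power is returned. ARE values: normal parent 3/π ≈ 0.955, uniform
1.0, logistic π²/9, Laplace 1.5, and the distribution-free minimum 0.864.
At dz = 1.15, α = 0.05 two-tailed, power 0.80 and the normal parent this
gives n = 9 (power 0.833; n = 8 reaches only 0.770). The variant that
first finds the paired-*t* sample size and then divides by the ARE gives
10 at these settings; the effective-sample-size formulation is the one
used by the standard power-analysis software for this test, and is the
package default. Defaults (two tails, normal parent) are a design choice
of this package; one-tailed and other parents are exposed.

## Negative consultation ratio

Paired sessions of one reader are linked: lesions by identity
(TP/FN states from the localized flags), false-positive marks one-to-one
across sessions by ascending distance within a 3 mm link radius (an
unlinked FP pairs with an implicit TN in the other session; (TN, TN) rows
cannot exist). Negative consultations are TP→FN and TN→FP rows. The
denominator contains all linked findings; undetected lesions ((FN, FN))
are excluded by default, reading "findings" as entities detected in at
least one session — a flag includes them. How the original analyses
linked non-lesion findings across sessions is not standardised; the 3 mm
radius mirrors the matching floor and is configurable. Readers partition
at NCR < 10 % (strict inequality) into low/high automation-bias strata.

## Synthetic study generator

The generator emulates the reference reader-study conditions so the analysis
chain can be tested end to end without clinical data:

- **Cases and lesions.** 30 cases; lesions per case follow
  3 + Binomial(7, 3/7) (support 3–10, mean and median 6), within the 2–11
  admissibility bounds. Lesion diameters are drawn from a monotone PCHIP
  interpolation of the reference size table treated as a CDF — knots at
  (4.1, 6, 7.9, 8, 10, 12, 74.5) mm with cumulative fractions
  (0, 35/186, ½, 95/186, 125/186, 137/186, 1) — so the median (7.9 mm) and
  every size bracket are matched in expectation by construction. A
  truncated log-normal re-solved for its post-truncation median is
  available as an alternative, but no log-normal matches all tabulated
  bracket counts simultaneously (its best fit puts ~25–30 % too many
  lesions below 6 mm), which is why the quantile-knot sampler is the
  default. Lesion types mix 85:66:35 (cyst:hemangioma:metastasis).
  Centres are placed uniformly in a 180×140×120 mm case box with ≥ 12 mm
  pairwise separation.
- **Observers.** Detection is Bernoulli per lesion with probability
  logistic in log-diameter. The AI profile (slope 4.66, midpoint 5.08 mm,
  14 FPs/case, constant rating 100) is calibrated so its expected
  cumulative-bracket LLFs are ≈ 0.49 / 0.70 / 0.75 / 0.77 / 0.82 from the
  ≤ 6 mm bracket upward; the human baseline (slope 3.06, midpoint
  5.57 mm, 1 FP/case) reproduces ≈ 0.40 / 0.61 / 0.65 / 0.67 / 0.74.
  True-positive marks sit at the lesion centre plus a Gaussian jitter
  (sd 0.5 mm) capped inside the matching threshold, so a simulated
  detection is a TP by construction; false positives are Poisson per case,
  placed uniformly beyond every lesion's threshold. TP ratings are
  N(75, 15) and FP ratings N(40, 20), clipped to [0, 100] — overlapping
  distributions keep the FOM away from 1 and allow occasional ties.
- **The assisted session** starts from the unassisted realization. Each
  finding's status is independently re-drawn with probability
  `session_noise` (default 0.02) — thinning plus Poisson superposition
  for FPs — which makes the two sessions exchangeable in distribution
  but not identical, as repeated human readings are. Automation bias then
  acts through three probabilities: `accept_ai_tp` (adopt an AI-flagged
  lesion the reader missed), `accept_ai_fp` (adopt an AI false-positive
  mark), and `drop_own_tp_when_unflagged` (abandon an own detection the
  AI did not confirm). The default panel has 10 low-bias readers
  (0.5 / 0.005 / 0) and 4 high-bias readers (0.7 / 0.06 / 0.15), which
  lands the two groups on either side of the 10 % NCR threshold with a
  clear gap. No fatigue, order or memory effects are modelled, and
  low-bias readers do not drop their own false positives when unflagged,
  so the generator does not reproduce the FP *decrease* some careful
  readers show with assistance — only the increase for biased readers.

What passing tests on this generator show is internal consistency: the
analysis chain recovers the parameters the generator was given, at the
study's scale. They do not validate the behavioural model against real
readers, and the profile parameters are stand-ins, not estimates.

## Phantom and detector

The phantom is a bright liver ellipsoid (semi-axes 60×52×45 mm, intensity
100) in dark background (20), with hypointense spherical lesions and
hypointense tubular vessels (intensity 40, piecewise-linear random walks
swept by a 1.5–3 mm radius), plus Gaussian noise (sd 2). Default grid
96×96×40 voxels at 1.5×1.5×3 mm — the 3 mm slice spacing of a typical
HBP protocol. No MRI physics (bias field, motion, partial volume) is
simulated, so detector results on phantoms bound what the geometry can
show, not clinical performance.

Liver segmentation is deliberately simple: Otsu threshold, largest
connected component, morphological closing and hole filling — vessels and
lesions inside the liver are retained in the mask, reproducing the known
limitation that vessels are not excluded. An all-background volume is
rejected by a bimodality check (between-class variance fraction ≥ 0.75).

Patches are cubes of physical side 6, 12 and 24 mm; the per-axis voxel
count is the nearest odd integer (`2·floor(scale/2s)+1`), so the centre
voxel is well defined under anisotropic spacing. Centres lie on a grid of
step 0.5·scale (any lesion centre is then within scale/4 of some patch
centre); mask voxels are binned by the stride and each bin keeps the
voxel nearest its centre, so sparse masks still produce patches. In the
full pipeline the mask is eroded per scale by the patch half-extent, so
no patch straddles the organ boundary — lesions hugging the boundary are
consequently missed, mirroring the boundary failure mode reported for
detectors of this design.

The patch scorer replaces the original trained CNN with an interpretable
geometric statistic computed on exactly the same representation (three
orthogonal minIP images): threshold each projection halfway between its
minimum and maximum (score 0 if the range is under 10 intensity units),
take the largest dark component (≥ 3 pixels), and compute
√(λ_min/λ_max) of its darkness-weighted second moments in physical
coordinates, with a half-pixel variance floor so single-file pixel rows
keep finite width. A sphere is compact in all three planes; a tube is
elongated in at least one, so the score maps the *worst-plane* isotropy
through a fixed logistic (slope 10, midpoint 0.45). Any callable
`(MinipTriplet) -> float` can be plugged in as an alternative scorer.
Candidates take the position of the blob centroid (each axis averaged
over its two planes), are thresholded on score, and merged across scales
by greedy non-maximum suppression with radius `0.5·max(scale_i, scale_j)`
and deterministic tie-breaking (score, smaller scale, lexicographic
centre). Detector ratings for FROC evaluation are 100·score.

## Problem sizes and numerical conventions

Simulation-based tests run at the study's own scale (30 cases, 186
lesions, 14 readers) with modest replicate counts chosen for quick
iteration: 500 replicates for the DBM type-I calibration (the fast
rating-table sampler bypasses spatial placement, which is statistically
equivalent because jitter is capped inside the matching threshold), 50
seeds for simulator parameter recovery, 100 instances for the matching
oracle, 100 seeds per level for NCR monotonicity on 6-case studies.
Oracle-equivalence checks (FOM double sum, minIP minima, NMS) assert to
1e-12 or exactly. Degenerate inputs raise typed errors
(`UndefinedMetricError`, `DegenerateStatisticError`) instead of returning
sentinel values; report assembly converts a degenerate bracket-level DBM
test (all bracket lesions in one case) to a missing *p*-value.

## Known limitations

- The behavioural reader model is a three-parameter caricature of
  consultation; it cannot express FP-reducing assistance or
  experience-dependent rating shifts.
- JAFROC1 weighting is unweighted per lesion; clinically weighted FROC
  variants and AFROC are out of scope.
- The detector's geometric scorer is not a trained classifier; its
  operating points on phantoms say nothing quantitative about clinical
  images.
- The phantom omits MRI artefacts entirely.
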