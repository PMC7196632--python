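# Methods

This note documents the models implemented in `nadhub`, the assumptions
behind them, the defaults and the numerical choices, in the package's own
terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Rate laws and their interpretation

The kinetics module defines six closed forms. The inhibition and activation
constants they carry (K_i, IC₅₀, K_act, K_E) are *empirical half-effect
constants* of the respective curves, not mechanistic dissociation constants:
the assays they summarise measure steady-state rates, not binding steps.

| model | form | parameters (units) |
|---|---|---|
| michaelis_menten | v = V_max·S/(K_m+S) | V_max (μmol s⁻¹), K_m (mM) |
| noncompetitive_mm | v = [V_max/(1+I/K_i)]·S/(K_m+S) | + K_i (mM) |
| hyperbolic_inhibition | v = v₀·(1 − I_max·I/(K_i+I)) | v₀ (%), I_max (fraction), K_i (mM) |
| hill_inhibition | v = v₀·(1 − I_max·Iⁿ/(IC₅₀ⁿ+Iⁿ)) | + n (–) |
| hyperbolic_activation | v = v_floor + (v_ceil−v_floor)·A/(K_act+A) | activities (%), K_act (μM trimer) |
| effector_inhibition | f = B + (T−B)·E/(K_E+E) | % inhibition vs 2-OG (μM) |

Default fits of the two inhibition models pin I_max = 1 (full inhibition at
saturating NAD⁺). This is a deliberate, documented choice: the residual
activity observed at 2.5 mM NAD⁺ in feedback-inhibition assays (~17%) is
somewhat below what a K_i = 1 mM hyperbola with I_max = 1 predicts (~29%),
and the data at hand cannot decide whether a sub-unity I_max, extra
cooperativity, or assay floor effects reconcile the two. Both I_max and n
are therefore exposed (`fixed={}` frees I_max) but the package does not
decide the question.

Concentration conventions follow the assays: enzyme per monomer
(NadE2 functional unit dimer in the binding work), PII per trimer.

### Initial velocities

The linear phase of an assay trace is detected by prefix growth: starting
from the first 3 points, the prefix extends while adding the next point
changes the fitted slope by less than `linearity_tolerance` (default 5%,
relative). This rule is deliberately simple so a brute-force oracle can
re-derive it in tests. Coupled-assay slopes (AU s⁻¹) convert to molar rates
by Beer–Lambert with ε_NADH = 6220 M⁻¹ cm⁻¹ and a 1-cm path — standard
values, configurable in `AssayConfig`.

### Fitting engine

All fits share one engine: trust-region-reflective least squares
(`scipy.optimize.least_squares`) from multiple starting points — seeded
draws within the parameter bounds (log-uniform for strictly positive
parameters spanning > 2 decades, uniform otherwise), plus a deterministic
data-driven heuristic start. The lowest-RSS converged solution wins, so the
procedure is bit-reproducible given (data, options, seed). Standard errors
come from the Gauss–Newton curvature, cov = RSS/(n−p)·(JᵀJ)⁻¹, via a
pseudoinverse; rank deficiency is flagged rather than fatal, and total
non-convergence returns a flagged result, never an exception. Defaults:
20 starts for dose–response fits, 10 for binding fits; the recovery studies
use 8 and 3 with the heuristic start, which the noise-free recovery tests
show is ample for these well-conditioned designs.

Model discrimination (hyperbolic vs sigmoidal) uses the extra-sum-of-squares
F-test for the nested pair and small-sample AICc otherwise; inhibition-mode
classification compares normal-approximation confidence intervals of K_m
and V_max between ± inhibitor fits (overlap ⇒ unchanged).

## Biolayer interferometry

Sensorgrams follow ideal Langmuir kinetics. Association:
R(t) = R_eq·(1−e^−(k_ON·C+k_OFF)t) with R_eq = R_max·C/(C+K_d);
dissociation decays at k_OFF from the association end point;
K_d = k_OFF/k_ON. The "2:1 heterogeneous ligand" model is two independent
1:1 sites sharing the analyte concentration, each with its own R_max (the
standard vendor definition); after fitting, sites are reported
slower-dissociating first. Mass-transport limitation is not modelled —
Langmuir is the analysis baseline, and the simulator that generates all test
data makes the same assumption.

Global fits share (k_ON, k_OFF, R_max) across concentrations. Observed
association responses are zeroed to their first point and the model
prediction is zeroed identically; elapsed time within a phase is
reconstructed from the sample immediately before the phase boundary, so
simulation and fit agree exactly in the noise-free limit (verified to
optimizer tolerance in tests). Baseline and loading phases are carried
through but not modelled. A single-concentration fit is allowed but flagged
`kd_rmax_confounded`.

Preprocessing subtracts a reference sensor pointwise, then applies
Savitzky–Golay smoothing (default window 11, order 3) *per phase segment*
so phase-boundary discontinuities are not smeared.

The 2-OG half-effect constant on complex formation is fitted from
equilibrium *plateau responses* versus 2-OG, R(OG) = R₀·K/(K+OG) (optional
floor). Amplitude- or rate-based derivations are plausible alternatives; the
plateau route was chosen because it needs no kinetic assumptions, and it is
documented here precisely because the choice was open.

## The regulatory switch

The switch model is this package's synthesis; its constants are the measured
ones (defaults): complex K_d 0.3 μM (ATP; 0.15 μM with ADP), 2-OG
half-effect 15.5 μM for forming and 1 mM for pre-formed complexes, free
enzyme K_i 1 mM, complexed enzyme IC₅₀ 2.5 mM with n 2.2.

Assumptions, each a deliberate simplification:

- **Uridylylation gates binding completely**: available PII =
  PII_total·(1−u). No partial-modification states per trimer.
- **2-OG acts as a competitive multiplier** on the complex K_d:
  K_d,eff = K_d·(1 + OG/K_OG). A full binding polynomial over the
  ATP/ADP/2-OG sites would need site occupancies no assay here constrains;
  ATP vs ADP enters only through the choice of K_d.
- **History is a discrete flag** (forming vs preformed), not a kinetic ODE:
  the data establish two regimes, not interconversion rates.
- **1 trimer : 1 dimer stoichiometry** in the exact tight-binding quadratic
  f = [(P+N+K_d) − √((P+N+K_d)² − 4PN)]/(2N), clipped to [0,1]; f ≡ 0 when
  N = 0. The discriminant is floored at 0 against rounding.
- **Linear mixing**: activity = f·sigmoid + (1−f)·hyperbola, the simplest
  two-population model. The complexed curve's NAD⁺-free ceiling is
  configurable (`relief_ceiling`, default 100%) because whether PII relief
  saturates below the uninhibited rate is not settled.

`hysteresis_scan` sweeps 2-OG with the preformed constant on the ascending
branch and the forming constant on the descending branch; the enclosed area
(`loop_area`, trapezoidal) is positive for 2-OG between the two half-effect
constants — the memory effect.

## Island pipeline

Deterministic filters, in order: (1) one genome per species, type strains
first, then assembly level complete > chromosome > scaffold > contig, ties
broken lexicographically by accession; (2) PII hits with e-value ≤ 1e-5
(boundary inclusive) become 10-kb-flank islands only if the window fits the
contig; (3) nadE hits (same e-value rule) lying entirely within an island
pair to the closest PII *gene* midpoint on the contig, floor-rounded
1-based coordinates, strand ignored, kept strictly below 2000 bp;
(4) dereplication by identical protein sequence when sequences are given,
else by protein id, first occurrence under a canonical
(genome, contig, start, id) sort; (5) taxonomy rollup per phylum/class with
an "unclassified" bucket.

Two open points were resolved as follows: the 2000-bp distance is measured
to the PII gene midpoint (the island midpoint variant is available via
`use_island_midpoint=True`); a nadE equidistant between two islands ties to
the lower-coordinate one, logged. Every discarded record is logged with its
reason. The pipeline consumes precomputed hit tables (BLAST outfmt-6 reader
included) rather than running a search engine, which keeps it deterministic
and testable; genome-scale censuses are out of scope because their counts
are database-snapshot dependent.

## Similarity clustering

The all-vs-all graph weights edges by a_ij = min(−log₁₀ E, 200)/200.
Sequences are compared with local affine-gap alignment (BLOSUM62, open 11,
extend 1) and a Karlin–Altschul-style e-value E = K·m·n·e^(−λS) with fixed
gapped-BLOSUM62 parameters (λ = 0.267, K = 0.041). This e-value is
approximate — hit-table ingestion is the exact-compatibility path. Cluster
labels are connected components of the cutoff-filtered graph, size-ordered
with smallest-member tie-break: deterministic and brute-force checkable,
unlike convex-clustering heuristics. The force-directed layout (seeded
uniform init; per-sweep displacement damping·clip(attraction − repulsion);
coincident points separated by an ε = 1e-6 offset) is for visualisation
only and never feeds cluster assignment.

## Enrichment

log₁₀((bait+c)/(control+c)) per protein per fraction, pseudocount c
defaulting to the smallest nonzero intensity in the table (scale-free; the
log base and zero handling are this module's choices). Swapping bait and
control negates every ratio exactly; ranking ties break on
(protein_id, fraction) so the output is row-order invariant.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed); substreams derive as
`default_rng([seed, crc32(scenario)])`, so adding a scenario never shifts
another's draws. Defaults mirror the assay designs: triplicate dose–response
curves at 3% CV (8 NAD⁺ levels 0–10 mM; PII trimer 0–10 μM; 2-OG 0–480 μM
or 0–5 mM at 5% CV), sensorgram sets at 30–2000 nM analyte with 0.02 nm
Gaussian noise and optional linear drift, genome sets with planted pairs at
midpoint distances below 2000 bp plus one decoy per discard rule (far nadE,
weak-e-value hits, edge-truncated and short-contig islands, redundant
same-species assemblies), and protein families as point-mutated descendants
(within-family mutation rate 0.2 per site, family ancestors at 0.7 from a
common root) — parameters chosen to bracket the separations the clustering
is expected to resolve.

What passing tests on these data do **not** show about real data: constant
CV is optimistic for plate readers at the low-signal end; Langmuir
sensorgrams exclude mass transport, rebinding and tip drift nonlinearity;
genome sets contain no compositional or annotation noise (coordinates are
exact, no ORF-calling errors); and iid point mutation without indels makes
families easier to separate than real NadE phylogeny. Recovery and
recall/precision results are therefore statements about the estimators under
their own assumptions, not about field performance.

The NaAD K_m used by the saturation generator (0.2 mM) is a plumbing
default in the mid-range of NadE-type substrate affinities, not a measured
constant; saturation designs are specified as multiples of K_m, so V_max
recovery does not depend on it.

## Problem sizes and tolerances

Recovery studies report the median over 50 seeds — enough to stabilise the
median while keeping each study to seconds on one CPU. Noise-free round
trips must recover parameters to 1e-6 relative; the optimizer runs at scipy
defaults (ftol/xtol/gtol 1e-8). BLI recovery uses 5 concentrations ×
(150 s association + 300 s dissociation) at 1 Hz. Island recall/precision
runs on 30–50 genomes with the full decoy set. Layout and clustering tests
use 3 families × 6 members of length 200.

## Known limitations

- No progress-curve (time-resolved) kinetic fitting; initial velocities only.
- No rapid-equilibrium derivation of the glutaminase/ammonia-tunnel
  chemistry; the rate laws are phenomenological.
- The 2:1 binding model's site assignment is only canonicalised by k_OFF
  ordering; with close sites the split is weakly identified (flagged via
  standard errors, not resolved).
- The switch model has no dynamics: it maps states to steady-state activity;
  uridylylation/deuridylylation kinetics by GlnD are out of scope.
- Relative PII-paralog affinities (GlnB vs GlnZ vs orthologs) are exposed
  only as user-settable K_d values, not measured here.
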