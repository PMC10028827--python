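# Methods

This note documents the models and procedures implemented in `metakin`,
their assumptions, the parameters that matter, and the design choices
made where the underlying protocol leaves room.

## Residence-time estimation

**Model.** Ligand unbinding under an infrequent, slowly grown bias V(t)
is treated as a rare-event first-passage problem. Provided hills are
deposited rarely enough that the transition-state region stays
essentially bias-free, the acceleration of the escape is the running
Boltzmann factor of the deposited bias, and each trajectory's unbiased
dissociation time is recovered as

t_rescaled = Σᵢ Δtᵢ · exp(Vᵢ / kT),

summed over frames up to and including the first frame with z > 15 Å
(first-passage convention: frames after the first crossing are ignored;
the crossing frame's bias is included). Frame times are ps internally;
rescaled times are reported in seconds and compared on the log₁₀ scale
downstream. Temperature defaults to 300 K with k_B = 0.0019872 kcal/(mol K).

Under these assumptions the rescaled times of repeated simulations are
i.i.d. exponential with mean τ (a homogeneous Poisson escape process).
τ is estimated by nonlinear least squares of the empirical CDF at
plotting positions (i − 0.5)/n against 1 − exp(−t/τ) (Levenberg–
Marquardt on log τ, initialised at the sample mean). The (i − 0.5)/n
positions avoid pinning the largest observation to CDF = 1; the
alternative maximum-likelihood estimator (the sample mean) is available
via `method="mle"` and is used as the fallback whenever the nonlinear
fit fails or a (bootstrap) sample has zero spread. On n ≥ 100
exponential samples the two estimators agree within a few percent.

**Reliability.** A two-sample Kolmogorov–Smirnov test compares the
observed times with a large sample (default 10⁶) drawn from Exp(τ̂);
the fit is flagged reliable when p > 0.05 (strict inequality; threshold
configurable). This tests the exponentiality assumption itself — it
fails, for example, when the sample mixes two well-separated timescales.

**Uncertainty.** Bootstrap: resample size-15 sets with replacement
10,000 times, refit τ on each (vectorised golden-section minimisation of
the same ECDF objective), and report the mean and the ddof-1 standard
deviation of the bootstrap distribution as the estimate and its standard
error. For exponential data at n = 15 this SEM tracks the analytic
τ/√15 within tens of percent.

## Synthetic unbinding trajectories

The generator draws the ground-truth rescaled time T* = −τ·ln(u) per
trajectory and integrates the deterministic bias schedule until the
accumulated rescaled time reaches T*, emitting one frame per 10 ps
deposition stride. By construction the kinetics stage recovers T* up to
one frame's rescaled increment, so estimator bias can be separated from
sampling noise.

Two growth laws are provided. `step_ramp` grows the bias linearly
(V = h·k after k depositions, capped), giving exponential acceleration —
useful for closed-form oracles (with βh = ln 2 the per-stride rescaled
increments form a geometric series). The default `saturating` law,
V(k) = s·ln(1 + h·k/s) with tempering scale s = 2 kcal/mol and
h = 0.5 kcal/mol, mimics the long-time logarithmic growth of a
well-tempered bias; the acceleration then grows as a power law
(1 + h·k/s)^(βs), which resolves residence times from seconds to
hundreds of seconds with ~10³–10⁴ frames per trajectory (wall times of
roughly 10–50 ns, matching the regime such simulations occupy) and a
per-event discretisation overshoot well below 1%. A hard exponential
ramp cannot cover both τ scales at once — its rescaled increments become
comparable to the accumulated time itself.

The z trace rises monotonically (plus noise) from the bound state (~2 Å)
and crosses the 15 Å threshold exactly at the event frame; the contact
count is anti-correlated with z and drops to zero after exit. These
shapes exercise the event detector; they carry no dynamics. The
generator makes no attempt to emulate CV-dependent bias, hill widths or
recrossings — only the statistical structure the estimator assumes.
Consequently the recovery tests validate the estimator, not the
metadynamics assumptions themselves (transition-state bias deposition,
CV quality), which real data can violate.

## Reweighting and free-energy surfaces

Static reweighting by the recorded instantaneous bias: wᵢ ∝ exp(+Vᵢ/kT),
normalised with a max-shift for stability. This is the common post-hoc
choice for COLVAR-style inputs; the time-dependent normalisation
correction c(t) is deliberately not modelled, which is adequate for the
qualitative basin comparisons the surfaces feed and is exactly testable
(samples drawn from exp(−(U+V)/kT) reweight back to U).

F = −kT·ln of the weighted histogram density, shifted so the occupied
minimum is 0; unoccupied bins are flagged, not numeric. Default bin
widths: 0.25 Å (distances), 0.5 kcal/mol (energies), 5° (angles).

Basins are found by a watershed over occupied bins in order of
increasing F with union-find merging: when a bin bridges two basins, any
basin whose persistence (saddle F minus its own minimum) is below the
`depth_cutoff` (default 1 kcal/mol) merges into the deeper one. Reported
membership is restricted to bins within the cutoff of the basin minimum,
which makes the two-wells case coincide with a flood-fill at
min + cutoff. Binding modes are assigned by testing basin minima against
named windows on the (amine–D147, amine–H297) distance plane: minimum
distance ≤ 4 Å for the salt-bridge/h-bond windows (configurable; chosen
as the conventional contact criterion since the graphical boxes in
typical figures do not print bounds), plus an explicit loosely-bound box
(default 7–9 Å × 13–15 Å).

## Structure–kinetics machine learning

**Features.** One feature per (residue, substituent) pair: the
interaction energy of substituent R1/R2/R4 with a receptor residue.
Frames are sampled uniformly without replacement per ligand from the
bound portion of the trajectories (z ≤ 15 Å). Pairs are filtered on two
reweighted statistics: keep a pair iff max over ligands of |reweighted
mean energy| ≥ 1.0 kcal/mol AND the cross-ligand standard deviation of
those means ≥ 0.25 kcal/mol. The first rule drops noise-level
interactions, the second drops strong-but-constant anchors that cannot
discriminate between ligands. Cutoff defaults are package choices (the
underlying protocol's exact rule is not published); both are exposed.

**Augmentation.** Each training row is the per-pair mean over a block of
`block_size` frames (default 100) drawn with replacement from one
ligand; `n_aug_per_ligand` rows per ligand (default 200). Block means
preserve each ligand's feature location while creating within-ligand
variance — the minimal structure that makes row-level splits meaningful.
The target log₁₀τ is constant within a ligand, so a row-level 80:20
split measures interpolation over the ligand panel (near-perfect scores
are expected and intended as a regime check); `split_by_ligand=True`
gives the honest generalization estimate instead and is deliberately not
the default.

**Models and evaluation.** Random forest, extremely randomized trees,
gradient boosting and XGBoost, tuned by 10-fold cross-validation on the
training 80% over a small grid (trees ∈ {100, 300}; depth ∈ {None, 8}
for the forests; learning rate ∈ {0.05, 0.1} for the boosted models) and
scored on the held-out 20% by squared Pearson correlation and RMSE.
The trial loop re-derives per-trial seeds from a master seed
(`numpy.random.SeedSequence`), optionally re-augmenting per trial, and
averages min-max-normalised permutation importances across trials and
the four models into the aggregate ranking (ties broken by mean
absolute attribution, then token order).

**Importance and attributions.** Permutation importance is the mean
decrease of the test score when one feature column is shuffled; a
feature the model never consults scores exactly zero. Additive
attributions are computed in-package: for scikit-learn trees, the
decision-path method (each split's change in node mean is credited to
the split feature), which is exactly additive by construction; for
XGBoost, the booster's native TreeSHAP contributions. Local accuracy —
base + Σ contributions = prediction — holds to 1e-6 relative to the
prediction scale on every supported model (XGBoost computes in float32,
which sets that scale).

**Synthetic feature data.** Per-pair base levels ~ N(−3, 2) kcal/mol
with per-ligand deviations of 0.6–1.4 kcal/mol for unplanted pairs and a
fixed 1.5 kcal/mol for the planted modulators (a pair can only modulate
kinetics if it differs between ligands, so modulators sit at the strong
end of the cross-ligand spread); frame-level scatter of 2 kcal/mol;
three planted modulators with weights −0.5, −0.4, −0.35 log₁₀s per
kcal/mol on (H297,R4), (W293,R1), (M151,R1); target noise 0.05 log₁₀s; and one maximally strong (−15 kcal/mol) zero-weight pair
(D147,R1) — a synthetic analogue of a dominant anchoring interaction
that every ligand shares and that therefore carries no kinetic signal.
The recovery claims (planted pairs in the top 5; the anchor pair near
zero) are statements about this generator, not about any particular
receptor. Real feature tables differ in ways the generator ignores:
energies are autocorrelated in time, non-Gaussian, and the true
energy-to-kinetics map need not be linear or sparse.

## Kinetics correlations and similarity

Pearson correlations are computed between log₁₀-transformed positive
quantities (base 10 throughout); records missing either value are
excluded pairwise and reported. The R2-exclusion subset rule drops the
R2-modified analogs — they are nearly indistinguishable chemically, so
neither calculation nor experiment resolves their τ differences and they
dilute the correlation. The packaged 19-ligand panel carries canonical
SMILES and substituent-class labels; its kinetic/affinity columns are a
synthetic stand-in encoding only qualitative orderings (see
`metakin/ligands.py`) and are not measurements. Tanimoto similarity uses
Morgan fingerprints (radius 2, 2048 bits) by default, with MACCS keys as
the alternative; because absolute Tanimoto values depend on the
fingerprint, only ordinal patterns (e.g. R2 analogs closer to the parent
than R4-substituted compounds) are asserted in tests.

## Numerical and interface choices

- All randomness flows from integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; derived seeds stay below
  2³¹. Identical seeds give byte-identical outputs.
- Degenerate inputs: < 3 events → error; zero-spread samples → error in
  the public fit, mean-fallback inside the bootstrap; empty histograms →
  error; single-ligand feature tables → error.
- COLVAR dialect: `#! FIELDS ...` header, `#` comments, whitespace rows;
  bias column name configurable (`metad.bias` default); times are the
  authoritative coordinate; floats written at 17 significant digits so
  round-trips are exact to 1e-10 relative.
- Problem sizes in the test suite are scaled to desk hardware (e.g. 200
  recovery replicates, 10⁵ Boltzmann samples, 20 generator seeds for the
  planted-recovery rate); the sizes are stated in the tests themselves.

## Known limitations

- The rescaling identity is only as good as the infrequent-deposition
  assumption; the package cannot detect bias deposited at the transition
  state.
- Static reweighting ignores the time-dependence of the bias
  normalisation; deep early frames are slightly mis-weighted.
- The block-mean augmentation plus row-level split intentionally
  measures the interpolation regime; ligand-level generalization from 19
  compounds is weak and should be assessed with `split_by_ligand=True`.
- The ligand panel's kinetic columns are synthetic stand-ins; analyses
  requiring measured constants must supply their own ligand CSV.
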