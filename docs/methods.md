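# Methods

This note documents the model implemented by `ncarbs`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Model and assumptions

NCaRBS is a non-parametric, evidence-based n-class classifier. Its unit of
computation is the Dempster–Shafer mass function (body of evidence, BOE)
over the frame of discernment Θ of the nD classes. Evidence enters only
through *constituent* BOEs — one per (subject, characteristic, state)
triple — each supported on exactly three focal elements: the state {d_h},
its complement {¬d_h}, and Θ (ignorance). The construction is a sigmoid
confidence cf(v) = 1/(1+e^{−k(v−θ)}) followed by the clipped linear mass
map with knot A and cap B (see the README for the equations).

Assumptions worth making explicit:

- **Monotone evidence per channel.** Along one characteristic, evidence for
  a state can only increase or decrease monotonically (the sigmoid is
  monotone). Non-monotone class structure is expressible only through the
  *combination* of channels (e.g. "not-low" ∧ "not-high" → middle class),
  not within a single channel.
- **Conditional independence of pooled evidence.** Dempster's rule treats
  the constituent BOEs as distinct, independent evidence sources. Correlated
  characteristics are pooled as if independent; this is inherent to the
  method, not a removable implementation choice.
- **Exchangeable subjects.** The objective is a plain mean over subjects;
  no weighting for class imbalance is applied.

Because the triplet family is closed under combination, state BOEs stay on
three focal elements; object BOEs live on the full power set of Θ minus ∅
(7 focal elements for nD = 3). The pignistic transform (split each focal
element's mass equally among its members) is the standard
transferable-belief-model definition.

## Parameters

Per (characteristic, state) pair, four control parameters; 4·nC·nD in total
(36 for a 3×3 problem):

| parameter | meaning | fit-time box |
|---|---|---|
| k | sigmoid slope, on the standardised (z-score) characteristic scale; sign sets the direction of evidence | [−5, 5] |
| θ | sigmoid centre (z-score units) | [−3, 3] |
| A | lower confidence knot: no directed mass below cf = A (for the state) or above 1−A (for the complement) | [0, 1) |
| B | cap on directed mass; the rest stays ignorance | [0, 0.6) |

The boxes assume characteristics standardised to mean 0, sample SD 1
(ddof = 1, computed over observed entries only; statistics are stored at fit
time and re-applied verbatim to prediction inputs — anything else would leak
information). They constrain the *optimiser*; user-supplied parameter sets
outside the box are accepted with a warning so contribution curves can be
drawn for hypothetical parameters.

Regimes of the mass map: for A < 0.5 the ignorance mass has a constant
plateau 1 − B(1−2A)/(1−A) on cf ∈ (A, 1−A); for A > 0.5 there is a
sub-interval (1−A, A) of *total* ignorance where both directed masses clip
to zero.

## Fitting

The objective is OB = 1/(nD·nO) Σ_i ‖BetP_i − a_i‖₂ with a_i the known
association vector (crisp labels are unit vectors). Implemented exactly as
written, with an optional `per-object` variant (divide by nO only) behind a
configuration switch; the two differ by the constant factor nD. The default
form is bounded by √2/nD.

Optimisation is Trigonometric Differential Evolution: DE/rand/1/bin
(v = x_{r1} + F(x_{r2} − x_{r3}), binomial crossover CR, greedy selection)
with probability 1 − Mt, and with probability Mt the trigonometric mutation

v = (x_{r1}+x_{r2}+x_{r3})/3 + (p₂−p₁)(x_{r1}−x_{r2}) +
    (p₃−p₂)(x_{r2}−x_{r3}) + (p₁−p₃)(x_{r3}−x_{r1}),

p_i = |f(x_{ri})| / Σ|f(x_{r·})|, falling back to the plain centroid when
all three objectives are zero. Operating parameters default to F = 0.99,
CR = 0.85, Mt = 0.05, NP = 200 — the values commonly used with this
optimiser family. Choices that were open:

- **Constraint handling:** out-of-box trial components are reflected at the
  walls (clamped only after pathological repeated overshoot). Reflection
  preserves search diffusion better than clamping to the boundary.
- **Stopping:** a fixed generation budget (default 250). An optional stall
  criterion (no improvement > 1e−8 over 50 generations) exists but is off
  by default, keeping run length — and hence run time — predictable.
- **Initialisation:** uniform in the box from the configured seed.
- **Best-of-n protocol:** `fit` runs the optimiser `n_runs` times (default
  5) from seeds derived deterministically from the user seed, and keeps the
  parameter set with the lowest objective; every run is recorded in the fit
  diary so the protocol is auditable.
- **Infeasible evaluations:** a parameter vector that drives some subject's
  evidence into total conflict (renormalisation denominator ≤ 1e−12) gets a
  large finite penalty (10.0, far above the objective's range) rather than
  an exception, so the search can continue; outside the fit, the same
  condition raises an error naming the subject.

## Numerical choices

- Sigmoid evaluated on the numerically stable branch (no overflow for any
  finite argument).
- Total conflict in Dempster's rule raises an error (rather than yielding
  NaN masses) at 1 − K ≤ 1e−12.
- Mass functions are kept in canonical form (zero-mass entries dropped);
  numeric equality uses tolerance 1e−9.
- Classification ties (equal maximal BetP within 1e−12) break to the
  earliest label in frame order and are flagged ambiguous.
- Undefined precision (a class never predicted) is reported as NaN and
  flagged, not silently zeroed.
- The hot path re-expresses the pipeline as dense vectorised operations
  over the 2^nD subset lattice; the object-level algebra is the reference
  implementation and the test suite asserts the two routes agree to 1e−10.
- Characteristic values outside the training range are extrapolated through
  the sigmoid (not clamped); the sigmoid saturates, so extrapolated evidence
  tends to the B cap, never beyond it.

## Synthetic data: what it does and does not emulate

The generator draws per-class, per-characteristic independent Gaussians,
assigns crisp unit-vector labels, and can blank cells uniformly at random.
The default cohort mirrors the structure of the Trendelenburg-test study
the technique is known from: classes LA/PA/NP of sizes 14/13/16,
characteristics C1 pelvic obliquity (°), C2 frontal-plane hip moment
(Nm/kg), C3 frontal-plane hip power (W/kg). The C2 distributions for LA
(0.49 ± 0.22) and PA (0.59 ± 0.34) are published cohort summaries; **every
other mean/SD is an invented default** chosen once to give moderate class
overlap, and the NP class is entirely unconstrained by published data. No
within-class covariance is modelled (none is published), no waveforms, no
measurement model for the motion-capture pipeline. Consequently, passing
tests demonstrate that the implementation recovers *known structure of this
synthetic form* — they say nothing quantitative about the clinical cohort,
whose subject-level values were never published.

`separated_cohort_spec(separation)` is the experimental dial: unit
within-class SDs and adjacent class means `separation` SDs apart on every
characteristic. At separation 2.0 (sizes 14/13/16, fixed seeds) a
best-of-5 fit reaches training accuracy ≥ 0.9 with objective far below the
uniform-prediction baseline √6/9 ≈ 0.272.

**Training accuracy at zero separation is not chance.** With 36 free
control parameters against 43 subjects, the fitted model partially
memorises noise: at separation 0 the best-of-5 training accuracy lands
around 0.6, roughly double chance (1/3), with the fitted objective below
the uniform baseline. This is ordinary overfitting — training accuracy is
an optimistic estimate of generalisation — and the corresponding test in
the suite documents the expectation-versus-measurement gap rather than
hiding it. Held-out evaluation (generate a second cohort from the same
spec and predict with the fitted model) is the appropriate way to verify
chance-level generalisation.

## Known limitations

- Accuracy figures computed on the training cohort are optimistic; the
  package provides no cross-validation machinery (out of scope).
- Dempster's rule can behave counterintuitively under strongly conflicting
  evidence; alternative combination rules are deliberately not offered.
- The simplex visualisation is limited to three-state frames.
- Frames larger than ~10 states make the dense 2^nD lattice representation
  wasteful; the intended regime is small nD (2–5).
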