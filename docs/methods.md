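# Methods

## Model

The package implements a five-species model of the intrinsic apoptosis
pathway downstream of mitochondrial Cytochrome C (CC) release:
apoptosome formation (a1cc), initiator caspase activation (procaspase-9
c9p → caspase-9 c9a), executioner caspase activation (procaspase-3
c3p → active caspase-3, CEA), constitutive synthesis and first-order
degradation of every species, and inhibition of CEA by IAP. All
binding steps are compacted by the quasi-steady-state assumption into
Michaelis–Menten/Hill factors; CC and IAP are parameters, not dynamic
species (CC is a boundary input that apoptosome formation does not
deplete, IAP an abundance held constant within a cell's lifetime).

Rate equations (μM, min):

    d[a1cc]/dt = k_f1·CC/(1 + K_H·CC) − (k_r1 + μ1)·[a1cc]
    d[c9p]/dt  = Ω9 − A − μ2·[c9p]
    d[c9a]/dt  = A − μ3·[c9a]
    d[c3p]/dt  = Ω_EZ − B − μ4·[c3p]
    d[CEA]/dt  = B − k_u·IAP·[CEA]/(1 + IAP·K_U) − μ5·[CEA]

with the activation fluxes

    A = k_f2 · Φ([CEA]) · [a1cc] · G([c9p]),
        G(x) = K_K·K_L·x²/(1 + K_K·x + K_K·K_L·x²)
    B = k_f3 · [c9a]^n · K_P·[c3p]/(1 + K_P·[c3p]),   n = 1.5

`G` is the two-site (Adair-type) saturation of procaspase-9 loading on
the apoptosome. The non-integer cooperativity n = 1.5 is applied to
the concentration expressed in μM.

Two variants are provided. The `fussenegger` variant is the plain
cascade: Φ = 1 and n = 1; it is monostable (a sigmoidal steady-state
response to CC) and serves as the reference topology. The `modified`
variant adds a positive feedback from executioner caspase activity
onto initiator caspase activation:

    Φ(CEA) = β + w · CEA^m/(CEA^m + K_c^m),
    β = 0.01881,  w = 0.2223,  m = 8

which makes the system a bistable switch.

### Provenance of the feedback constants

The feedback term is the one genuinely under-determined piece of the
model: published descriptions of this pathway modification are
typographically ambiguous about how the CEA feedback and the c9a
autocatalysis enter the activation flux. A literal multiplicative
gating Φ ∝ CEA/(CEA+K_c)·c9a was implemented first and rejected on
structural grounds: it makes the caspase-free state globally absorbing
(its linearization is diag(−μ3, −γ) for every CC, where
γ = k_u·IAP/(1+IAP·K_U) + μ5), so the survival branch can never fold
and the bifurcation diagram has a single saddle-node — no ON
threshold, no sustained low-level caspase activity, no hysteresis
loop. The form above — a small basal activation efficiency β plus a
steep, saturating feedback — is the simplest member of the families we
scanned (leaky/multiplicative/saturating autocatalysis, Hill orders
1–12) that produces the documented switch. Its three constants were
calibrated once, by differential evolution, against four published
steady-state anchors: the OFF and ON saddle-node thresholds (0.08 and
0.83 μM CC) and the survival/apoptotic branch levels (≈0.055 μM at
the upper fold and ≈0.96 μM at mid-window). The calibrated model
reproduces all four within 4% (`sweep_bifurcation` yields SN1 = 0.084,
SN2 = 0.829). No dynamic or stochastic quantity was used in the
calibration, and the constants are ordinary `ModelParameters` fields —
they can be refit if an authoritative algebra becomes available.

### Nominal parameters

k_f1=0.12/min, k_f2=0.3, k_f3=0.015/(μM·min), k_r1=0.4/min; K_H=1,
K_K=0.5, K_L=0.3, K_P=0.1, K_U=0.1 (all μM⁻¹); k_u=0.03/(μM·min);
IAP=0.018 μM; K_c=0.1 μM; μ1..μ5=0.005/min; Ω_EZ=Ω9=0.05 μM/min;
n=1.5. The unstimulated procaspase pools are therefore Ω/μ = 10 μM.

## Deterministic analysis

The rate equations are integrated with LSODA (relative tolerance 1e-8,
absolute 1e-10), clipping at zero; outputs are sampled on a regular
grid (default 1 min).

Equilibria are located by multi-start damped root finding (`hybr`) on
the derivative map. Start points come from a deterministic lattice
spanning twice the synthesis/degradation scales **plus** seeds from a
one-dimensional reduction: at equilibrium a1cc is fixed by CC alone
and c9p, c3p, CEA follow from the linear balances, leaving a single
scalar residual in c9a whose sign changes locate every branch,
including the unstable one a coarse lattice can miss. Duplicates are
merged at relative distance 1e-4; stability is the sign of the
dominant real eigenvalue of a central-difference Jacobian.

Saddle nodes are localized by bisection on the equilibrium count over
the CC axis to 1e-3 μM — robust for a five-state system and an order
of magnitude finer than the two-decimal thresholds being reproduced.
The two-parameter bistability map declares a grid cell bistable when
any CC in a log-spaced scan window yields two stable equilibria.
Hysteresis is checked by a quasi-static up/down CC sweep of the
integrator, carrying the state between grid points (4000 min of
settling per point; switching is detected against a 0.3 μM CEA level).

The default initial state places the procaspase pools at their
unstimulated values, no apoptosome, and a seed ε of active caspase-9
and caspase-3. ε is needed at all because the modified model's
activation is nearly shut at CEA = 0; its default, **ε = 0.1 μM**, was
chosen from the geometry of the calibrated switch: the unstable
(saddle) branch lies at CEA ≈ 0.06–0.13 μM across the bistable window,
so a 0.1 μM seed puts a quiescent cell at the basin boundary. That
places the deterministic ignition threshold near CC ≈ 0.25 μM —
matching the documented location of peak delay-time variability under
extrinsic CC noise — and lets intrinsic noise split a clonal
population into committed and surviving fractions inside the window.
Delay-time experiments instead start caspase-free (ε = 0), because T_d
measures the first rise of caspase activity after CC release and a
preexisting seed would truncate it.

## Stochastic simulation (intrinsic noise)

The same twelve lumped fluxes serve directly as reaction propensities
(the Michaelis–Menten factors are not expanded into elementary steps):
a propensity is the deterministic flux evaluated at concentrations
count/V_c, multiplied by V_c. Gillespie's direct method is implemented
in a numba kernel; per event, the waiting-time uniform is drawn before
the reaction-choice uniform, so one integer seed fully determines a
trajectory. Trajectories are recorded last-value-carried-forward on a
regular grid (default 1 min) with an event budget (default 5×10⁷) that
raises a truncation error carrying the partial record. Population runs
give cell i the seed base+i, making results independent of execution
order and trivially parallelizable.

The volume scale V_c = 1000 molecules/μM maps the nominal 10 μM
procaspase pools to 10⁴ molecules per cell and the bistable window to
roughly 80–830 CC molecules. At V_c = 10⁵ the population-mean
trajectory agrees with the rate equations within three standard errors
at every recorded time (tested), which doubles as the consistency
check between the propensity table and the rate equations.

### Copy-number conditions

The eight study conditions pair procaspase-9 ∈ {5×10³, 10⁴} with
procaspase-3 ∈ {10, 10², 10³, 10⁴} molecules per cell. Two
realizations are implemented:

- `initial` (default): the targets are initial molecule counts under
  nominal synthesis — sub-nominal abundances are transients, as after
  partial degradation or dilution. This is the only realization
  consistent with apoptotic steady states of hundreds of CEA
  molecules at low-c3p conditions: rescaled synthesis caps steady CEA
  at c3p_target·μ4/γ (≈9 molecules for a 10-molecule c3p condition).
- `synthesis`: synthesis rates are rescaled (Ω9 = c9p_target·μ2/V_c,
  Ω_EZ = c3p_target·μ4/V_c) so the targets persist as open-loop steady
  counts. Use this to model constitutively low expression; note it
  changes the bifurcation structure itself.

## Extrinsic and combined noise

Extrinsic noise is static cell-to-cell variation: each cell draws its
CC and/or IAP abundance from a log-normal distribution parametrized so
the arithmetic mean and CV are exact (σ² = ln(1+cv²),
μ = ln(mean) − σ²/2; default CV 0.25) and keeps it for life. In the
extrinsic-only regime the rate equations are solved per cell; in the
combined regime each cell also runs one stochastic realization (CC
drawn in molecule counts, rounded, zero-draws resampled once; IAP in
μM). Protein draws use a stream disjoint from the per-cell simulation
seeds, and an empty fluctuating-protein set reduces the combined
regime exactly to the intrinsic-only population at the same seeds
(tested). Heat maps over (mean CC, mean IAP) draw an independent
population per grid point.

## Response statistics

- **Steady state**: mean CEA over the trailing 10% of the time grid,
  with a convergence flag comparing against the preceding window.
- **T_d**: first time CEA reaches half of a common population
  reference, linearly interpolated between samples; cells that never
  cross are non-responders and are excluded from T_d statistics. The
  reference is, in `responders` mode, the mean steady state of cells
  in the elevated mode (above half the population maximum and above an
  ignition floor, default 0.2 μM or 200 molecules — populations where
  no cell ignites have no reference, the "blank" regions of the noise
  maps); in `population` mode, the mean over all cells, which below
  threshold measures relaxation toward the survival state and is the
  mode used for the delay-versus-CC curves so that T_d remains defined
  at sub-threshold inputs.
- **CV and Fano factor** use n−1 denominators (samples are 150 cells).
- **Bimodality**: exhaustive-threshold two-cluster split minimizing
  within-cluster variance; bimodal iff both clusters hold ≥5% of cells
  and the mode means are ≥3 pooled within-cluster SDs apart. The rule
  is a package convention; both knobs are arguments.
- **Stochastic bistability thresholds**: over a CC scan of population
  histograms, the ON (OFF) threshold is the smallest (largest) CC
  whose high (low) mode holds ≥95% of cells. In the zero-noise limit
  the window collapses onto the deterministic saddle-node window up to
  grid resolution — the rationale for the 95% convention.

## Problem sizes

Populations default to 150 cells (the study-scale sample). The test
suite and the acceptance script use 150 cells for the bimodality,
extrinsic-noise and CV-plateau computations, 60–150 cells for the
delay-time means, 40 cells for the high-copy-number noise floor, and
20-cell ensembles at inflated volume for the thermodynamic-limit
check; a full acceptance run takes a few minutes on one CPU.

## What the simulations do and do not emulate

The synthetic populations capture reaction-event stochasticity at
physiologic copy numbers and static abundance variation of two key
proteins. They do not include transcriptional bursting, time-varying
(Ornstein–Uhlenbeck-style) extrinsic fluctuations, cell growth or
division, spatial effects, receptor-pathway cross-talk, or IAP
feedback on caspase-9 (deliberately excluded from the topology).
Passing tests therefore demonstrate properties of this idealized
switch, not of real apoptosis data.

## Known limitations

- The feedback algebra is a calibrated reconstruction. The
  deterministic switch (thresholds, branch levels, hysteresis,
  monostable reference variant) is reproduced quantitatively, but four
  stochastic readouts deviate from their documented values in
  characteristic ways: (i) the survival-mode mean of the bimodal
  steady-state histogram sits at ~25–40 rather than ~55 molecules at
  the CC where the apoptotic mode is ~10³ — on the calibrated S-curve
  the two documented mode values are attained at different CC, so no
  single histogram can show both; (ii) mean delay times at moderate CC
  are 2–3× longer than the documented ~160 min, and (iii) the
  high-copy noise floor is ~0.05 rather than ~0.01 — both follow from
  the 1/μ3 = 200 min caspase-9 relaxation time that the nominal
  parameters impose on any algebra, suggesting the original
  implementation used faster initiator-caspase kinetics; (iv) the
  ordering of delay-time CVs across copy-number conditions flattens
  under the `initial` realization (condition differences are
  transient) and would require the `synthesis` realization, which is
  incompatible with (i)–(iii). These gaps are left visible rather than
  papered over; the corresponding checks in `tests/test_acceptance.py`
  fail by design and document the discrepancy.
- The SSA keeps lumped Hill propensities; at extremely low copy
  numbers the quasi-steady-state assumption behind them weakens.
- `find_equilibria` guarantees only the branches reachable from its
  start lattice and 1-D reduction seeds; exotic parameter corners may
  need more starts.
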