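# Methods

## Model

The simulator describes an idealized tumour as a Krogh cylinder: a
single straight, rigid vessel of radius R_C = 100 µm on the axis of an
interstitial annulus out to R_T = 1200 µm, length L = 1 cm.  The tissue
is homogeneous, the cells uniform, stationary and initially all alive;
blood is Newtonian and the flow steady.  These assumptions trade realism
(vascular networks, heterogeneity, cell cycle) for a transparent test
bed in which the interplay of transport and intracellular signalling can
be read off directly.

**Flow.**  At lumen Reynolds number ≈ 1.6 and aspect ratio R_C/L = 0.01,
the momentum equation reduces to Poiseuille flow with distributed
leakage: Q(z) = −(πR_C⁴/8µ)dP_v/dz with dQ/dz = −2πR_C·J_F and Dirichlet
pressures P_A = 15 mmHg, P_V = 0 at the ends.  The contract exposes only
P_v, the cross-section mean velocity and J_F, so a 2D Navier–Stokes
lumen could replace this without interface change; for the baseline
parameters the leak removes ~0.05% of the perfusion and P_v is linear to
numerical precision, consistent with the reduction.  The interstitium is
Darcy flow, ∇·(K∇P_i) = 0, with the Starling filtration J_F =
L_p(P_v − P_i) as a wall Neumann flux and the ambient pressure P_0 on
the outer radius and both end annuli.  The oncotic term of Starling's
law is dropped (highly permeable tumour vessels); the osmotic reflection
coefficient therefore never enters the water balance.  The two problems
are fixed-point iterated on J_F (relaxation 0.5, relative tolerance
1e-8, cap 200 iterations; converges in ~20).  The Dirichlet/Neumann
discontinuity where the end annuli meet the wall is left as-is: it
produces the sharp entrance rise of interstitial pressure and the sharp
near-inlet fall of J_F that the model is expected to show, and is not
smoothed.

**Drug transport.**  Vascular c_v (cross-section averaged, 1D),
extracellular c_E and intracellular c_I (2D axisymmetric), all stored
normalized: 0.001 µg/mm³ for c_v and c_E, 1 ng per 10⁵ cells for c_I,
10⁶ cells/mm³ for density.  The wall exchanges solute by the
Kedem–Katchalsky flux J_s = P(c_v − c_E) + J_F(1 − σ_F)Δc_lm with the
log-mean concentration Δc_lm = (c_v − c_E)/ln(c_v/c_E).  Membrane
exchange is Michaelis–Menten both ways (V₁ = V₂ = 0.28 ng/10⁵cells/min,
k₁ = 0.219 µg/ml, k₂ = 1.37 ng/10⁵cells), giving an intracellular
equilibrium c_I = (k₂/k₁)c_E ≈ 6.26·c_E — the drug is preferentially
sequestered in cells, which is why interstitial penetration is
capacity-limited.  The extracellular sink is the net exchange times the
*live* local density.

**Signalling and density.**  The bistable switch
dR/dt = V_f(1−R)/(K_m1+1−R) + (p+qc_I)k_fb·R(1−R) − V_rR/(K_m2+R)
has, at zero drug, stable states at R ≈ 0.019 and 0.749 separated by an
unstable state at ≈ 0.092; its low branch vanishes at the saddle-node
input c_I* ≈ 1.009, beyond which R commits irreversibly to the high
branch.  The monostable switch dR/dt = k(c_I¹⁰/(k_h+c_I¹⁰) − R) has one
steady state for every input and half-activates at c_I = 1; its
irreversibility is a permanent latch on the downstream trigger.  Both
feed dR₁/dt = k_fR(1−R₁) − k_rR₁ (read as activation-by-R with
first-order decay — the only reading consistent with the tabulated
"activation rate"/"degradation rate" labels and R₁ ∈ [0,1]); sustained
R = 1 drives R₁ to 0.9615, above the 0.9 threshold, and the minimum
sustained R that can trigger is 0.36.  Density follows
dc_t/dt = a₁c_t − a₂c_t − bc_t², whose non-trivial steady state
(a₁−a₂)/b = 1.003×10⁶ cells/mm³ matches the initial density within
0.5%.  Triggering gates the growth rate hard to zero (re-evaluated every
step in bistable mode, latched in monostable mode): the simplest
realization that makes extinction the only attractor in triggered
cells.  An important quantitative consequence: with the tabulated rates
the gated decay is ≈ 0.5/day, so cells triggered a few hours before the
10 h readout have lost only 5–15% of their density.

## Numerics

Cell-centered finite volumes on an axisymmetric (r, z) grid; radial
spacing is geometrically clustered toward the wall (default ratio 3
between outermost and wall-adjacent cell) because the drug boundary
layer is ~100 µm; z is uniform.  The production grid is 240×100 with
10 s steps; whole-run tests and the acceptance script use 96×24 with
20 s steps (≈ 40 radial cells inside 5R_C), which moves the baseline
death width by about half a wall-region cell relative to the doubled
grid.

Per global step: (1) the lumen advances by one fully implicit
(backward-Euler, upwind, flux-form) tridiagonal solve — the convective
transit of 0.16 s relaxes to its quasi-steady profile with no CFL
limit; (2) the interstitium advances by one implicit solve whose
constant matrix carries diffusion *and* first-order upwind Darcy
advection plus the P·c_E part of the wall exchange.  Advection is kept
inside the implicit operator deliberately: the wall-clustered cells turn
over advectively in ~20 s, and splitting advection into its own explicit
stage produced an O(1) steady-state error exactly in the boundary layer
the clustering resolves.  The wall coupling is predictor–corrector: the
lumen is solved against c_E^n, the tissue against that lumen profile,
then the lumen is re-solved against the new wall c_E.  The convective
(solvent-drag) part of J_s is explicit with the log-mean regularized in
three continuous branches (both sides ~0 → 0; nearly equal → arithmetic
limit; one side ~0 → floored at 1e-12, which sends the flux smoothly to
zero).  (3) The pointwise stiff stage — membrane exchange with its
density-weighted sink, both switches, R₁, logistic density — integrates
with classical RK4 at 1–2 s sub-steps (stiffest local rate ≈ 0.2/s),
the growth gate frozen per sub-step so the integrand stays smooth, R and
R₁ clipped to [0,1] against roundoff overshoot.

**Mass accounting.**  A per-step ledger tracks lumen, extracellular and
intracellular (c_I·c_t) masses, cumulative inlet/outlet fluxes, any
negativity clips, and the drug destroyed inside dying cells — in this
model the Eq-for-c_E sink is per live cell while c_I is a per-cell
concentration, so intracellular drug in cells that die leaves the books;
the ledger integrates that term with the same RK4 quadrature and treats
it as a model sink alongside outflow.  The conservation criterion is the
*unaccounted* remainder relative to cumulative inflow, which verifies
the discretization: < 2×10⁻⁵ on the reduced grid and < 10⁻⁷ on the
production grid over a full baseline run, with no monotone drift.  The
predictor–corrector wall mismatch P·A·dt·(c_v_corr − c_v_pred) is part
of that remainder.

## Readout and experiments

The death-region width is the contiguous radial extent from the wall
over which c_t < frac·c_t0 at z/L = 0.5 and t = 10 h.  The threshold
fraction is a reporting knob (reported with every width); the default is
frac = 0.95.  This choice follows from the gated decay rate above: a
cell triggered at 3–5 h has lost 5–15% of its density by 10 h, so a 5%
depletion contour marks the triggered region, whereas a 50% contour
detects nothing anywhere within the window for any stimulus and would
make every experiment degenerate.  "Relative death region" in the
experiment tables is width normalized by the baseline-case width.

The experiment drivers rerun the full pipeline per point: pulse
intensity/duration scans, equal-dose fractionation (the fixture set
shares S·T = 2: (1, 2 h), (0.75, 8/3 h), (0.5, 4 h) — reconstructed
from the constraint that the distinguished long-weak case is S = 0.5,
T = 4 h), and multiplicative sweeps of D_E, P, R_T, L_p, K.  The
higher-dosage arm of the diffusivity sweep uses S = 4, chosen as the
regime where doubling D visibly widens the kill region while 10× D
changes it little.

## Bidirectional coupling, and what the tests show

The transport → kill direction is strong and visible (the death region
is set by where c_I stays above ~1 long enough).  The kill → transport
direction is implemented exactly as specified — the extracellular sink
uses the live density every sub-step — but with the hard gate and the
tabulated logistic rates its within-window effect is tiny: density falls
~13% only in a thin annulus and only in the final hours, shifting c_I by
~10⁻⁵ relative, far below the width quantization (freezing the density
at its initial value changes no width).  The tests therefore verify the
coupling pathway directly (fields differ between live and frozen
density; halving the cell density measurably deepens penetration) rather
than asserting a width-level inequality the parameterization cannot
produce.  A model variant with a faster post-trigger death rate would
make the feedback loop quantitatively important; that is a parameter
choice, not a structural change.

## Synthetic conditions and limitations

There is no external data: the parameter table *is* the study
condition, and every experiment is generated by the simulator itself.
Consequences to keep in mind: the single-vessel geometry has no
avascular regions or vascular heterogeneity, so absolute widths
characterize the idealized cylinder, not a real tumour; plasma-protein
binding, lymphatic drainage, the host tissue, drug metabolism beyond the
membrane exchange, pulsatile flow and cell-level stochasticity are all
outside the model; the lumen is cross-section averaged, so the radial
concentration boundary layer inside the vessel is not represented, only
its axial depletion.  Passing tests show the coupled scheme is
conservative, convergent and reproduces the qualitative transport and
signalling phenomenology of this idealized system — they do not
validate the parameter values against experimental tumours.

Degenerate inputs are handled explicitly: L_p = 0 decouples the flow
problem (pure Poiseuille, quiescent tissue); q = 0 decouples the
bistable switch from drug and the saddle-node search reports it; S = 0
leaves all drug fields identically zero while the signalling relaxes to
its drug-free rest state (R on the low branch, R₁ ≈ 0.32, no
triggering) and the density drifts < 0.5% toward its logistic steady
state.  Ties in the width metric resolve toward the wall: the width is
zero as soon as the wall-adjacent cell is above threshold.
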