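# Methods

## Model

One molecular species, `N_T` copies, conserved. Each copy is either
*inactive* — cytosolic, assumed well mixed because cytosolic diffusion
is orders of magnitude faster than membrane diffusion — or *active* —
bound to a 1-D circular membrane of circumference `L`, diffusing
laterally with coefficient `D_m`. Transitions are mass action:

| event | propensity |
| --- | --- |
| inactivation (per active molecule) | `k_off` |
| spontaneous activation (per inactive molecule) | `k_on · V_on/V` |
| recruitment (per active–inactive pair) | `k_fb · V_fb/V` |

A recruited molecule appears exactly at its recruiter's position and
thereafter diffuses independently; this is the positive feedback, and
it is also what carries *genealogy*: the recruit inherits the
recruiter's clan label, dissociation erases identity, and a clan that
loses its last member never returns.

Everything is controlled by the derived constants

    rho_T = N_T / V                total density
    rho_star = k_off / (k_fb V_fb) critical density
    alpha = k_on V_on / (k_off V)  on/off ratio (imperfection parameter)
    beta  = k_on V_on / (k_fb V_fb) on/feedback ratio
    R0 = rho_T / rho_star,  N_star = rho_star · V

`rho_star` depends only on the feedback reaction itself, never on cell
volume or molecule count; `R0` is the analogue of an SIS epidemic's
basic reproductive ratio (cytosolic molecules = susceptibles, membrane
molecules = infectives, recruitment = contact infection). Note that
jointly rescaling `(V, V_on, V_fb, N_T)` leaves `alpha`, `beta` and
`rho_T` unchanged but *not* `rho_star`, which is set by the molecular
feedback volume alone — the switch threshold is a density, not a
number.

## Deterministic layer

In time rescaled by `k_off` the cytosolic density obeys
`dρ_c/dτ = (ρ_T − ρ_c)(1 − ρ_c/ρ*) − αρ_c`. The equilibria solve
`ρ² − bρ + ρ_T ρ* = 0` with `b = ρ_T + ρ*(1+α)`; the smaller root is
computed as `2ρ_Tρ*/(b + √disc)` because the textbook `(b − √disc)/2`
loses all significant digits near the transcritical point when
`α ≪ 1`. At `α = 0` the equilibria are exactly `{ρ_T, ρ*}` with the
smaller stable (transcritical exchange at `ρ_T = ρ*`); for `α > 0` the
discriminant is strictly positive, the larger root always exceeds
`ρ_T` (unphysical), and the unique physical equilibrium is stable
(imperfect transcritical). Roots closer than `1e-9·ρ*` are reported as
degenerate rather than returned as near-equal pairs. Time integration
uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-9) on the rescaled
equation and un-rescales on output; solver failure raises, the
trajectory is never clipped silently.

## Stochastic count layer

The cytosolic count is a one-step birth–death chain on `{0..N_T}`,
birth `k_off(N_T − n)`, death `k_on(V_on/V)n + k_fb(V_fb/V)n(N_T−n)`.
The stationary pmf follows from the detailed-balance product
recursion, accumulated as a cumulative sum of log rate ratios and
normalized with `logsumexp`, stable up to `N_T ~ 1e5`. With `k_on = 0`
the state `n = N_T` is absorbing and the point mass there is returned
(the α → 0 limit is meaningful, mirroring disease extinction in the
stochastic SIS model). Mode detection merges plateaus of exactly equal
probability into one candidate and discards modes whose basin
(delimited by the minima between adjacent candidates) holds less than
`min_mass = 1e-4`; "bimodal" means at least two surviving modes. Far
above threshold the pmf is compared against a Poisson with mean
`N_star`, truncated to the support and renormalized, via total
variation distance.

## Particle simulation

Fixed-step operator splitting, per step of length `dt`: (a) each
membrane molecule dissociates with probability `k_off·dt`; (b) each
*surviving* membrane molecule recruits with probability
`k_fb(V_fb/V)·N_c·dt`, using the start-of-step cytosolic count, the
recruit placed at the recruiter's position with its clan id; (c)
`Poisson(k_on(V_on/V)·N_c·dt)` spontaneous attachments at uniform
positions, each founding a fresh clan (reseed perturbations likewise
assign fresh ids — identity is lineage, so every founder is new); (d)
Gaussian diffusion steps of variance `2·D_m·dt`, wrapped mod `L`.
Mass conservation is exact by construction and asserted at every
record.

Numerical choices: the step is validated so every per-molecule event
probability stays below 0.1, and the default `dt` is sized from the
largest molecule count the schedule will reach (cytosol additions
included). Dissociation-before-recruitment on the pre-step set is a
fixed convention; any such ordering is consistent as `dt → 0`, and the
dt-convergence test guards the splitting bias. That bias is first
order in `dt` and is largest near the critical point, where the mean
membrane fraction is most sensitive — at the default step size the
long-run mean membrane fraction at `R0 = 1.5` is depressed by a few
percent relative to the exact chain, while occupancy histograms deep
in the off or on regimes are indistinguishable from the master
equation (TV ~ 1e-4). Regime classification uses thresholds far
coarser than this bias. If the total number of conversion draws in one
step would exceed the cytosolic pool (an O(dt²) event at the enforced
probabilities), the surplus draws are dropped at random.

Perturbation protocols: `reseed(f, w)` moves `round(f·N_c)` cytosolic
molecules to uniform positions inside a single window of width `w·L`
at a uniformly random start angle (outcomes must be rotation
invariant, so the window is never pinned); `add_cytosol`/
`remove_cytosol` change `N_c` and `N_T` together, and removal beyond
the current pool raises before any mutation.

## Clan genealogy

Between on-events every membrane molecule recruits and dissociates at
equal per-capita rates, so clan sizes perform neutral drift with
per-capita turnover `λ = (k_off + k_fb(V_fb/V)N_c)/2` — equal to
`k_off` at quasi-steady state where recruitment balances dissociation.
Treating the membrane population as a Moran-type neutral process with
pairwise lineage-coalescence rate `2λ/N_m` gives the consolidation
timescales

    T_half   = N_m / (K λ)          (half the K initial clans extinct)
    T_single = (1 − 1/K) N_m / λ    (one clan remaining)

These forms are self-consistent (`T_single(K) − T_single(K/2) =
N_m/(Kλ)`), coincide at `K = 2`, halve `T_half` exactly when `K`
doubles, and shorten with faster feedback turnover at fixed membrane
population. A critical-branching alternative derivation produces the
same structure with an extra `1/ln 2` factor; simulation medians
across a parameter sweep (ratios 0.77–1.08 for the half-life,
0.83–0.98 for the single-clan time) select the coalescent
normalization, which is how the constants were locked. Both formulas
are expectations over a wide-variance process; concordance is asserted
at 25% (half-life) and a factor of two (single-clan time) against
medians, matching that variance, and the half-life estimator crosses
at `⌈K/2⌉` surviving clans (parity must be fixed somehow; the ceiling
is the documented choice).

Two closed-form predicates bound the polarized regime. *On-rarity*:
spontaneous attachments found clans that dilute the winner; requiring
the standing spontaneous-origin fraction accumulated over `T_single`
to stay below δ gives `beta·(1 − 1/K)/ln 2 ≤ δ` (with `k_on = 0` any δ
is satisfied). *Locality*: the winning clan's spatial spread is
diffusion over the consolidation time, `√(2 D_m T_single)`; demanding
it stay below the compartment scale caps the molecule number,
`N_T ≤ N_star + C·L²·k_off/D_m`, with `C` an order-one constant tied
to the size of the initial clan regions (default 0.25; `D_m = 0`
satisfies the bound for any `N_T`). With the default geometry these
bounds put the loss-of-polarity boundary at `N_T ≈ 2750 ≈ 3·N_star`,
where the simulated polarization frequency indeed collapses.

## Polarity metric and regimes

A state is polarized when more than 20 molecules are membrane-bound
and at least 50% of them lie inside one circular window covering a
fraction (0.15/0.20/0.25, default 0.25) of the membrane; the window is
scanned at 360 equally spaced starts, making the discretization error
(≤ 1/360 of the mass) negligible against the 15–25% widths.
Polarization frequency is the fraction of post-burn-in (run, time)
samples polarized, with a binomial standard error.

Regime classification: OFF if the time-mean membrane fraction is below
`off_eps = 0.02`; else POLARIZED if the polarization frequency reaches
`pol_threshold = 0.3`; otherwise the membrane is substantially
occupied but not singly polarized, and the call between MULTI_CLAN and
HOMOGENEOUS_ON is made spatially: the time-mean enrichment of the best
window (best-window fraction / window fraction) is ≈ 1 for a flat
membrane and > 1.4 for distinct clusters. A surviving-clan-count rule
was considered for MULTI_CLAN and rejected: with `k_on > 0` the
homogeneous regime carries dozens of long-lived transient clans (its
consolidation time `~N_m/k_off` reaches 10³ minutes at `8·N_star`), so
clan counts cannot separate several-localized-clusters from
homogeneous-on at any practical horizon; spatial flatness can. All
thresholds are artifact choices exposed as keyword arguments, not
claims about the biology.

Phase scans vary `N_T` and compartment size `V` (the 1-D circumference
scales with `V` so density and geometry stay linked), classify each
cell from replicate simulations, and overlay the analytic expectation:
OFF where `R0 ≤ 1`, POLARIZED where `R0 > 1` and both clan bounds
hold, boundary otherwise. Cell failures are recorded and the scan
continues.

## Finite-diffusion geometries

The variant model drops the well-mixed assumption: inactive molecules
diffuse at finite `D_c` (≫ `D_m`) in the sphere interior, the periodic
plane, or the periodic box, and recruitment becomes a proximity
reaction — each active–inactive pair within `reaction_radius` converts
with probability `p_react` per step, at most one conversion per
inactive molecule per step, pair order randomized to avoid bias.
Neighbor queries use a k-d tree with periodic box support; sphere-
surface diffusion takes a tangent-plane Gaussian step and re-projects
radially (error O(dt), covered by the dt-convergence check);
inactive molecules reflect radially at the sphere boundary. The
correspondence to the well-mixed model is the reaction-limited
effective coefficient `k_fb·V_fb = p_react·v_r/dt`, `v_r` the
neighborhood measure (`πr²` in 2-D, `4πr³/3` in 3-D); `p_react` can be
calibrated from a target `k_fb·V_fb` by inversion. This is a
Smoluchowski-spirit approximation, accurate in the reaction-limited
regime (`p_react` small, `D_c` large); it is not intended to be
diffusion-limit accurate.

## Default parameters

| parameter | default | unit | origin |
| --- | --- | --- | --- |
| `k_off` | 9 | 1/min | literature-derived dissociation rate |
| `k_on` | 5e-4 | 1/min | assumed small spontaneous activation |
| `k_fb` | 0.01 | 1/min | literature-derived feedback rate |
| `V = V_on = V_fb` | 1 | volume | unit-domain convention, so `N* = k_off/k_fb = 900` |
| `D_m` | 1.2 | µm²/min | membrane GTPase diffusion estimate |
| `L` | 2π·5 ≈ 31.4 | µm | circumference of a 5 µm-radius cell |
| `dt` | 0.1/max rate | min | per-event probability < 0.1 |
| `delta` | 0.1 | — | tolerated non-winner fraction in the on-rarity bound |
| `K` | 50 | — | initial clan partitions |

The domain scale deserves a note: the composite rates are quoted for a
unit reaction volume, which fixes `N_star` but not the membrane
length. With `D_m` in physical units the circumference sets the
diffusion-to-turnover ratio `D_m/(L²k_off)` that decides whether
clusters can stay localized; a 1 µm circumference homogenizes the
membrane within a minute and admits no polarized window at any `N_T`.
The default is a cell of radius 5 µm, chosen once as a realistic cell
scale at which the simulation shows the full repression → single
recurrent cluster → homogeneous progression (peak polarization
frequency ≈ 0.75–0.85 near `1.5·N_star` with the 25% window);
smaller cells polarize more weakly, larger ones more sharply.

## What the simulations do and do not show

The synthetic dynamics emulate a conserved two-state signaling pool
with local recruitment on an idealized geometry. They deliberately
omit: intermediate species of real feedback loops (GEFs, adaptors,
GDI cycling), membrane crowding and excluded volume (reaction volumes
never saturate, so very high densities are extrapolations),
curvature effects, and any fitting to measured copy numbers. Passing
tests therefore demonstrate the internal consistency of the switch
mechanism — threshold position, noise buffering, neutral-drift
consolidation, density-dependent loss of polarity — not quantitative
agreement with any particular cell type.

## Known limitations

* The operator-split simulator is first-order in `dt`; near the
  critical density long-run means carry a few percent bias at the
  default step. Halve `dt` (or lower the safety factor) when
  quantitative means near `R0 ≈ 1` matter.
* The locality constant `C` and the classification thresholds are
  order-of-magnitude choices; the phase-diagram boundaries shift
  smoothly with them.
* The stationary-pmf recursion assumes `k_on > 0` mixing; the
  `k_on = 0` point mass is the absorbing-limit answer, not a
  quasi-stationary distribution (which is out of scope).
* The geometry variant's effective-rate map is reaction-limited; at
  large `p_react` or slow `D_c` recruitment becomes diffusion-limited
  and the mapped `k_fb` overestimates the true flux.
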