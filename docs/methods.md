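# Methods

This note records the model, its assumptions, the default parameter
choices and why they were made, and what the synthetic test bed does and
does not establish.

## Scope and intent

The package is an in-silico test of the retroperfusion washout
hypothesis: a closed-loop 0D (lumped-parameter) coronary network under
occlusion and retroperfusion boundary conditions, with Lagrangian
indicator transport. It deliberately excludes oxygen/nutrient transport,
wave propagation (a 0D model cannot represent wave reflection; the GCV
retroperfusion pressure is therefore a prescribed input, not a predicted
quantity), baroreflex control, and any tissue mechanics beyond a
prescribed intramyocardial pressure. Conclusions it supports are
*directional and structural* (which exit routes dominate under which
boundary conditions), not quantitative predictions for any animal.

## Synthetic morphometry

Real coronary morphometry at full scale has ~10⁶ vessels; published
reduced network models use a few thousand *equivalent* vessels. The
default table here is a further reduction to 296 geometric vessels
spanning all orders 11..−12, sized for test-suite turnaround. Two
calibration choices follow from that reduction, and both are properties
of the shipped default table (plain config data — any other table can be
supplied as CSV):

- **Compressed diameter range** (capillary-order vessels ~25 µm up to
  ~600–800 µm trunks, rather than 8 µm–4 mm). With only ~60
  capillary-order vessels, anatomical diameters would give the network a
  macro-volume-to-micro-flow ratio implying transit times of hours;
  the compressed range keeps path resistances and volumes in proportions
  that put convective timescales where a 10-minute protocol can see them.
- **Branching-ratio column ~1.6**, consistent with the reduced per-order
  count progression (the anatomical value ~3 belongs to the full-scale
  tree; using it with reduced counts makes the compliance progression
  inconsistent with the vessel volumes actually present).

Counts must be non-decreasing toward the capillaries on each side so that
every vessel lies on an inlet→outlet path, and the capillary count must be
at least twice the order-1 count so each terminal arteriole feeds ≥ 2
capillaries. Networks are generated deterministically from (table, seed);
serialization is canonical JSON, so equal inputs give byte-identical
files.

**Thebesian shunts** (default 10) are placed uniformly at random among
interior nodes whose incident vessels all have |order| ≤ 3 — the
arteriole/venule neighbourhood — and drain into a cardiac chamber node.
Their lumped resistance defaults to 5× the order −1 venule resistance.
The default chamber is the low-pressure (atrial) one: Thebesian drainage
predominantly enters the low-pressure chambers, and a mean LV
backpressure (~45 mmHg time-averaged) would sit above the balloon-deflated
retroperfusion pressure, which would make beat-averaged washout
ill-posed. Setting `thebesian_chamber: LV` is one config line.

**Equivalent microvascular networks.** The embedded micro network
(orders −6..6) is accompanied by 15 registered copies. Each copy is
assembled as a single lumped R–C pseudo-vessel spanning the embedded
network's entry/exit nodes, with R equal to the embedded region's
effective (reference-state) resistance obtained by Laplacian reduction,
C its summed compliance, and volume its summed luminal volume — so for
identical copies total microvascular flow is (1 + n) × the embedded flow,
and tracer transit through a copy matches the embedded network's
volume/flow time. Copies are lumped: tracer inside a copy has no
addressable position, and copy interiors host no Thebesian shunts.

## Vessel element

State is the stored volume V of each compliant vessel. The element is two
resistive halves around the compliant midpoint:

- transmural pressure from volume: P_tm = P_ref + (V − V_ref)/C₀, with a
  stiff floor below V = 0.25·V_ref (compliance × 0.01) so collapse cannot
  produce negative volumes or a singular inversion;
- resistance from transmural pressure: the distension factor
  f = 1 + β(P_tm − P_ref)/P_ref is clamped to [0.5, 2.0] and R = R₀/f⁴.
  β defaults to 0.2, P_ref to 45 mmHg; during systole the intramyocardial
  squeeze drives P_tm negative in the microcirculation and resistance
  rises several-fold, the expected systolic impediment;
- external pressure: P_ext = w·P_LV(t) with w = 0.75 at the capillaries
  tapering linearly to 0 at |order| ≥ 7.

A remark on consistency: one could instead derive compliance from the
same distension law (C = dV/dP_tm). That would fix C per vessel from
geometry and β, leaving no freedom to impose the per-order aggregate
compliance progression that the R/C scaling contract prescribes. The
linear-C law anchored at the scaled C₀ keeps both requirements and stays
smooth and invertible; β then shapes resistance only.

Per-order aggregate compliance is anchored at the capillary order
(5×10⁻⁸ mL/mmHg total) and multiplied by the branching ratio per order
step outward; a ratio of 1 makes all orders equal, the documented
degenerate case. The anchor keeps compliance-driven volume excursions
under the systolic pressure swing below the collapse floor.

## Heart, periphery, boundary handling

Chambers: P = E(t)(V − V₀) with a raised-cosine activation (continuous
first derivative, periodic). Defaults: period 0.6 s (~100 bpm swine), LV
E_max/E_min = 2.0/0.06 mmHg/mL, V₀ = 10 mL; LA 0.25/0.12, V₀ = 5 mL,
onset at 80 % of the cycle. Periphery: C_as = 1.5 mL/mmHg,
C_vs = 60 mL/mmHg, R_sys = 1.2 mmHg·s/mL, soft-diode valves (sigmoid
conductance over 0.25 mmHg). These land aortic pressure at ~86–132 mmHg
and LV at ~3–134 mmHg on the default network.

Junction nodes store no volume, so their pressures are algebraic. With
compliant vessels everywhere the node system is diagonal (each junction
sees only known midpoint pressures); rigid vessels (C₀ = 0) couple
junctions and trigger a sparse symmetric solve. Occlusion multiplies a
vessel's conductance by 10⁻¹² instead of deleting it, preserving the
state dimension across scenarios. The retroperfusion source is a
prescribed pressure node (mean + half-pulse·sin, at the heart period)
behind a short, low-resistance terminal line segment; when a scenario has
no source the line is held closed the same way as an occlusion.

Integration: `scipy.integrate.solve_ivp` BDF with rtol 10⁻⁷ and per-state
absolute tolerances of 10⁻⁹ × each reference volume (the volumes span
five orders of magnitude; a scalar atol would be meaningless at one end
or the other). The Jacobian sparsity pattern (vessel-adjacency plus dense
chamber rows/columns for the intramyocardial coupling) is supplied so the
stiff solver's finite-difference Jacobians stay cheap. The output grid is
2 ms by default. Diagnostics carried on every solution: the maximum
junction mass-balance residual, normalized by the local flow scale with a
floor at 10⁻³ of the network-wide maximum flow so that rounding dust at
stagnant nodes does not register; and the periodicity residual (relative
L2 distance between successive beats, which decays geometrically under
constant parameters).

Scenario solves cover 8 beats (10 for the baseline conservation check) —
enough for the periodicity residual to fall below ~10⁻² — and the final
beat is reused periodically for the 600 s tracking window.

## Indicator transport

Indicators move kinematically (no diffusion, no intra-vessel mixing) at
the plug rate ds/dt = Q/V along the fractional arc s of their vessel. At
a junction the next vessel is drawn with probability proportional to the
instantaneous outflow magnitudes — stochastic routing keeps indicators
integer and conservation exact. Entering a Thebesian shunt clears to the
chamber (`cleared_thebesian`); reaching the coronary sinus or any other
systemic boundary (arterial inlet, source line) clears systemically
(`cleared_sinus`); a stagnant junction adjacent to an occluded vessel
traps (`trapped_stump`); anything else remains `in_network`. Fates are
immutable and counts are conserved exactly at every step.

Two flow-field couplings are provided, since either reading is defensible
for a beat-periodic field: the default **steady** mode advects through
the beat-averaged flows with *exact event-driven transit* (no time step
at all — each vessel passage is resolved analytically), and the
**instantaneous** mode sub-steps through the time-resolved periodic field
(default step: period/120) resolving junction crossings *within* each
step, so no junction can be skipped at any step size. Steady mode is the
default for 10-minute windows; with the default (atrial) shunt chamber
the beat-averaged Thebesian flows are strictly positive in every
scenario, so averaging does not suppress the clearance route.

**Tracer-volume calibration.** Each equivalent vessel of the reduced
network stands for a bundle of real microvessels, so its bare lumen badly
underestimates the blood volume a metabolite sample occupies; taking the
lumen literally, the whole embedded micro region holds 2.4×10⁻³ mL and
any perfusion clears it within seconds. Advection therefore scales
microvascular volumes (|order| ≤ 6 and equivalent-network lumps) by
`MICRO_VOLUME_SCALE = 30`, calibrated from myocardial blood-volume
figures: it puts the embedded region at ~0.07 mL, i.e. ~1.1 mL across
the 16 parallel micro networks, matching ~3 mL/100 g over a ~40 g
LAD-analog territory. Hemodynamic states keep lumen volumes; the scale
affects transport timescales only.

Release defaults: bolus at t = 0, sites drawn volume-weighted among
ischemic-region vessels of orders {1, 0, −1}, position uniform along the
vessel; continuous release over a window is available. The ischemic
region is defined as the embedded micro network (all of it lies distal to
the occluded main artery).

## Comparison metrics and replicates

`washout_fraction_600s` is the cumulative `cleared_thebesian` fraction at
600 s. `retro_perfusion_fraction` releases tracer in the source line and
reports the fraction of ischemic-region capillaries entered by at least
one tracer; it is 0 by definition when the scenario prescribes no source.
Stochastic metrics are reported as mean ± SD over 5 seed replicates;
replicates redraw release and routing seeds over each scenario's single
deterministic flow solution (the hemodynamics has no stochastic element;
replicating the network seed as well is a config choice). All sub-seeds
derive from one base seed; identical configuration and seed give
byte-identical fate tables and reports.

Default problem sizes — 306 vessels, 8-beat solves at 2 ms output, 1,000
indicators × 5 replicates per scenario — were chosen so the full
four-scenario comparison completes in roughly a minute while leaving the
directional contrasts many standard errors wide.

## What the defaults show, and what they cannot

On the default network the model produces the expected structural
signatures: occluded-vessel flows fall by ~10 orders of magnitude;
proximal GCV flow reverses sign under balloon-occluded retroperfusion;
washout orders sarp_b ≥ sarp_nb > occlusion_only with a sarp_b −
occlusion_only separation of ~0.6–0.7 far exceeding replicate noise; and
source tracer reaches ischemic capillaries only under SARP. These are
consequences of network structure and boundary conditions, and they are
the package's acceptance properties.

Limitations worth keeping in view: the morphometry is a synthetic
surrogate, not swine data, so absolute flows (e.g. coronary inflow
~0.01 mL/s at this reduced scale) are not physiological even though
pressures and timescales are; metabolite transport is purely convective,
with no interstitial exchange, diffusion, or consumption; the GCV
pressure during retroperfusion is an input, so the model cannot predict
retroperfusion pressure–flow relationships; and "washout" here is
counted only through the Thebesian route — systemic clearance through
the sinus is reported separately, not merged.
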