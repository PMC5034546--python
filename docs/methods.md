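# Model and methods

`halfsarc` simulates an ensemble of myosin motors in a half-sarcomere with
rigid filaments, comparing two wirings of the same five-state cross-bridge
cycle: a **conventional** model in which the availability of detached
motors is regulated by thin-filament nearest-neighbour cooperativity, and a
**mechanosensing (MS)** model in which it is regulated by the tension borne
by the thick filament. The simulated preparation is a frog fibre at low
temperature (isometric tetanus tension rise, recovery after unloaded
shortening, force–velocity behaviour, ATP turnover).

## States and geometry

Each of `N_fil` thick/thin filament couples carries `n_xb = 76` myosin
heads. A head is in one of five states:

* **OFF** — packed on the thick-filament backbone (super-relaxed),
  cannot attach, negligible ATPase;
* **ON** — detached but available for actin binding
  (disordered-relaxed / weakly attached);
* **S0, S1, S2** — strongly attached, in the pre-power-stroke well or
  after the first or second power-stroke step.

Crowns sit every 14.3 nm on the 825 − 50 nm functional span of the thick
half-filament, giving the familiar 54 molecules per half filament; in the
3-D lattice each thin filament is reached by 54·3/6 = 27 molecules, and the
2-D per-actin head count is deliberately raised to 76 to account for
contributions from neighbouring heads. Extra heads beyond the 54 crowns are
interleaved at half-spacing so anchor positions remain strictly increasing.

All thin filaments share one sliding coordinate `z` through the Z-line
(`z = 0` at optimal length; shortening decreases `z`). Filaments are rigid,
so an attached head's elastic extension is affine in `z`: `x = C + z`, with
the constant `C` set at attachment and shifted by ±`d` per power-stroke
hop. The motor force is `kappa_m x` with `kappa_m = 2 pN/nm`. A release
(`dz < 0`) therefore drops every attached strain — the classic T1
response — and a forward stroke re-stretches the head by `d` — the
Huxley–Simmons tension recovery. (Note the attached-state landscape below
is written in the stroke coordinate, which runs opposite to the extension:
a forward hop moves *down* the landscape and *up* in extension.)

## Attached-state energy landscape

The strongly attached head lives on a three-well landscape: a sinusoid of
amplitude `H = 5.8 KT` tilted by `F_atp = 8 KT / d`, so consecutive minima
drop by exactly 8 KT — two steps of the power stroke, 16 of the 20 KT of
one ATP (85 pN nm with `KT = 4.25 pN nm`; the remainder is budgeted to the
attachment bias). Wells are rendered as parabolas of stiffness
`kappa_well = 48 pN/nm`; the convex humps between them are C1 cubic
connectors through the saddle position and height derived from the tilted
sinusoid (forward barrier 7.88 KT, saddle at 0.43 d from the minimum). The
phase constant shifts the first minimum to the extension at attachment,
`x0`.

Because `kappa_well >> kappa_m`, the conformational coordinate is
adiabatically pinned at well bottoms and the continuous landscape reduces
to a three-state hopping process with Kramers rates

    r = nu_attempt * exp(-dE_barrier / KT),

where the barrier is measured on the *total* energy (landscape plus
`kappa_m x^2 / 2`). Forward/backward pairs satisfy detailed balance
exactly; a strain-erased barrier caps the rate at `nu_attempt`. Both
power-stroke steps are equal by construction; reverse hops are allowed.

`nu_attempt` is set to `1e7 /s`, the order of magnitude of the Kramers
prefactor for a 48 pN/nm well with the viscous drag of a myosin head
(`sqrt(kappa_well * kappa_saddle) / (2 pi gamma_drag)` with
`gamma_drag ~ 1e-7 pN s/nm`). This makes the phase-2 stroke response after
a release sub-millisecond, as observed; see "Numerics" for how the sampler
accommodates rates this fast.

## Attachment and detachment (H57 kinetics)

Only ON heads attach, only into the pre-stroke well, and only when
stretched: the hazard is `f1 * x` on the window `(0, x_lim]` and zero
outside (the classic convention for the upper cutoff). The extension at
attachment is the candidate-site offset plus a uniform jitter in
[−2.5, +2.5] nm representing the actin diameter. Detachment from any
attached well has hazard `g1 * x` for `x > 0` and the large constant `g2`
for `x <= 0` (boundary on the fast branch); if `|x|` exceeds 20 nm the head
is mechanically dislodged. Every detachment — ordinary or dislodged, from
any attached state including pre-stroke — consumes one ATP.

Candidate binding sites are modelled as a periodic offset per head: a fixed
phase `phi_i` in `[0, site_period)` drawn once at lattice construction,
wrapped with sliding (`c_i = (phi_i + z) mod site_period`). The default
`site_period = 11 nm` lies between the actin monomer spacing and the
helical repeat; together with `x_lim = 9 nm` it sets the fraction of heads
with an eligible site at any instant (~0.8), one of the levers that places
the plateau attached fraction at ~1/3.

## The OFF/ON gate

Conventional wiring: `k01 = k01_0 * gamma^n`, `k10 = k10_0 * gamma^-n`,
with `n` the number of axially adjacent crowns (same filament) that are
weakly or strongly attached (ON or any S state); boundary heads have one
neighbour. Detachment returns heads to OFF.

MS wiring: `k01 = k01_0 * ON_f(T)` with

    ON_f(T) = m + (1 - m) exp(-t_f / T_rel^2),

`T_rel` the instantaneous per-filament tension over the calibrated plateau
tension `T0`, clamped at zero from below; `k10 = k10_0` constant;
detachment returns heads to ON. `ON_f` rises from the floor `m` at zero
tension and saturates above roughly `0.5 T0`. The feedback tension is
per-filament by default; the ensemble-mean alternative is available as a
switch but produces a collective nucleation (a long dead time followed by
an explosive rise) unlike the observed transients. `t_f = 0` is a sentinel
that forces `ON_f = 1`; with `gamma = 1` and the detachment destination
aligned, the two wirings then run bit-identically through the shared
kernel — a tested invariant.

Thin-filament activation is saturating: attachment is scaled by a linear
calcium ramp over the first millisecond of an activation and is off in the
relaxed protocol. An activation starts from the resting gate equilibrium
(each head ON with the analytic probability
`m k01_0 / (m k01_0 + k10_0) ~ 5%` — "almost all" OFF), not from strictly
all-OFF: that 5% seed is what produces the ~15 ms activation delay with a
gate this slow.

## Boundary conditions

*Length control* holds `z` after applying an optional instantaneous step.
*Load control* solves the rigid, massless force balance every step:
`z = T_total/(n_att kappa_m) − mean(C)` over attached heads; with no
attached heads and a nonzero target a starvation flag is raised.
Zero-tension shortening is load control with target 0. Dislodging is
enforced after every `z` update, so `|x| <= 20 nm` holds at every step end.

## Numerics

Fixed time step `dt = 2 µs`. Per motor and step, one transition is sampled
with probability `1 − exp(−k_total dt)` and the destination drawn
proportionally to the individual hazards — the embedded jump chain of the
continuous-time process. For the slow channels (gate, attachment,
detachment) a startup validation requires worst-case `k dt < 0.1`. Well
hops are physically much faster and may saturate toward probability one
within a step; the embedded-chain sampler handles one fast channel per
step exactly, and the error of missing a second transition in the same
step is of order (slow rate)·dt ~ 1e-3 and merely delays a hop cascade by
one 2 µs step. The alternative — capping `nu_attempt` at `0.1/dt` — was
measured to distort the physics qualitatively (phase-2 recovery stretched
from ~0.1 ms to tens of ms, halving the peak efficiency), which is why the
blanket validation is narrowed to the slow channels.

Randomness is an explicit xoshiro256** stream seeded through splitmix64;
runs are bit-reproducible from `(parameters, protocol, seed)`. Both
wirings execute the same kernel and consume the same number of draws per
step. Recording cadence is 0.2 ms.

## Calibration

Supplementary numeric values for the gate, the H57 slopes and the attempt
frequency are not tabulated anywhere usable, so they are recovered against
the stated constraints: resting ON fraction 5 ± 1% (enforced analytically
through `k10_0 = 19 m k01_0`), plateau attached fraction 1/3 ± 5 pp,
activation `tau_R ~ 34 ms` (delayed single-exponential fit), recruitment
saturating above `0.5 T0`, and an unloaded velocity comparable to frog
fibres (~2.75 nm/ms per half-sarcomere, i.e. 10% of fibre length in
40 ms). The recovery time constants after 20/40 ms of unloaded shortening,
the double-step behaviour and all energetics were *not* calibration
targets. `T0` is fixed self-consistently at the measured plateau.

The frozen reference files (in `halfsarc/data/`) are, for the MS model:
`k01_0 = 750 /s`, `k10_0 = 130 /s`, `m = 0.00912`, `t_f = 0.036`,
`f1 = 9 /(s nm)`, `g1 = 11 /(s nm)`, `g2 = 480 /s`, `x_lim = 9 nm`,
`T0 = 221 pN`; for the conventional model: `k01_0 = 18 /s`,
`k10_0 = 100 /s`, `gamma = 3.5`, `f1 = 7`, `g1 = 7`, `g2 = 480`,
`T0 = 213 pN`. Shared: `d = 5.5 nm` (11 nm total working stroke),
`nu_attempt = 1e7 /s`, geometry and stiffnesses as above. They were found
by constrained search over short common-random-number runs (the
`calibration` module's measurement operations) and verified at
`N_fil = 50` over five seeds. The `calibrate()` entry point automates the
same loop (Nelder–Mead in log space, CRN seeds, self-consistent `T0`).

With these sets (N_fil = 50, five+ seeds): MS `tau_R = 34.8 ms`, delay
14.3 ms, `tau_20 ~ 20-21 ms`, `tau_40 ~ 31-33 ms` (ordering
`tau_20 < tau_40 < tau_R`), attached fraction 0.30, isometric ATP
16.3 /myosin/s, `V0 = 3.7 nm/ms`; conventional `tau_R = 36 ms`,
`tau_20 ~ tau_40 ~ 16 ms` (indistinguishable — no tension feedback, the
deliberate failure mode), ATP 10.0 /myosin/s.

## What the synthetic data does and does not emulate

The `fixtures` module generates delayed-exponential tension traces with
Gaussian noise (known tau/delay/plateau) for fit validation, and 1–3-motor
ensembles for hand-checkable force balance and ATP accounting. The noise
model is white; real tension transducers have coloured noise and baseline
drift, so fit-bias results on fixtures bound only the statistical, not the
instrumental, error. Micro-ensembles exercise bookkeeping, not collective
behaviour.

## Known limitations

* **Recovery-constant placement.** The fitted recovery constants sit at
  ~20 ms (20 ms release) and ~32 ms (40 ms release) against the
  experimental 24/28 ms: the model's OFF/ON warmth gradient, which is what
  makes the ordering possible at all, spreads the two recoveries further
  apart than observed. Compressing the gap (faster `k10_0`, larger floor
  `m` under the 5%-rest tie) inverts the ordering instead.
* **Double-step (conditioning/test) ordering.** The recovered tension
  after the test step is essentially delay-independent here
  (~0.25–0.28 T0 at 2–14 ms): with two stroke steps, ±2.5 nm attachment
  jitter and sub-millisecond hops, the attached ensemble never exhausts
  its stroke capacity after a 5 + 2 nm release sequence, so the
  regeneration signature does not emerge.
* **Efficiency peak location.** Maximum efficiency (0.77 MS, 0.82
  conventional, both above the experimental 0.45–0.56 floor) falls at
  ~0.25 V0 (MS) vs ~0.29 V0 (conventional); the expected rightward shift
  of the MS peak is not resolved at these ensemble sizes.
* Rigid filaments, single-headed motors, equal stroke steps, no
  calcium-activation kinetics beyond the 1 ms ramp, no overlap change with
  the ≤10% length excursions of the protocols — all deliberate scope
  limits of the model.
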