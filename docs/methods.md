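# Methods

## Scope and model structure

`opkin` models the aqueous chemistry of online aerosol oxidative-potential
assays as a deterministic mass-action reaction network.  Air-side inputs
(component mass concentrations in µg m⁻³, sampling flow, collection
efficiency, liquid wash flow) are converted to liquid-phase molar initial
conditions once, at scenario compilation; everything downstream is a stiff
ODE system in mol L⁻¹.  The assay protocol is two stages — 600 s at pH 6.8
(the reaction bath) and 120 s at pH 2 (the derivatization step) — with pH
entering through a clamped H⁺ species that jumps at the stage boundary.
Readouts use the 600 s window: the derivatization stage is simulated for
protocol fidelity, but instrument DHA quantification reflects oxidation
during the reaction bath, and at pH 2 ascorbate is protonated to the
unreactive AH₂ form (pKa 4.1 equilibrium included), which shuts the
DHA-forming channels down.

Assumptions worth stating plainly:

* **Mass action with integer stoichiometry.**  Fractional yields are
  expressed as parallel reaction channels (e.g. the 2% H₂O₂-releasing
  branch of the Cu(II) catalytic turnover).
* **Clamping instead of acid–base/oxygen dynamics.**  H⁺ is clamped per
  stage (the 10 mM HEPES buffer justifies a fixed pH without simulating
  stiff proton transfer); dissolved O₂ is clamped at air saturation
  (2.5×10⁻⁴ M).  The format supports explicit buffer reactions, but the
  shipped mechanisms clamp.
* **Room-temperature rate constants.**  Constants are used at their
  literature temperature even though the bath runs at 37 °C; an optional
  per-reaction `temperature_scale` multiplier exists and defaults to 1.
* **Catalytic direct oxidation.**  Fe(III) and Cu(II) oxidize ascorbate
  catalytically (metal regenerated, O₂ the implicit co-oxidant, DHA the
  product), not as a stoichiometric redox pair — the behaviour that
  predicts DHA formation well in this assay family.

## Numerical treatment

Integration uses an implicit Radau IIA method (adaptive, stiff-capable)
stage by stage; the step controller restarts at the known stage boundary,
so no event detection is needed.  Defaults: `rel_tol` 10⁻⁶, `abs_tol`
10⁻¹² M — the absolute tolerance sits far below meaningful radical
concentrations so radical chains are resolved; tightening both by 10×
moves OP_AA by far less than 0.1%.

Per-reaction cumulative extents are integrated as additional state
variables (one per reaction) rather than recovered by quadrature of saved
fluxes: attribution must close the DHA balance exactly, and adaptive output
grids make post-hoc quadrature lossy.

Fluxes are evaluated at the raw state, without clipping negative values.
Quasi-steady radicals (free •OH sits near 10⁻¹⁶ M, far below `abs_tol`)
can make tiny negative excursions; un-clipped mass action gives those
excursions a stiff restoring force (negative concentration ⇒ negative
consumption flux), so they self-correct.  Clipping inside the right-hand
side removes that force and can park a radical at a negative value.
On output, concentrations in [−10·abs_tol, 0) are clipped to zero; anything
more negative raises an error carrying the failing time and stage — the 10×
headroom distinguishes legitimate local solver error from mechanism bugs.

A fixed-step classical Runge–Kutta integrator (`oracle_integrate`) serves
as an independent cross-check on non-stiff toy networks (agreement within
relative 10⁻⁴ in the test suite); it detects divergence and advises a
smaller step.  It is a validation oracle only, never the production path.

## The shipped mechanism and its constants

Literature-printed constants (fixed): k(Fe²⁺+H₂O₂) = 55,
k(Cu²⁺+H₂O₂) = 480, k(AH⁻+H₂O₂) = 1.6×10², k(AH⁻+•OH) = 7.9×10⁹,
k(AH⁻/AA+RO) = 1×10⁴ (all L mol⁻¹ s⁻¹), ROOH homolysis 0.0015 s⁻¹, and the
optional Fe(II)+peracid/hydroperoxide channels at 5×10⁴ and 4×10⁴.

Choices the package makes where the literature gives a range or the
predecessor model's table is not reproduced here:

* **Direct catalytic constants** k(Fe(III)+AH⁻) = 22 and
  k(Cu(II)+AH⁻) = 52 L mol⁻¹ s⁻¹ (the Cu constant must exceed the Fe one).
  These were calibrated once, analytically, so that metal-only runs
  reproduce the predecessor model's reported behaviour: ~99% (Cu) and ~92%
  (Fe) direct-channel attribution with ~11% through •OH for iron, and a
  Cu:Fe per-mass OP_AA ratio of ≈2.4.
* **Channel taxonomy.**  The hydroxyl pie slice groups the whole H₂O₂/•OH
  oxidation system: AH⁻ + H₂O₂ is modelled one-electron
  (→ A•⁻ + •OH + OH⁻) and tagged `OH`, as is AH⁻ + •OH.  At 200 µM
  ascorbate the AH⁻+H₂O₂ path (0.032 s⁻¹ pseudo-first-order) outcompetes
  Fenton chemistry (55·[Fe²⁺] ≈ 10⁻⁴ s⁻¹ at µM iron) for H₂O₂, so any
  hydroxyl-channel contribution at these conditions necessarily flows
  through that reaction; tagging it `OH` is the taxonomy consistent with
  an ~11% OH share for iron.  Channel tags are plain strings on reactions
  and fully overridable.
* **Iron oxidation** Fe²⁺ + O₂ → Fe³⁺ + HO₂ at an effective 0.01 s⁻¹
  (k = 40 with clamped O₂) — an autoxidation rate representative of the
  near-neutral, ROS-assisted conditions of the bath.  The superoxide/H₂O₂
  released by this stoichiometric oxidation is what feeds the iron OH
  channel; Cu(II) needs no oxidation step, which is why its pie is almost
  purely direct.  Superoxide dismutates (2 HO₂ → H₂O₂ + O₂, 8.3×10⁵);
  the superoxide–ascorbate reaction is deliberately omitted from the
  reduced mechanism (see Limitations).
* **HEPES scavenging** k(HEPES+•OH) = 2.2×10⁹ at 10 mM sets the free-OH →
  ascorbate yield at ≈6.7%.  This single constant makes the BSOA preset
  land at 0.075 nmol DHA/µg against the measured 0.08 ± 0.02 using only
  the stated ROOH yield (80%), molar mass (205 g mol⁻¹) and homolysis rate.
* **Alkoxyl radicals** are lost to H-abstraction/β-scission at 10³ s⁻¹,
  so only ≈0.2% reach ascorbate (k = 10⁴ × 2×10⁻⁴ M = 2 s⁻¹) — RO forms in
  equal amounts to •OH but contributes a few percent of DHA at most.
* **Naphthoquinones**: one-electron oxidation of AH⁻ by 1,2-NQN (k = 10³)
  and 1,4-NQN (k = 3×10²), fast semiquinone disproportionation (10⁸)
  and slow hydroquinone autoxidation (k = 1, i.e. 2.5×10⁻⁴ s⁻¹ at air
  saturation).  Each quinone molecule therefore performs ≈2 ascorbate
  oxidations inside the window, so the isomer split follows the mole
  yields.  NSOA mass yields default to 3.6% (1,2-NQN) and 0.4% (1,4-NQN):
  total 4% sits in the reported quinone-yield range for naphthalene
  photooxidation, the 9:1 mole ratio carries the ~90/~10 isomer
  attribution split, and the total reproduces NSOA OP_AA ≈ 0.28 nmol/µg.
* **Fe–HULIS complexation** (30% HULIS mass fraction of NSOA, 250 g mol⁻¹):
  Fe²⁺ binds HULIS (10⁶); the complex oxidizes ten times faster than free
  iron (k = 400 with clamped O₂, complexation-enhanced autoxidation),
  carries enhanced Fenton chemistry (k = 300 > 55), keeps the direct
  catalytic channel in its +3 state, and is re-reduced by a stoichiometric
  pool of HULIS reducing moieties (one equivalent per HULIS, k = 10³).
  The complex thus pumps superoxide/H₂O₂ until the reducing pool is spent,
  roughly doubling the hydroxyl share of DHA formation in NSOA + Fe(II)
  mixtures (≈10% → ≈19%) and making the mixture synergistic (≈ +24%
  against the same amounts run separately) — without the sustained cycling,
  rerouting H₂O₂ through Fenton chemistry would *lower* the OH share,
  because free •OH is mostly scavenged by HEPES.
* **TA probe**: k(TA+•OH) = 4.4×10⁹ with a 35% hTA branching ratio,
  written as two parallel channels.
* **Metal mass basis**: nebulized masses are interpreted as sulfate-salt
  mass (FeSO₄/CuSO₄) by default; a `metal` basis switch exists because
  reported particle masses are ambiguous.  Fe(III) availability at pH 6.8
  can be scaled by `Fe3_solubility_factor` (a surrogate for Fe(OH)₂⁺
  insolubility; default 1, no speciation solve).
* **q_liquid** (wash flow) defaults to 1.0 mL min⁻¹; fractions and
  mass-normalized outputs are insensitive to it.

## Synthetic data

Two kinds of synthetic inputs stand in for instrument data, and the
scenario presets define the simulated study conditions:

* The eight presets place components at the experimental envelope
  midpoints — SOA 300 µg m⁻³ (envelope 245–408), metals 20 µg m⁻³ alone
  (envelope 5–35), mixtures at 10:1 SOA:Fe and 50:1 SOA:Cu mass ratios,
  200 µM ascorbate, 10 mM HEPES, 16 L min⁻¹ sampling.
* Calibration fixtures generate linear standard curves (declared slope and
  intercept per analyte) with seeded Gaussian noise.

What this emulates — and does not: the generator reproduces the *mean*
composition-to-concentration pathway of the instruments.  It does not
emulate instrument noise on the kinetics themselves, particle-to-particle
composition variability, wall losses, size-dependent collection
efficiency, or fluorescence artefacts (inner-filter effects, quantum
yields).  Passing tests therefore demonstrate that the chemistry module
turns stated compositions into the reported assay readouts, not that the
full instrument chain is modelled.

## Problem sizes

Shipped networks are small by design: ≤ ~35 species and ~25 reactions plus
one extent variable each, integrated over 720 s.  A preset run takes a
fraction of a second on one CPU; the full acceptance sweep (13 runs across
the concentration envelopes) and the test suite each complete in well under
a minute.

## Limitations

* The mechanism is a curated reduction, not the full assay mechanism:
  superoxide–ascorbate oxidation, metal–superoxide redox shuttling,
  Fe(III) reduction by ascorbate (the "redox" pathway), quinone–metal
  complexation and Cu–HULIS chemistry are omitted.  Consequences we know
  about: Fe(II)+BSOA mixtures come out mildly synergistic in the model
  (the Fe(II)+ROOH step accelerates Fe(III) formation) although
  measurements show suppression — the missing Fe–carboxylate complexation
  is the likely cause — and Cu-containing NSOA mixtures do not reproduce
  the measured OP_OH rank above Fe-containing ones.
* Attribution fractions inherit the channel taxonomy above; a different
  grouping of the H₂O₂/•OH system would shift the direct/OH split.
* H₂O₂ equivalents use declared response factors (all 1.0 by default), a
  deliberate accounting surrogate for peroxidase/fluorescein kinetics.
* No gas-phase photochemistry, SOA formation, gas–particle partitioning,
  transport, thermodynamic consistency checking or charge balance; metal
  speciation beyond the scalar availability factor is out of scope.
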