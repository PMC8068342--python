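# Methods

## Damage-induction model

A cluster is the set of elementary lesions produced by one track within a
short DNA segment, scored as a single damage site.  The generative law is
deliberately minimal:

* cluster count per exposure ~ Poisson(ρ · D · G), with ρ the cluster rate
  (clusters /Gy/Gbp), D the dose (Gy) and G the simulated genome (Gbp);
* lesions per cluster K = 1 + Poisson(ν) — every cluster carries at least
  one lesion, ν tunes damage complexity;
* lesion positions i.i.d. uniform integers on [0, nseg), strands fair-coin,
  kind = strand break with probability p, otherwise base damage.

Classification follows the conventional taxonomy.  Strand breaks are paired
greedily left-to-right, each unpaired break taking its nearest unpaired
opposite-strand partner within 10 bp (ties to the leftmost partner).  With
d pairs: d ≥ 2 → DSB⁺⁺; d = 1 → DSB⁺ if an unpaired break remains, else
DSB; d = 0 → 2SSB if both strands carry breaks, SSB⁺ if one strand carries
several, SSB for a single break; no breaks → BD; no lesions → discarded.
On every cluster of ≤ 5 breaks with positions in [0, 30) this greedy count
equals the exhaustive maximum matching (property-tested), so the pair count
is well defined.  Base damages never change a break-bearing class.  A BD
site is one *cluster* containing only base damage, not one base lesion; the
absolute BD calibration absorbs the difference from a per-lesion convention.

Yields are class counts divided by D·G (per Gy per Gbp) with Poisson
standard errors; per-cell values use 6 Gbp per mammalian cell.  In
fixed-count mode (N clusters exactly) the equivalent exposure N/ρ is
recorded on the population and used for normalisation.

## Calibration

Free parameters (ρ, ν, p, nseg) are fitted once to the published MCDS
62 MeV proton class yields under aerobic, scavenger-free conditions.  Since
every generated cluster is one damage site, ρ equals the total damage yield
(616.15 /Gy/Gbp).  For each candidate nseg in 16–30 bp, (ν, p) minimise
(Nelder-Mead in log space) the relative squared error on BD, total SSB,
total DSB and the DSB⁺ share of total DSB; the best segment length wins
(23 bp with the shipped geometry tables; ν ≈ 0.73, p ≈ 0.20).  The fit uses
a semi-analytic engine rather than nested simulation: thinning each lesion
with survival s makes the surviving-break count exactly
Bernoulli(p·s) + Poisson(ν·p·s) while surviving positions/strands stay
i.i.d. uniform, so expected class fractions are closed-form count
probabilities times per-break-count geometry tables (exact for ≤ 2 breaks,
fixed-seed 2×10⁵-sample tables for 3–9 breaks).  The Monte Carlo pipeline
samples exactly this law, so the fit transfers without bias; a verification
simulation (4×10⁵ clusters) must reproduce all four targets within the 3%
calibration tolerance or a `CalibrationError` with residuals is raised.

Residual structure: the three continuous degrees of freedom cannot match
every class simultaneously — with BD, total DSB and DSB⁺ share pinned, the
SSB⁺/2SSB split inside total SSB deviates from the published row (SSB⁺ high
by ~30%, 2SSB by ~3×) and DSB⁺⁺ is under-populated.  All acceptance
endpoints depend only on the pinned quantities.

## Modifiers

DMSO and oxygen act multiplicatively on the *lesion* level, before
classification, as independent Bernoulli survival ("thinning") factors:

* DMSO: s(c) = FNSD + (1 − FNSD)·CHMX/(CHMX + c), with the published
  presets (0.52, 0.21 M) for ⁶⁰Co γ-rays, (0.52, 0.07 M) for 62 MeV
  protons, (0.75, 0.14 M) for 3.31 MeV helium ions.
* Oxygen: h(x) = (m·x + K)/(x + K) normalised at 21% O₂.  m is fitted to
  the DSB-class OER endpoint (2.9 at 21% vs 0.001% O₂ for the low-LET
  qualities, 1.2 for helium) and K to the 0.1%-O₂ total-DSB yield
  (3.55 /Gy/Gbp); the fitted proton values are m ≈ 1.75, K ≈ 0.54% O₂.
  Above the reference tension the factor would exceed 1; the pipeline caps
  retention at 1 (damage saturates at ambient oxygen).

Lesion-level action is the essential modelling choice: one survival factor
then yields the observed pattern of small BD/SSB reductions together with
roughly squared DSB reductions, because a surviving DSB needs two
surviving breaks.  A literal reading of CHMX as the concentration that
halves *DSB* yields is inconsistent with the published retentions (54% at
0.28 M, 53% at 0.1 M proton); the lesion-level hyperbola reproduces them.
Two caveats are accepted as model error: (i) the combined DMSO×O₂ factor is
exactly multiplicative here, while the published combined rows are only
multiplicative to within a few percent — no interaction term is
implemented; (ii) BD-class reductions are under-predicted (≈12% vs the
printed 19% at 0.1 M DMSO) because thinning migrates break-bearing clusters
into the BD class, partially refilling it.  Neither affects the DSB-class
endpoints.

Cluster identity is fixed at generation: a thinned cluster is never split,
so a surviving opposite-strand pair > 10 bp apart remains one 2SSB site.

## Gamma reference and helium

The γ-ray absolute yields are not published.  Both the γ spectrum
(2.4 keV/µm) and the 62 MeV proton beam (1.051 keV/µm) are low-LET, so the
γ reference reuses the proton baseline damage spectrum with the γ scavenger
preset; zero-DMSO RBE is then 1 by construction and the RBE-vs-DMSO curve
tests purely the CHMX differential.  Helium absolute yields are likewise
unpublished: the helium quality keeps the calibrated segment length, uses
ν = 3.0 and p = 0.30 — a high-LET shape choice giving a complex-DSB share
(DSB⁺+DSB⁺⁺ of total DSB) of ≈ 51%, versus ≈ 13% for the proton baseline —
and scales its cluster rate so the zero-DMSO DSB-class RBE equals the 2.9
anchor.  The 2 M helium RBE endpoint is therefore the least-constrained
prediction.  For photon work the dose-weighted spectral average over a
secondary-electron fluence spectrum is provided (trapezoidal quadrature,
log-log LET interpolation, linear yield interpolation); the single-quality
γ reference remains the default since no measured spectrum ships with the
package — the synthetic log-normal spectrum in `fixtures` exists for
testing the quadrature, not as physics.

## Repair model

Non-DSB clusters enter excision repair; DSB-class sites are rejected (their
repair is different machinery and out of scope).  Lesions are processed in
a uniformly random order.  Strand breaks are end-processed and religated;
until religated they are open discontinuities.  A base damage is excised
(opening a point discontinuity at its position) and resynthesised with a
patch extending toward higher positions: 1 nt (SP BER), uniform 2–10 nt
(LP BER) or uniform 24–32 nt (NER); hybrid pathways route each base damage
to NER with probability p_ner = 0.5, else to their BER mode.  If an
excision opens opposite an un-religated break within 10 bp (the DSB pairing
distance, reused as the conversion distance), the outcome is a
repair-induced DSB and processing stops; such sites are tallied separately
and excluded from mutation frequency.  Each still-unrepaired base damage on
the template strand inside a patch is bypassed, inserting an incorrect base
with probability q_bypass; at least one incorrect insertion anywhere in the
cluster's repair history (and no DSB conversion) scores the cluster as a
point mutation.

Because a substitution requires an excised base damage *and* a second
surviving template base damage, mutation probabilities per cluster are of
order 10⁻⁵ and naive outcome sampling would need ~10⁹ clusters per
condition.  `mutation_frequency` therefore defaults to a Rao-Blackwellised
estimator: for each cluster the *exact* mutation probability is computed by
enumerating processing orders (exhaustive to 6 lesions, deterministic
240-order subsample above) and averaging patch lengths, routing and bypass
errors in closed form — DSB conversion depends only on the order, and the
no-substitution probability factorises over excisions as
E[(1−q)^m(L)] — then the population mean is taken (per-cluster results are
cached by lesion signature).  The only remaining error is population
sampling, reported as sqrt(Σp²)·scale.  A per-history sampler
(`repair_cluster`, `method="sample"`) implements the identical dynamics and
is tested against the enumeration on small clusters.

q_bypass is a calibration constant: mutation frequency is linear in q at
this scale, and q = 1.67×10⁻⁴ centres the four aerobic proton pathway
frequencies (geometric mean) on the published 0.008–0.065 per Gy per cell
band; the model's SP-to-NER/LP spread (≈8.6×) then nearly matches the
published ≈8.1×.  All DMSO-response conclusions are ratios and do not
depend on this absolute scale.  Mutation frequency is reported per Gy per
cell via the 6 Gbp/cell factor; the per-Gbp value is value/6.

## Numerics and reproducibility

All randomness flows from one root generator; pipelines spawn per-stage
child streams and record them in run metadata.  Thinning can take a shared
per-lesion uniform array, coupling survival levels so survivor sets are
nested — sweep curves are then monotone by construction and ratio endpoints
(RBE, OER) benefit from strongly correlated numerators and denominators.
Classification runs in a numba-compiled flat kernel (pure-Python fallback)
at ~10⁷ clusters/s; 2×10⁶ clusters per condition keep the total-DSB Monte
Carlo SE below 1% (the error-control contract), and the acceptance script
uses that size per condition with 1.5×10⁵ clusters for repair endpoints
(~2% SE via the exact estimator), finishing in about a minute.

Degenerate inputs: zero-multiplicity qualities produce only BD/SSB sites;
empty cluster collections tally to zero yields; survival outside [0, 1],
non-positive rates/doses, out-of-range oxygen, unsorted clusters and
DSB-class repair inputs raise typed errors.

## Known limitations

No spatial genome coordinates beyond within-cluster offsets, no chromatin
structure, no track structure, no dose-rate effects, no DSB repair
(NHEJ/HR), no enzyme kinetics or repair timing, no scavenger chemistry or
DMSO–hypoxia interaction term, no cell-survival endpoint.  The synthetic
spectrum is a test fixture, not a measured electron spectrum.  Passing
tests demonstrate internal consistency with the published simulation
anchors, not agreement with wet-lab measurements.
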