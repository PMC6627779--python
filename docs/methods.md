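# Methods

## Signal model and corrections

All steady-state analyses operate on the fluorescence intensity at a single
analysis wavelength (for tryptophan work typically 340 nm; an optional
±window mean is available on `EmissionSpectrum.intensity_at`). When
excitation/emission absorbances accompany a titration, the inner-filter
correction F_corr = F_obs·10^((A_ex+A_em)/2) is applied once at load time,
before any fit, and the series records that it happened; without absorbance
columns the intensities are taken as already corrected. Quench percentages
ΔF = |F−F₀|/F₀·100 are computed from the corrected intensities — the
convention this package fixes, since corrected and raw intensities give
slightly different ΔF scales.

Dilution by titration aliquots is *not* corrected by default (small-aliquot
titrations conventionally neglect it); an opt-in switch rescales intensities
by (V₀+v_added)/V₀ from a cumulative added-volume column.

Internal units are mol/L, K, cm and ns everywhere; CSV dialects (µM, nM, …)
convert at the boundary. Concentrations from absorbance use Beer–Lambert
c = A/(ε·l) with the user's extinction coefficient (e.g. 16 500 M⁻¹cm⁻¹ at
345 nm for piperine, 38 915 M⁻¹cm⁻¹ at 280 nm for rat serum albumin).

## Linear quenching fits

**Stern–Volmer.** F₀/F is regressed on total quencher concentration by
unweighted OLS. The intercept is fitted, not pinned to 1; its deviation from
unity is a linearity diagnostic. F₀ is the intensity at the ligand-free
point, which the series must contain.

**Double-log.** log₁₀((F₀−F)/F) is regressed on
log₁₀([L]tot − ((F₀−F)/F_denom)·[P]tot); the slope is the apparent site
number n and the intercept n·log₁₀(K_a). The bracket's denominator is F by
default, with a `bracket_denominator="F0"` switch for the common variant —
the two differ only when depletion is appreciable. Points with F ≥ F₀
(enhancement/noise) or a non-positive bracket are dropped with a warning; at
least three usable points are required. Logs here are base-10; the Van't
Hoff analysis uses natural logs.

**Mechanism classification.** Static quenching requires K_SV strictly
decreasing with temperature and, when τ₀/τ ratios are supplied, their mean
absolute deviation from unity below `ratio_threshold` (default 0.05 — "close
to unity" made concrete). Increasing K_SV with deviating ratios (or no
ratios) is dynamic; everything else, including a single temperature with no
lifetime data, is indeterminate.

## IDF / Scatchard analysis

Each titration becomes a **quench curve**: a monotone shape-preserving
piecewise-cubic (PCHIP) interpolant of [L]tot as a function of ΔF. No
parametric sigmoid is imposed — the IDF method's point is model
independence. ΔF must be non-decreasing within a noise tolerance (default 2
percentage points; larger reversals are an error); ties and small inversions
are merged by averaging neighbouring knots so the inverse map is
single-valued.

**Level grid.** Unless given explicitly, 10 ΔF levels span the intersection
of all curves' ΔF ranges, trimmed by 5% of the span at each end (both
configurable). How many sections the original graphical procedure used is
not recorded; 10 balances information content against noise amplification at
the range ends.

**Extraction.** At each level, [L]tot read off every curve is regressed on
[P]tot by unweighted OLS: slope = Σν, intercept = [L]free, with standard
errors kept per level. Levels with negative [L]free are unphysical and
excluded with a warning rather than clamped (clamping would bias the
Scatchard fit).

**Scatchard.** Σν/[L]free on Σν by OLS: K_b = −slope, n = intercept/K_b.
r² ≥ 0.95 (configurable) flags the single-class linear, non-cooperative
regime. Additionally, points whose Σν or [L]free lie below 2× their own
standard error from the level regression are screened out before fitting:
at the low-ΔF end these quantities are statistically indistinguishable from
zero while Σν/[L]free carries maximal leverage, and keeping them lets a few
noisy levels dominate the line. If fewer than three points survive, the
screen is dropped and all positive-[L]free points are used; `significance=0`
disables it entirely. A non-negative fitted slope raises "no saturable
binding detected".

## Thermodynamics

ln K_a against 1/T by OLS gives ΔH = −R·slope and ΔS = R·intercept with
R = 8.314 J/(mol·K); ΔG = ΔH − T·ΔS per temperature, with ΔG's standard
error propagated from ΔH and ΔS treated as independent. The linear form
assumes ΔCp = 0 over the (narrow) experimental range; no curvature extension
is provided. Docking scores in kcal/mol convert via K_b = exp(−ΔG/(R·T))
with R = 1.987×10⁻³ kcal/(mol·K) and a default of 300 K, the conventional
simulation thermostat temperature for such scores.

Force classification follows the standard sign rules: ΔH<0 with ΔS<0, or a
dominant negative ΔH, indicates hydrogen bonding / van der Waals contacts;
ΔH>0 with ΔS>0 hydrophobic burial; ΔH<0 with dominant positive T·ΔS
electrostatics.

## TCSPC lifetimes

Decays are fitted from the peak channel onward (tail fit). No instrument
response deconvolution is attempted — with sub-nanosecond IRFs and
nanosecond lifetimes the tail fit is adequate, and no IRF is part of the
data model. The model is b + Σ αᵢ·e^(−t/τᵢ) (constant baseline fitted by
default), minimized with Poisson weights 1/√max(counts, 1) by bounded
nonlinear least squares. Initialization is a deterministic multi-start:
lifetimes log-spaced between the bin width and half the fitted time range,
five sliding windows, best reduced χ² wins; no RNG is involved in fitting.
Components are reported sorted by lifetime with amplitudes normalized to
sum 1. τ_avg = Σ αᵢτᵢ²/Σ αᵢτᵢ generalizes the two-component
intensity-weighted formula to 1–3 components. One to three components are
supported; the default of 2 is the usual choice for single-tryptophan
proteins.

## Synthetic data

The titration generator draws from the n-site identical-independent-site
model. Free ligand comes from the exact mass balance — substituting
Σν = n·K_b·L_f/(1+K_b·L_f) into [L]tot = L_f + Σν·[P]tot gives

    K_b·L_f² + (1 + K_b·(n·[P]tot − [L]tot))·L_f − [L]tot = 0,

solved by the cancellation-free quadratic formula (the root is validated
against a bracketing root-finder in the tests). Signal transduction is
linear in fractional occupancy, F = F₀·(1 − q_max·Σν/n): the minimal
monotone, protein-concentration-independent choice the IDF construction
requires, under which n=1, q_max=1 reduces exactly to F₀/F = 1 + K_b·L_f.
Noise is multiplicative Gaussian on F with one RNG stream per protein
concentration derived from (seed, series index), so adding a series never
perturbs existing ones.

Defaults mirror the reference experimental design: protein at 2, 4 and 8 µM,
ligand 0–30 µM in 1 µM steps, 288 K, F₀ = 100. q_max defaults to 0.8 — the
saturation quench depth is not documented for the reference system, and 0.8
is typical of strong tryptophan quenching while keeping F bounded away from
zero. Ka-by-temperature series come from the exact Van't Hoff forward model
`ka_at_temperature`; decays from the multiexponential model scaled to a
target peak count with Poisson sampling.

What the generator does **not** emulate: spectral shapes and shifts,
collisional-quenching kinetics, inner-filter effects (simulated intensities
are "already corrected"), detector dead time and IRF convolution, pipetting
(dilution) errors, or baseline drift. Recovery tests therefore demonstrate
correctness of the inference chain under the stated model, not robustness to
every artefact of real instruments.

## Validation problem sizes

The recovery studies run at the study design above: noiseless recovery of
(n = 3, K_b = 7×10⁴ M⁻¹) through the full IDF pipeline; 100 seeded
replicates at 1% intensity noise for the stochastic medians (a few percent
of replicates legitimately fail with "no saturable binding" under noise and
are excluded from the medians); 1000 randomized mass-balance cases against
the bracketing oracle; 50 Poisson replicates at 10⁴ peak counts for the
lifetime medians. These sizes make the full suite run in seconds while
leaving the medians stable.

## Pipeline and reports

`run_pipeline` executes only the stages whose inputs are present; a stage
failure is recorded in `report.errors` and halts only its dependents. The
report is a pydantic model with a units table covering every numeric field,
serialized as sorted-key JSON; re-running on identical inputs is
byte-identical after stripping the timestamp. The JSON schema is available
from `quenchbind.report_schema()`.

## Known limitations

- Single-class sites only: no Hill/cooperative or multi-class Scatchard
  decomposition (the linear Scatchard regime is a prerequisite, and the
  r² flag reports when it fails).
- No global multi-temperature or linked-lifetime fits; each dataset is
  fitted independently.
- The double-log n and the IDF site count answer different questions
  (apparent reaction order vs. saturation stoichiometry) and are reported
  side by side without reconciliation.
- CD secondary-structure deconvolution is out of scope; only the
  mean-residue-ellipticity conversion is provided (with n = residue count,
  584 for rat serum albumin, rather than peptide-bond count).
- No vendor binary formats; CSV/JSON only.
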