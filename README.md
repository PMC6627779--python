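# quenchbind

Quantitative analysis of protein–ligand binding from fluorescence quenching
titrations, built around the rat-serum-albumin/piperine system but applicable
to any single-tryptophan (or single-reporter) protein titrated with a
quenching ligand.

When a ligand binds near a protein's intrinsic fluorophore, the emission
intensity F drops as the titration proceeds. `quenchbind` turns those
intensities into binding parameters through the standard ladder of analyses:

- **Stern–Volmer**: F₀/F = 1 + K_SV·[Q]. The temperature dependence of K_SV
  separates static quenching (ground-state complex; K_SV falls with T,
  lifetimes unchanged, τ₀/τ ≈ 1) from dynamic quenching.
- **Double-log binding fit**:
  log₁₀((F₀−F)/F) = n·log₁₀(K_a) − n·log₁₀([Q] − ((F₀−F)/F)·[P]),
  giving the association constant K_a and apparent site number n.
- **Interaction density function (IDF) / Scatchard**: a model-independent
  route. Equal quench percentages ΔF = |F−F₀|/F₀·100 at several total
  protein concentrations imply equal binding density Σν and free ligand
  [L]free; mass conservation [L]tot = [L]free + Σν·[P]tot makes [L]tot
  linear in [P]tot at fixed ΔF (slope Σν, intercept [L]free). The Scatchard
  line Σν/[L]free = n·K_b − K_b·Σν then yields the true site count and
  binding constant, and its linearity diagnoses non-cooperativity.
- **Van't Hoff**: ln K_a = −ΔH/(R·T) + ΔS/R over temperatures, then
  ΔG = ΔH − T·ΔS, with a dominant-force classification
  (H-bond/van der Waals, hydrophobic, electrostatic).
- **TCSPC lifetimes**: multiexponential tail fits I(t) = Σ αᵢ·e^(−t/τᵢ) and
  the intensity-weighted τ_avg = Σ αᵢτᵢ²/Σ αᵢτᵢ for the τ₀/τ diagnostic.
- **Supporting conversions**: inner-filter correction
  F_corr = F_obs·10^((A_ex+A_em)/2), Beer–Lambert concentrations, mean
  residue ellipticity [θ] = θ/(10·[P]·l·n), and docking-score conversion
  K_b = e^(−ΔG/RT).

A seeded forward simulator (`quenchbind.simulate`) generates titrations from
an n-site identical-independent-site isotherm with exact mass conservation
and Poisson-noised decay traces, with full ground truth, so every stage has
parameter-recovery tests.

## Worked example

```python
import quenchbind as qb

# Van't Hoff analysis of per-temperature association constants (M^-1)
fit = qb.vant_hoff_fit([288, 298, 308], [3.90e4, 2.77e4, 2.06e4])
print(f"dH = {fit.delta_h/1e3:.2f} kJ/mol, dS = {fit.delta_s:.1f} J/(mol K)")
rec = qb.gibbs_free_energy(fit, 298.0)
print(f"dG(298 K) = {rec.delta_g/1e3:.2f} kJ/mol, T.dS = {rec.t_delta_s/1e3:.2f} kJ/mol")
print(qb.dominant_forces(fit.delta_h, fit.delta_s, 298.0))

# IDF/Scatchard on three simulated titrations ([P] = 2, 4, 8 uM)
series, truth = qb.simulate_titration(qb.SimConfig(noise_rel=0.0))
points, sc = qb.idf_pipeline(series)
print(f"K_b = {sc.k_b:.3g} M^-1, n = {sc.n_sites:.2f} ({sc.cooperativity_flag.value})")
```

prints

```
dH = -23.55 kJ/mol, dS = 6.1 J/(mol K)
dG(298 K) = -25.36 kJ/mol, T.dS = 1.82 kJ/mol
enthalpy-driven: hydrogen bond / van der Waals
K_b = 7.01e+04 M^-1, n = 3.00 (non_cooperative_linear)
```

— a spontaneous, enthalpy-dominated association (hydrogen bonds / van der
Waals contacts) and, from the model-independent route, three equivalent
independent sites with K_b ≈ 7×10⁴ M⁻¹ recovered from the simulated
titrations (true values: n = 3, K_b = 7×10⁴ M⁻¹).

## Command line

```bash
quenchbind simulate --out sim/                 # titration CSVs + ground_truth.json
quenchbind sv-fit sim/sim_P4e-06.csv
quenchbind idf --series sim/sim_P2e-06.csv --series sim/sim_P4e-06.csv --series sim/sim_P8e-06.csv
quenchbind vant-hoff ka_by_temperature.csv
quenchbind lifetime decay0.csv decay1.csv --components 2
quenchbind score2kb --dg-kcal -6.7 --temp 300
quenchbind run --config pipeline.yaml --out results/
```

Every subcommand emits JSON. Titration CSVs carry `#`-prefixed header lines
(`protein_conc=…`, `temperature=…`, `units=uM|M`) above
`ligand_total,intensity[,a_ex,a_em]` columns; decay CSVs have
`time_ns,counts`.

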