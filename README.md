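# phoscycle

Steady states of phosphorylation–dephosphorylation cycles **with enzyme
sequestration**, and binomial phosphoform distributions for multisite
proteins.

A substrate `W` is phosphorylated by a kinase `K` and dephosphorylated by a
phosphatase `P` through Michaelis complexes:

```
W + K <=> WK -> Wp + K        (a1, d1, k1)
Wp + P <=> WpP -> W + P       (a2, d2, k2)
```

The classical Goldbeter–Koshland treatment drops the complexes `WK`/`WpP`,
which is only valid when both enzyme totals are far below the substrate
total. `phoscycle` solves the full system:

- **Closed-form steady state.** At steady state the catalytic fluxes balance
  (`k1·WK = k2·WpP`) and the system reduces to a cubic in the enzyme
  saturation variable, solved analytically (Cardano/trigonometric branches)
  with all six species reconstructed exactly. The cubic has exactly one root
  in its admissible interval for any positive parameters (the underlying
  balance function is strictly increasing).
- **Two independent oracles.** A bracketed Brent root on the monotone
  balance function and a stiff BDF ODE integration of the mass-action
  kinetics; the three routes agree to ~1e-10 (root) / 1e-6 (species) across
  thousands of random parameter sets.
- **Goldbeter–Koshland reference** (`gk_fraction`) plus a validity
  diagnostic, for quantifying when the complex-free approximation breaks.
- **Multisite phosphorylation.** For `n` independent identical sites the
  per-site probability `p` comes from the single-site solution with the
  substrate total rescaled to `n·W_T`; phosphoform classes are then
  binomial: `[m of n] = W_T·C(n,m)·p^m·(1-p)^(n-m)`. `effective_hill`
  measures switch steepness as `log 81 / log(EC90/EC10)`.
- **Michaelis-constant estimation** from measured steady-state species
  (`Km1 = W·(K_T-WK)/WK`, `Km2 = Wp·(P_T-WpP)/WpP`).
- **Bundled scenarios**: `stat3*` (single site, JAK/SHP-1 roles) and
  `irf5*` (six sites, TBK-1/alkaline-phosphatase roles) dose–response
  sweeps over kinase:phosphatase total ratios or catalytic rate ratios,
  with the complex-free comparison. Parameters are regime-representative,
  not fits.

Throughout, the phosphorylation probability counts phosphatase-bound
substrate as phosphorylated: `p = (Wp + WpP) / W_T`. Units are arbitrary
but consistent (nominal "conc" and 1/time).

## CLI

```bash
phoscycle solve --a1 1 --d1 1 --k1 1 --a2 1 --d2 1 --k2 1 \
                --wt 1 --kt 0.5 --pt 0.5 --check
phoscycle solve --config params.yaml --out solution.csv
phoscycle scenario list
phoscycle sweep irf5 --out irf5.csv          # axis,p,gk,species_0..6
phoscycle sweep --config my_scenario.yaml --out sweep.csv
phoscycle generate --regime comparable --count 20 --seed 7 --out params.csv \
                   --measurements-out meas.csv --rel-noise 0.05
phoscycle estimate-km meas.csv
```

Parameter configs are flat YAML/JSON mappings with keys
`a1 d1 k1 a2 d2 k2 W_T K_T P_T`. Scenario configs add `name`, `n_sites`,
`sweep_axis` (`kinase_total_ratio` or `rate_ratio`), `grid`
(`{start, stop, num}` log-spaced, or a list) and a nested `params` block.
Every file-writing run drops a `<file>.manifest.json` provenance record;
logs go to stderr, data to stdout/files.

## Package layout

| module | contents |
|---|---|
| `phoscycle.cycle` | parameters/state types, mass-action RHS, stiff integrator |
| `phoscycle.closed_form` | nondimensionalization, cubic, closed-form & numeric solvers |
| `phoscycle.gk` | complex-free approximation + validity check |
| `phoscycle.multisite` | binomial phosphoform distribution, effective Hill |
| `phoscycle.km` | Michaelis-constant estimators |
| `phoscycle.scenarios` | sweep configs, bundled stat3/irf5 experiments |
| `phoscycle.sampling` | seeded regime sampling, synthetic measurements |
| `phoscycle.cli` | `phoscycle` command-line tool |
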