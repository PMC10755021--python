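# sabrekit

Quantitative receptor pharmacology built around a response model with an
explicit **signal amplification gain**. The five-parameter model describes
fractional response as a function of ligand concentration via

```
E/Emax = (ε·γ·L^n + ε_R0·γ·Kd^n) / ((ε·γ − ε + 1)·L^n + (ε_R0·γ − ε_R0 + 1)·Kd^n)
```

with binding affinity `Kd`, receptor-activation efficacy `ε ∈ [0, 1]`,
constitutive-activity efficacy `ε_R0`, gain `γ` (`γ > 1` left-shifts the
response relative to occupancy, `γ < 1` right-shifts it — apparent signal
attenuation/loss) and Hill slope `n`. Constraining parameters recovers the
familiar reductions (`ε_R0 = 0, n = 1` → three-parameter form; `γ = 1` →
Clark; and the classic Hill sigmoid as the empirical comparator).

The package provides:

- **`sabrekit.model`** — pure closed-form evaluation: the full and reduced
  response forms, occupancy, apparent `EC50`/`e_max` (`Kobs = Kd/(εγ−ε+1)`,
  `e_max = εγ/(εγ−ε+1)`), the occupancy→response transforms, the shift
  parameter `κ = Kd/EC50 = εγ−ε+1`, the operational (Black & Leff)
  comparator, and a Cheng-Prusoff correction.
- **`sabrekit.fitting`** — constrained global nonlinear least squares over
  multi-ligand, multi-pathway panels. Each parameter is declared
  `Fixed`, `Shared` (globally / per ligand / per pathway / custom groups) or
  free per curve; optimisation runs on transformed coordinates (log10 gain,
  logit efficacy) with a seeded Latin-hypercube multistart; SSE/AICc metrics
  and model comparison included. Per-curve Hill fitting is the empirical
  baseline.
- **`sabrekit.bias`** — biased-agonism diagnostics: pathway-specific
  efficacy refits with a documented significance rule, bias-plot data
  tables, and the conventional ΔΔlog(Emax/EC50) comparator.
- **`sabrekit.simulate`** — synthetic panel generation from ground-truth
  scenarios, including built-in presets (`fig1`, `fig4`, `fig5`, three
  two-pathway `mopr_*` study presets, and occupancy-threshold curves
  `f_resp ∝ f_occup^ν`).
- **`sabrekit.cli`** — `simulate` / `fit` / `bias` / `report` subcommands
  over tidy CSV panels and YAML constraint files.

## CLI quick tour

```sh
# simulate a three-compound, two-pathway panel with a biased ligand
sabrekit simulate --preset fig4 --sigma 0.02 --seed 1 --out runs/sim

# constraints: known Kd per ligand, one efficacy per ligand, one gain per pathway
cat > runs/constraints.yaml <<'EOF'
log_kd:
  fixed: {CpdTst1: -7.0, CpdTst2: -6.5, CpdTst3: -8.0}
efficacy:
  shared: per-ligand
gain:
  shared: per-pathway
EOF

sabrekit fit  --panel runs/sim/panel.csv --constraints runs/constraints.yaml --out runs/fit
sabrekit bias --panel runs/sim/panel.csv --constraints runs/constraints.yaml \
              --reference CpdTst1 --out runs/bias
sabrekit report --fit-dir runs/fit --panel runs/sim/panel.csv
```

Panels are long-format CSV (`ligand, pathway, log_conc_M, response_pct[, weight]`),
with concentrations in log10 molar (`--conc-units M|nM` converts linear
inputs) and responses in percent of the assay maximum.

## Notes

- Responses are fractions in `[0, 1]` internally; percent only at I/O.
- Efficacy is hard-capped at 1; the `κ = 1` singularity of the
  occupancy→response map is evaluated at its removable linear limit.
- Fits are deterministic given a seed; every seed is echoed into the
  metadata JSON artifacts.
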