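# lipidmix

Mixture design of experiments, Scheffé polynomial response modeling and
multi-response desirability optimization for lipid nanoparticle (LNP)
formulations.

## Who this is for

Formulation scientists screening LNP compositions — ionizable lipid,
helper phospholipid, cholesterol, PEG-lipid as molar fractions summing to
one — who want to plan a small optimal design, model the measured responses
(mRNA encapsulation efficiency, particle diameter, transfection read-outs),
judge whether the fitted surfaces are trustworthy, and pick candidate
compositions for follow-up, all from scripts or a shell instead of
point-and-click DoE software.

## What it computes

**Designs.** A mixture experiment lives on the simplex
`Σᵢ xᵢ = 1`, `lᵢ ≤ xᵢ ≤ uᵢ`. `lipidmix` enumerates the extreme vertices and
centroids of the bounded region, estimates the region moment matrix
`M = E[f(x) f(x)ᵀ]` by Monte Carlo, and improves a starting design by
Fedorov point exchange against the I-criterion `tr((XᵀX)⁻¹M)` (average
scaled prediction variance, minimized) or the D-criterion `−log det(XᵀX)`.

**Models.** Responses are fitted on a power scale `t = y^λ` (`ln y` at
λ = 0), with λ chosen by a Box–Cox profile-likelihood scan and snapped to a
convenient value inside its confidence interval. The model is the canonical
Scheffé polynomial — no intercept, linear blending terms `βᵢxᵢ` and binary
blending terms `βᵢⱼxᵢxⱼ` — fitted by OLS. Adequacy follows response-surface
conventions: R², adjusted R², PRESS-based predicted R², CV%, and adequate
precision `(max ŷ − min ŷ)/√(p·MSE/n)` with the `> 4` rule and the
`adjusted − predicted R² < 0.2` over-fit screen.

**Selection.** Binary terms are screened by sequential (type-I) sums of
squares and selected by BIC (`n·ln(SSE/n) + k·ln n`) forward selection or
backward elimination, with the linear blending terms mandatory so every
model is hierarchy-valid. An exhaustive best-subset oracle is included for
verification.

**Optimization.** Each response gets a Derringer–Suich desirability
`d ∈ [0, 1]`; candidates are ranked by the importance-weighted geometric
mean `D = (Π dᵢ^rᵢ)^(1/Σrᵢ)` and refined by multistart Nelder–Mead over the
feasible sub-simplex, with selected components (e.g. the ionizable and
PEG-lipid fractions) pinned at fixed values.

**Built-in study.** The package ships the 15-run I-optimal design of an
S-type (Spikevax-composition) LNP screen plus its hold-out run MS at the
commercial molar ratios 10/50/38.5/1.5 (DSPC/SM-102/cholesterol/
DMG-PEG2000), and the three published fitted models (encapsulation %,
diameter on `Y^0.5`, nMFI on `Y^−1.5`) with their residual SDs, so the whole
pipeline can be exercised on synthetic data with realistic structure.

## Worked example

```python
import lipidmix as lm

design = lm.builtin_design()                    # 15 runs + MS hold-out
truths = lm.builtin_models()
responses = lm.simulate_responses(design, seed=1)

for name, truth in truths.items():
    model = lm.fit_scheffe(design, responses[name].to_numpy(),
                           truth.spec, truth.transform, response_name=name)
    stats = lm.fit_statistics(model)
    print(f"{name}: {model.transform.label()} = {model.equation()}")
    print(f"  R2={stats.r2:.4f} adjR2={stats.adj_r2:.4f} "
          f"predR2={stats.pred_r2:.4f} AP={stats.adequate_precision:.2f} "
          f"adequate={stats.adequacy().passed}")
```

prints (seed 1):

```
encapsulation_pct: Y^1 = 62.40 A + 54.08 B + 105.73 C - 107.31 D
  R2=0.5961 adjR2=0.4860 predR2=0.3211 AP=8.14 adequate=True
diameter_nm: Y^0.5 = 20.37 A + 2.52 B - 3.94 C - 22.86 D + 3.26 A*B + 53.07 B*C - 60.88 B*D + 67.49 C*D
  R2=0.7091 adjR2=0.4182 predR2=0.1587 AP=6.23 adequate=False
nmfi: Y^-1.5 = - 0.18 A + 0.30 B + 0.49 C + 6.09 D + 0.86 A*C
  R2=0.9166 adjR2=0.8833 predR2=0.7864 AP=14.02 adequate=True
```

A, B, C, D are the DSPC, SM-102, cholesterol and DMG-PEG2000 fractions; the
coefficients are on the proportion scale. The nMFI model (fitted on
`Y^−1.5`, so *smaller* transformed values mean *brighter* cells) is the most
reliable surface here; the diameter fit fails the over-fit screen
(adjusted − predicted R² = 0.26 > 0.2), mirroring why a diameter model would
be excluded from composition optimization.

Optimizing encapsulation (weight 2, importance 3) and nMFI (importance 5)
with the ionizable lipid fixed at 0.65 and the PEG-lipid at 0.01:

```python
models = {n: lm.fit_scheffe(design, responses[n].to_numpy(),
                            truths[n].spec, truths[n].transform)
          for n in ("encapsulation_pct", "nmfi")}
goals = [lm.Goal("encapsulation_pct", "maximize", low=40, target=95,
                 weight=2, importance=3),
         lm.Goal("nmfi", "maximize", low=1.0, target=3.0, importance=5)]
result = lm.optimize_formulation(models, goals, lm.builtin_bounds(),
                                 fixed={"SM-102": 0.65, "DMG-PEG2000": 0.01},
                                 n_starts=10, seed=1)
```

```
best candidate: DSPC=0.190, SM-102=0.650, cholesterol=0.150, DMG-PEG2000=0.010
  predicted: EE=61.8% nMFI=2.13  D=0.349
```

i.e. a DSPC-to-cholesterol ratio of about 1.3 under this simulated screen,
with the overall desirability D on the 0–1 scale.

The same pipeline is scriptable from the shell:

```bash
lipidmix simulate --seed 1 --out responses.csv
lipidmix fit --responses-file responses.csv --out-dir fit_out
lipidmix select --responses-file responses.csv --response nmfi
lipidmix optimize --config goals.yaml --out candidates.csv
```

## Layout

- `lipidmix.design` — bounds, designs, Scheffé term sets, candidate sets,
  I/D criteria, point exchange, ratio-series designs
- `lipidmix.models` — power transforms, Box–Cox scan, OLS fits, fit
  statistics, adequacy, prediction, hold-out validation
- `lipidmix.selection` — sequential SS, BIC stepwise, exhaustive oracle
- `lipidmix.optimize` — desirability goals, overall D, multistart search
- `lipidmix.datasets` — packaged design/models, synthetic generators
- `lipidmix.io`, `lipidmix.cli` — CSV schemas, reports, configuration, CLI

See `docs/methods.md` for the statistical conventions and their rationale.
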