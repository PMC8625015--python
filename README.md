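# microhdx

Analysis toolkit for **microdroplet hydrogen–deuterium exchange (HDX) mass
spectrometry** of small molecules. When a sample is sprayed with a
methanol–D₂O solvent, every labile (heteroatom-bound) proton of an analyte
can be replaced by deuterium in flight, shifting the ion mass by
≈1.0063 Da per exchange. Isobaric ions — same formula, same m/z,
indistinguishable by mass alone — then produce different "deuterium
ladders" (peak series D₀, D₁, …, Dₙ), because they differ in the number
and chemistry of their exchangeable sites. This package simulates,
detects and interprets those ladders for:

- **isobaric-ion discrimination** — counting exchangeable sites and
  comparing base-peak positions (e.g. codeine vs. hydrocodone at m/z
  300.1594, glucose vs. inositol at 181.0707);
- **mixture deconvolution** — estimating the molar composition of a
  two-component isobaric mixture from its mixed ladder;
- **quantitation** — absolute concentration of one isobar from its unique
  deuterium channel, ratioed to an internal standard;
- **cohort profiling** — augmenting untargeted metabolic profiles with
  deuterium-channel features so that PCA separates groups an
  intensity-only profile cannot.

It is aimed at mass spectrometrists working with ambient/direct-infusion
sources who want a tested, scriptable model of the HDX ladder rather than
spreadsheet arithmetic.

## The model in brief

Each exchangeable site *i* exchanges independently with probability *pᵢ*
(functional-group class dependent; back exchange and D₂O fraction scale it),
so the deuterium count follows a **Poisson-binomial** distribution; the
charging proton of [M+H]⁺-type adducts adds one more Bernoulli trial. The
observed ladder is that distribution convolved with the ion's natural
isotope pattern (¹³C/²H/¹⁵N fine structure is unresolved at R = 120,000):

```
I(k) = Σ_{d+j=k} P(D = d) · A_nat(j)
```

Detection inverts this by forward substitution (natural-isotope
correction). A two-component isobaric mixture obeys
`I_abs = N_g·I_g + N_i·I_i` (equal ionization efficiencies assumed);
patterns are compared after base-peak normalization
(`I_rel = 100·I_abs/I_BP`) with the mean absolute deviation
`Loss = (1/(n+1)) Σ |I_sim − I_obs|`, and composition is estimated by
minimizing that loss over the mole-fraction simplex.

## Worked example

```python
import microhdx as mx
from microhdx.ladder_detection import judge_deuteration

lib = {f.name: f for f in mx.fixture_library()}
for name in ("codeine", "hydrocodone"):
    fx = lib[name]
    lad = mx.fixture_ladder(name)              # noiseless post-HDX ladder
    j = judge_deuteration(lad, fx.formula, fx.adduct)
    rel = ", ".join(f"D{k}={v:.1f}" for k, v in enumerate(lad.relative[:4]))
    print(f"{name}: m/z {lad.precursor_mz:.4f}  {rel}  sites={j.site_count_estimate}")
```

prints

```
codeine: m/z 300.1594  D0=73.9, D1=100.0, D2=39.2, D3=6.4  sites=1
hydrocodone: m/z 300.1594  D0=100.0, D1=53.5, D2=9.3, D3=1.1  sites=0
```

Both ions sit at the same m/z, but codeine's free 6-hydroxyl gives it an
extra deuterium channel (site count 1 vs. 0) and moves its base peak to
D₁ — the two drugs are distinguished without MS/MS. Deconvolving synthetic
glucose/inositol mixtures (100 µM total, 3% channel noise):

```python
from microhdx.mixture_deconvolution import estimate_composition, to_relative
samples, g, i = mx.generate_mixture_samples(seed=7)
for s in samples:
    fit = estimate_composition(to_relative(s.observed), g, i)
    print(f"ratio {s.ratio}: true fg={s.true_fractions[0]:.2f} "
          f"fitted fg={fit.composition.fractions[0]:.3f} loss={fit.loss:.2f}%")
```

```
ratio (2, 2): true fg=0.50 fitted fg=0.520 loss=0.25%
ratio (1, 3): true fg=0.25 fitted fg=0.324 loss=0.65%
ratio (3, 1): true fg=0.75 fitted fg=0.686 loss=0.63%
```

The loss is the mean channel-wise deviation (in % of base peak) between
the best-fitting linear combination and the observed pattern; the fitted
glucose mole fraction tracks the truth to within a few hundredths here
(see `docs/methods.md` for its sampling spread).

A thin CLI mirrors the library: `microhdx simulate | normalize | average |
detect | deconvolve | quantify | synth-cohort | profile` (see `--help`).

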