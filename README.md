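# lucikin

Progress-curve kinetics for bioluminescent luciferase assays: simulate
plate-reader luminescence experiments, transform raw intensity traces into
conversion curves, globally fit full progress curves to recover kinetic
constants, and quantify how well those constants are actually determined.

## The problem

Luciferases (here NanoLuc-type enzymes oxidizing imidazopyrazinone
luciferins such as coelenterazine and furimazine) are characterized by a
turnover number k_cat, a Michaelis constant K_m, and — because the
oxidized product rebinds the enzyme — a product dissociation constant K_p
that shapes the flash-like decay of the light signal.  A luminometer only
reports relative light units (RLU), so absolute rates are not directly
measurable.  The trick this package implements is the progress-curve
route: intensity is proportional to the product-formation rate, so the
*cumulative* luminescence is proportional to product concentration,

    C(t) = f · [P](t),      f in RLU·s per µM,

and when a reaction is run to complete conversion of a known substrate
amount S0, the plateau fixes the scaling factor f = C(∞)/S0.  Full
time courses across a substrate series (0.25–4×K_m) then determine
k_cat, K_m and K_p by global nonlinear least squares, with f and bounded
(±5%) per-curve concentration corrections as nuisance parameters — no
photon-yield calibration required.

The forward model is the quasi-steady-state rate law with competitive
product inhibition and optional uncompetitive substrate inhibition,

    v = k_cat·E0·S / ( K_m·(1 + P/K_p) + S·(1 + S/K_s) ),

backed by a full mass-action integrator for regimes where the
approximation is in doubt.  Identifiability is assessed with
profile-chi² confidence contours: for each pair of parameters, every
other parameter (including nuisances) is re-optimized on a grid, and the
region under an F-statistic threshold delimits jointly acceptable values.

Who it is for: enzymologists analysing luminescent (or analogously
fluorogenic) progress-curve assays, and method developers who need a
tested synthetic-data generator with known ground truth for benchmarking
progress-curve estimators.

## Worked example

Simulate a three-replicate coelenterazine study at the wild-type
constants (k_cat = 2.48 s⁻¹, K_m = 0.57 µM, K_p = 0.256 µM, f = 10⁶),
then run the two-stage pipeline (initial rates → global progress-curve
fit → derived quantities):

```python
from lucikin.io import load_config, run_pipeline

config = {
    "seed": 7,
    "design": {"replicates": 3},
    "simulate": {
        "entries": [{"variant": "NanoLuc", "luciferin": "CTZ",
                     "k_cat": 2.48, "K_m": 0.57, "K_p": 0.256,
                     "scaling_f": 1.0e6}],
        "E0": 0.01,
        "read_interval_s": 2.0,
    },
    "fit": {"multistart_n": 2},
}
report = run_pipeline(load_config(config), output_dir="example_out")
print(report["groups"]["NanoLuc|CTZ"]["params"])
```

Output (seed 7):

```
stage-1 (initial rates)  K_m ≈ 0.80 µM            # provisional seed value
global fit               k_cat = 2.466 s⁻¹
                         K_m   = 0.565 µM
                         K_p   = 0.255 µM
                         f     = 9.994e5 RLU·s/µM
                         chi²  = 4799  (n = 3330 points)
derived                  k_cat/K_m = 4.37 ± 0.01 s⁻¹µM⁻¹
```

All three kinetic constants land within ~1% of the generating values
under 2% proportional + 5 RLU additive noise; the stage-1 K_m is biased
high (a 15-s window already feels product inhibition) which is exactly
why it is only used to seed the global fit.  The specificity constant
4.37 s⁻¹µM⁻¹ is the published wild-type/coelenterazine value (prints as
4.4 ± 0.2).

The same stages are exposed on the command line:

```
lucikin simulate   --config config.yaml --out simdir
lucikin fit-initial --traces simdir/traces.csv --out initial.json
lucikin fit-global  --traces simdir/traces.csv --out fit.json
lucikin contours    --traces simdir/traces.csv --pair k_cat,K_m --out grid.csv
lucikin report      --config config.yaml --out outdir
```

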