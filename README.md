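# cartkin

Kinetic modeling of CAR-T cell cytotoxicity from real-time impedance
assays.

Clinical CAR-T products are routinely profiled before infusion with
real-time impedance cytotoxicity assays: tumor target cells attach and
grow in a microelectrode plate for ~24 h, the effector product (CAR-T
plus untransduced T cells) is added at several effector:target (E:T)
ratios, and the instrument reports a dimensionless cell index (CI) every
15 minutes for 72 h. `cartkin` turns those traces into product-specific
kinetic parameters and asks whether those parameters differ across
clinical outcome groups. It is written for quantitative researchers in
cell-therapy labs who have assay exports and outcome labels and want a
reproducible, testable pipeline rather than ad-hoc spreadsheet fits.

## The model

Three populations per well — tumor `T`, CAR-T `CART`, untransduced
T cells `TC`:

    dT/dt    = k_p1 · T (1 − T/C_T) − F_C
    dCART/dt = F_P · ln(C_E / (CART + TC)) − k_d · CART
    dTC/dt   = −k_d · TC

with ratio-dependent Hill-type killing and killing-driven expansion,

    F_C = k_c · r^n / (K_mr^n + r^n) · T ,   r = CART/T
    F_P = k_p2 · F_C² / (K_mp² + F_C²) · CART .

`K_mr` is the E:T ratio at half-maximal killing, `n` the cooperativity
of the killing switch, `K_mp` the cytolysis level at half-maximal
CAR-T expansion ("responsiveness"), `C_T`/`C_E` assay carrying
capacities, `k_d` basal T-cell decay. Estimation is staged: tumor
parameters from target-control wells, decay from effector-control
wells, then the six effector parameters from all co-culture wells
jointly by multi-start bounded least squares on CI residuals, through a
per-product linear CI↔cell calibration. Cohort comparisons use
two-sided Wilcoxon rank-sum tests with rank-biserial effect sizes.

Because no public per-product dataset exists for this assay family, the
package ships a synthetic cohort generator (`cartkin.synthetic`) that
emulates the clinical data — including transduction-efficiency spread,
measurement noise, and outcome labels statistically linked to the
ground-truth kinetics — so every stage is testable end to end.

## Worked example

Generate one synthetic product, fit it, and compare with the ground
truth:

```python
from cartkin import synthetic as syn
from cartkin.estimation import FitConfig, fit_product

cfg = syn.CohortConfig(n_products=1, seed=7)
product = syn.draw_product(cfg, 0)
dataset = syn.emit_traces(product, cfg)

fit = fit_product(dataset, FitConfig(n_starts=100, seed=1,
                                     declared_addition_time=24.0))
print(f"overall R2 = {fit.r2_overall:.4f}, SSR = {fit.ssr:.3f} CI^2")
for name in ("kp1", "CT", "kd", "kc", "Kmr", "n"):
    print(f"{name:>4s}: estimate {getattr(fit.params, name):10.4g}"
          f"   truth {getattr(product.truth, name):10.4g}")
```

Output:

    overall R2 = 0.9987, SSR = 3.212 CI^2
     kp1: estimate    0.03983   truth    0.04001
      CT: estimate  1.075e+06   truth   1.06e+06
      kd: estimate   0.006986   truth   0.007016
      kc: estimate     0.2157   truth     0.2329
     Kmr: estimate      1.644   truth      1.555
       n: estimate     0.8588   truth     0.8863

The fit explains 99.9% of the CI variance and recovers the growth rate
(`kp1`, per hour), carrying capacity (`CT`, cells), decay rate (`kd`),
saturated killing rate (`kc`), half-saturation ratio (`Kmr`) and
cooperativity (`n`) to within a few percent of the generating truth at
the default 2% measurement noise. The expansion-side parameters
(`kp2`, `Kmp`, `CE`) are weakly identified in this assay type — see
`docs/methods.md`.

The same pipeline is scriptable from the shell:

    cartkin generate --out cohort/ --seed 3 --products 45
    cartkin fit      --in cohort/ --out fits.csv --seed 2 --n-starts 100
    cartkin cohort   --fits fits.csv --cohort-dir cohort/ --out stats.csv
    cartkin sensitivity --out sens/

## Layout

    src/cartkin/model.py        ODE system, protocol, forward simulation
    src/cartkin/calibration.py  normalization, alignment, CI↔cell maps
    src/cartkin/estimation.py   staged multi-start fitting
    src/cartkin/sensitivity.py  error/global sensitivity, identifiability
    src/cartkin/cohort.py       outcome groupings and rank statistics
    src/cartkin/synthetic.py    synthetic cohort generator
    src/cartkin/workflows.py    recovery / calibration / power studies
    src/cartkin/io.py, cli.py   serialization and command line
    docs/methods.md             model, conventions, design choices
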