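"""Recover known conditional-quantile lines with the exact LP fit.

Draws y = x + (0.5 + x) * eps, whose tau-quantile line has the closed-form
slope 1 + z_tau, fits both tails by check-loss minimization, and attaches
pairs-bootstrap standard errors.
"""

import fire_equity as fe

cfg = fe.SimConfig(
    seed=4,
    heteroscedastic_params=fe.HeteroscedasticParams(n_points=1500),
)
x, y, truth = fe.generate_heteroscedastic_xy(cfg)

for tau in (0.05, 0.95):
    fit = fe.fit_quantile_line(x, y, tau)
    se0, se1 = fe.bootstrap_se(x, y, tau, n_boot=60, seed=4)
    _, true_slope = truth.true_quantile_line(tau)
    print(
        f"tau={tau:.2f}: slope {fit.beta1:+.3f} (SE {se1:.3f}), "
        f"analytic {true_slope:+.4f}, check loss {fit.objective:.1f}, n={fit.n}"
    )

print()
print("The 0.95 line bounds the top of the response envelope, the 0.05 line")
print("its floor; heteroscedasticity makes the two slopes differ from the")
print("mean-regression slope of 1.")

cv_low, cv_high, n_low, n_high = fe.extremes_cv(x, y - y.min() + 0.1, window=0.25)
print(f"CV of the response at the low/high ends of x: "
      f"{cv_low:.2f} (n={n_low}) / {cv_high:.2f} (n={n_high})")
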