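"""Effect-size-theory benchmark responses from within-group variances.

BMR = exp((1/8) * 7 * sqrt(var)) - 1: one eighth of the log-transformed
maximum effect, with the maximum effect tied to var through the empirical
proportionality ln(c) ~ 7 * sqrt(var).
"""

from ecsbmr import bmr_from_c, bmr_from_var, bmr_interval_from_var_ci

published = {
    "DupSeq": (0.078, (0.073, 0.084), 47),
    "HawkSeq": (0.031, (0.024, 0.041), 6),
    "PECCSeq": (0.057, (0.043, 0.079), 3),
}

print(f"{'technology':<10} {'n':>3} {'var':>6}  {'BMR%':>5}  (90% CI)")
for tech, (var, ci, n) in published.items():
    res = bmr_from_var(var, n_basis=n)
    lo, hi = bmr_interval_from_var_ci(ci)
    print(f"{tech:<10} {n:>3} {var:>6.3f}  {res.percent:>5.1f}  ({100*lo:.1f}-{100*hi:.1f})")

# the c-based variant, usable when the maximum fold change is well estimated:
print(f"\nc-based BMR at c=17.2: {bmr_from_c(17.2).percent:.1f}%"
      " (larger: the fitted c exceeds what ln(c)=7*sqrt(var) would imply)")
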