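"""Separation in the simplest setting: a 2x2 table with an empty cell.

Builds the observation-level data for a table with no events in the exposed
group, shows that the ML estimate does not exist, and that Firth's correction
returns a finite log odds ratio with a profile penalized-likelihood CI.
"""

import firthiss as fi

# counts f_yx: 20 unexposed non-events, 10 exposed non-events,
# 4 unexposed events, 0 exposed events
d = fi.dataset_from_2x2(20, 10, 4, 0)

report = fi.detect_separation(d)
print(f"separation: {report.kind}")

ml = fi.ml_fit(d)
print(f"ML estimate exists: {ml.estimate_exists}")

fc = fi.firth_fit(d)
lo, hi = fi.profile_penalized_ci(d, fc, j=1)
print(f"Firth log OR for exposure: {fc.beta[1]:.3f}  (95% profile CI {lo:.2f} to {hi:.2f})")
print(f"closed form (ML on counts + 0.5): {fi.fit_2x2_closed_form(20, 10, 4, 0, 'FC'):.3f}")

# The finite Firth estimate replaces the diverging ML one; the interval is
# asymmetric because the penalized likelihood is skewed near the empty cell.
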