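"""How much does the arbitrary choice of PTA bins move the fitted limit?

The sub-group methods (simulation, Harrell-Davis) must first bin ears by
PTA, and different published binnings exist.  Fitting the CL curve under
four alternative schemes and comparing them on a PTA grid shows the binning
itself shifts the limit by a few percentage points — a problem quantile
regression avoids entirely.
"""

from speechnorms import BUILTIN_SCHEMES, default_model, gen_cohort, grouping_sensitivity

cohort = gen_cohort(642, default_model("R", "skewed_beta"), seed=13)
schemes = [BUILTIN_SCHEMES[k] for k in ("group1", "group2", "group3", "group4")]

rows = grouping_sensitivity(cohort, schemes, method="simulation",
                            seed=13, n_sims=20_000)
print(f"{'scheme':>8} {'RMS diff':>9} {'max':>6} {'min':>7}   (vs {rows[0]['scheme']})")
for row in rows[1:]:
    print(f"{row['scheme']:>8} {row['rms_diff']:9.2f} {row['max_diff']:6.2f} "
          f"{row['min_diff']:7.2f}")

print()
print("RMS differences of a few percentage points mean two clinics using")
print("different PTA bins would flag different ears as abnormal.")
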