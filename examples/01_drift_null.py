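"""How unlikely is a 1% allele-frequency change under pure drift?

Evaluates the Wright-Fisher drift null at the study conditions: an
effective population size of 3.3e7 and 82 generations between archived
samples, with the allele at p = 0.5 (the fastest-drifting frequency).
"""

from fossilrecord import DriftParams, drift_change_probability, drift_sd, drift_variance

params = DriftParams(p=0.5, t=82, ne=3.3e7)

var = drift_variance(params)
sd = drift_sd(params)
p_1pct = drift_change_probability(0.01, params)

print(f"variance of dp after 82 generations : {var:.3e}")
print(f"standard deviation                  : {sd:.3e}  ({sd:.2%} of frequency)")
print(f"P(|dp| >= 1%) under drift alone     : {p_1pct:.3e}")
print()
print(
    "At this population size drift moves allele frequencies by ~0.08% per\n"
    "sampling interval, so any observed change of >= 1% is effectively\n"
    "impossible under drift and marks a selection (or hitchhiking) candidate."
)
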