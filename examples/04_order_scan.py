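"""Scan mixture orders 1-8 and tabulate goodness of fit.

On a two-species profile a single Gaussian leaves a structured residual;
two components capture the shape, and further components add nothing.
This is the diagnostic that justifies the default order of 2.
"""

from diffsizer import Species, SpeciesMix, simulate_profiles
from diffsizer.mixturefit import order_scan
from diffsizer.pipeline import RunConfig, preprocess_set

ms = simulate_profiles(SpeciesMix((Species(1.5), Species(3.0))))
sections = preprocess_set(ms, RunConfig())
mid = sections[5]  # a mid-channel measurement point

table = order_scan([(mid.pair.label, mid.x_inside, mid.fluor_inside)],
                   max_order=8, seed=0)
print(table[["point", "order", "rmse", "adj_r2"]].to_string(index=False,
      float_format=lambda v: f"{v:.3e}"))
print("RMSE collapses from order 1 to order 2 and is flat beyond: "
      "two components describe this analyte.")
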