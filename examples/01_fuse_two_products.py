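"""Fuse two synthetic LE products and compare errors against the truth.

Builds the default benchmark — a rank-3 seasonal truth field (40x40 grid,
46 eight-day steps) and two corrupted products — then runs the EOF
component-mixing fusion and the simple-average baseline, and prints each
field's RMSE against the known truth.
"""

import numpy as np

from eoflux import FusionConfig, default_benchmark, eof_fuse, simple_average

truth, product_a, product_b = default_benchmark(seed=42)
fused = eof_fuse(product_a, product_b, FusionConfig())
baseline = simple_average(product_a, product_b)


def rmse(field):
    observed = ~field.mask
    return np.sqrt(np.mean((field.values[observed] - truth.values[observed]) ** 2))


print(f"product A (primary, noisy):    RMSE = {rmse(product_a):6.2f} W/m2")
print(f"product B (secondary, gappy):  RMSE = {rmse(product_b):6.2f} W/m2")
print(f"simple average (weight 0.5):   RMSE = {rmse(baseline):6.2f} W/m2")
print(f"EOF fusion (W=4, 80/20):       RMSE = {rmse(fused):6.2f} W/m2")
print()
print("The fused field keeps product A's dominant seasonal patterns, adds")
print("product B's complementary minor components, and ends up closer to")
print("the truth than either input or the constant-weight average.")
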