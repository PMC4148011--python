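"""Geodesic distance between connectomes and the order normalization.

Shows the affine-invariant distance d_AI on simple SPD pairs, calibrates
how it scales with matrix order using random Wishart pairs, and uses the
calibration to compare distances across network sizes.
"""

import numpy as np

from conncca import calibrate_order_normalization, dai, make_wishart_pairs, normalized_dai

# a matrix that differs from the identity by a factor e^2 in one direction
# is at distance exactly 2 (the log-eigenvalues are 2 and 0)
P = np.diag([np.e**2, 1.0])
print(f"dai(diag(e^2, 1), I) = {dai(P, np.eye(2)):.6f}  (exact value: 2)")

# distance grows with matrix order even for 'equally unusual' matrices
cal = calibrate_order_normalization(range(10, 101, 10), n_pairs=100, seed=0)
print("\nmedian Wishart-pair distance by order:")
for order, med in zip(cal.orders, cal.medians):
    print(f"  order {order:3d}: {med:.3f}")
print(f"line fit: median = {cal.slope:.4f} * order + {cal.intercept:.3f}, "
      f"R^2 = {cal.fit_r2:.3f}")

# after normalization, pair distances are comparable across orders
for order in (68, 82):
    pairs = make_wishart_pairs(order, 2 * order, 50, seed=order)
    norm = np.median([normalized_dai(A, B, cal) for A, B in pairs])
    print(f"order {order}: median normalized distance = {norm:.3f}")
print("\nThe near-equal normalized medians show the calibration removes "
      "the order dependence, so 68- and 82-region networks can be compared.")
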