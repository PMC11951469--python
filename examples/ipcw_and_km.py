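"""Kaplan-Meier, reverse Kaplan-Meier and IPCW weights on a tiny sample.

Shows the product-limit identity that motivates the weights: the IPCW
reweighted empirical distribution of the uncensored observations equals the
Kaplan-Meier estimate.
"""

import numpy as np

from cse import ipcw_weights, kaplan_meier, reverse_kaplan_meier

times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
events = np.array([1, 1, 0, 1, 1])  # the third subject is censored

km = kaplan_meier(times, events)
g = reverse_kaplan_meier(times, events)
w = ipcw_weights(times, events, g)

print("t    S_km(t)  G_hat(t)  W")
for t, e, wi in zip(times, events, w):
    print(f"{t:.0f}    {km(t):.3f}    {g(t):.3f}   {wi:.2f}  ({'event' if e else 'censored'})")

# identity: S_km(t) = 1 - (1/n) sum_i W_i 1{T_i <= t}
grid = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
ipcw_cdf = np.array([(w * (times <= t)).sum() / len(times) for t in grid])
print("\ngrid       :", grid)
print("KM         :", km(grid))
print("1 - IPCW F :", 1 - ipcw_cdf)
print("\nThe censored subject gets weight 0; the events after it are up-weighted")
print("by 1/G(t-) = 1.5, exactly compensating the censoring-induced selection.")
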