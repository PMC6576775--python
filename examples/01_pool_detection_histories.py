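"""Pool per-camera daily histories into the five survey-method histories.

Builds a tiny two-site survey by hand, pools it with the default T-array
method map (m1 = A; m2 = B,C; m3 = A,B,C; m4 = D,E; m5 = B,D,E) and prints
the pooled occasion records plus design-free effort summaries.
"""

import numpy as np

from multiscale_occupancy import (
    DetectionArray,
    default_method_map,
    naive_summaries,
    pool_histories,
)

# two sites, five cameras (A-E), four daily occasions; -1 marks a missing visit
obs = np.zeros((2, 5, 4), dtype=np.int8)
obs[0, 0, 0] = 1   # site s1: camera A fires on day 1
obs[0, 2, 2] = 1   # site s1: camera C fires on day 3
obs[1, :, 1] = -1  # site s2: the whole array was snowed in on day 2
obs[1, 3, 3] = 1   # site s2: camera D fires on day 4

d = DetectionArray(["s1", "s2"], ["A", "B", "C", "D", "E"], [4, 4], obs)
mmap = default_method_map()
pooled = pool_histories(d, mmap)

print("pooled histories (rows = methods, columns = days; -1 = missing):")
for i, site in enumerate(pooled.site_ids):
    print(f"  site {site}")
    for j, mid in enumerate(pooled.method_ids):
        cams = ",".join(mmap.methods[j].cameras)
        print(f"    {mid} ({cams:5s}): {pooled.obs[i, j].tolist()}")

print("\nnaive summaries:", naive_summaries(d))
# A detection by any member camera makes its methods detect (day 1: A fires,
# so m1 and m3 detect); a day is missing for a method only when every member
# camera is missing. The summaries count raw effort before any modelling.
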