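"""Build a fate-balanced synthetic single-cell snapshot and export it.

Generates the standard 1200-cell dataset (400 independent SDE paths per
fate, cyclically permuted, one observation time each), writes it to CSV and
summarizes the barycentric spread of early vs late cells.
"""

import numpy as np

from cfrlineage import (
    CFRParams,
    SimSettings,
    barycentric_project,
    generate_dataset,
    log_transform,
    write_dataset,
)

ds = generate_dataset(
    CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.01), seed=7
)
write_dataset(ds, "snapshot_alpha1000.csv")
print(f"wrote {len(ds)} cells to snapshot_alpha1000.csv")

y = barycentric_project(log_transform(ds))
r = np.linalg.norm(y, axis=1)
early = ds.times < 400
print(f"median distance from the diagonal, early cells (t<400): {np.median(r[early]):.2f}")
print(f"median distance from the diagonal, late cells (t>1800): {np.median(r[ds.times > 1800]):.2f}")
print(
    "Early multi-potent cells hug the (1,1,1) diagonal (small barycentric "
    "radius); committed cells sit far out along one of three fate directions."
)
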