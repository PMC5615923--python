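"""Perseus-style preprocessing: min-valid filtering, downshifted imputation.

Proteins need at least 4 observed values in one genotype to survive; the
remaining holes are filled per sample column from Normal(m - 1.8 s, (0.3 s)^2)
using that column's observed mean m and sd s.
"""

import numpy as np

from foxodep import ImputationParams, SimConfig, filter_min_valid, impute_downshift, make_bundle

bundle = make_bundle(SimConfig(n_proteins=2000, seed=1))
filtered = filter_min_valid(bundle.observed, min_valid=4)
print(f"proteins: {bundle.observed.n_proteins} -> {filtered.n_proteins} after filtering")

imputed = impute_downshift(filtered, ImputationParams(width=0.3, downshift=1.8, seed=102))
col = imputed.values.columns[0]
obs = filtered.values[col].dropna()
fill = imputed.values.loc[filtered.values[col].isna(), col]
print(f"\ncolumn {col}: observed mean {obs.mean():.2f} (sd {obs.std(ddof=1):.2f})")
print(f"imputed cells: {len(fill)}, mean {fill.mean():.2f}")
offset = (fill.mean() - obs.mean()) / obs.std(ddof=1)
print(f"imputed mean sits {offset:.2f} observed-sd units below the column mean")
print(f"matrix complete: {imputed.is_complete()}")
# Imputed values land in the low-intensity tail (about -1.8 sd), standing in
# for proteins that were most likely below the detection limit.
assert np.isclose(offset, -1.8, atol=0.15)
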