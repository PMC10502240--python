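"""Test whether chromatin proximity explains sequence/profile disparity.

Draws 2% of the samples, partitions nonzero-contact pairs by the gap
between their sequence-similarity and profile-similarity percentiles, and
compares interaction frequencies across the partition with one-sided
rank-sum tests.  With structure-driven labels (beta = 0.5) the "under"
pairs — more alike in profile than their sequences explain — should show
significantly higher contact frequencies.
"""

from epimodal.disparity import run_disparity_test
from epimodal.protocols import DISPARITY_FIXTURE
from epimodal.synthetic import SyntheticConfig, generate_fixture

import dataclasses

cfg = dataclasses.replace(DISPARITY_FIXTURE, seed=1)
fx = generate_fixture(cfg)
report = run_disparity_test(fx.sequences, fx.labels, fx.sample_hic_bins,
                            fx.matrix, frac=0.02, repeats=3, margin=10, seed=1)

for r in range(report.repeats):
    cells = report.cell_sizes[r]
    print(f"repeat {r}: under p = {report.under_p[r]:.4g}, "
          f"over p = {report.over_p[r]:.4g}, cells = {cells}")
print(f"frequency of p < .05 (under): {report.significance_frequency('under'):.2f}")
# A small "under" p-value says pairs with unexpectedly similar profiles
# sit closer in 3D than percentile-consistent pairs.  In this clean block
# model the symmetric "over" direction also reaches significance; in real
# chromatin data remoteness constrains profiles far less than proximity
# promotes them, so only the "under" direction is robustly significant.
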