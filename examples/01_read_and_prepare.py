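"""Read a block-layout peak table and apply the detection threshold and size range.

Builds the six-profile example table (three samples in duplicate, at most
three fragments each), parses it, and filters with a peak detection
threshold of 50 fluorescence units over the 50-1020 base analysis range.
"""

from pathlib import Path
import tempfile

from trflptools import apply_threshold_and_range, read_dataset

TABLE = """\
Sample Name\tSample 1.1\tSample 1.2\tSample 2.1\tSample 2.2\tSample 3.1\tSample 3.2
T-RF 1\t1\t1\t1\t1\t1\t1
T-RF 2\t1\t1\t1\t1\t1\t1
T-RF 3\t0\t1\t1\t1\t0\t0
Size 1\t167.78\t167.75\t167.78\t167.87\t167.78\t167.88
Size 2\t300\t299.92\t300\t299.84\t300\t299.92
Size 3\t\t478.02\t478.24\t478.23\t\t
Height 1\t900\t578\t900\t426\t900\t362
Height 2\t640\t434\t640\t331\t640\t278
Height 3\t\t720\t966\t488\t\t
Area 1\t10798\t7164\t10798\t5293\t10798\t4393
Area 2\t7376\t4869\t7376\t3807\t7376\t3129
Area 3\t\t11992\t15617\t7958\t\t
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "peaks.tsv"
    path.write_text(TABLE)
    dataset = read_dataset(path, n_samples=3, n_replicates=2)

print(f"parsed {len(dataset)} profiles")
for profile in dataset:
    print(f"  {profile.name}: {len(profile)} T-RFs at "
          f"{[p.size for p in profile]} bases")

filtered, report = apply_threshold_and_range(dataset, pdt=50, size_min=50, size_max=1020)
print(f"\nafter PDT 50 and range 50-1020: max {report.max_trfs_per_profile} "
      f"T-RFs per profile, {report.removed_below_pdt} peaks below threshold, "
      f"{report.removed_out_of_range} outside the range")
# Every example peak is a real signal inside the range, so nothing is removed.
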