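import pytest
from hypothesis import HealthCheck, settings

from trflptools import Peak, Profile

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_profile(name, sizes, heights=None, areas=None):
    """Profile with given sizes; heights/areas default to 100/1000."""
    sizes = sorted(sizes)
    heights = heights if heights is not None else [100.0] * len(sizes)
    areas = areas if areas is not None else [1000.0] * len(sizes)
    order = sorted(range(len(sizes)), key=lambda i: sizes[i])
    return Profile(
        name,
        tuple(Peak(sizes[i], float(heights[i]), float(areas[i])) for i in order),
    )


# The six-profile example peak table: three samples in duplicate, at most
# three fragments each.  Sample x.1 of samples 1-3 share identical loadings.
TABLE1_ROWS = [
    ["Sample Name", "Sample 1.1", "Sample 1.2", "Sample 2.1", "Sample 2.2",
     "Sample 3.1", "Sample 3.2"],
    ["T-RF 1", "1", "1", "1", "1", "1", "1"],
    ["T-RF 2", "1", "1", "1", "1", "1", "1"],
    ["T-RF 3", "0", "1", "1", "1", "0", "0"],
    ["Size 1", "167.78", "167.75", "167.78", "167.87", "167.78", "167.88"],
    ["Size 2", "300", "299.92", "300", "299.84", "300", "299.92"],
    ["Size 3", "", "478.02", "478.24", "478.23", "", ""],
    ["Height 1", "900", "578", "900", "426", "900", "362"],
    ["Height 2", "640", "434", "640", "331", "640", "278"],
    ["Height 3", "", "720", "966", "488", "", ""],
    ["Area 1", "10798", "7164", "10798", "5293", "10798", "4393"],
    ["Area 2", "7376", "4869", "7376", "3807", "7376", "3129"],
    ["Area 3", "", "11992", "15617", "7958", "", ""],
]


def table1_text(rows=None):
    return "\n".join("\t".join(r) for r in (rows or TABLE1_ROWS)) + "\n"


@pytest.fixture
def table1_path(tmp_path):
    path = tmp_path / "table1.tsv"
    path.write_text(table1_text())
    return path


# Worked alignment examples: per-profile fragment sizes.
TABLE4_PROFILES = {
    "Sample 1": [207.43, 208.52, 433.69],
    "Sample 2": [208.26, 432.71, 433.84],
}
TABLE5_PROFILES = {
    "Sample 1": [254.11],
    "Sample 2": [253.81],
    "Sample 3": [254.87],
    "Sample 4": [254.66],
}
TABLE6_PROFILES = {
    "1": [309.61], "2": [309.30], "3": [310.31],
    "4": [310.29], "5": [311.18], "6": [310.46],
}
TABLE7_PROFILES = {
    "1": [162.99, 164.10, 166.18, 167.97],
    "2": [163.30, 164.88, 168.25],
    "3": [163.32, 164.65, 168.22],
    "4": [163.03, 164.28, 166.95, 167.77],
}


def profiles_from(table):
    return [make_profile(name, sizes) for name, sizes in table.items()]
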