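"""Worked-example values: published per-hemisphere gradient directions and
relative angles for auditory fields A1, R and CL in three macaques (two
hemispheres each), used as known inputs for the table-aggregation and
angle arithmetic checks."""

# per-hemisphere relative angles (degrees) per field
ALPHA_ROWS = {
    "A1": [137.0, 73.0, 120.0, 133.0, 121.0, 128.0],
    "R": [81.0, 140.0, 51.0, 103.0, 180.0, 148.0],
    "CL": [161.0, 113.0, 163.0, 102.0, 168.0, 158.0],
}

# published Average / Std-dev of those rows
ALPHA_SUMMARY = {
    "A1": (118.7, 23.3),
    "R": (117.2, 47.6),
    "CL": (144.2, 28.8),
}

# A1 per-hemisphere gradient directions (degrees)
A1_FREQ_DIRECTIONS = [162.0, 155.0, 175.0, 160.0, 164.0, 175.0]  # mean 165.2
A1_RATE_DIRECTIONS = [25.0, 82.0, 56.0, 66.0, 43.0, 47.0]  # mean 53.2
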