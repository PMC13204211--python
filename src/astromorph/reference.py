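"""Reference cohort constants.

Global medians/IQRs of the six descriptors over a pooled reference cohort of
human striatal astrocytes, per-profile medians where available, and the
above/below signature table defining the six morphometric profiles.  These
values serve as distribution centers for the synthetic cohort generator and
as consistency fixtures; they are not recomputed by the pipeline.
"""

from __future__ import annotations

from .types import METRIC_NAMES

#: Pooled global median per metric.
GLOBAL_MEDIANS = {
    "max_process_length": 33.0,
    "total_intersections": 1783.0,
    "terminal_primary_ratio": 1.96,
    "soma_size": 118.8,
    "length_soma_ratio": 0.25,
    "territory_size": 253.5,
}

#: Pooled 25th-75th percentile interval per metric.
GLOBAL_IQRS = {
    "max_process_length": (22.86, 36.78),
    "total_intersections": (910.25, 3183.0),
    "terminal_primary_ratio": (1.3, 2.19),
    "soma_size": (89.7, 165.72),
    "length_soma_ratio": (0.13, 0.37),
    "territory_size": (209.46, 424.22),
}

#: Published per-profile medians (only the reported metrics appear).
PROFILE_MEDIANS = {
    1: {
        "max_process_length": 20.3,
        "total_intersections": 918.0,
        "soma_size": 115.1,
        "territory_size": 220.5,
    },
    2: {
        "max_process_length": 16.8,
        "total_intersections": 522.0,
        "soma_size": 202.6,
        "territory_size": 240.8,
    },
    3: {
        "max_process_length": 36.4,
        "total_intersections": 3425.0,
        "soma_size": 184.2,
        "territory_size": 512.2,
    },
    4: {
        "max_process_length": 34.0,
        "total_intersections": 3385.0,
        "soma_size": 103.9,
        "territory_size": 382.5,
        "length_soma_ratio": 0.4,
    },
    5: {
        "max_process_length": 28.9,
        "total_intersections": 1724.0,
        "soma_size": 69.85,
        "territory_size": 189.0,
        "length_soma_ratio": 0.5,
    },
    6: {
        "max_process_length": 39.9,
        "total_intersections": 2888.0,
        "soma_size": 109.9,
        "territory_size": 327.0,
        "length_soma_ratio": 0.4,
    },
}

_A, _B = "above", "below"

#: Profile signature table: side of the global median per metric, in
#: METRIC_NAMES order.  Profiles 4 and 6 share a pattern and are told apart
#: by a rank-based disambiguator (see :mod:`astromorph.profiling`).
TABLE_PATTERNS = {
    1: (_B, _B, _B, _B, _B, _B),
    2: (_B, _B, _B, _A, _B, _B),
    3: (_A, _A, _B, _A, _B, _A),
    4: (_A, _A, _A, _B, _A, _A),
    5: (_B, _B, _B, _B, _A, _B),
    6: (_A, _A, _A, _B, _A, _A),
}

assert all(len(p) == len(METRIC_NAMES) for p in TABLE_PATTERNS.values())
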