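"""Shared constants: region ordering, frequency bands, metric ordering."""

from __future__ import annotations

#: Fixed region ordering used everywhere a region axis appears.
REGION_ORDER: tuple[str, ...] = ("MTL", "PFC", "OFC")

#: Trial conditions.
CONDITIONS: tuple[str, ...] = ("identity", "spatial", "temporal")

#: Frequency bands in Hz, half-open intervals [low, high) so a shared
#: printed edge (e.g. 8 Hz) is counted once, in the upper band.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 80.0),
    "high_gamma": (80.0, 200.0),
}

#: Fixed node-metric ordering; combined with REGION_ORDER this defines the
#: 27-value feature layout (region-major).
METRIC_ORDER: tuple[str, ...] = (
    "degree",
    "in_degree",
    "out_degree",
    "strength",
    "in_strength",
    "out_strength",
    "clustering_coefficient",
    "betweenness_centrality",
    "eigenvector_centrality",
)

#: Column names of the 27-value region-by-metric feature vector.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{region}.{metric}" for region in REGION_ORDER for metric in METRIC_ORDER
)
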