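"""Fixed study constants: age grouping, the WHO world standard population, exposure names.

The analysis uses 17 five-year age groups with an open-ended 80+ top group.
The WHO 2000-2025 world standard population (Ahmad et al., GPE discussion
paper 31) is distributed on 18 groups (80-84 and 85+ separate); the packaged
weights collapse the top two by summing, to match the 17-group scheme.
Weights are stored as the published percentages and normalized to unit sum
before use.  Alternative standards can be loaded from a YAML file with the
same age-group keys.
"""

from __future__ import annotations

import importlib.resources

import yaml

AGE_GROUPS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80+",
)

SEXES: tuple[str, ...] = ("M", "F")

# WHO world standard 2000-2025, percent of total population; 80+ = 0.91 (80-84)
# + 0.635 (85+, itself the sum of the published 85-89 ... 100+ groups).
WHO_WORLD_STANDARD: dict[str, float] = {
    "0-4": 8.86, "5-9": 8.69, "10-14": 8.60, "15-19": 8.47, "20-24": 8.22,
    "25-29": 7.93, "30-34": 7.61, "35-39": 7.15, "40-44": 6.59, "45-49": 6.04,
    "50-54": 5.37, "55-59": 4.55, "60-64": 3.72, "65-69": 2.96, "70-74": 2.21,
    "75-79": 1.52, "80+": 1.545,
}

#: Continuous built/social-environment exposures plus the binary transit flag.
EXPOSURE_NAMES: tuple[str, ...] = (
    "nearest_neighbor_distance",   # area-weighted mean nearest neighbor distance (m)
    "patch_density",               # urban-fragmentation measure
    "circuity",                    # average street circuity
    "street_length_avg",           # average street segment length (m)
    "intersection_density",        # intersections per km2 of built-up area
    "street_node_avg",             # average street segments per node
    "population_density",          # inhabitants per km2
    "transit_presence",            # BRT or rail transit present (0/1)
    "travel_delay_index",          # urban traffic congestion index
    "gdp_per_capita",              # US$
    "social_environment_index",    # composite, higher = better social environment
)

BINARY_EXPOSURES: tuple[str, ...] = ("transit_presence",)

#: The interrelated street-layout variables used in the sensitivity analysis.
STREET_LAYOUT_VARS: tuple[str, ...] = (
    "street_length_avg", "intersection_density", "street_node_avg", "circuity",
)

MOTORIZATION_COL = "moto_per_1000"

#: Road-user groups that specific road-traffic ICD-10 codes map to.
ROAD_USER_GROUPS: tuple[str, ...] = (
    "motorcyclist", "pedestrian", "bicyclist", "car_occupant", "other_rt",
)


def load_standard_population(path=None) -> dict[str, float]:
    """Return age-group -> weight, from ``path`` or the packaged WHO standard.

    Weights must be positive and cover all 17 age groups; they are returned
    as stored (un-normalized).
    """
    if path is None:
        ref = importlib.resources.files("motomort").joinpath(
            "data/standard_population.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    weights = {str(k): float(v) for k, v in raw["weights"].items()}
    missing = [g for g in AGE_GROUPS if g not in weights]
    if missing:
        raise ValueError(f"standard population missing age groups: {missing}")
    bad = [g for g, w in weights.items() if not w > 0]
    if bad:
        raise ValueError(f"standard population weights must be > 0: {bad}")
    return {g: weights[g] for g in AGE_GROUPS}
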