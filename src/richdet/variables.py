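"""Registry of the 19 environmental covariates used in the richness analysis.

Each variable carries a hypothesis category (one of the five classic
richness hypotheses: water-energy dynamics, ambient energy, productivity,
environmental stability, habitat heterogeneity) and a scale-transform flag.
Strictly positive continuous variables enter the analysis on the log10
scale; signed variables (temperature levels stored in 0.1 °C, which drop
below zero in cold regions) and the categorical land-cover code pass
through untransformed.

Per-stratum calibration targets (mean, SD on the raw measurement scale)
are given for three regions modelled on the Eastern Monsoon (EMR),
Northwestern Arid (NAR) and Qinghai-Tibetan Plateau (QTR) macro-regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CATEGORIES = (
    "water_energy",
    "ambient_energy",
    "productivity",
    "stability",
    "heterogeneity",
)


@dataclass(frozen=True)
class VariableSpec:
    """Static description of one environmental covariate."""

    name: str
    category: str
    transform: str  # "log10" or "none"
    unit: str = ""
    categorical: bool = False


VARIABLES: tuple[VariableSpec, ...] = (
    # water-energy dynamics
    VariableSpec("mean_annual_precipitation", "water_energy", "log10", "mm"),
    VariableSpec("precip_wettest_quarter", "water_energy", "log10", "mm"),
    VariableSpec("precip_driest_quarter", "water_energy", "log10", "mm"),
    VariableSpec("mean_annual_dryness", "water_energy", "log10", "ratio"),
    # ambient energy: temperature levels are stored in 0.1 degC and can be
    # negative, so they stay on the raw scale
    VariableSpec("mean_annual_temperature", "ambient_energy", "none", "0.1degC"),
    VariableSpec("max_temp_warmest_month", "ambient_energy", "log10", "0.1degC"),
    VariableSpec("min_temp_coldest_month", "ambient_energy", "none", "0.1degC"),
    VariableSpec("annual_potential_evapotranspiration", "ambient_energy", "log10", "mm"),
    # productivity
    VariableSpec("annual_actual_evapotranspiration", "productivity", "log10", "mm"),
    VariableSpec("net_primary_productivity", "productivity", "log10", "gC/m2/a"),
    VariableSpec("ndvi", "productivity", "log10", "index*1000"),
    # environmental stability
    VariableSpec("mean_diurnal_range", "stability", "log10", "0.1degC"),
    VariableSpec("temperature_seasonality", "stability", "log10", ""),
    VariableSpec("temperature_annual_range", "stability", "log10", "0.1degC"),
    VariableSpec("precipitation_seasonality", "stability", "log10", "CV"),
    # habitat heterogeneity
    VariableSpec("elevational_range", "heterogeneity", "log10", "m"),
    VariableSpec("mean_elevation", "heterogeneity", "log10", "m"),
    VariableSpec("main_land_cover_type", "heterogeneity", "none", "class", True),
    VariableSpec("n_land_cover_types", "heterogeneity", "log10", "count"),
)

VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in VARIABLES)
SPEC_BY_NAME: dict[str, VariableSpec] = {v.name: v for v in VARIABLES}
CATEGORY_OF: dict[str, str] = {v.name: v.category for v in VARIABLES}
TRANSFORM_OF: dict[str, str] = {v.name: v.transform for v in VARIABLES}

# Per-region (mean, SD) calibration targets on the raw measurement scale.
# mean_annual_dryness is derived downstream as MAP/PET rather than drawn,
# and main_land_cover_type is a categorical code without moment targets.
REGION_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "EMR": {
        "mean_annual_precipitation": (1029.1, 448.9),
        "precip_wettest_quarter": (522.7, 180.8),
        "precip_driest_quarter": (70.4, 59.1),
        "mean_annual_temperature": (140.5, 49.6),
        "max_temp_warmest_month": (299.5, 28.1),
        "min_temp_coldest_month": (-34.9, 92.7),
        "annual_potential_evapotranspiration": (1091.4, 130.7),
        "net_primary_productivity": (488.6, 208.8),
        "annual_actual_evapotranspiration": (780.5, 232.3),
        "ndvi": (527.6, 98.5),
        "temperature_annual_range": (334.4, 83.9),
        "mean_diurnal_range": (95.4, 20.0),
        "temperature_seasonality": (8522.7, 2573.9),
        "precipitation_seasonality": (78.7, 23.0),
        "elevational_range": (1024.8, 812.1),
        "mean_elevation": (541.7, 609.4),
        "n_land_cover_types": (6.4, 2.1),
    },
    "NAR": {
        "mean_annual_precipitation": (253.6, 136.6),
        "precip_wettest_quarter": (158.8, 97.0),
        "precip_driest_quarter": (9.1, 7.7),
        "mean_annual_temperature": (54.5, 32.3),
        "max_temp_warmest_month": (274.9, 29.8),
        "min_temp_coldest_month": (-189.8, 39.6),
        "annual_potential_evapotranspiration": (952.1, 134.3),
        "net_primary_productivity": (129.1, 79.4),
        "annual_actual_evapotranspiration": (258.8, 137.8),
        "ndvi": (303.8, 163.2),
        "temperature_annual_range": (464.7, 31.3),
        "mean_diurnal_range": (130.5, 10.6),
        "temperature_seasonality": (11971.4, 1243.9),
        "precipitation_seasonality": (90.6, 22.6),
        "elevational_range": (1884.0, 1533.8),
        "mean_elevation": (1308.9, 515.4),
        "n_land_cover_types": (6.8, 2.4),
    },
    "QTR": {
        "mean_annual_precipitation": (483.4, 249.3),
        "precip_wettest_quarter": (293.0, 130.8),
        "precip_driest_quarter": (11.0, 9.2),
        "mean_annual_temperature": (10.0, 35.7),
        "max_temp_warmest_month": (162.8, 30.4),
        "min_temp_coldest_month": (-178.5, 48.6),
        "annual_potential_evapotranspiration": (767.1, 109.3),
        "net_primary_productivity": (225.3, 195.7),
        "annual_actual_evapotranspiration": (485.9, 194.9),
        "ndvi": (346.0, 167.3),
        "temperature_annual_range": (341.3, 38.2),
        "mean_diurnal_range": (137.6, 14.8),
        "temperature_seasonality": (7103.1, 1154.4),
        "precipitation_seasonality": (100.5, 17.9),
        "elevational_range": (3060.8, 1211.3),
        "mean_elevation": (4029.8, 842.7),
        "n_land_cover_types": (7.0, 2.2),
    },
}
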