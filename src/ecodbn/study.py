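"""Variable schema of the Gulf of Mexico annual ecosystem table.

The analysis this package implements was designed around a 32-year table
(1984–2015) of 28 annual ecosystem components: the Atlantic Multidecadal
Oscillation index, three regional shelf sea-surface-temperature series
(Texas, Louisiana, west Florida), six physiochemical pressures (riverine
total nitrogen and phosphorus, four seasonal bottom-water dissolved-oxygen
series), net primary production, two zooplankton biovolume surveys,
fourteen stock-productivity series (recruitment deviations from stock
assessments) and a brown pelican abundance index.  Eighteen of these — the
biological components — are the prediction targets of the model
comparison; the climate and physiochemical series are drivers.

This module only declares that schema, so a user with the original table
(as CSV with a ``year`` column and these exact variable names) can load it
with :func:`ecodbn.read_table` and full metadata.
"""

from __future__ import annotations

from .timeseries_io import VariableDescriptor


def study_schema() -> tuple[VariableDescriptor, ...]:
    """Descriptors for the 28 Gulf of Mexico ecosystem components."""
    climate = [
        VariableDescriptor("AMO", "climate"),
        VariableDescriptor("SST TX", "climate", sst_region_flag=True),
        VariableDescriptor("SST LA", "climate", sst_region_flag=True),
        VariableDescriptor("SST FL", "climate", sst_region_flag=True),
    ]
    physio = [
        VariableDescriptor(n, "physiochemical")
        for n in (
            "TN", "TP", "Summer LA DO", "Summer TX DO", "Fall LA DO", "Fall TX DO"
        )
    ]
    production = [
        VariableDescriptor("NPP", "primary_production", predicted_flag=True)
    ]
    populations = [
        VariableDescriptor("Spring zooplankton", "population_estimate", predicted_flag=True),
        VariableDescriptor("Fall zooplankton", "population_estimate", predicted_flag=True),
        VariableDescriptor("Brown pelican", "population_estimate", predicted_flag=True),
    ]
    stocks = [
        VariableDescriptor(n, "stock_productivity", predicted_flag=True)
        for n in (
            "Pink shrimp", "Brown shrimp", "White shrimp", "Menhaden", "Cobia",
            "Gag grouper", "Red grouper", "Red snapper", "Spanish mackerel",
            "Greater amberjack", "King mackerel", "Gray triggerfish",
            "Vermillion snapper", "Tilefish",
        )
    ]
    return tuple(climate + physio + production + populations + stocks)
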