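"""Readout statistics: ΔF/F0, replicate summaries, selectivity, analyte panel.

ΔF/F0 = (F - F0)/F0, where F0 is the baseline (DI-water control) intensity
and F the intensity after analyte addition, both read at a single fixed
emission wavelength (1202 nm by default).  Selectivity for serotonin over
dopamine is the ratio of the two ΔF/F0 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import (
    PROTOCOL_CONCENTRATION_UM,
    READOUT_WAVELENGTH_NM,
    FluorescenceSpectrum,
    Landscape,
    NoiseModel,
)
from .sequences import SensorSequence


@dataclass
class ResponseMeasurement:
    """Replicate ΔF/F0 readouts for one (sensor, analyte, concentration)."""

    sensor: str
    analyte: str
    concentration_um: float
    replicates: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate is required")
        self.mean, self.sd = summarize_replicates(self.replicates)


@dataclass(frozen=True)
class SelectivityResult:
    """Serotonin-over-dopamine selectivity of one sensor."""

    sensor: str
    dff0_5ht: float
    dff0_da: float

    @property
    def ratio(self) -> float:
        if self.dff0_da == 0:
            raise ZeroDivisionError("selectivity undefined for zero DA response")
        return self.dff0_5ht / self.dff0_da


def intensity_at(spectrum: FluorescenceSpectrum, wavelength_nm: float) -> float:
    """Intensity at the grid sample nearest to ``wavelength_nm``.

    A fixed-wavelength read of the nearest sample, not a local peak fit;
    queries outside the grid raise.
    """
    grid = spectrum.wavelengths
    if not grid[0] <= wavelength_nm <= grid[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid [{grid[0]}, {grid[-1]}]"
        )
    return float(spectrum.intensities[int(np.abs(grid - wavelength_nm).argmin())])


def delta_f_over_f0(f: float, f0: float) -> float:
    """Relative fluorescence change (F - F0)/F0; requires F0 > 0."""
    if f0 <= 0:
        raise ValueError("baseline intensity F0 must be positive")
    return (f - f0) / f0


def selectivity_ratio(dff0_5ht: float, dff0_da: float, sensor: str = "") -> SelectivityResult:
    """5HT/DA selectivity; raises (never returns ±inf) for zero DA response."""
    result = SelectivityResult(sensor=sensor, dff0_5ht=dff0_5ht, dff0_da=dff0_da)
    result.ratio  # validate eagerly
    return result


def fold_improvement(new: float, reference: float) -> float:
    """How many times larger the evolved statistic is than the reference."""
    if reference == 0:
        raise ValueError("reference statistic must be nonzero")
    return new / reference


def summarize_replicates(replicates: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation; sd=0 for n=1."""
    if len(replicates) == 0:
        raise ValueError("empty replicate list")
    mean = float(np.mean(replicates))
    sd = float(np.std(replicates, ddof=1)) if len(replicates) > 1 else 0.0
    return mean, sd


def spectrum_response(
    landscape: Landscape,
    seq: SensorSequence | str,
    analyte: str,
    concentration_um: float,
    wavelength_nm: float = READOUT_WAVELENGTH_NM,
) -> float:
    """ΔF/F0 computed the instrument's way: two spectra, one wavelength."""
    baseline = landscape.baseline_spectrum()
    after = landscape.simulate_spectrum(seq, analyte, concentration_um)
    return delta_f_over_f0(
        intensity_at(after, wavelength_nm), intensity_at(baseline, wavelength_nm)
    )


def analyte_panel(
    landscape: Landscape,
    noise: NoiseModel,
    sensor: SensorSequence,
    analytes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Multi-analyte screen of one sensor at protocol concentrations.

    Each analyte is measured in triplicate at 100 µM (10 µM for uric acid,
    whose stock is solubility-limited), plus a DI-water control row with
    ΔF/F0 = 0 by construction.  Rows are deterministic per (sensor, analyte)
    regardless of the order analytes are listed in.
    """
    if analytes is None:
        analytes = landscape.analytes
    unknown = set(analytes) - set(landscape.analytes)
    if unknown:
        raise KeyError(f"unknown analytes: {sorted(unknown)}")
    rows = []
    for analyte in analytes:
        conc = PROTOCOL_CONCENTRATION_UM.get(analyte, 100.0)
        m = landscape.simulate_measurement(noise, sensor, analyte, conc)
        rows.append(_panel_row(m))
    water = ResponseMeasurement(
        sensor=sensor.name or sensor.bases,
        analyte="DI-water",
        concentration_um=0.0,
        replicates=[0.0] * noise.replicate_count,
    )
    rows.append(_panel_row(water))
    return pd.DataFrame(rows)


def _panel_row(m: ResponseMeasurement) -> dict:
    row = {
        "sensor": m.sensor,
        "analyte": m.analyte,
        "conc_uM": m.concentration_um,
    }
    row.update({f"rep{i + 1}": r for i, r in enumerate(m.replicates)})
    row["mean_dFF0"] = m.mean
    row["sd_dFF0"] = m.sd
    return row


def panel_selectivity(panel: pd.DataFrame) -> SelectivityResult:
    """5HT/DA selectivity from a panel table's triplicate means."""
    sensor = str(panel["sensor"].iloc[0])
    by_analyte = panel.set_index("analyte")["mean_dFF0"]
    return selectivity_ratio(
        float(by_analyte["5HT"]), float(by_analyte["DA"]), sensor=sensor
    )


def measurements_to_frame(measurements: list[ResponseMeasurement]) -> pd.DataFrame:
    """Long-format CSV-ready table (sensor, analyte, conc_uM, rep, dFF0)."""
    records = [
        {
            "sensor": m.sensor,
            "analyte": m.analyte,
            "conc_uM": m.concentration_um,
            "rep": i + 1,
            "dFF0": r,
        }
        for m in measurements
        for i, r in enumerate(m.replicates)
    ]
    return pd.DataFrame.from_records(records)


def is_finite_response(x: float) -> bool:
    return math.isfinite(x)
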