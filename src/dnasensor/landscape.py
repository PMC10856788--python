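"""Synthetic sequence-to-fluorescence landscape standing in for the wet-lab assay.

The ground truth maps a (sensor sequence, analyte) pair to a saturating
relative fluorescence change ΔF/F0 (read at a single near-infrared emission
wavelength).  The model is additive over variable-region position-base
weights, with optional sparse pairwise epistasis, a per-analyte offset, and
a floor at -1 (fluorescence cannot drop below zero intensity).  Calibration
anchors pin the original sensor's serotonin response at 0.949 and its
serotonin/dopamine selectivity at 0.508, the values the assay reports for
that sequence, so simulated campaigns start from the published operating
point.

Concentration dependence follows a Hill isotherm with a per-(sequence,
analyte) dissociation constant drawn near 10 µM; measurements add
multiplicative Gaussian replicate noise (triplicates by default).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .sequences import (
    ALPHABET,
    KNOWN_SENSORS,
    VARIABLE_LENGTH,
    SensorSequence,
    validate_sequence,
)

DEFAULT_ANALYTES = ("5HT", "DA", "Ach", "GABA", "Glu", "UA", "AA")

#: Protocol concentration per analyte, µM (uric acid is capped by solubility).
PROTOCOL_CONCENTRATION_UM = {a: 100.0 for a in DEFAULT_ANALYTES}
PROTOCOL_CONCENTRATION_UM["UA"] = 10.0

READOUT_WAVELENGTH_NM = 1202.0

# Baseline emission: Gaussian peaks standing in for nanotube chirality bands.
# Only the readout peak responds to analyte; the others are kept narrow enough
# that their tails at the readout wavelength are numerically negligible.
_BASELINE_PEAKS = (  # (center nm, width nm, amplitude a.u.)
    (1000.0, 10.0, 600.0),
    (1130.0, 9.0, 800.0),
    (READOUT_WAVELENGTH_NM, 8.0, 1000.0),
    (1270.0, 9.0, 500.0),
)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class CalibrationError(ValueError):
    """Anchor constraints are contradictory or infeasible."""


@dataclass(frozen=True)
class Anchor:
    """Pin true_response(sequence, analyte) to a target value.

    ``kd_um`` optionally fixes the dissociation constant of that pair as well
    (used for the original sensor, whose serotonin K_d is known).
    """

    bases: str
    analyte: str
    target: float
    kd_um: float | None = None


DEFAULT_ANCHORS = (
    Anchor(KNOWN_SENSORS["original"], "5HT", 0.949, kd_um=11.6),
    # Selectivity 5HT/DA = 0.508 for the original sensor fixes its DA response.
    Anchor(KNOWN_SENSORS["original"], "DA", 0.949 / 0.508),
)


@dataclass
class NoiseModel:
    """Multiplicative Gaussian replicate noise for simulated measurements."""

    relative_sd: float = 0.05
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class FluorescenceSpectrum:
    """Emission spectrum on a fixed wavelength grid (arbitrary units)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    sensor: str = ""
    analyte: str = "baseline"
    concentration_um: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


def _stable_hash(*parts: object) -> int:
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _onehot_indices(seq: SensorSequence) -> np.ndarray:
    var = seq.variable_region
    return np.fromiter(
        (i * 4 + _BASE_INDEX[b] for i, b in enumerate(var)), dtype=np.intp, count=len(var)
    )


@dataclass
class Landscape:
    """Calibrated ground-truth (sequence, analyte) → ΔF/F0 map.

    Parameters
    ----------
    seed:
        Drives every random draw (weights, epistasis, K_d values); identical
        seeds give identical landscapes.
    analytes:
        Panel of analytes the model knows.
    weight_sd:
        Std-dev of position-base weights for the two neurotransmitters the
        campaign optimises against (serotonin, dopamine), response units.
    minor_weight_sd / minor_offset:
        Scale and baseline for the low-response panel analytes.
    epistasis_density:
        Expected fraction of variable-region position pairs carrying a
        pairwise interaction term (0 = purely additive).
    epistasis_sd:
        Std-dev of the pairwise interaction coefficients.
    anchors:
        Calibration constraints applied after the random draw.
    kd_log_sd:
        Log-space spread of per-(sequence, analyte) dissociation constants
        around ``kd_median_um``.
    """

    seed: int = 0
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    weight_sd: float = 0.15
    minor_weight_sd: float = 0.02
    minor_offset: float = 0.05
    epistasis_density: float = 0.0
    epistasis_sd: float = 0.05
    anchors: tuple[Anchor, ...] = DEFAULT_ANCHORS
    kd_median_um: float = 10.0
    kd_log_sd: float = 0.3

    _weights: dict[str, np.ndarray] = field(init=False, repr=False)
    _epistasis: dict[str, list[tuple[int, int, int, int, float]]] = field(
        init=False, repr=False
    )
    _offsets: dict[str, float] = field(init=False, repr=False)
    _anchor_kd: dict[tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        major = {"5HT", "DA", "AA"}
        self._weights = {}
        self._epistasis = {}
        self._offsets = {}
        for analyte in self.analytes:
            sd = self.weight_sd if analyte in major else self.minor_weight_sd
            self._weights[analyte] = rng.normal(0.0, sd, size=(VARIABLE_LENGTH, 4))
            pairs: list[tuple[int, int, int, int, float]] = []
            if self.epistasis_density > 0:
                for i in range(VARIABLE_LENGTH):
                    for j in range(i + 1, VARIABLE_LENGTH):
                        if rng.random() < self.epistasis_density:
                            pairs.append(
                                (
                                    i,
                                    j,
                                    int(rng.integers(4)),
                                    int(rng.integers(4)),
                                    float(rng.normal(0.0, self.epistasis_sd)),
                                )
                            )
            self._epistasis[analyte] = pairs
            if analyte in major:
                self._offsets[analyte] = float(rng.normal(0.6 if analyte == "AA" else 1.0, 0.1))
            else:
                self._offsets[analyte] = float(rng.normal(self.minor_offset, 0.01))
        self._anchor_kd = {}
        self._calibrate()

    # -- calibration -----------------------------------------------------

    def _calibrate(self) -> None:
        """Solve per-analyte offsets so every anchor holds exactly.

        One anchor per (sequence, analyte) pair shifts that analyte's offset;
        two anchors on the same analyte are feasible only if they demand the
        same shift.  Re-running calibration is a no-op (idempotent).
        """
        shifts: dict[str, float] = {}
        for anchor in self.anchors:
            if anchor.analyte not in self._weights:
                raise CalibrationError(f"anchor for unknown analyte {anchor.analyte!r}")
            if anchor.target < -1:
                raise CalibrationError("anchor target below the -1 response floor")
            seq = validate_sequence(anchor.bases)
            raw = self._raw_response(seq, anchor.analyte)
            shift = anchor.target - raw - self._offsets[anchor.analyte]
            prev = shifts.get(anchor.analyte)
            if prev is not None and abs(prev - shift) > 1e-12:
                raise CalibrationError(
                    f"contradictory anchors for analyte {anchor.analyte!r}"
                )
            shifts[anchor.analyte] = shift
            if anchor.kd_um is not None:
                if anchor.kd_um <= 0:
                    raise CalibrationError("anchored K_d must be positive")
                self._anchor_kd[(anchor.bases, anchor.analyte)] = anchor.kd_um
        for analyte, shift in shifts.items():
            self._offsets[analyte] += shift

    # -- ground truth ----------------------------------------------------

    def _raw_response(self, seq: SensorSequence, analyte: str) -> float:
        idx = _onehot_indices(seq)
        total = float(self._weights[analyte].ravel()[idx].sum())
        var = seq.variable_region
        for i, j, bi, bj, w in self._epistasis[analyte]:
            if _BASE_INDEX[var[i]] == bi and _BASE_INDEX[var[j]] == bj:
                total += w
        return total

    def true_response(self, seq: SensorSequence | str, analyte: str) -> float:
        """Saturating ΔF/F0 of a sensor for one analyte (noise-free).

        This is the plateau of the dose-response curve; a measurement at a
        finite concentration is attenuated by the Hill fraction.
        """
        if analyte not in self._weights:
            raise KeyError(f"unknown analyte {analyte!r}")
        if isinstance(seq, str):
            seq = validate_sequence(seq)
        return max(self._raw_response(seq, analyte) + self._offsets[analyte], -1.0)

    def true_response_batch(
        self, seqs: list[SensorSequence], analyte: str
    ) -> np.ndarray:
        """Vectorised :meth:`true_response` over a library (additive part)."""
        if analyte not in self._weights:
            raise KeyError(f"unknown analyte {analyte!r}")
        flat = self._weights[analyte].ravel()
        idx = np.stack([_onehot_indices(s) for s in seqs])
        values = flat[idx].sum(axis=1) + self._offsets[analyte]
        if self._epistasis[analyte]:
            values = values + np.array(
                [
                    sum(
                        w
                        for i, j, bi, bj, w in self._epistasis[analyte]
                        if _BASE_INDEX[s.variable_region[i]] == bi
                        and _BASE_INDEX[s.variable_region[j]] == bj
                    )
                    for s in seqs
                ]
            )
        return np.maximum(values, -1.0)

    # -- concentration dependence ---------------------------------------

    def kd_um(self, seq: SensorSequence | str, analyte: str) -> float:
        """Dissociation constant of the (sensor, analyte) pair, µM.

        Anchored pairs use their pinned value; otherwise K_d is a
        deterministic log-normal draw around the ~10 µM regime the assay
        reports across the sensor lineage.
        """
        bases = seq.bases if isinstance(seq, SensorSequence) else seq
        pinned = self._anchor_kd.get((bases, analyte))
        if pinned is not None:
            return pinned
        rng = np.random.default_rng(_stable_hash(self.seed, "kd", bases, analyte))
        return float(self.kd_median_um * np.exp(rng.normal(0.0, self.kd_log_sd)))

    def hill_fraction(
        self, seq: SensorSequence | str, analyte: str, concentration_um: float
    ) -> float:
        """Fractional saturation c/(K_d + c) at a given concentration."""
        if concentration_um < 0:
            raise ValueError("concentration must be >= 0")
        kd = self.kd_um(seq, analyte)
        return concentration_um / (kd + concentration_um)

    def response_at(
        self, seq: SensorSequence | str, analyte: str, concentration_um: float
    ) -> float:
        """Noise-free ΔF/F0 at a finite analyte concentration."""
        return self.true_response(seq, analyte) * self.hill_fraction(
            seq, analyte, concentration_um
        )

    # -- simulated instrument -------------------------------------------

    def baseline_spectrum(
        self, wavelengths: np.ndarray | None = None
    ) -> FluorescenceSpectrum:
        if wavelengths is None:
            wavelengths = np.arange(950.0, 1351.0, 1.0)
        wavelengths = np.asarray(wavelengths, dtype=float)
        intensities = np.zeros_like(wavelengths)
        for center, width, amplitude in _BASELINE_PEAKS:
            intensities += amplitude * np.exp(
                -0.5 * ((wavelengths - center) / width) ** 2
            )
        return FluorescenceSpectrum(wavelengths, intensities)

    def simulate_spectrum(
        self,
        seq: SensorSequence | str,
        analyte: str,
        concentration_um: float,
        wavelengths: np.ndarray | None = None,
    ) -> FluorescenceSpectrum:
        """Emission spectrum after analyte addition (noise-free).

        The readout peak is scaled by ``1 + true_response * hill_fraction``;
        zero concentration returns the baseline exactly.
        """
        if concentration_um < 0:
            raise ValueError("concentration must be >= 0")
        base = self.baseline_spectrum(wavelengths)
        factor = 1.0 + self.true_response(seq, analyte) * self.hill_fraction(
            seq, analyte, concentration_um
        )
        center, width, amplitude = next(
            p for p in _BASELINE_PEAKS if p[0] == READOUT_WAVELENGTH_NM
        )
        peak = amplitude * np.exp(-0.5 * ((base.wavelengths - center) / width) ** 2)
        name = seq.name if isinstance(seq, SensorSequence) else ""
        return FluorescenceSpectrum(
            base.wavelengths,
            base.intensities + (factor - 1.0) * peak,
            sensor=name,
            analyte=analyte,
            concentration_um=concentration_um,
        )

    def simulate_measurement(
        self,
        noise: NoiseModel,
        seq: SensorSequence | str,
        analyte: str,
        concentration_um: float,
        rng: np.random.Generator | None = None,
    ):
        """Replicate ΔF/F0 readouts with multiplicative Gaussian noise.

        The replicate RNG is derived from the noise seed and the measurement
        identity (sequence, analyte, concentration), so a panel is invariant
        to the order its rows are simulated in.
        """
        from .response import ResponseMeasurement  # local import to avoid cycle

        bases = seq.bases if isinstance(seq, SensorSequence) else seq
        name = seq.name if isinstance(seq, SensorSequence) else ""
        if rng is None:
            rng = np.random.default_rng(
                _stable_hash(noise.seed, "meas", bases, analyte, concentration_um)
            )
        noiseless = self.response_at(seq, analyte, concentration_um)
        eps = rng.normal(0.0, noise.relative_sd, size=noise.replicate_count)
        replicates = noiseless * (1.0 + eps)
        return ResponseMeasurement(
            sensor=name or bases,
            analyte=analyte,
            concentration_um=concentration_um,
            replicates=list(map(float, replicates)),
        )
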