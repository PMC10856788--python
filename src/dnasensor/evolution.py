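"""Multi-round directed-evolution driver.

Each round enumerates the exact-3-substitution library around the current
parent, screens it with the surrogate ensemble (trained on a seeded sample
of simulated measurements), measures the top-20 candidates in simulated
triplicate, and promotes the best performer — highest mean serotonin ΔF/F0
for the sensitivity objective, highest 5HT/DA ratio of triplicate means for
the selectivity objective — as the next round's parent.  Saturation between
consecutive rounds is judged by a two-sided Welch t-test on the winners'
replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .ensemble import (
    EnsemblePrediction,
    OracleSurrogate,
    ResponseEnsemble,
    select_top_k,
)
from .landscape import PROTOCOL_CONCENTRATION_UM, Landscape, NoiseModel
from .response import ResponseMeasurement, summarize_replicates
from .sequences import MutantLibrary, SensorSequence, enumerate_k_mutants

OBJECTIVES = ("sensitivity", "selectivity")


@dataclass
class RoundConfig:
    """Knobs of one evolution round (defaults follow the assay protocol)."""

    objective: str = "sensitivity"
    k_mut: int = 3
    k_top: int = 20
    n_train: int = 500
    readout_wavelength_nm: float = 1202.0
    surrogate: str = "ensemble"  # or "oracle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")


@dataclass
class CandidateResult:
    """Measured outcome for one screened candidate."""

    sequence: SensorSequence
    measurements: dict[str, ResponseMeasurement]
    statistic: float


@dataclass
class RoundResult:
    round_id: int
    parent: SensorSequence
    parent_statistic: float
    top_predictions: list[EnsemblePrediction]
    candidates: list[CandidateResult]
    best: CandidateResult
    library_size: int

    @property
    def best_sequence(self) -> SensorSequence:
        return self.best.sequence

    @property
    def best_statistic(self) -> float:
        return self.best.statistic


@dataclass
class EvolutionTrace:
    rounds: list[RoundResult] = field(default_factory=list)
    saturation_p: list[float] = field(default_factory=list)

    @property
    def best_statistics(self) -> list[float]:
        return [r.best_statistic for r in self.rounds]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds):
            rows.append(
                {
                    "round": r.round_id,
                    "parent": r.parent.bases,
                    "best_seq": r.best_sequence.bases,
                    "best_stat": r.best_statistic,
                    "parent_stat": r.parent_statistic,
                    "p_saturation": self.saturation_p[i - 1] if i >= 1 else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def saturation_test(
    replicates_a, replicates_b, alpha: float = 0.05
) -> tuple[float, bool]:
    """Welch two-sample t-test between two replicate sets.

    Returns (p_value, significant); "not significant" between consecutive
    round winners is the saturation signal that further rounds are unlikely
    to help.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.pvalue), bool(result.pvalue < alpha)


def _measure_candidate(
    landscape: Landscape,
    noise: NoiseModel,
    seq: SensorSequence,
    objective: str,
) -> CandidateResult:
    conc_5ht = PROTOCOL_CONCENTRATION_UM["5HT"]
    m5ht = landscape.simulate_measurement(noise, seq, "5HT", conc_5ht)
    measurements = {"5HT": m5ht}
    if objective == "selectivity":
        conc_da = PROTOCOL_CONCENTRATION_UM["DA"]
        mda = landscape.simulate_measurement(noise, seq, "DA", conc_da)
        measurements["DA"] = mda
        if mda.mean == 0:
            raise ZeroDivisionError("zero mean DA response; ratio undefined")
        statistic = m5ht.mean / mda.mean  # ratio of triplicate means
    else:
        statistic = m5ht.mean
    return CandidateResult(sequence=seq, measurements=measurements, statistic=statistic)


def _train_surrogate(
    library: MutantLibrary,
    landscape: Landscape,
    noise: NoiseModel,
    cfg: RoundConfig,
    rng: np.random.Generator,
) -> ResponseEnsemble:
    """Fit the screening ensemble on a seeded sample of simulated assays."""
    n = min(cfg.n_train, len(library))
    idx = rng.choice(len(library), size=n, replace=False)
    train_seqs = [library.members[i] for i in idx]
    conc = PROTOCOL_CONCENTRATION_UM["5HT"]
    labels = [
        landscape.simulate_measurement(noise, s, "5HT", conc).mean for s in train_seqs
    ]
    return ResponseEnsemble(random_state=int(rng.integers(2**31))).fit(
        train_seqs, labels
    )


def run_round(
    parent: SensorSequence,
    landscape: Landscape,
    cfg: RoundConfig,
    noise: NoiseModel | None = None,
    round_id: int = 1,
    surrogate=None,
) -> RoundResult:
    """One enumerate → screen → measure → select cycle.

    The parent is re-measured alongside the candidates so fold improvements
    are computed within-round.  ``surrogate`` may be a pre-fitted model
    (``--frozen-model`` regime); by default one is trained per round, or the
    exact landscape oracle is used when ``cfg.surrogate == "oracle"``.
    """
    if noise is None:
        noise = NoiseModel(seed=cfg.seed)
    library = enumerate_k_mutants(parent, cfg.k_mut, round_id=round_id)
    if surrogate is None:
        if cfg.surrogate == "oracle":
            surrogate = OracleSurrogate(landscape, analyte="5HT")
        else:
            rng = np.random.default_rng((cfg.seed, round_id))
            surrogate = _train_surrogate(library, landscape, noise, cfg, rng)
    preds = surrogate.predict_ensemble(library.members)
    top = select_top_k(preds, cfg.k_top)
    if not top:
        raise RuntimeError("no candidate passed the classifier-consistency filter")
    candidates = [
        _measure_candidate(landscape, noise, p.sequence, cfg.objective) for p in top
    ]
    parent_stat = _measure_candidate(landscape, noise, parent, cfg.objective).statistic
    best = max(candidates, key=lambda c: (c.statistic, c.sequence.bases))
    return RoundResult(
        round_id=round_id,
        parent=parent,
        parent_statistic=parent_stat,
        top_predictions=top,
        candidates=candidates,
        best=best,
        library_size=len(library),
    )


def run_evolution(
    start: SensorSequence,
    landscape: Landscape,
    n_rounds: int,
    cfg: RoundConfig | None = None,
    noise: NoiseModel | None = None,
    early_stop: bool = False,
    alpha: float = 0.05,
) -> EvolutionTrace:
    """Chain rounds, promoting each round's winner to the next parent.

    With ``early_stop`` the campaign halts when consecutive winners are not
    significantly different (saturation); by default all rounds run and the
    saturation p-values are recorded post hoc.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    cfg = cfg or RoundConfig()
    trace = EvolutionTrace()
    parent = start
    for r in range(1, n_rounds + 1):
        result = run_round(parent, landscape, cfg, noise=noise, round_id=r)
        trace.rounds.append(result)
        if r >= 2:
            prev = trace.rounds[-2].best.measurements["5HT"].replicates
            curr = result.best.measurements["5HT"].replicates
            p, significant = saturation_test(prev, curr, alpha=alpha)
            trace.saturation_p.append(p)
            if early_stop and not significant:
                break
        parent = result.best_sequence
    return trace


def write_provenance(path: str | Path, cfg: RoundConfig, landscape: Landscape,
                     noise: NoiseModel, extra: dict | None = None) -> None:
    """Record everything needed to regenerate an output file."""
    payload = {
        "package_version": __version__,
        "round_config": asdict(cfg),
        "landscape": {
            "seed": landscape.seed,
            "analytes": list(landscape.analytes),
            "weight_sd": landscape.weight_sd,
            "minor_weight_sd": landscape.minor_weight_sd,
            "minor_offset": landscape.minor_offset,
            "epistasis_density": landscape.epistasis_density,
            "epistasis_sd": landscape.epistasis_sd,
            "kd_median_um": landscape.kd_median_um,
            "kd_log_sd": landscape.kd_log_sd,
        },
        "noise": asdict(noise),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
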