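"""Carbon-fate accounting for growth on a single two-carbon substrate.

Every carbon atom taken up as acetate ends in one of three fates:
incorporated into biomass, respired as CO2, or secreted in some other
form.  With acetate the only carbon source and no net CO2 fixation, the
acetate that disappears from the medium measures total uptake directly
(2 C per molecule).  Incorporation follows from the OD gain via the TOC
slope (mmol C per OD·L); respiration from cumulative O2 consumption via
the respiratory exchange ratio (RER = CO2 produced / O2 consumed, ~1 for
complete acetate oxidation).  The residual delta closes the ledger
exactly: delta = uptake - incorporated - respired.  All amounts are µmol
carbon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_RER = 1.0
CARBON_PER_ACETATE = 2.0


@dataclass
class GrowthExperiment:
    """Time series of a batch culture: OD, residual acetate, cumulative O2.

    times strictly increasing; o2_cum non-decreasing; od > 0.  volume_ml
    may be scalar (constant) or per-sample.
    """

    times_h: np.ndarray
    od: np.ndarray
    acetate_mM: np.ndarray
    o2_cum_umol: np.ndarray
    volume_ml: np.ndarray | float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.od = np.asarray(self.od, float)
        self.acetate_mM = np.asarray(self.acetate_mM, float)
        self.o2_cum_umol = np.asarray(self.o2_cum_umol, float)
        n = len(self.times_h)
        for name in ("od", "acetate_mM", "o2_cum_umol"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times_h")
        self.volume_ml = np.broadcast_to(np.asarray(self.volume_ml, float), (n,)).copy()
        if n >= 2 and not (np.diff(self.times_h) > 0).all():
            raise ValueError("times_h must be strictly increasing")
        if n >= 2 and not (np.diff(self.o2_cum_umol) >= -1e-12).all():
            raise ValueError("o2_cum_umol must be non-decreasing")
        if not (self.od > 0).all():
            raise ValueError("od must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.times_h)


# -- elementary conversions --------------------------------------------------


def total_carbon_uptake(acetate_consumed_umol: float) -> float:
    """µmol C from µmol acetate consumed (two carbon atoms per molecule)."""
    if acetate_consumed_umol < 0:
        raise ValueError("acetate consumed must be >= 0")
    return CARBON_PER_ACETATE * acetate_consumed_umol


def incorporated_carbon(delta_od: float, volume_l: float, toc_slope: float) -> float:
    """µmol C fixed into biomass for an OD gain: ΔOD x V[L] x slope[mmol
    C/OD·L] x 1000.  Negative ΔOD (lysis) keeps its sign."""
    if toc_slope <= 0:
        raise ValueError("toc_slope must be > 0")
    return delta_od * volume_l * toc_slope * 1000.0


def respired_carbon(o2_consumed_umol: float, rer: float = DEFAULT_RER) -> float:
    """µmol C respired as CO2: O2 consumed x RER (1 C per CO2)."""
    if rer <= 0:
        raise ValueError("rer must be > 0")
    return o2_consumed_umol * rer


# -- full accounting ---------------------------------------------------------


@dataclass
class CarbonFateResult:
    """Interval-wise and cumulative three-fate carbon ledger (µmol C).

    The interval arrays have length n_samples - 1; cumulative arrays
    include the zero starting point (length n_samples) and are the data
    behind the uptake/incorporation/respiration curves.  Fractions are of
    cumulative total uptake; with the delta included they sum to 1.
    """

    interval_uptake_C: np.ndarray
    interval_incorporated_C: np.ndarray
    interval_respired_C: np.ndarray
    interval_delta_C: np.ndarray
    cumulative_uptake_C: np.ndarray
    cumulative_incorporated_C: np.ndarray
    cumulative_respired_C: np.ndarray
    cumulative_delta_C: np.ndarray
    incorporated_fraction: float
    respired_fraction: float
    delta_fraction: float
    flagged_intervals: list[int] = field(default_factory=list)

    @property
    def total_uptake_C(self) -> float:
        return float(self.cumulative_uptake_C[-1])


def carbon_fate_accounting(
    experiment: GrowthExperiment, toc_slope: float, rer: float = DEFAULT_RER
) -> CarbonFateResult:
    """Compute the three-fate ledger between consecutive samples.

    Intervals where acetate increases (impossible consumption, e.g. an
    outlier measurement) are flagged and contribute zero uptake; a warning
    is emitted.  The ledger identity delta = uptake - incorporated -
    respired holds exactly per interval and cumulatively.
    """
    exp = experiment
    n = exp.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    uptake = np.zeros(n - 1)
    incorporated = np.zeros(n - 1)
    respired = np.zeros(n - 1)
    flagged: list[int] = []
    for i in range(n - 1):
        d_acetate_mM = exp.acetate_mM[i] - exp.acetate_mM[i + 1]
        acetate_umol = d_acetate_mM * exp.volume_ml[i]  # mM x ml = µmol
        if acetate_umol < 0:
            flagged.append(i)
            warnings.warn(
                f"acetate increased over interval {i} "
                f"({exp.times_h[i]}-{exp.times_h[i + 1]} h); excluded from uptake",
                stacklevel=2,
            )
            acetate_umol = 0.0
        uptake[i] = total_carbon_uptake(acetate_umol)
        incorporated[i] = incorporated_carbon(
            exp.od[i + 1] - exp.od[i], exp.volume_ml[i] / 1000.0, toc_slope
        )
        respired[i] = respired_carbon(
            exp.o2_cum_umol[i + 1] - exp.o2_cum_umol[i], rer
        )
    delta = uptake - incorporated - respired

    def cum(x: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(x)])

    total_up = float(uptake.sum())
    if total_up > 0:
        frac_inc = float(incorporated.sum()) / total_up
        frac_resp = float(respired.sum()) / total_up
        frac_delta = float(delta.sum()) / total_up
    else:
        frac_inc = frac_resp = frac_delta = 0.0
    return CarbonFateResult(
        interval_uptake_C=uptake,
        interval_incorporated_C=incorporated,
        interval_respired_C=respired,
        interval_delta_C=delta,
        cumulative_uptake_C=cum(uptake),
        cumulative_incorporated_C=cum(incorporated),
        cumulative_respired_C=cum(respired),
        cumulative_delta_C=cum(delta),
        incorporated_fraction=frac_inc,
        respired_fraction=frac_resp,
        delta_fraction=frac_delta,
        flagged_intervals=flagged,
    )


def write_carbon_ledger(
    result: CarbonFateResult, experiment: GrowthExperiment, path: str | Path
) -> None:
    """TSV ledger: one row per interval with the four carbon columns."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["t_start_h", "t_end_h", "uptake_C", "incorporated_C", "respired_C", "delta_C"])
        for i in range(len(result.interval_uptake_C)):
            w.writerow(
                [
                    repr(float(experiment.times_h[i])),
                    repr(float(experiment.times_h[i + 1])),
                    repr(float(result.interval_uptake_C[i])),
                    repr(float(result.interval_incorporated_C[i])),
                    repr(float(result.interval_respired_C[i])),
                    repr(float(result.interval_delta_C[i])),
                ]
            )


def carbon_summary_json(result: CarbonFateResult) -> str:
    """Cumulative totals and fractions as a JSON document."""
    return json.dumps(
        {
            "total_uptake_C_umol": result.total_uptake_C,
            "total_incorporated_C_umol": float(result.cumulative_incorporated_C[-1]),
            "total_respired_C_umol": float(result.cumulative_respired_C[-1]),
            "total_delta_C_umol": float(result.cumulative_delta_C[-1]),
            "incorporated_fraction": result.incorporated_fraction,
            "respired_fraction": result.respired_fraction,
            "delta_fraction": result.delta_fraction,
            "flagged_intervals": result.flagged_intervals,
        },
        indent=2,
    )
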