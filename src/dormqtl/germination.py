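"""Seed-dormancy traits from cumulative germination curves.

Dishes of ``n_seeds`` seeds are scored every 24 h for 7 days; the four
derived traits are

* ``G3d``  — cumulative germination percentage at 72 h after imbibition;
* ``G7d``  — maximum germination percentage, read at 168 h;
* ``T50``  — time (h) to reach germination of 50% of the *tested* seeds,
  linearly interpolated at the first upward crossing; dormant lines that
  never reach 50% are right-censored at 168 h and flagged rather than
  dropped (dropping them would delete exactly the dormancy signal);
* ``AUC``  — area under the percentage curve over [0, 168] h (%.h), taken
  as the trapezoidal integral of the piecewise-linear interpolant of the
  observed curve (a deterministic stand-in for integrating a fitted
  parametric curve; stamped into output metadata).

A t = 0 observation with fraction 0 is always prepended. If an exact 72 h
or 168 h reading is absent, the nearest prior observation is used (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("dormqtl")

CENSOR_TIME = 168.0


@dataclass
class GerminationCurve:
    """Cumulative germination fractions over time for one dish."""

    timepoints: np.ndarray  # hours, starts at 0, strictly increasing
    fractions: np.ndarray   # in [0,1], non-decreasing, fractions[0] == 0
    n_seeds: int
    line_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.timepoints[0] != 0:
            raise ValueError("curve must include a t=0 observation")
        if self.fractions[0] != 0:
            # degenerate but representable: e.g. everything germinated at once
            log.info("curve for line %s starts above zero (fraction %.3f at t=0)",
                     self.line_id, self.fractions[0])
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(np.diff(self.fractions) < 0):
            raise ValueError("fractions must be non-decreasing")
        if self.fractions[-1] > 1 or np.any(self.fractions < 0):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GerminationParams:
    """The four dormancy traits for one dish."""

    G3d: float   # %
    G7d: float   # %
    T50: float   # hours; == CENSOR_TIME when censored
    AUC: float   # %.h over [0, 168]
    t50_censored: bool
    line_id: str = ""
    replicate: int = 0


def cumulative_fractions(counts, n_seeds: int, timepoints=None,
                         line_id: str = "", replicate: int = 0) -> GerminationCurve:
    """Build a curve from cumulative germinated-seed counts.

    ``counts`` are the cumulative counts at ``timepoints`` (default 24..168
    by 24 h); a (0, 0) origin is prepended. Decreasing counts or counts
    above ``n_seeds`` indicate corrupt input and are rejected.
    """
    counts = np.asarray(counts)
    if timepoints is None:
        timepoints = 24.0 * np.arange(1, len(counts) + 1)
    timepoints = np.asarray(timepoints, dtype=float)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    if np.any(np.diff(counts) < 0):
        raise ValueError(f"decreasing cumulative counts for line {line_id!r}")
    if np.any(counts > n_seeds) or np.any(counts < 0):
        raise ValueError(f"counts outside [0, n_seeds={n_seeds}] for line {line_id!r}")
    t = np.concatenate(([0.0], timepoints))
    f = np.concatenate(([0.0], counts / n_seeds))
    return GerminationCurve(t, f, n_seeds, line_id, replicate)


def germination_params(curve: GerminationCurve) -> GerminationParams:
    """Extract G3d, G7d, T50 and AUC from one curve."""
    t, f = curve.timepoints, curve.fractions

    def frac_at(target: float, label: str) -> float:
        exact = np.flatnonzero(t == target)
        if exact.size:
            return f[exact[0]]
        prior = np.flatnonzero(t <= target)
        log.info("germination_params: no %s h reading for line %s; using t=%s h",
                 label, curve.line_id, t[prior[-1]])
        return f[prior[-1]]

    g3d = 100.0 * frac_at(72.0, "72")
    g7d = 100.0 * frac_at(168.0, "168")

    in_range = t <= CENSOR_TIME
    auc = float(np.trapezoid(100.0 * f[in_range], t[in_range]))

    cross = np.flatnonzero(f >= 0.5)
    if cross.size == 0:
        t50, censored = CENSOR_TIME, True
    else:
        k = cross[0]
        if k == 0 or f[k] == f[k - 1]:
            t50, censored = float(t[k]), False
        else:
            t50 = float(t[k - 1] + (t[k] - t[k - 1]) * (0.5 - f[k - 1]) / (f[k] - f[k - 1]))
            censored = False
    return GerminationParams(g3d, g7d, t50, auc, censored, curve.line_id, curve.replicate)


def aggregate_replicates(params: list[GerminationParams]) -> dict:
    """Per-line arithmetic mean and sample SD of each trait over replicates.

    Censored T50 replicates contribute the censoring time (168 h); the line
    is flagged when any replicate is censored.
    """
    if not params:
        raise ValueError("need at least one replicate")
    out: dict = {"line_id": params[0].line_id, "n_replicates": len(params)}
    for trait in ("G3d", "G7d", "T50", "AUC"):
        vals = np.array([getattr(p, trait) for p in params], dtype=float)
        out[trait] = float(vals.mean())
        out[f"{trait}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["t50_censored"] = any(p.t50_censored for p in params)
    return out


def traits_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-line trait table from a tidy counts frame.

    Input columns: line_id, replicate, hour, cumulative_count, n_seeds.
    Traits are extracted per replicate and then averaged (the order matters
    for T50 near censoring and is documented as this package's convention).
    """
    rows = []
    for (line_id, rep), grp in counts.groupby(["line_id", "replicate"], sort=False):
        grp = grp.sort_values("hour")
        n_seeds = int(grp["n_seeds"].iloc[0])
        curve = cumulative_fractions(grp["cumulative_count"].to_numpy(), n_seeds,
                                     grp["hour"].to_numpy(dtype=float),
                                     line_id=str(line_id), replicate=int(rep))
        rows.append(germination_params(curve))
    per_line = []
    frame = pd.DataFrame([vars(p) for p in rows])
    for line_id, grp in frame.groupby("line_id", sort=False):
        params = [rows[i] for i in grp.index]
        per_line.append(aggregate_replicates(params))
    return pd.DataFrame(per_line)
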