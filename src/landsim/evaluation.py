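"""Model-vs-observation summary statistics.

The suite mirrors common practice for judging agro-ecosystem simulators:
means and standard deviations of both series, root mean square error
expressed as a percentage of the observed mean, and the Pearson sample
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean_obs: float
    sd_obs: float
    mean_sim: float
    sd_sim: float
    rmse_pct: float
    r: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def summary_stats(observed, simulated) -> SummaryStats:
    """Paired-series statistics.

    RMSE% = 100/mean(obs) * sqrt(mean((obs-sim)^2)) (division by n inside
    the root); standard deviations use the n-1 denominator; r is Pearson.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("series must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two pairs")
    if np.isnan(obs).any() or np.isnan(sim).any():
        raise ValueError("missing values are not allowed after alignment")
    mean_obs = obs.mean()
    if mean_obs == 0.0:
        raise ZeroDivisionError("RMSE%% undefined: observed mean is zero")
    rmse_pct = 100.0 / mean_obs * np.sqrt(np.mean((obs - sim) ** 2))
    r = float(np.corrcoef(obs, sim)[0, 1])
    return SummaryStats(
        n=obs.size,
        mean_obs=float(mean_obs), sd_obs=float(obs.std(ddof=1)),
        mean_sim=float(sim.mean()), sd_sim=float(sim.std(ddof=1)),
        rmse_pct=float(rmse_pct), r=r)
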