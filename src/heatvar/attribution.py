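"""Heat-attributable deaths per summer, split into mild and extreme heat.

For each warm-season day i of year j a coefficient beta_ijT expresses the
effect of that day's exposure relative to the threshold Tref: the log
relative risk from Tref to the day's lagged exposure at the day's time
index, with beta = 0 exactly when the exposure does not exceed Tref.  The
deaths attributable to heat in year j are then

    AD_j = sum_i  y_ij * (1 - e^{-beta_ijT})

Each day's whole contribution is classified as mild heat (exposure between
Tref and the study-period 95th percentile) or extreme heat (above the 95th
percentile); the two components add up to the total exactly.

Days above Tref whose estimated beta is negative (sampling noise) are kept
as computed by default — preserving the estimator's distribution — which
can make yearly totals slightly negative; ``truncate_negative`` sets those
betas to zero instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FittedModel, tensor_contrast

__all__ = ["daily_beta", "attributable_deaths"]


def daily_beta(model: FittedModel, frame: pd.DataFrame, tref: float,
               ) -> np.ndarray:
    """Per-day log-RR from Tref to each day's lagged exposure.

    Zero exactly for days whose exposure is at or below Tref.
    """
    tm = frame["tmean_n"].to_numpy(dtype=float)
    times = frame["time"].to_numpy(dtype=float)
    betas = np.zeros(len(frame))
    hot = tm > tref
    if hot.any():
        logrr, _ = tensor_contrast(model, tm[hot], np.full(hot.sum(), tref),
                                   times[hot])
        betas[hot] = logrr
    return betas


def attributable_deaths(frame: pd.DataFrame, betas: np.ndarray, p95: float,
                        tref: float, truncate_negative: bool = False,
                        ) -> pd.DataFrame:
    """Yearly attributable-death table from per-day betas.

    Returns one row per year: year, ad_total, ad_mild, ad_extreme,
    n_mild_days, n_extreme_days.  ad_total = ad_mild + ad_extreme exactly.
    """
    if len(betas) != len(frame):
        raise ValueError("betas and frame are misaligned")
    b = np.asarray(betas, dtype=float)
    if truncate_negative:
        b = np.maximum(b, 0.0)
    tm = frame["tmean_n"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    contrib = y * (1.0 - np.exp(-b))

    mild = (tm > tref) & (tm <= p95)
    extreme = tm > p95

    rows = []
    for yr in sorted(frame["year"].unique()):
        sel = (frame["year"] == yr).to_numpy()
        rows.append({
            "year": int(yr),
            "ad_total": float(contrib[sel & (mild | extreme)].sum()),
            "ad_mild": float(contrib[sel & mild].sum()),
            "ad_extreme": float(contrib[sel & extreme].sum()),
            "n_mild_days": int((sel & mild).sum()),
            "n_extreme_days": int((sel & extreme).sum()),
        })
    return pd.DataFrame(rows)
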