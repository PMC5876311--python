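"""Convenience glue: cleaned observations -> fitted model, per vital.

Heart rates are integer-valued and ages categorical, so HR observations are
aggregated to (age, value) cells with frequency weights before fitting --
identical likelihood, much smaller working set.  Respiratory rates are
dithered and log-transformed (see :func:`vitalcentiles.gamlss.rr_preprocess`)
and fitted unaggregated on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vitalcentiles import gamlss
from vitalcentiles.distributions import BCPE, BCT

__all__ = ["prepare_observations", "fit_vital"]


def prepare_observations(clean: pd.DataFrame, vital: str, seed=0):
    """Return ``(observations, weights, log_scale)`` ready for fitting."""
    vital = vital.lower()
    age = clean["age_midpoint"].to_numpy(dtype=float)
    if vital == "hr":
        cells = (clean.groupby(["age_midpoint", "hr"]).size()
                 .reset_index(name="w"))
        obs = cells[["age_midpoint", "hr"]].to_numpy(dtype=float)
        return obs, cells["w"].to_numpy(dtype=float), False
    if vital == "rr":
        lrr = gamlss.rr_preprocess(clean["rr"].to_numpy(dtype=float), seed)
        return np.column_stack([age, lrr]), None, True
    raise ValueError("vital must be 'hr' or 'rr'")


def fit_vital(clean: pd.DataFrame, vital: str, *, seed=0, config=None,
              zeta=None, select=False) -> gamlss.CentileModel:
    """Fit one vital from a cleaned observation table.

    ``zeta`` fixes the age power; ``select=True`` runs the SBC grid search
    instead.  The RR dither seed is recorded in the returned model.
    """
    obs, weights, log_scale = prepare_observations(clean, vital, seed)
    family = BCPE if vital.lower() == "hr" else BCT
    dither_seed = seed if log_scale else None
    if select:
        return gamlss.select_model(obs, family, log_scale, config,
                                   weights=weights, dither_seed=dither_seed)
    return gamlss.fit_model(obs, family, log_scale, config, weights=weights,
                            zeta=zeta, dither_seed=dither_seed)
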