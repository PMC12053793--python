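"""Shared fixtures: tiny hand-built surveys and simulator scenario configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metapatch.spom import SimConfig


def make_survey(rows, year):
    """Build a survey table from (plot_id, dist_km, x_m, y_m, area, N) tuples."""
    df = pd.DataFrame(rows, columns=["plot_id", "dist_km", "x_m", "y_m",
                                     "suitable_area_m2", "abundance"])
    df["year"] = year
    df["causes"] = [frozenset()] * len(df)
    df["is_dune"] = True
    return df


@pytest.fixture
def toy_pair_surveys():
    """Four plots covering every candidate-pool case:

    A: vacant -> colonised; B: occupied -> extinct; C: never suitable,
    never occupied; D: occupied -> still occupied.
    """
    t1 = make_survey(
        [("A", 10.0, 10000.0, 0.0, 2.0, 0),
         ("B", 20.0, 20000.0, 0.0, 4.0, 3),
         ("C", 30.0, 30000.0, 0.0, 0.0, 0),
         ("D", 40.0, 40000.0, 0.0, 6.0, 1)], 2019)
    t2 = make_survey(
        [("A", 10.0, 10000.0, 0.0, 5.0, 2),
         ("B", 20.0, 20000.0, 0.0, 4.0, 0),
         ("C", 30.0, 30000.0, 0.0, 0.0, 0),
         ("D", 40.0, 40000.0, 0.0, 6.0, 4)], 2022)
    return t1, t2


def counts_to_pairs(n_col: int, k_col: int, n_ext: int, k_ext: int):
    """Synthetic paired table with given candidate-pool sizes and event
    counts (plot geometry irrelevant): the colonisation pool holds vacant
    plots suitable at the second survey, ``k_col`` of them colonised; the
    extinction pool holds occupied plots, ``k_ext`` of them extinct."""
    from metapatch.survey import pair_surveys

    rows = []
    for i in range(n_col):
        rows.append((f"C{i}", 1.0, i * 10.0, 0.0, 0.0, 0, 2.0, 1 if i < k_col else 0))
    for i in range(n_ext):
        rows.append((f"E{i}", 1.0, (n_col + i) * 10.0, 0.0, 2.0, 2,
                     2.0, 0 if i < k_ext else 1))
    t1 = make_survey([(r[0], r[1], r[2], r[3], r[4], r[5]) for r in rows], 2019)
    t2 = make_survey([(r[0], r[1], r[2], r[3], r[6], r[7]) for r in rows], 2022)
    return pair_surveys(t1, t2)


def recovery_config(seed: int, n_plots: int = 3000) -> SimConfig:
    """One generation between snapshots, habitat dynamics off: the fitted
    interval covariate models are exactly the generating models."""
    return SimConfig(n_plots=n_plots, seed=seed, generations=1,
                     succ_intercept=-40.0, wind_intercept=-40.0,
                     p_driftwood=0.0, p_water=0.0, recovery_prob=0.0)


def distance_only_config(seed: int, n_plots: int = 1000) -> SimConfig:
    """Pure-distance generator: covariate effects and habitat dynamics off,
    so the interval rates are exactly logistic in distance and the true
    n*(d) is known in closed form."""
    return SimConfig(n_plots=n_plots, seed=seed, generations=1,
                     beta_area=0.0, beta_local=0.0, beta_N=0.0, beta_area_ext=0.0,
                     beta_dist_c=0.0012, beta_dist_e=-0.0006,
                     alpha_c=-1.8, alpha_e=-0.8,
                     succ_intercept=-40.0, wind_intercept=-40.0,
                     p_driftwood=0.0, p_water=0.0, recovery_prob=0.0)


def constant_rate_config(seed: int, c: float, e: float, n_plots: int = 400) -> SimConfig:
    """Homogeneous landscape with constant per-generation colonisation and
    extinction probabilities c and e (no habitat dynamics, no covariate or
    distance effects)."""
    logit = lambda p: float(np.log(p / (1 - p)))
    return SimConfig(n_plots=n_plots, seed=seed, generations=1, burn_in=0,
                     area_core_mean=10.0, area_decline_per_km=0.0, area_sd=1e-9,
                     beta_area=0.0, beta_local=0.0, beta_N=0.0, beta_area_ext=0.0,
                     alpha_c=logit(c), alpha_e=logit(e),
                     succ_intercept=-40.0, wind_intercept=-40.0,
                     p_driftwood=0.0, p_water=0.0, recovery_prob=0.0)
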