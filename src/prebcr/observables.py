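"""Reported observables and replicate summaries.

Aggregate-size percentages are *receptor-weighted*: the percent of
receptors engaged in chains of each size (a trimer contributes three
receptors), matching how aggregation is reported.  Phospho percentages
count receptors whose Igα (resp. Igβ) site is singly or doubly
phosphorylated.  Kinase percentages are relative to the available Lyn pool
and the total Syk count in the box.

Steady-state summaries are time averages over samples with t >= t_ini
(the equilibration window is discarded); across replicates the mean of the
replicate means is reported with the sample (n-1) standard deviation.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import _kernel as K
from .dynamics import SimulationState


def aggregate_size_percentages(state: SimulationState) -> dict[int, float]:
    """Percent of receptors engaged per aggregate size: 100 * m * N_m / N."""
    n = state.n_receptors
    out: dict[int, float] = {}
    if n == 0:
        return out
    for size in state.chain_sizes():
        size = int(size)
        out[size] = out.get(size, 0.0) + 100.0 * size / n
    return out


def phospho_percentages(state: SimulationState) -> dict[str, float]:
    """Percent of receptors with singly / doubly phosphorylated Igα, Igβ."""
    n = max(state.n_receptors, 1)
    iga = state.rec_i[:, K.R_IGA]
    igb = state.rec_i[:, K.R_IGB]
    return {
        "pct_iga_mono": 100.0 * np.count_nonzero(iga == 1) / n,
        "pct_iga_doubly": 100.0 * np.count_nonzero(iga == 2) / n,
        "pct_igb_mono": 100.0 * np.count_nonzero(igb == 1) / n,
        "pct_igb_doubly": 100.0 * np.count_nonzero(igb == 2) / n,
    }


def kinase_percentages(state: SimulationState) -> dict[str, float]:
    """Lyn percentages over the available pool; Syk over total box Syk.

    "Activated" Lyn means Y397 phosphorylated; Syk phosphorylation is
    reported per lumped site (catalytic Y519/Y520 vs linker Y342/Y346).
    """
    nl = max(state.n_lyn, 1)
    ns = max(state.n_syk, 1)
    return {
        "pct_lyn_bound":
            100.0 * np.count_nonzero(state.lyn_i[:, K.L_REC] >= 0) / nl,
        "pct_lyn_activated":
            100.0 * np.count_nonzero(state.lyn_i[:, K.L_Y397] == 1) / nl,
        "pct_syk_bound":
            100.0 * np.count_nonzero(state.syk_i[:, K.S_REC] >= 0) / ns,
        "pct_syk_cat_phospho":
            100.0 * np.count_nonzero(state.syk_i[:, K.S_CAT] == 1) / ns,
        "pct_syk_linker_phospho":
            100.0 * np.count_nonzero(state.syk_i[:, K.S_LNK] == 1) / ns,
    }


def steady_state_summary(
    timeseries: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    t_ini: float,
) -> pd.DataFrame:
    """Per-observable steady-state summary over one or more replicates.

    Returns a frame indexed by observable with columns ``mean`` (mean of
    the replicate time-means), ``sd_between`` (sample SD of replicate
    means; NaN for a single replicate), ``sd_within`` (average within-run
    SD of the equilibrium fluctuations) and ``n_replicates``.
    """
    if isinstance(timeseries, pd.DataFrame):
        timeseries = [timeseries]
    if len(timeseries) == 0:
        raise ValueError("no replicates given")
    means = []
    sds = []
    for ts in timeseries:
        post = ts[ts["t"] >= t_ini].drop(columns=["t"])
        if post.empty:
            raise ValueError(f"no samples at or after t_ini={t_ini}")
        means.append(post.mean())
        sds.append(post.std(ddof=1))
    means_df = pd.DataFrame(means)
    sds_df = pd.DataFrame(sds)
    out = pd.DataFrame({
        "mean": means_df.mean(),
        "sd_between": means_df.std(ddof=1),
        "sd_within": sds_df.mean(),
    })
    out["n_replicates"] = len(timeseries)
    return out


def percent_to_cellwide_count(pct: float, n_cell: int) -> float:
    """Convert a box-level percentage to a whole-cell molecule count
    (e.g. 0.033% of ~274000 Syk is about 90 molecules)."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percent must be in [0, 100], got {pct}")
    return pct / 100.0 * n_cell
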