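"""Well-mixed stochastic model of linear-chain aggregation.

This is the spatially homogeneous counterpart of the Brownian engine, used
to calibrate the receptor-receptor binding radius and to serve as an oracle
for the domain-free spatial model.  The state is the multiset of chain
lengths; any two chains associate (end-joining, linearity preserved) at a
size-independent per-pair rate ``k_on``, and every bond breaks at ``k_off``.
Events are sampled exactly (event-driven, exponential waiting times), so
the oracle carries no time-discretization error.

``k_on`` is a required input with no default: it is an effective,
volume-scaled association rate that must be estimated (e.g. from the
spatial engine's measured per-pair encounter-and-bind rate, or supplied
externally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import DomainMap
from .model_config import ModelParameters


@dataclass
class WellMixedParams:
    n_receptors: int
    k_on: float        # per chain pair per second
    k_off: float       # per bond per second
    t_total: float
    seed: int = 0
    t_ini: float = 0.0
    sample_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.n_receptors < 1:
            raise ValueError("n_receptors must be >= 1")
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if self.t_total <= 0 or self.sample_interval <= 0:
            raise ValueError("times must be > 0")


@dataclass
class WellMixedResult:
    params: WellMixedParams
    timeseries: pd.DataFrame  # t, frac_monomer, frac_dimer, frac_higher (receptor-weighted)
    n_events: int

    def steady_state_fractions(self, t_ini: Optional[float] = None) -> np.ndarray:
        """Time-averaged receptor-weighted (monomer, dimer, >=trimer)."""
        if t_ini is None:
            t_ini = self.params.t_ini
        post = self.timeseries[self.timeseries["t"] >= t_ini]
        if post.empty:
            raise ValueError("no samples after t_ini")
        return post[["frac_monomer", "frac_dimer", "frac_higher"]].mean().to_numpy()


def simulate_wellmixed(params: WellMixedParams) -> WellMixedResult:
    """Exact event-driven simulation of the chain-population dynamics.

    Association picks an unordered chain pair uniformly; dissociation picks
    a bond uniformly (a chain of length m holds m - 1 bonds).  Receptor
    count is conserved; bond count is always N - (number of chains).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_receptors
    lengths = [1] * n  # multiset of chain lengths
    t = 0.0
    sample_times = np.arange(params.sample_interval, params.t_total + 1e-12,
                             params.sample_interval)
    rows = np.zeros((len(sample_times), 3))
    si = 0
    n_events = 0
    while si < len(sample_times):
        c = len(lengths)
        a_on = params.k_on * c * (c - 1) / 2.0
        a_off = params.k_off * (n - c)
        a_tot = a_on + a_off
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf
        while si < len(sample_times) and sample_times[si] <= t_next:
            rows[si] = _fractions(lengths, n)
            si += 1
        if si >= len(sample_times):
            break
        if not np.isfinite(t_next):
            break
        t = t_next
        n_events += 1
        if rng.random() * a_tot < a_on:
            i, j = _pick_pair(rng, c)
            merged = lengths[i] + lengths[j]
            for idx in sorted((i, j), reverse=True):
                lengths.pop(idx)
            lengths.append(merged)
        else:
            # pick a bond uniformly: chain weighted by (length - 1)
            weights = np.array([m - 1 for m in lengths], dtype=float)
            i = int(rng.choice(len(lengths), p=weights / weights.sum()))
            m = lengths.pop(i)
            cut = int(rng.integers(1, m))  # bond index 1..m-1
            lengths.extend((cut, m - cut))
    ts = pd.DataFrame({
        "t": sample_times,
        "frac_monomer": rows[:, 0],
        "frac_dimer": rows[:, 1],
        "frac_higher": rows[:, 2],
    })
    return WellMixedResult(params=params, timeseries=ts, n_events=n_events)


def _pick_pair(rng: np.random.Generator, c: int) -> tuple[int, int]:
    i = int(rng.integers(0, c))
    j = int(rng.integers(0, c - 1))
    if j >= i:
        j += 1
    return i, j


def _fractions(lengths: Sequence[int], n: int) -> np.ndarray:
    mono = sum(m for m in lengths if m == 1)
    di = sum(m for m in lengths if m == 2)
    hi = n - mono - di
    return np.array([mono, di, hi], dtype=float) / n


@dataclass
class CalibrationResult:
    selected_radius: float
    scores: pd.DataFrame  # radius, l1_distance, frac_monomer/dimer/higher


def spatial_size_fractions(
    params: ModelParameters,
    seed: int,
    domain_map: Optional[DomainMap] = None,
) -> np.ndarray:
    """Steady-state receptor-weighted (monomer, dimer, >=trimer) fractions
    from the spatial engine (receptors only; kinases do not influence
    aggregation)."""
    from .dynamics import run_simulation

    p = params.replace(n_syk_cell=0, lyn_fraction=0.0)
    res = run_simulation(p, domain_map=domain_map, seed=seed)
    post = res.timeseries[res.timeseries["t"] >= params.t_ini]
    return (post[["pct_monomer", "pct_dimer", "pct_higher"]].mean()
            .to_numpy() / 100.0)


def calibrate_binding_radius(
    target_distribution: Sequence[float],
    radii_grid: Sequence[float],
    spatial_params: ModelParameters,
    seed: int = 0,
) -> CalibrationResult:
    """Sweep the receptor binding radius in domain-free spatial runs and
    pick the radius whose steady-state (monomer, dimer, >=trimer)
    receptor-weighted fractions are closest (L1) to the target — typically
    the output of :func:`simulate_wellmixed`."""
    radii = list(radii_grid)
    if not radii:
        raise ValueError("radii_grid must be non-empty")
    if any(r < 0 for r in radii):
        raise ValueError("binding radii must be >= 0")
    target = np.asarray(target_distribution, dtype=float)
    if target.shape != (3,):
        raise ValueError("target_distribution must be (monomer, dimer, higher)")
    rows = []
    any_events = False
    for r in radii:
        p = spatial_params.replace(sigma_rec=float(r))
        frac = spatial_size_fractions(p, seed=seed)
        if frac[0] < 1.0:
            any_events = True
        rows.append({
            "radius": float(r),
            "l1_distance": float(np.abs(frac - target).sum()),
            "frac_monomer": frac[0],
            "frac_dimer": frac[1],
            "frac_higher": frac[2],
        })
    if not any_events and len(radii) > 1:
        raise RuntimeError(
            "all calibration runs were degenerate (no aggregation events); "
            "increase density, radius range or run length"
        )
    scores = pd.DataFrame(rows).sort_values("radius").reset_index(drop=True)
    best = scores.loc[scores["l1_distance"].idxmin(), "radius"]
    return CalibrationResult(selected_radius=float(best), scores=scores)
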