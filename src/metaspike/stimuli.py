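"""Seeded stimulus generators and the package-wide randomness contract.

Every stochastic operation in the suite draws randomness from a
:class:`numpy.random.Generator` created from an integer seed passed in
explicitly (directly or through a config).  Independent subsystems get
independent streams by spawning from a single :class:`~numpy.random.SeedSequence`,
so results do not depend on the order in which components consume
randomness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rngs", "poisson_fixture", "periodic_times"]


def split_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed into ``n`` independent generators."""
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def poisson_fixture(
    rate_hz: float,
    duration_ms: float,
    n_trains: int = 1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Generate independent homogeneous Poisson spike trains.

    Parameters
    ----------
    rate_hz : float
        Expected firing rate of each train, in hertz (events per second).
    duration_ms : float
        Length of the observation window in milliseconds.
    n_trains : int
        Number of independent trains.
    seed : int
        Seed for the generator; identical seeds give identical trains.

    Returns
    -------
    list of ndarray
        One strictly increasing array of spike times (ms) per train.
    """
    if rate_hz < 0:
        raise ValueError("rate_hz must be nonnegative")
    rng = np.random.default_rng(seed)
    trains = []
    lam = rate_hz * duration_ms / 1000.0
    for _ in range(n_trains):
        n = rng.poisson(lam)
        t = np.sort(rng.uniform(0.0, duration_ms, size=n))
        # ties have probability zero in theory; drop them so the strict
        # monotonicity contract holds even at float precision
        if n > 1:
            t = t[np.concatenate(([True], np.diff(t) > 0))]
        trains.append(t)
    return trains


def periodic_times(rate_hz: float, duration_ms: float, t_start: float = 0.0) -> np.ndarray:
    """Evenly spaced spike times at ``rate_hz`` within ``[t_start, duration_ms)``."""
    if rate_hz <= 0:
        return np.empty(0)
    isi = 1000.0 / rate_hz
    return np.arange(t_start + isi, duration_ms, isi)
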