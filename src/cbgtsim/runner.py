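"""Seeded parallel execution of independent simulations.

Simulation ``i`` of a batch runs under seed ``base_seed + i``; each run is
a pure function of (configuration, seed), so results are identical whether
they are executed serially or on a process pool, and arrive in submission
order regardless of scheduling.
"""

from __future__ import annotations

import multiprocessing as mp
from typing import Any

from .config import Configuration, validate_config
from .sim import ResultsBundle, simulate_one

__all__ = ["run_simulations"]


def _worker(args: tuple[Configuration, int]) -> tuple[int, Any]:
    config, seed = args
    try:
        return seed, simulate_one(config, seed=seed)
    except Exception as exc:  # propagated with the failing seed
        return seed, exc


def run_simulations(
    config: Configuration | dict[str, Any],
    n_sims: int = 1,
    cores: int = 1,
    base_seed: int | None = None,
) -> list[ResultsBundle]:
    """Run ``n_sims`` simulations with the same configuration, seeds
    ``base_seed + i`` (default base: the configuration's seed)."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not isinstance(config, Configuration):
        config = validate_config(config)
    if base_seed is None:
        base_seed = config.seed
    jobs = [(config, int(base_seed) + i) for i in range(n_sims)]
    if cores <= 1 or n_sims == 1:
        outs = [_worker(j) for j in jobs]
    else:
        ctx = mp.get_context("spawn")
        with ctx.Pool(processes=min(cores, n_sims)) as pool:
            outs = pool.map(_worker, jobs)
    results = []
    for seed, out in outs:
        if isinstance(out, Exception):
            raise RuntimeError(f"simulation with seed {seed} failed: {out}") from out
        results.append(out)
    return results
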