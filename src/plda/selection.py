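"""Model selection: choosing the number of signatures by the ELBO.

The marginal-likelihood bound self-penalizes model complexity, so K is
chosen simply as the candidate maximizing the best-restart ELBO; ties break
to the smaller K.  Restart seeds are derived arithmetically from a single
base seed, making an entire selection experiment reproducible from one
integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catalog import MutationCatalog
from .model import FitResult, NumericalError, fit

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """Raised when every restart fails for some candidate K."""


@dataclass(frozen=True)
class RestartRecord:
    K: int
    seed: int
    elbo: float
    converged: bool
    error: str | None = None


@dataclass(frozen=True)
class SelectionResult:
    k_grid: tuple[int, ...]
    best_elbo_per_k: dict[int, float]
    chosen_k: int
    best_fit: FitResult
    restart_log: tuple[RestartRecord, ...]
    fits_per_k: dict[int, FitResult]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "K": k,
                    "best_elbo": self.best_elbo_per_k[k],
                    "chosen": k == self.chosen_k,
                }
                for k in self.k_grid
            ]
        )


def select_k(
    catalog: MutationCatalog,
    k_min: int,
    k_max: int,
    restarts: int = 10,
    base_seed: int = 0,
    **fit_kwargs,
) -> SelectionResult:
    """Fit every K in ``[k_min, k_max]`` with restarts; keep the best ELBO.

    Restart i uses seed ``base_seed + i`` for every K.  A restart whose fit
    aborts with a numerical error is recorded and skipped; if every restart
    fails for some K a :class:`SelectionError` is raised.  Fully
    deterministic given ``(catalog, grid, restarts, base_seed, fit_kwargs)``.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    log: list[RestartRecord] = []
    best_per_k: dict[int, FitResult] = {}
    for K in range(k_min, k_max + 1):
        for i in range(restarts):
            seed = base_seed + i
            try:
                result = fit(catalog, K, seed=seed, **fit_kwargs)
            except NumericalError as e:
                logger.warning("fit(K=%d, seed=%d) aborted: %s", K, seed, e)
                log.append(RestartRecord(K=K, seed=seed, elbo=float("nan"), converged=False, error=str(e)))
                continue
            log.append(RestartRecord(K=K, seed=seed, elbo=result.elbo, converged=result.converged))
            if K not in best_per_k or result.elbo > best_per_k[K].elbo:
                best_per_k[K] = result
        if K not in best_per_k:
            raise SelectionError(f"all {restarts} restarts failed for K={K}")
    best_elbo_per_k = {k: f.elbo for k, f in best_per_k.items()}
    chosen_k = max(sorted(best_elbo_per_k), key=lambda k: (best_elbo_per_k[k], -k))
    return SelectionResult(
        k_grid=tuple(range(k_min, k_max + 1)),
        best_elbo_per_k=best_elbo_per_k,
        chosen_k=chosen_k,
        best_fit=best_per_k[chosen_k],
        restart_log=tuple(log),
        fits_per_k=best_per_k,
    )
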