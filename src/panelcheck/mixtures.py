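"""In silico mixtures of two libraries at a stated RNA-mass fraction.

A mixture of a parent sample with a diluent at diluent mass fraction ``f`` is
modeled at the composition level: with each sample reduced to its count
proportions (reads are taken as proportional to RNA mass — the identity
conversion, since the assay mixes by total RNA mass), the mixture proportions
are the convex combination ``(1-f)*p_parent + f*p_diluent``. Technical
variability enters in two places: the realized fraction ``f'`` is drawn from a
truncated Normal around ``f`` (pipetting/mixing error), and the measured
counts are a single multinomial draw at the simulated read depth. The
multinomial layer deliberately carries no extra NB dispersion — the parent
counts already embody the biological overdispersion, and adding it again
would double-count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MixtureSpec", "mix_proportions", "simulate_mixture", "grid_ensembles"]


@dataclass
class MixtureSpec:
    """One simulated dilution series point: parent, diluent, fraction, noise."""

    parent_id: str
    diluent_id: str
    fraction: float
    sigma_f: float = 0.02
    depth: int = 100_000
    n_simulations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("diluent mass fraction must lie in [0, 1]")
        if self.sigma_f < 0:
            raise ValueError("sigma_f must be >= 0")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no reads; proportions undefined")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    return c / total


def mix_proportions(parent_counts, diluent_counts, f: float) -> np.ndarray:
    """Per-gene proportions of a parent/diluent mixture at diluent fraction ``f``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("mass fraction must lie in [0, 1]")
    p = _proportions(parent_counts)
    d = _proportions(diluent_counts)
    if p.shape != d.shape:
        raise ValueError("parent and diluent must cover the same panel")
    return (1.0 - f) * p + f * d


def _draw_fractions(rng, f: float, sigma_f: float, n: int) -> np.ndarray:
    if sigma_f == 0.0:
        return np.full(n, f)
    a, b = (0.0 - f) / sigma_f, (1.0 - f) / sigma_f
    return stats.truncnorm.rvs(a, b, loc=f, scale=sigma_f, size=n, random_state=rng)


def simulate_mixture(spec: MixtureSpec, counts: pd.DataFrame):
    """Simulate an ensemble of mixture libraries for one grid point.

    For each of ``spec.n_simulations`` draws: a realized fraction
    ``f' ~ TruncNormal(f, sigma_f; [0, 1])``, then a multinomial count vector
    at ``spec.depth`` with :func:`mix_proportions` probabilities. Returns
    ``(ensemble, realized_f)`` with the ensemble as a genes x simulations
    DataFrame.
    """
    for sid in (spec.parent_id, spec.diluent_id):
        if sid not in counts.columns:
            raise ValueError(f"sample {sid!r} not present in the count matrix")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    parent = counts[spec.parent_id].to_numpy()
    diluent = counts[spec.diluent_id].to_numpy()
    realized = _draw_fractions(rng, spec.fraction, spec.sigma_f, spec.n_simulations)
    sims = np.empty((counts.shape[0], spec.n_simulations), dtype=np.int64)
    for k, fk in enumerate(realized):
        sims[:, k] = rng.multinomial(spec.depth, mix_proportions(parent, diluent, fk))
    ensemble = pd.DataFrame(
        sims, index=counts.index,
        columns=[f"sim{k:04d}" for k in range(spec.n_simulations)],
    )
    return ensemble, realized


def grid_ensembles(
    counts: pd.DataFrame,
    parent_ids,
    diluent_ids,
    fractions,
    n_simulations: int = 200,
    sigma_f: float = 0.02,
    depth: int = 100_000,
    seed: int = 0,
):
    """Mixture ensembles over a fraction grid, cycling all parent/diluent pairs.

    When technical replicates of the parent or diluent exist, every pairwise
    combination is used: the ``n_simulations`` draws at each grid point are
    assigned round-robin over ``product(parent_ids, diluent_ids)`` and each
    simulation records which pair produced it.

    Returns a dict mapping each fraction to
    ``(ensemble DataFrame, realized_f, pair_labels)``.
    """
    pairs = list(product(list(parent_ids), list(diluent_ids)))
    if not pairs:
        raise ValueError("need at least one parent and one diluent sample")
    fractions = np.asarray(sorted(fractions), dtype=float)
    rng_seed = np.random.SeedSequence([seed, 505])
    out = {}
    for i, f in enumerate(fractions):
        rng = np.random.default_rng(rng_seed.spawn(1)[0])
        realized = _draw_fractions(rng, float(f), sigma_f, n_simulations)
        sims = np.empty((counts.shape[0], n_simulations), dtype=np.int64)
        labels = []
        for k in range(n_simulations):
            pid, did = pairs[k % len(pairs)]
            labels.append(f"{pid}|{did}")
            p = mix_proportions(counts[pid].to_numpy(), counts[did].to_numpy(), realized[k])
            sims[:, k] = rng.multinomial(depth, p)
        ensemble = pd.DataFrame(
            sims, index=counts.index,
            columns=[f"f{f:.4f}_sim{k:04d}" for k in range(n_simulations)],
        )
        out[float(f)] = (ensemble, realized, labels)
    return out
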