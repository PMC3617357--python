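"""Stochastic draws: hormone environment, mutational effects, inheritance noise.

These functions are the library-level surface for the model's three noise
sources, built on :class:`numpy.random.Generator`.  The population engine
draws the same distributions inside its compiled kernel from one seeded
stream per simulation, so a simulation is bit-reproducible given
``(seed, params)``.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters, MutationModelSpec

__all__ = ["draw_environment", "draw_mutation_effects", "perturb_inherited_alpha"]


def draw_environment(rng: np.random.Generator, params: ModelParameters, size=None):
    """Per-cell hormone environment beta (cycles/month^2).

    Normal(beta_mean, beta_sd^2), truncated by resampling at
    ``beta_truncate_sd`` standard deviations (off when <= 0).  ``beta_sd = 0``
    degenerates to exactly ``beta_mean``.
    """
    n = 1 if size is None else int(size)
    z = rng.standard_normal(n)
    t = params.beta_truncate_sd
    if t > 0:
        bad = np.abs(z) > t
        while bad.any():
            z[bad] = rng.standard_normal(int(bad.sum()))
            bad = np.abs(z) > t
    out = params.beta_mean + params.beta_sd * z
    return float(out[0]) if size is None else out


def draw_mutation_effects(rng: np.random.Generator, spec: MutationModelSpec) -> np.ndarray:
    """Effects ``m_i`` (1/month) carried by one newborn daughter.

    Length is ``per_daughter`` (or Poisson(per_daughter) when configured);
    draws are independent.  Effects add to the differentiation coefficient,
    ``k = max(0, k_p(g) + sum m_i)``.
    """
    spec.validate()
    if spec.count_distribution == "poisson":
        n = int(rng.poisson(spec.per_daughter))
    else:
        n = spec.per_daughter
    if spec.family == "point_mass":
        return np.full(n, spec.value)
    if spec.family == "gaussian":
        return spec.loc + spec.scale * rng.standard_normal(n)
    out = np.empty(n)
    for i in range(n):
        if rng.random() < spec.tail_prob:
            out[i] = -rng.exponential(spec.tail_scale)
        else:
            out[i] = spec.loc + spec.bulk_sd * rng.standard_normal()
    return out


def perturb_inherited_alpha(
    parent_alpha: float, rng: np.random.Generator, params: ModelParameters
) -> float:
    """Daughter proliferation potential at birth: the parent's alpha at
    division plus zero-mean Gaussian noise (SD ``inheritance_noise_sd``)."""
    if not np.isfinite(parent_alpha):
        raise ValueError("parent alpha must be finite")
    return float(parent_alpha + params.inheritance_noise_sd * rng.standard_normal())
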