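"""Model parameters for the single-cell clonal-dynamics model.

The model describes each uterine epithelial cell by a small phenotype vector
(proliferation potential ``alpha``, differentiation coefficient ``k``,
generation number ``g``) evolving under a programmed differentiation
trajectory, a hormonal environment ``beta`` and additive mutational effects
``m_i`` on ``k``.  Everything tunable lives in :class:`ModelParameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "MutationModelSpec",
    "ModelParameters",
    "Phenotype",
    "MUT_POINT_MASS",
    "MUT_GAUSSIAN",
    "MUT_MIXTURE",
]

# integer tags shared with the compiled kernel
MUT_POINT_MASS = 0
MUT_GAUSSIAN = 1
MUT_MIXTURE = 2

_FAMILIES = {"point_mass": MUT_POINT_MASS, "gaussian": MUT_GAUSSIAN, "mixture": MUT_MIXTURE}


def _check_known_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown field(s) {sorted(unknown)}")


@dataclass
class MutationModelSpec:
    """Distribution of per-mutation additive effects on the differentiation
    coefficient (units 1/month; negative values erode differentiation).

    Families
    --------
    ``point_mass``
        every effect equals ``value`` (``value = 0`` is the neutral model).
    ``gaussian``
        Normal(``loc``, ``scale``^2); the default, calibrated against the
        printed clone and tumor statistics.  The small positive location
        encodes that random alterations are on average slightly deleterious
        to proliferative fitness (they strengthen the differentiation pull),
        while the spread supplies the heritable variation that selection
        acts on during tumor growth.
    ``mixture``
        with probability ``tail_prob`` draw ``-Exponential(tail_scale)``,
        otherwise Normal(``loc``, ``bulk_sd``^2): a heavy negative tail of
        rare strongly de-differentiating hits on top of a near-neutral bulk,
        for exploring spontaneous immortalization of normal progenitors.
    """

    family: str = "gaussian"
    value: float = 0.0
    loc: float = 0.004
    scale: float = 0.05
    bulk_sd: float = 0.05
    tail_prob: float = 0.1
    tail_scale: float = 0.15
    per_daughter: int = 2
    count_distribution: str = "fixed"  # "fixed" | "poisson"

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown mutation family {self.family!r}")
        if not 0.0 <= self.tail_prob <= 1.0:
            raise ValueError("tail_prob must be in [0, 1]")
        if self.scale < 0 or self.bulk_sd < 0 or self.tail_scale <= 0:
            raise ValueError("mutation scales must be positive")
        if self.per_daughter < 0:
            raise ValueError("per_daughter must be >= 0")
        if self.count_distribution not in ("fixed", "poisson"):
            raise ValueError("count_distribution must be 'fixed' or 'poisson'")

    @property
    def mean_effect(self) -> float:
        """Analytic mean of a single draw."""
        if self.family == "point_mass":
            return self.value
        if self.family == "gaussian":
            return self.loc
        return (1.0 - self.tail_prob) * self.loc + self.tail_prob * (-self.tail_scale)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MutationModelSpec":
        _check_known_keys(d, set(cls.__dataclass_fields__), "mutation_model")
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class ModelParameters:
    """All coefficients of the cell-fate equations plus run-level thresholds.

    Units: time in months (1 month = 30 days for day conversions), ``alpha``
    in cycles/month, ``k`` in 1/month, ``beta`` in cycles/month^2.
    """

    g_limit: float = 10.0               # programmed generation limit
    alpha_p_scale: float = 17.0         # scale of the programmed proliferation curve
    # programmed proliferation curve shape:
    #   "saturating" (default): scale*(g_limit-g)/g_limit while g <= g_limit;
    #       past the limit the senescence pull deepens superlinearly and
    #       saturates, -scale*min(1, ((g-g_limit)/senescence_span)^q) with
    #       q chosen so that |alpha_p(g_limit+1)| = senescence_onset (the
    #       death pace of the first post-limit generation, which the printed
    #       clone-lifespan statistics pin down).
    #   "clipped"  scale*max((g_limit-g)/g_limit, -1)
    #   "linear"   scale*(g_limit-g)/g_limit
    #   "rational" scale*(g_limit-g)/g
    alpha_p_form: str = "saturating"
    senescence_span: float = 4.0        # generations past g_limit to full pull
    senescence_onset: float = 1.76      # |alpha_p| one generation past the limit
    kp_saturation: float = 3.78         # k_p(g) = sat*(1-exp(-rate*g)) + lin*g
    kp_rate: float = 0.4
    kp_linear: float = 0.03
    beta_mean: float = 5.0              # hormone environment ~ N(mean, sd^2)
    beta_sd: float = 0.5
    beta_truncate_sd: float = 3.4       # resample draws beyond this many SD (<=0: off)
    mutation_model: MutationModelSpec = field(default_factory=MutationModelSpec)
    inheritance_noise_sd: float = 0.1   # SD of daughter-alpha perturbation
    alpha_initial: float = 2.95         # progenitor alpha at t = 0
    detect_threshold: int = 1_000_000   # living cells defining a detectable tumor
    k_floor: float = 0.0                # lower clamp of k (de-differentiation floor)
    max_sim_time: float = 120.0         # months; hard stop / censoring horizon
    max_cells: int = 6_000_000          # memory guard on total cells ever born

    def validate(self) -> None:
        if self.beta_sd < 0:
            raise ValueError("beta_sd must be >= 0")
        if self.inheritance_noise_sd < 0:
            raise ValueError("inheritance_noise_sd must be >= 0")
        if self.detect_threshold < 1:
            raise ValueError("detect_threshold must be >= 1")
        if self.k_floor != 0.0:
            raise ValueError("k_floor is fixed at 0 in this model")
        if self.max_sim_time <= 0:
            raise ValueError("max_sim_time must be > 0")
        if self.g_limit <= 0 or self.alpha_p_scale <= 0:
            raise ValueError("g_limit and alpha_p_scale must be > 0")
        if self.alpha_p_form not in ("saturating", "clipped", "linear", "rational"):
            raise ValueError(
                "alpha_p_form must be 'saturating', 'clipped', 'linear' or 'rational'")
        if self.senescence_span <= 1.0:
            raise ValueError("senescence_span must be > 1")
        if not 0.0 < self.senescence_onset < self.alpha_p_scale:
            raise ValueError("senescence_onset must be in (0, alpha_p_scale)")
        self.mutation_model.validate()

    # ---- packing for the compiled kernel -------------------------------
    def to_array(self) -> np.ndarray:
        m = self.mutation_model
        return np.array(
            [
                self.g_limit,
                self.alpha_p_scale,
                self.kp_saturation,
                self.kp_rate,
                self.kp_linear,
                self.beta_mean,
                self.beta_sd,
                float(m.per_daughter),
                float(_FAMILIES[m.family]),
                m.value if m.family == "point_mass" else m.loc,
                m.scale if m.family == "gaussian" else m.bulk_sd,
                m.tail_prob,
                m.tail_scale,
                self.inheritance_noise_sd,
                self.alpha_initial,
                float(self.detect_threshold),
                self.k_floor,
                self.max_sim_time,
                1.0 if m.count_distribution == "poisson" else 0.0,
                float(self.max_cells),
                {"saturating": 0.0, "clipped": 1.0, "linear": 2.0, "rational": 3.0}[
                    self.alpha_p_form
                ],
                self.senescence_span,
                self.beta_truncate_sd,
                # exponent of the post-limit pull: |alpha_p(gl+1)| = onset
                np.log(self.alpha_p_scale / self.senescence_onset)
                / np.log(self.senescence_span),
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        d = dict(d)
        _check_known_keys(d, set(cls.__dataclass_fields__), "model")
        mm = d.pop("mutation_model", None)
        params = cls(**d)
        if mm is not None:
            params.mutation_model = (
                mm if isinstance(mm, MutationModelSpec) else MutationModelSpec.from_dict(mm)
            )
        params.validate()
        return params

    # ---- convenience variants ------------------------------------------
    def neutral(self) -> "ModelParameters":
        """Copy with zero mutation effects, zero inheritance noise and a
        degenerate hormone distribution: the deterministic programmed
        trajectory (every clone is a full binary tree of depth g_limit)."""
        p = ModelParameters.from_dict(self.to_dict())
        p.mutation_model = MutationModelSpec(
            family="point_mass", value=0.0,
            per_daughter=self.mutation_model.per_daughter)
        p.inheritance_noise_sd = 0.0
        p.beta_sd = 0.0
        return p


@dataclass(frozen=True)
class Phenotype:
    """Initializer triple for tumor-initiating-cell runs.

    ``k`` 1/month, ``alpha`` cycles/month, ``g`` generations.  The typical
    tumor-initiating cancer cell (TICC) is (0.18, 3.66, 17); its stem
    counterpart (TICSC) has k = 0.
    """

    k: float
    alpha: float
    g: int

    def validate(self) -> None:
        if self.k < 0:
            raise ValueError("phenotype k must be >= 0")
        if self.g < 1:
            raise ValueError("phenotype g must be >= 1")


#: the paper-style typical tumor-initiating cancer (stem) cell phenotypes
TICC = Phenotype(k=0.18, alpha=3.66, g=17)
TICSC = Phenotype(k=0.0, alpha=3.66, g=17)
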