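"""Shared result container for fitted mixed models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FitResult:
    """A fitted weighted mixed model (beta-logit or Gaussian family).

    Coefficients are on the link scale (logit for the beta family, identity
    for the Gaussian).  ``precision`` is the beta dispersion phi or the
    Gaussian residual variance.  ``bic = -2 loglik + k ln(n_obs)`` with k the
    number of free parameters (fixed effects + dispersion + variance
    components).
    """

    family: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    cov_fixed: np.ndarray
    random_variances: dict[str, float]
    precision: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    term_names: list[str] = field(default_factory=list)
    metric: str | None = None
    subset: str | None = None
    fixed_effects: tuple[str, ...] = ()
    random_structure: str = "source_only"
    message: str = ""
    singular: bool = False

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.term_names])

    def summary_rows(self) -> list[dict]:
        return [
            {
                "term": t,
                "estimate": self.coefficients[t],
                "se": self.standard_errors[t],
            }
            for t in self.term_names
        ]
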