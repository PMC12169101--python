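"""Response transforms and study weights for the mixed models.

The beta likelihood is undefined at the boundaries 0 and 1, which intactness
and similarity can attain; the Smithson–Verkuilen compression
``(y (n-1) + 0.5) / n`` maps [0, 1] into the open interval, where ``n`` is
the number of observations entering the model fit.  Study weights are the
square root of the reference-site species count, so studies sampling many
species carry more influence.
"""

from __future__ import annotations

import math

import numpy as np


def smithson_verkuilen(y, n: int):
    """Compress proportions from [0, 1] into (0, 1).

    Parameters
    ----------
    y:
        Scalar or array of responses in [0, 1].
    n:
        Number of observations in the model the response enters; must be >= 2.
    """
    if n < 2:
        raise ValueError(f"Smithson-Verkuilen transform requires n >= 2, got {n}")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def smithson_verkuilen_inverse(z, n: int):
    """Invert the compression (for mapping estimates back to the data scale)."""
    z = np.asarray(z, dtype=float)
    out = (z * n - 0.5) / (n - 1)
    return float(out) if out.ndim == 0 else out


def study_weight(n_ref_species: int) -> float:
    """sqrt of the reference-site species count; the model weight of a study."""
    if n_ref_species < 1:
        raise ValueError("study weight undefined for zero reference species")
    return math.sqrt(n_ref_species)


def inv_logit(x):
    """Numerically stable inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return float(out) if out.ndim == 0 else out


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out
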