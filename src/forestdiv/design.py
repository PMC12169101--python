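"""Fixed-effect design matrices for the metric-level models.

Coding convention: when management is the sole fixed effect the model uses
cell-means coding — one indicator column per system and no global intercept —
so each coefficient is directly that system's link-scale mean.  With
additional covariates (taxonomic class, continent, time), management switches
to treatment coding with the alphabetically first system as baseline and an
intercept is included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; the message names the term."""


def build_design(
    df: pd.DataFrame, fixed_effects: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Construct the design matrix for the requested fixed effects.

    Supported effects: ``intercept_only``, ``management``, ``time``,
    ``log_time`` (ln(t+1), so freshly harvested stands are admissible),
    ``taxon_class``, ``continent``.  Returns ``(X, term_names)``.
    """
    n = len(df)
    effects = tuple(fixed_effects)
    cols: list[np.ndarray] = []
    names: list[str] = []

    management_only = effects == ("management",)
    covariates = [e for e in effects if e not in ("management", "intercept_only")]

    if effects == ("intercept_only",) or (not management_only and "management" not in effects):
        cols.append(np.ones(n))
        names.append("intercept")

    if "management" in effects:
        levels = sorted(df["system"].unique())
        if management_only:
            for lev in levels:
                cols.append((df["system"] == lev).to_numpy(float))
                names.append(f"system:{lev}")
        else:
            cols.append(np.ones(n))
            names.append("intercept")
            for lev in levels[1:]:
                cols.append((df["system"] == lev).to_numpy(float))
                names.append(f"system:{lev}")

    for eff in covariates:
        if eff == "time":
            t = df["time_since_years"].to_numpy(float)
            cols.append(t)
            names.append("time")
        elif eff == "log_time":
            t = df["time_since_years"].to_numpy(float)
            cols.append(np.log1p(t))
            names.append("log_time")
        elif eff in ("taxon_class", "continent"):
            col = "taxon_group" if eff == "taxon_class" else "continent"
            levels = sorted(df[col].dropna().unique())
            for lev in levels[1:]:
                cols.append((df[col] == lev).to_numpy(float))
                names.append(f"{col}:{lev}")
        else:
            raise ValueError(f"unknown fixed effect: {eff!r}")

    X = np.column_stack(cols) if cols else np.ones((n, 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column by greedy elimination
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise RankDeficientError(
                    f"design matrix rank deficient; term {names[j]!r} is collinear"
                )
        raise RankDeficientError("design matrix rank deficient")
    return X, names
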