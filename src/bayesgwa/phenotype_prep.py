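"""Phenotype tables, intermediate-optimum trait splitting, design matrices.

Structural soundness traits are subjective 1-9 scores.  For traits whose
optimum is the scale midpoint (e.g. top line, turned legs), a single
linear effect cannot represent the phenotype, so each such trait is
split into two one-sided traits before analysis: the folded deviation
above the optimum and the folded deviation below it.

Fixed effects (genetic line, measurement date, scorer) enter the model
through a reference-coded incidence matrix; continuous covariates such
as body weight are centered so the intercept stays interpretable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class PhenotypeError(ValueError):
    """Invalid phenotype input."""


@dataclass
class PhenotypeTable:
    """Per-animal trait values plus fixed-effect factors and covariates."""

    data: pd.DataFrame
    traits: list[str]
    factors: list[str] = field(default_factory=lambda: ["line", "date", "scorer"])
    covariates: list[str] = field(default_factory=lambda: ["body_weight"])
    id_column: str = "animal_id"

    def __post_init__(self) -> None:
        missing = [
            c
            for c in [self.id_column, *self.traits, *self.factors, *self.covariates]
            if c not in self.data.columns
        ]
        if missing:
            raise PhenotypeError(f"phenotype table lacks columns {missing}")

    @classmethod
    def from_csv(cls, path, traits, factors=None, covariates=None, **kw) -> "PhenotypeTable":
        df = pd.read_csv(path)
        kwargs = {}
        if factors is not None:
            kwargs["factors"] = list(factors)
        if covariates is not None:
            kwargs["covariates"] = list(covariates)
        return cls(df, traits=list(traits), **kwargs, **kw)


def split_intermediate_trait(
    scores, optimum: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Split an intermediate-optimum 1-9 score into two one-sided traits.

    ``trait_high = max(score - optimum, 0)`` and
    ``trait_low = max(optimum - score, 0)``; at most one of the pair is
    positive for any animal, and ``trait_high - trait_low + optimum``
    recovers the original score exactly.
    """
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    if ((finite < 1) | (finite > 9)).any():
        bad = finite[(finite < 1) | (finite > 9)][0]
        raise PhenotypeError(f"score {bad} outside the 1-9 scale")
    high = np.maximum(scores - optimum, 0.0)
    low = np.maximum(optimum - scores, 0.0)
    return high, low


@dataclass
class DesignMatrix:
    """Reference-coded fixed-effect incidence matrix aligned with y."""

    X: np.ndarray
    column_names: list[str]
    animal_ids: list[str]


def build_design(
    pt: PhenotypeTable,
    trait: str,
    factors: list[str] | None = None,
    covariates: list[str] | None = None,
) -> tuple[np.ndarray, DesignMatrix]:
    """Build the response vector and fixed-effects design for one trait.

    Animals missing the trait or any covariate are dropped (complete
    case, logged).  Each factor is reference-coded (first level in sort
    order dropped); a single-level factor contributes no column and
    raises a warning.  Covariates are centered.  A rank-deficient design
    after coding raises, naming the confounded columns.
    """
    factors = pt.factors if factors is None else list(factors)
    covariates = pt.covariates if covariates is None else list(covariates)
    df = pt.data
    needed = [trait, *covariates]
    keep = df[needed].notna().all(axis=1)
    if (~keep).any():
        logger.info(
            "dropping %d animals with missing %s or covariates", (~keep).sum(), trait
        )
    df = df.loc[keep]
    if df[factors].isna().any().any():
        raise PhenotypeError("missing factor levels; factors must be complete")

    y = df[trait].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        levels = sorted(df[f].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; column omitted")
            continue
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        confounded = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise PhenotypeError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"confounded columns: {confounded}"
        )
    ids = df[pt.id_column].astype(str).tolist()
    return y, DesignMatrix(X=X, column_names=names, animal_ids=ids)


def describe_trait(values) -> dict:
    """Moment summary (n, mean, sd, min, max, skewness, kurtosis).

    Constant traits report sd 0 with skewness/kurtosis NaN and
    ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise PhenotypeError("trait summary needs at least two values")
    sd = float(v.std(ddof=1))
    degenerate = sd == 0.0
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": sd,
        "min": float(v.min()),
        "max": float(v.max()),
        "skewness": np.nan if degenerate else float(stats.skew(v)),
        "kurtosis": np.nan if degenerate else float(stats.kurtosis(v)),
        "degenerate": degenerate,
    }
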