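"""Bayes C mixture-model whole-genome regression by Gibbs sampling.

The model is

    y = X b + sum_j Z_j u_j delta_j + e

with fixed effects ``b`` (flat prior), per-SNP substitution effects
``u_j ~ N(0, sigma_u^2)`` entering the model through the 0/1 indicator
``delta_j`` (zero with prior probability ``pi``), a single effect
variance common to all included loci, and residuals
``e ~ N(0, sigma_e^2 I)``.  Both variances carry scaled inverse
chi-square priors.  Each Gibbs sweep updates fixed effects, then every
locus jointly -- the indicator is sampled from the two-component
marginal likelihood with the effect integrated out, and the effect is
then drawn from its normal full conditional when included -- and finally
the two variances from their conjugate conditionals.

The evidence statistic for association is the *model frequency*: the
fraction of post-burn-in iterations in which a SNP is in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from bayesgwa._kernels import gibbs_kernel
from bayesgwa.genotype_data import MISSING, GenotypeMatrix


class EngineError(ValueError):
    """Invalid sampler configuration or numeric failure."""


@dataclass
class ModelSpec:
    """Hyperparameters and chain control for one Bayes C run.

    ``pi`` is the prior probability a SNP is excluded (0.995 by
    default); ``v_u``/``v_e`` and ``s2_u``/``s2_e`` parameterize the
    scaled inverse chi-square variance priors.  When the scale
    parameters are left unset they are derived from ``h2_prior`` and the
    phenotypic variance at fit time (see :func:`derive_scales`).
    """

    seed: int
    pi: float = 0.995
    v_u: float = 4.0
    v_e: float = 10.0
    s2_u: float | None = None
    s2_e: float | None = None
    h2_prior: float = 0.5
    chain_length: int = 11_000
    burn_in: int = 1_000
    thin: int = 1
    update_variances: bool = True
    sigma_u2_init: float | None = None
    sigma_e2_init: float | None = None
    check_every: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise EngineError(f"pi={self.pi} outside [0, 1]")
        if self.v_u <= 0 or self.v_e <= 0:
            raise EngineError("degrees of freedom must be positive")
        if not 0 <= self.burn_in < self.chain_length:
            raise EngineError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise EngineError("thinning interval must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior output of one chain.

    ``model_freq`` is the per-SNP inclusion frequency over kept
    iterations; ``effect_mean`` the posterior mean effect (zeros
    included); ``effect_delta`` the conditional mean effect
    (effect / model frequency, 0 where the SNP was never included, with
    ``delta_undefined`` marking those).  The kept indicator trace is
    stored bit-packed; :meth:`unpack_delta` recovers the boolean
    (samples x SNPs) matrix used by window statistics.
    """

    model_freq: np.ndarray
    effect_mean: np.ndarray
    b_mean: np.ndarray
    var_u_trace: np.ndarray
    var_e_trace: np.ndarray
    included_count_trace: np.ndarray
    delta_packed: np.ndarray
    n_snps: int
    n_samples: int
    resid_max_dev: float
    spec: ModelSpec
    snp_ids: list[str] | None = None
    fixed_names: list[str] | None = None
    effect_delta: np.ndarray = field(init=False)
    delta_undefined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        freq = self.model_freq
        self.delta_undefined = freq == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(self.delta_undefined, 0.0, self.effect_mean / np.where(freq == 0, 1.0, freq))
        self.effect_delta = d

    @property
    def var_u_mean(self) -> float:
        return float(self.var_u_trace.mean())

    @property
    def var_e_mean(self) -> float:
        return float(self.var_e_trace.mean())

    def unpack_delta(self) -> np.ndarray:
        """Kept-iteration inclusion indicators, shape (n_samples, n_snps)."""
        out = np.unpackbits(self.delta_packed, axis=1, count=self.n_snps)
        return out.astype(bool)


def marker_effect_delta(effect_mean: float, model_frequency: float) -> float:
    """Posterior mean effect conditional on inclusion: effect / frequency.

    Returns 0.0 when the model frequency is zero (the conditional mean
    is undefined for a SNP never included).
    """
    if not 0.0 <= model_frequency <= 1.0:
        raise EngineError(f"model frequency {model_frequency} outside [0, 1]")
    if model_frequency == 0.0:
        return 0.0
    return effect_mean / model_frequency


def derive_scales(
    h2_prior: float,
    phenotypic_variance: float,
    allele_freqs: np.ndarray,
    spec: ModelSpec,
) -> tuple[float, float]:
    """Calibrate the variance-prior scales from a heritability prior.

    The prior mean of the common effect variance is set so that
    ``E[sigma_u^2] * (1 - pi) * K * mean(2 p (1-p))`` equals
    ``h2_prior * V_p`` -- i.e. the expected number of included loci
    times their expected per-locus variance contribution matches the
    genetic variance implied by the heritability prior.  The residual
    scale targets ``(1 - h2_prior) * V_p``.  Since a scaled inverse
    chi-square with df v and scale S^2 has mean ``v S^2 / (v - 2)``,
    each scale is the target mean times ``(v - 2) / v`` (df > 2
    required).
    """
    if not 0.0 < h2_prior < 1.0:
        raise EngineError(f"h2_prior={h2_prior} outside (0, 1)")
    if spec.v_u <= 2 or spec.v_e <= 2:
        raise EngineError("scale derivation needs df > 2 for a finite prior mean")
    p = np.asarray(allele_freqs, dtype=float)
    mean_2pq = float(np.mean(2.0 * p * (1.0 - p)))
    if mean_2pq <= 0.0:
        raise EngineError("mean 2p(1-p) is zero; panel is monomorphic")
    expected_in = (1.0 - spec.pi) * p.size
    if expected_in <= 0.0:
        raise EngineError("pi = 1 leaves no locus to carry genetic variance")
    mean_su2 = h2_prior * phenotypic_variance / (expected_in * mean_2pq)
    s2_u = mean_su2 * (spec.v_u - 2.0) / spec.v_u
    s2_e = (1.0 - h2_prior) * phenotypic_variance * (spec.v_e - 2.0) / spec.v_e
    return s2_u, s2_e


def dosage_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """0-2 B-allele dosage covariates with missing calls mean-imputed.

    A missing call is replaced by twice the SNP's B-allele frequency
    (the column mean of observed calls), preserving allele frequencies.
    """
    z = gm.calls.astype(np.float64)
    miss = gm.calls == MISSING
    for j in np.where(miss.any(axis=0))[0]:
        obs = z[~miss[:, j], j]
        if obs.size == 0:
            raise EngineError(
                f"SNP {gm.snps['snp_id'].iloc[j]!r} has no observed call; "
                "run qc_filter first"
            )
        z[miss[:, j], j] = obs.mean()
    return z


def run_chain(
    y: np.ndarray,
    X: np.ndarray | None,
    Z: np.ndarray,
    spec: ModelSpec,
    snp_ids: Sequence[str] | None = None,
    fixed_names: Sequence[str] | None = None,
    scan_order: np.ndarray | None = None,
) -> PosteriorSummary:
    """Run one Gibbs chain and summarize the posterior.

    ``X`` may be ``None`` or an (n, 0) array when there are no fixed
    effects.  ``Z`` holds 0-2 dosage covariates (use
    :func:`dosage_matrix` to impute missing calls first).
    ``scan_order`` optionally fixes the within-sweep locus visitation
    order (default: column order); supplying the matching permutation
    makes a column-permuted run bit-identical.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = y.shape[0]
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] != n:
        raise EngineError(f"Z has {Z.shape[0]} rows for {n} phenotypes")
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=np.float64)
    p = X.shape[1]
    if p > 0 and np.linalg.matrix_rank(X) < p:
        raise EngineError("fixed-effect design matrix is rank deficient")
    k = Z.shape[1]
    if scan_order is None:
        scan_order = np.arange(k, dtype=np.int64)
    else:
        scan_order = np.asarray(scan_order, dtype=np.int64)
        if sorted(scan_order.tolist()) != list(range(k)):
            raise EngineError("scan_order must be a permutation of the loci")

    s2_u, s2_e = spec.s2_u, spec.s2_e
    if s2_u is None or s2_e is None:
        freqs = Z.mean(axis=0) / 2.0
        d_u, d_e = derive_scales(spec.h2_prior, float(y.var(ddof=1)), freqs, spec)
        s2_u = d_u if s2_u is None else s2_u
        s2_e = d_e if s2_e is None else s2_e

    su2_init = spec.sigma_u2_init
    if su2_init is None:
        su2_init = s2_u * spec.v_u / max(spec.v_u - 2.0, 0.5)
    se2_init = spec.sigma_e2_init
    if se2_init is None:
        se2_init = s2_e * spec.v_e / max(spec.v_e - 2.0, 0.5)

    (
        model_freq,
        effect_mean,
        b_mean,
        var_u_trace,
        var_e_trace,
        incl_trace,
        delta_trace,
        resid_max_dev,
        err_locus,
    ) = gibbs_kernel(
        y,
        np.ascontiguousarray(X.T),
        np.ascontiguousarray(Z.T),
        float(spec.pi),
        float(spec.v_u),
        float(s2_u),
        float(spec.v_e),
        float(s2_e),
        int(spec.chain_length),
        int(spec.burn_in),
        int(spec.thin),
        int(spec.seed),
        spec.update_variances,
        float(su2_init),
        float(se2_init),
        int(spec.check_every),
        scan_order,
    )
    if err_locus >= 0:
        name = snp_ids[err_locus] if snp_ids is not None else f"column {err_locus}"
        raise EngineError(f"non-finite likelihood at locus {name}")

    return PosteriorSummary(
        model_freq=model_freq,
        effect_mean=effect_mean,
        b_mean=b_mean,
        var_u_trace=var_u_trace,
        var_e_trace=var_e_trace,
        included_count_trace=incl_trace,
        delta_packed=np.packbits(delta_trace, axis=1),
        n_snps=k,
        n_samples=delta_trace.shape[0],
        resid_max_dev=float(resid_max_dev),
        spec=replace(spec, s2_u=s2_u, s2_e=s2_e),
        snp_ids=list(snp_ids) if snp_ids is not None else None,
        fixed_names=list(fixed_names) if fixed_names is not None else None,
    )


def add_fixed_covariate(
    y: np.ndarray,
    X: np.ndarray | None,
    Z: np.ndarray,
    spec: ModelSpec,
    covariate: int | str,
    snp_ids: Sequence[str] | None = None,
    fixed_names: Sequence[str] | None = None,
) -> PosteriorSummary:
    """Re-fit with one SNP moved from the mixture to the fixed effects.

    The named (or indexed) SNP column is appended to ``X`` and removed
    from the random-effect set, so it no longer appears in the SNP
    posterior summaries.  Used to test whether a candidate absorbs the
    signal of its high-LD neighbors.
    """
    if isinstance(covariate, str):
        if snp_ids is None or covariate not in snp_ids:
            raise EngineError(f"unknown covariate {covariate!r}")
        idx = list(snp_ids).index(covariate)
    else:
        idx = int(covariate)
        if not 0 <= idx < Z.shape[1]:
            raise EngineError(f"covariate index {idx} out of range")
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    base = np.empty((n, 0)) if X is None else np.asarray(X, dtype=np.float64)
    new_x = np.column_stack([base, Z[:, idx]])
    new_z = np.delete(Z, idx, axis=1)
    kept_ids = None
    if snp_ids is not None:
        kept_ids = [s for i, s in enumerate(snp_ids) if i != idx]
    moved = snp_ids[idx] if snp_ids is not None else f"snp_{idx}"
    names = list(fixed_names) if fixed_names is not None else [
        f"x{q}" for q in range(base.shape[1])
    ]
    return run_chain(
        y, new_x, new_z, spec, snp_ids=kept_ids, fixed_names=names + [moved]
    )
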