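"""Synthetic two-line genotype/phenotype generator with known architecture.

The generator emulates the design of a commercial-pig association study:
two related genetic lines genotyped on a dense SNP array, linkage
disequilibrium between neighboring SNPs, a small fraction of markers
with true effects, fixed effects of line, measurement date and scorer, a
body-weight covariate, and subjective nine-point score traits alongside
the continuous trait.

Haplotypes come from a first-order Markov copying model along each
chromosome: with probability ``rho`` a haplotype copies its allele at
the previous SNP, otherwise it draws afresh at that SNP's base
frequency.  Adjacent-SNP correlation is then ``rho`` per step, giving
pairwise r-squared decaying roughly as ``rho**(2d)`` with SNP distance
``d`` -- a single-parameter stand-in for population LD.  The second line
samples from a pool whose base frequencies are beta-perturbed around the
first line's, creating mild, tunable divergence.

Every dataset ships with a :class:`TruthRecord` that reproduces the
phenotype exactly when fixed effects, breeding values and residuals are
summed, so downstream inference can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from bayesgwa.genotype_data import MISSING, GenotypeMatrix, write_genotypes


class SimulationError(ValueError):
    """Simulation cannot satisfy the requested configuration."""


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    Defaults mirror the emulated study design: 412 + 408 animals in two
    related lines, a dense panel scaled down to 2,000 SNPs over 10
    chromosomes, mixture fraction 0.995 (so ~10 causal SNPs), a
    moderately heritable trait (h2 = 0.5), 14 measurement dates, two
    scorers, and a body-weight covariate (124 +/- 11 kg).
    """

    seed: int
    n_line1: int = 412
    n_line2: int = 408
    n_snps: int = 2000
    n_chromosomes: int = 10
    rho: float = 0.8
    pi_true: float = 0.995
    qtl_effect_var: float = 1.0
    h2: float = 0.5
    line_effect: float = 0.3
    date_sd: float = 0.2
    scorer_sd: float = 0.1
    bw_slope: float = 0.02
    bw_mean: float = 124.0
    bw_sd: float = 11.0
    mu: float = 5.0
    missing_rate: float = 0.01
    line_divergence: float = 0.05
    pool_size: int | None = None
    snp_spacing_bp: int = 40_000
    n_dates: int = 14
    n_scorers: int = 2

    def __post_init__(self) -> None:
        for name in ("rho", "pi_true", "missing_rate", "line_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.h2 < 1.0:
            raise SimulationError(f"h2={self.h2} outside (0, 1)")
        if self.seed is None:
            raise SimulationError("seed is mandatory")

    @property
    def n_animals(self) -> int:
        return self.n_line1 + self.n_line2

    def chromosome_of(self, j: int) -> int:
        """Chromosome index (0-based) of SNP column j, contiguous blocks."""
        per = -(-self.n_snps // self.n_chromosomes)
        return j // per


@dataclass
class HaplotypePool:
    """Phased haplotypes (pool x SNPs, alleles 0/1) with panel layout."""

    haplotypes: np.ndarray
    base_freqs: np.ndarray
    chrom_index: np.ndarray  # 0-based chromosome of each SNP
    positions: np.ndarray  # 1-based bp


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated dataset."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    var_genetic: float
    realized_h2: float
    tbv: np.ndarray
    fixed_part: np.ndarray
    residuals: np.ndarray

    def to_json(self, path: str | Path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            qtl_indices=np.asarray(d["qtl_indices"], dtype=int),
            effects=np.asarray(d["effects"], dtype=float),
            var_genetic=float(d["var_genetic"]),
            realized_h2=float(d["realized_h2"]),
            tbv=np.asarray(d["tbv"], dtype=float),
            fixed_part=np.asarray(d["fixed_part"], dtype=float),
            residuals=np.asarray(d["residuals"], dtype=float),
        )


def _markov_haplotypes(
    freqs: np.ndarray, rho: float, n_hap: int, chrom_index: np.ndarray, rng
) -> np.ndarray:
    """Draw haplotypes column by column under the Markov copying model.

    The fresh-draw probability at each SNP is adjusted so the marginal
    allele frequency tracks ``freqs[j]`` rather than a running average
    of upstream frequencies (copying smooths marginals otherwise); at
    ``rho = 1`` no fresh draws occur past a chromosome start and each
    chromosome haplotype is one repeated allele.
    """
    k = freqs.size
    h = np.empty((n_hap, k), dtype=np.int8)
    marginal = 0.0
    for j in range(k):
        new_chrom = j == 0 or chrom_index[j] != chrom_index[j - 1]
        if new_chrom or rho >= 1.0:
            f_j = freqs[j]
        else:
            f_j = min(max((freqs[j] - rho * marginal) / (1.0 - rho), 0.0), 1.0)
        fresh = rng.random(n_hap) < f_j
        if new_chrom:
            h[:, j] = fresh
            marginal = f_j
        else:
            copy = rng.random(n_hap) < rho
            h[:, j] = np.where(copy, h[:, j - 1], fresh)
            marginal = rho * marginal + (1.0 - rho) * f_j
    return h


def simulate_haplotypes(cfg: SimConfig) -> HaplotypePool:
    """Generate the base (line 1) haplotype pool."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    chrom_index = np.array([cfg.chromosome_of(j) for j in range(k)])
    pos = np.empty(k, dtype=np.int64)
    for c in np.unique(chrom_index):
        idx = np.where(chrom_index == c)[0]
        pos[idx] = (np.arange(idx.size) + 1) * cfg.snp_spacing_bp
    freqs = rng.uniform(0.1, 0.9, size=k)
    n_hap = cfg.pool_size or 2 * max(cfg.n_line1, cfg.n_line2)
    haps = _markov_haplotypes(freqs, cfg.rho, n_hap, chrom_index, rng)
    return HaplotypePool(haps, freqs, chrom_index, pos)


def simulate_genotypes(
    pool: HaplotypePool, cfg: SimConfig
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Sample animals as haplotype pairs; inject missing calls.

    Line 1 animals draw two haplotypes from ``pool``.  Line 2 draws from
    a second pool regenerated with beta-perturbed base frequencies
    (concentration set by ``line_divergence``, an F_ST-like magnitude;
    zero divergence reuses the base frequencies).  Returns the genotype
    matrix (with missing calls and sampled GenTrain scores) and the true
    phased haplotypes, shape (n_animals, 2, n_snps).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    k = cfg.n_snps
    n_hap = pool.haplotypes.shape[0]

    idx1 = rng.integers(0, n_hap, size=(cfg.n_line1, 2))
    haps1 = pool.haplotypes[idx1]  # (n1, 2, k)

    if cfg.line_divergence > 0:
        f = cfg.line_divergence
        c = (1.0 - f) / f
        # beta perturbation with per-SNP marginal Beta(p c, (1-p) c) driven
        # by one shared quantile per 20-SNP segment: drift-like frequency
        # shifts correlated along the chromosome, so they survive the
        # marginal smoothing of the haplotype copying process
        seg = pool.chrom_index * 10_000 + np.arange(k) // 20
        u = {s: rng.random() for s in np.unique(seg)}
        quant = np.array([u[s] for s in seg])
        p2 = stats.beta.ppf(
            quant, pool.base_freqs * c, (1.0 - pool.base_freqs) * c
        )
        p2 = np.clip(p2, 0.02, 0.98)
    else:
        p2 = pool.base_freqs
    pool2 = _markov_haplotypes(p2, cfg.rho, n_hap, pool.chrom_index, rng)
    idx2 = rng.integers(0, n_hap, size=(cfg.n_line2, 2))
    haps2 = pool2[idx2]

    haps = np.concatenate([haps1, haps2], axis=0)
    calls = haps.sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    animal_ids = [f"L1_{i:05d}" for i in range(cfg.n_line1)] + [
        f"L2_{i:05d}" for i in range(cfg.n_line2)
    ]
    gentrain = np.clip(rng.beta(20, 2, size=k), 0.0, 1.0)
    snps = pd.DataFrame(
        {
            "snp_id": [f"SNP{j:05d}" for j in range(k)],
            "chromosome": [str(c + 1) for c in pool.chrom_index],
            "position_bp": pd.array(pool.positions, dtype="Int64"),
            "gentrain_score": gentrain,
        }
    )
    return GenotypeMatrix(animal_ids, snps, calls), haps


def line_labels(gm: GenotypeMatrix) -> np.ndarray:
    """Genetic line of each animal, parsed from the simulated id prefix."""
    return np.array([a.split("_")[0] for a in gm.animal_ids])


def simulate_phenotypes(
    gm: GenotypeMatrix, cfg: SimConfig, haps: np.ndarray | None = None
) -> tuple["PhenotypeTable", TruthRecord]:
    """Draw QTL effects and phenotypes on top of simulated genotypes.

    A QTL set of size ``round((1 - pi_true) * n_snps)`` receives normal
    effects, rescaled so the sample variance of true breeding values
    equals ``h2`` on a unit phenotypic-variance scale; residual variance
    is ``1 - h2``.  Line, date and scorer effects plus the body-weight
    term are added, and each continuous trait is also emitted as a
    nine-point score by rank-binning into equal-frequency bins.
    """
    from bayesgwa.phenotype_prep import PhenotypeTable

    rng = np.random.default_rng(cfg.seed + 2)
    n, k = gm.n_animals, gm.n_snps
    if haps is not None:
        g = haps.sum(axis=1).astype(float)
    else:
        g = gm.calls.astype(float)
        for j in range(k):
            m = g[:, j] == MISSING
            if m.any():
                g[m, j] = g[~m, j].mean()

    n_qtl = int(round((1.0 - cfg.pi_true) * k))
    if n_qtl > 0:
        qtl = np.sort(rng.choice(k, size=n_qtl, replace=False))
        effects = rng.normal(0.0, np.sqrt(cfg.qtl_effect_var), size=n_qtl)
        tbv = g[:, qtl] @ effects
        var_raw = tbv.var(ddof=1)
        if var_raw <= 0:
            raise SimulationError(
                "drawn QTL carry no genetic variance; increase the number of "
                "QTL (lower pi_true) or check allele frequencies"
            )
        scale = np.sqrt(cfg.h2 / var_raw)
        effects *= scale
        tbv *= scale
        resid_sd = np.sqrt(1.0 - cfg.h2)
    else:
        qtl = np.array([], dtype=int)
        effects = np.array([])
        tbv = np.zeros(n)
        resid_sd = 1.0

    lines = np.array([0] * cfg.n_line1 + [1] * cfg.n_line2)
    dates = rng.integers(0, cfg.n_dates, size=n)
    scorers = rng.integers(0, cfg.n_scorers, size=n)
    date_eff = rng.normal(0.0, cfg.date_sd, size=cfg.n_dates)
    scorer_eff = rng.normal(0.0, cfg.scorer_sd, size=cfg.n_scorers)
    bw = rng.normal(cfg.bw_mean, cfg.bw_sd, size=n)

    fixed = (
        cfg.mu
        + cfg.line_effect * lines
        + date_eff[dates]
        + scorer_eff[scorers]
        + cfg.bw_slope * (bw - cfg.bw_mean)
    )
    resid = rng.normal(0.0, resid_sd, size=n)
    y = fixed + tbv + resid

    var_tbv = tbv.var(ddof=1) if n_qtl > 0 else 0.0
    realized_h2 = var_tbv / (tbv + resid).var(ddof=1) if n_qtl > 0 else 0.0
    truth = TruthRecord(
        qtl_indices=qtl,
        effects=effects,
        var_genetic=float(var_tbv),
        realized_h2=float(realized_h2),
        tbv=tbv,
        fixed_part=fixed,
        residuals=resid,
    )

    score = pd.Series(y).rank(method="first").to_numpy()
    score = np.ceil(score * 9 / n).astype(int)
    data = pd.DataFrame(
        {
            "animal_id": gm.animal_ids,
            "line": np.where(lines == 0, "L1", "L2"),
            "date": [f"d{d:02d}" for d in dates],
            "scorer": [f"s{s}" for s in scorers],
            "body_weight": bw,
            "trait": y,
            "trait_score": score,
        }
    )
    pt = PhenotypeTable(data, traits=["trait", "trait_score"])
    return pt, truth


def simulate_dataset(cfg: SimConfig):
    """Full pipeline: haplotype pool -> genotypes -> phenotypes + truth."""
    pool = simulate_haplotypes(cfg)
    gm, haps = simulate_genotypes(pool, cfg)
    pt, truth = simulate_phenotypes(gm, cfg, haps=haps)
    return gm, haps, pt, truth


def write_dataset(outdir: str | Path, cfg: SimConfig) -> None:
    """Simulate and write a dataset in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, haps, pt, truth = simulate_dataset(cfg)
    write_genotypes(gm, outdir / "genotypes", dialect="ped_map")
    pt.data.to_csv(outdir / "phenotypes.csv", index=False)
    truth.to_json(outdir / "truth.json")
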