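"""Genotype containers, file I/O, quality control, and IBS clustering.

Genotypes are stored as counts of the array "B" allele (0, 1, 2) with a
sentinel for missing calls, alongside per-SNP metadata (chromosome,
physical position, GenTrain clustering-quality score).  Quality control
follows the conventional array pipeline: drop low-call-rate animals
first, then filter SNPs in a fixed order (no call, call rate, GenTrain,
minor allele frequency, Hardy-Weinberg equilibrium) so that each removed
SNP has a single primary reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

MISSING = -1

#: canonical SNP metadata columns
SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "gentrain_score"]


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


def chromosome_sort_key(chrom: str) -> tuple[int, float, str]:
    """Sort key: numeric autosomes ascending, then X, then UNMAPPED last."""
    c = str(chrom)
    if c.upper() == "UNMAPPED":
        return (2, 0.0, c)
    if c.upper() == "X":
        return (1, 0.0, c)
    try:
        return (0, float(c), c)
    except ValueError:
        return (1, 1.0, c)  # other non-numeric labels (Y, MT) after X


@dataclass
class SnpMeta:
    """Metadata for one SNP assay."""

    snp_id: str
    chromosome: str = "UNMAPPED"
    position_bp: int | None = None
    gentrain_score: float | None = None


@dataclass
class GenotypeMatrix:
    """Animals x SNPs matrix of B-allele counts with per-SNP metadata.

    ``calls`` is an int8 array with entries in {0, 1, 2} or ``MISSING``
    (-1).  ``snps`` is a DataFrame with columns ``snp_id``,
    ``chromosome``, ``position_bp`` (nullable) and ``gentrain_score``
    (nullable), in matrix column order.
    """

    animal_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        n, k = self.calls.shape
        if len(self.animal_ids) != n:
            raise GenotypeError(
                f"{len(self.animal_ids)} animal ids for {n} call rows"
            )
        if len(self.snps) != k:
            raise GenotypeError(f"{len(self.snps)} SNP records for {k} call columns")
        if len(set(self.animal_ids)) != n:
            raise GenotypeError("duplicate animal ids")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise GenotypeError(f"duplicate SNP id {dup!r}")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.calls[~valid].flat[0]
            raise GenotypeError(f"genotype call {bad} outside {{0,1,2,missing}}")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sorted_by_genome(self) -> "GenotypeMatrix":
        """Return a copy with SNPs in genome order (chrom, then bp)."""
        keys = [chromosome_sort_key(c) for c in self.snps["chromosome"]]
        pos = self.snps["position_bp"].fillna(0).to_numpy()
        order = sorted(range(self.n_snps), key=lambda j: (keys[j], pos[j]))
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snps=self.snps.iloc[order],
            calls=self.calls[:, order],
        )


def _empty_meta(snp_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": "UNMAPPED",
            "position_bp": pd.array([pd.NA] * len(snp_ids), dtype="Int64"),
            "gentrain_score": np.full(len(snp_ids), np.nan),
        }
    )


def read_map(path: str | Path) -> pd.DataFrame:
    """Read a PLINK-style .map file (chrom, snp_id, cM, bp [, gentrain])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeError(f"{path}:{lineno}: expected >=4 map columns")
            chrom, snp_id, _cm, bp = parts[:4]
            gentrain = float(parts[4]) if len(parts) > 4 else np.nan
            unmapped = chrom in ("0", "UNMAPPED") or int(bp) <= 0
            rows.append(
                {
                    "snp_id": snp_id,
                    "chromosome": "UNMAPPED" if unmapped else chrom,
                    "position_bp": pd.NA if unmapped else int(bp),
                    "gentrain_score": gentrain,
                }
            )
    meta = pd.DataFrame(rows)
    meta["position_bp"] = meta["position_bp"].astype("Int64")
    return meta


def _read_ped_map(path: Path) -> GenotypeMatrix:
    prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
    meta = read_map(prefix.with_suffix(".map"))
    k = len(meta)
    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * k:
                raise GenotypeError(
                    f"{prefix.with_suffix('.ped')}:{lineno}: expected "
                    f"{6 + 2 * k} fields, found {len(parts)}"
                )
            animal_ids.append(parts[1])
            calls = np.empty(k, dtype=np.int8)
            alleles = parts[6:]
            for j in range(k):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    calls[j] = MISSING
                else:
                    try:
                        calls[j] = "AB".index(a1) + "AB".index(a2)
                    except ValueError:
                        raise GenotypeError(
                            f"{prefix.with_suffix('.ped')}:{lineno}: allele "
                            f"code {a1!r}/{a2!r} at SNP {j + 1} is not A/B/0"
                        ) from None
            rows.append(calls)
    return GenotypeMatrix(animal_ids, meta, np.array(rows, dtype=np.int8))


def _read_csv_wide(path: Path, map_path: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    snp_ids = [str(c) for c in df.columns]
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        vals = df[col]
        ok = vals.notna() & (vals.str.upper() != "NA")
        parsed = pd.to_numeric(vals[ok], errors="coerce")
        if parsed.isna().any() or not parsed.isin([0, 1, 2]).all():
            bad = vals[ok][~parsed.isin([0, 1, 2]) | parsed.isna()].iloc[0]
            raise GenotypeError(f"{path}: value {bad!r} in column {col} not 0/1/2/NA")
        calls[np.where(ok)[0], j] = parsed.astype(np.int8)
    if map_path is not None:
        meta = read_map(map_path).set_index("snp_id").loc[snp_ids].reset_index()
    else:
        meta = _empty_meta(snp_ids)
    return GenotypeMatrix([str(i) for i in df.index], meta, calls)


def read_genotypes(
    path: str | Path,
    dialect: str = "ped_map",
    map_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a text PLINK .ped/.map pair or a wide CSV.

    Parameters
    ----------
    path
        For ``ped_map``, the file prefix or either member of the pair.
        For ``csv_wide``, the CSV (header = SNP ids, one row per animal,
        values 0/1/2/NA counting B alleles).
    dialect
        ``"ped_map"`` or ``"csv_wide"``.
    map_path
        Optional .map file supplying SNP metadata for ``csv_wide``.
    """
    path = Path(path)
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "csv_wide":
        return _read_csv_wide(path, map_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: str = "ped_map") -> None:
    """Write genotypes in the same dialects :func:`read_genotypes` accepts."""
    path = Path(path)
    if dialect == "ped_map":
        prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, s in gm.snps.iterrows():
                chrom = s["chromosome"]
                bp = 0 if pd.isna(s["position_bp"]) else int(s["position_bp"])
                if chrom == "UNMAPPED":
                    chrom, bp = "0", 0
                gt = s["gentrain_score"]
                extra = "" if pd.isna(gt) else f"\t{gt:.4f}"
                fh.write(f"{chrom}\t{s['snp_id']}\t0\t{bp}{extra}\n")
        code = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, aid in enumerate(gm.animal_ids):
                alleles = " ".join(code[int(c)] for c in gm.calls[i])
                fh.write(f"FAM {aid} 0 0 0 -9 {alleles}\n")
    elif dialect == "csv_wide":
        out = pd.DataFrame(
            np.where(gm.calls == MISSING, None, gm.calls),
            index=pd.Index(gm.animal_ids, name="animal_id"),
            columns=gm.snps["snp_id"].tolist(),
        )
        out.to_csv(path, na_rep="NA")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def allele_frequency(calls: np.ndarray) -> float:
    """Frequency of the B allele in one SNP column, ignoring missing calls."""
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise GenotypeError("allele frequency undefined: all calls missing")
    return float(obs.sum()) / (2.0 * obs.size)


def hwe_chisq_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the observed allele frequency.
    Monomorphic SNPs return p = 1 (no departure is testable).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    n = counts.sum()
    if n < 1:
        raise GenotypeError("HWE test needs at least one genotype")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QcThresholds:
    """Quality-control thresholds (a zero threshold disables that check)."""

    animal_call_rate: float = 0.80
    snp_call_rate: float = 0.90
    gentrain: float = 0.50
    maf: float = 0.05
    hwe_p: float = 1e-6


@dataclass
class QcReport:
    """Record of what quality control removed and why."""

    animals_removed: list[tuple[str, str]] = field(default_factory=list)
    snps_removed: list[tuple[str, str]] = field(default_factory=list)
    thresholds: QcThresholds = field(default_factory=QcThresholds)

    def to_tsv(self, path: str | Path) -> None:
        rows = [("animal", aid, why) for aid, why in self.animals_removed]
        rows += [("snp", sid, why) for sid, why in self.snps_removed]
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def qc_filter(
    gm: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    hwe_groups: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter animals, then SNPs, in a fixed order of checks.

    Animals with call rate below ``animal_call_rate`` go first.  On the
    animal-filtered matrix, SNPs are then tested in the order
    no_call -> call_rate -> gentrain -> maf -> hwe; the first failing
    check is the SNP's recorded removal reason.  When ``hwe_groups`` is
    given the HWE test runs within each group (e.g. genetic line) and
    the minimum p-value is compared against the threshold.
    """
    th = thresholds or QcThresholds()
    report = QcReport(thresholds=th)

    observed = gm.calls != MISSING
    a_rate = observed.mean(axis=1)
    keep_a = a_rate >= th.animal_call_rate
    for i in np.where(~keep_a)[0]:
        report.animals_removed.append((gm.animal_ids[i], "call_rate"))

    calls = gm.calls[keep_a]
    groups = None if hwe_groups is None else np.asarray(hwe_groups)[keep_a]
    observed = calls != MISSING
    n_kept = calls.shape[0]

    keep_s = np.ones(gm.n_snps, dtype=bool)
    for j in range(gm.n_snps):
        col = calls[:, j]
        n_obs = int(observed[:, j].sum())
        reason = None
        if n_obs == 0 and th.snp_call_rate > 0:
            reason = "no_call"
        elif th.snp_call_rate > 0 and n_obs / n_kept < th.snp_call_rate:
            reason = "call_rate"
        else:
            gt = gm.snps["gentrain_score"].iloc[j]
            if th.gentrain > 0 and not pd.isna(gt) and gt < th.gentrain:
                reason = "gentrain"
            elif th.maf > 0:
                freq = allele_frequency(col)
                if min(freq, 1 - freq) < th.maf:
                    reason = "maf"
            if reason is None and th.hwe_p > 0:
                if groups is None:
                    grouping = [np.ones(n_kept, dtype=bool)]
                else:
                    grouping = [groups == g for g in np.unique(groups)]
                pmin = 1.0
                for g in grouping:
                    sub = col[g & observed[:, j]]
                    if sub.size:
                        pmin = min(
                            pmin,
                            hwe_chisq_pvalue(
                                int((sub == 0).sum()),
                                int((sub == 1).sum()),
                                int((sub == 2).sum()),
                            ),
                        )
                if pmin < th.hwe_p:
                    reason = "hwe"
        if reason is not None:
            keep_s[j] = False
            report.snps_removed.append((gm.snps["snp_id"].iloc[j], reason))

    if not keep_s.any():
        raise GenotypeError("quality control removed every SNP")
    out = GenotypeMatrix(
        animal_ids=[a for a, k in zip(gm.animal_ids, keep_a) if k],
        snps=gm.snps.loc[keep_s],
        calls=calls[:, keep_s],
    )
    return out, report


def ibs_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state distance, 1 - shared alleles / (2 loci).

    At each locus jointly called in both animals, genotypes g1, g2 in
    {0,1,2} share ``2 - |g1 - g2|`` of their two allele copies.
    """
    if gm.n_animals < 2:
        raise GenotypeError("IBS distance needs at least two animals")
    calls = gm.calls.astype(np.int16)
    obs = calls != MISSING
    n = gm.n_animals
    dist = np.zeros((n, n))
    for i in range(n):
        joint = obs[i] & obs[i + 1 :]
        n_joint = joint.sum(axis=1)
        if (n_joint == 0).any():
            j = i + 1 + int(np.argmax(n_joint == 0))
            raise GenotypeError(
                f"animals {gm.animal_ids[i]!r} and {gm.animal_ids[j]!r} share "
                "no jointly called locus"
            )
        shared = np.where(joint, 2 - np.abs(calls[i] - calls[i + 1 :]), 0).sum(axis=1)
        d = 1.0 - shared / (2.0 * n_joint)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def cluster_ibs(dist: np.ndarray, k: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering of an IBS distance matrix.

    Returns 0-based labels renumbered by first occurrence, so the result
    is deterministic for a given input order.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    if n == 1 or k == n:
        return np.arange(n) if k == n else np.zeros(n, dtype=int)
    z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    return labels
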