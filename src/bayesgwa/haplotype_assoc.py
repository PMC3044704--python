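"""Haplotype-dosage association through the Bayes C engine.

Within a phased block, each animal carries 0, 1 or 2 copies of every
haplotype.  Haplotypes above a frequency threshold (1% by default)
become additional 0-2 dosage covariates merged into the SNP set, and a
single Bayes C run reports their model frequencies alongside the SNPs'.
Phasing and block discovery are external inputs: the simulator supplies
truth-phased blocks, and field data can come from any phasing tool via
the two-string-per-animal representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from bayesgwa.bayesc_engine import ModelSpec, PosteriorSummary, run_chain


class HaplotypeError(ValueError):
    """Invalid haplotype input."""

_MISSING_CHARS = set("N?-.")


@dataclass
class HaplotypeBlock:
    """A contiguous phased block: SNP ids plus two allele strings/animal."""

    chromosome: str
    snp_ids: list[str]
    animal_ids: list[str]
    haplotypes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.animal_ids):
            raise HaplotypeError("one haplotype pair required per animal")
        width = len(self.snp_ids)
        for aid, (h1, h2) in zip(self.animal_ids, self.haplotypes):
            if len(h1) != width or len(h2) != width:
                raise HaplotypeError(
                    f"animal {aid!r}: haplotype length != {width} block SNPs"
                )
            if set(h1) & _MISSING_CHARS or set(h2) & _MISSING_CHARS:
                raise HaplotypeError(
                    f"animal {aid!r} has unphased/missing alleles; impute or "
                    "re-phase the block before dosage construction"
                )


@dataclass
class HaplotypeDosage:
    """Copy counts of each retained (frequency > threshold) haplotype."""

    labels: list[str]
    dosage: np.ndarray  # n_animals x n_haplotypes, values 0/1/2
    frequencies: np.ndarray  # of retained haplotypes
    dropped: dict[str, float]  # label -> frequency of dropped haplotypes
    min_freq: float


def block_from_phase(
    haps: np.ndarray,
    snp_indices,
    snp_ids,
    chromosome: str,
    animal_ids,
) -> HaplotypeBlock:
    """Build a block from a phased (n, 2, K) 0/1 allele array.

    Convenience for simulator output: alleles 0/1 become letters A/B.
    """
    snp_indices = list(snp_indices)
    pairs = []
    letters = np.array(["A", "B"])
    for a in range(haps.shape[0]):
        h1 = "".join(letters[haps[a, 0, snp_indices]])
        h2 = "".join(letters[haps[a, 1, snp_indices]])
        pairs.append((h1, h2))
    return HaplotypeBlock(
        chromosome=str(chromosome),
        snp_ids=list(snp_ids),
        animal_ids=list(animal_ids),
        haplotypes=pairs,
    )


def read_phase_file(path: str | Path, snp_ids, chromosome: str = "?") -> HaplotypeBlock:
    """Read a phased block from a two-line-per-animal text file.

    Each line is ``animal_id<whitespace>allele_string`` (letters per
    block SNP, e.g. ``pig01 ABBAB``); the two consecutive lines of an
    animal are its two haplotypes.  Blank lines and ``#`` comments are
    skipped.
    """
    animal_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    pending: tuple[str, str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise HaplotypeError(f"{path}:{lineno}: expected 'animal haplotype'")
            aid, hap = parts
            if pending is None:
                pending = (aid, hap)
            else:
                if pending[0] != aid:
                    raise HaplotypeError(
                        f"{path}:{lineno}: haplotype pair for {pending[0]!r} "
                        f"interrupted by {aid!r}"
                    )
                animal_ids.append(aid)
                pairs.append((pending[1], hap))
                pending = None
    if pending is not None:
        raise HaplotypeError(f"{path}: odd number of haplotype lines")
    return HaplotypeBlock(str(chromosome), list(snp_ids), animal_ids, pairs)


def read_block_definition(path: str | Path) -> dict:
    """Read a YAML block definition.

    Keys: ``chromosome`` plus either an explicit ``snp_ids`` list or a
    ``start_bp``/``end_bp`` range (1-based inclusive) to be resolved
    against a SNP metadata table.
    """
    d = yaml.safe_load(Path(path).read_text())
    if "chromosome" not in d or not ({"snp_ids"} <= d.keys() or {"start_bp", "end_bp"} <= d.keys()):
        raise HaplotypeError(
            "block definition needs 'chromosome' and either 'snp_ids' or "
            "'start_bp'/'end_bp'"
        )
    return d


def resolve_block_snps(definition: dict, snps) -> list[str]:
    """SNP ids of a block definition, resolved against SNP metadata."""
    if "snp_ids" in definition:
        return [str(s) for s in definition["snp_ids"]]
    sel = snps[
        (snps["chromosome"].astype(str) == str(definition["chromosome"]))
        & (snps["position_bp"] >= definition["start_bp"])
        & (snps["position_bp"] <= definition["end_bp"])
    ]
    if sel.empty:
        raise HaplotypeError("block range matches no SNP")
    return sel["snp_id"].tolist()


def haplotype_dosage(block: HaplotypeBlock, min_freq: float = 0.01) -> HaplotypeDosage:
    """Count copies of each haplotype; drop those at or below ``min_freq``.

    Frequency is copies / (2 n).  Retained and dropped frequencies sum
    to one exactly; an animal's dosage row sums to 2 minus its copies of
    dropped haplotypes.
    """
    n = len(block.animal_ids)
    counts: dict[str, int] = {}
    for h1, h2 in block.haplotypes:
        counts[h1] = counts.get(h1, 0) + 1
        counts[h2] = counts.get(h2, 0) + 1
    total = 2 * n
    labels = sorted(
        (h for h, c in counts.items() if c / total > min_freq),
        key=lambda h: (-counts[h], h),
    )
    dropped = {h: c / total for h, c in sorted(counts.items()) if c / total <= min_freq}
    index = {h: i for i, h in enumerate(labels)}
    dosage = np.zeros((n, len(labels)), dtype=np.int8)
    for a, (h1, h2) in enumerate(block.haplotypes):
        for h in (h1, h2):
            if h in index:
                dosage[a, index[h]] += 1
    return HaplotypeDosage(
        labels=labels,
        dosage=dosage,
        frequencies=np.array([counts[h] / total for h in labels]),
        dropped=dropped,
        min_freq=min_freq,
    )


def haplotype_model_frequency(
    dosage: HaplotypeDosage,
    y: np.ndarray,
    X: np.ndarray | None,
    Z: np.ndarray,
    spec: ModelSpec,
    snp_ids=None,
) -> tuple[dict[str, float], PosteriorSummary]:
    """Model frequency of each haplotype, fitted jointly with the SNPs.

    Haplotype copy counts are appended to the SNP covariate matrix and
    the whole set is fitted in one Bayes C run (same mixture prior for
    both kinds of column).  Returns a label -> model frequency mapping
    and the full posterior summary (haplotype columns last).
    """
    Z = np.asarray(Z, dtype=float)
    h = dosage.dosage.astype(float)
    for c in range(h.shape[1]):
        if (Z == h[:, c : c + 1]).all(axis=0).any():
            warnings.warn(
                f"haplotype {dosage.labels[c]!r} duplicates an SNP dosage "
                "column; kept"
            )
    z_aug = np.column_stack([Z, h])
    ids = None
    if snp_ids is not None:
        ids = list(snp_ids) + [f"hap:{lab}" for lab in dosage.labels]
    summary = run_chain(y, X, z_aug, spec, snp_ids=ids)
    k = Z.shape[1]
    freqs = {
        lab: float(summary.model_freq[k + i]) for i, lab in enumerate(dosage.labels)
    }
    return freqs, summary
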