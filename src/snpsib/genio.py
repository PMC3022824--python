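"""Genotype I/O, categorical encoding, and majority imputation.

Genotypes are held as a samples x SNPs matrix of small integer codes:
0 = minor-allele homozygote, 1 = heterozygote, 2 = major-allele homozygote,
with ``MISSING`` (-1) as the missing sentinel.  Which allele counts as
"minor" is decided on the *training* cohort only and the same mapping is
frozen and applied to the test cohort, so no test-set information leaks
into the coding.  Missing calls are filled with the per-SNP majority
category, again computed on the training matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "read_ped_map",
    "allele_frequencies",
    "encode_genotypes",
    "impute_missing",
    "read_tsv_matrix",
]

MISSING: int = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Samples x SNPs categorical genotype codes with metadata.

    Parameters
    ----------
    codes : int8 ndarray, shape (n_samples, n_snps)
        Genotype codes in {0, 1, 2} or ``MISSING``.
    sample_ids, snp_ids : lists of str
        Row / column identifiers; snp_ids (rs numbers) must be unique.
    chromosomes : list of str, optional
        Per-SNP chromosome label.
    alleles : list of (minor, major) pairs, optional
        Per-SNP allele mapping where known.
    """

    codes: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: list[str] | None = None
    alleles: list[tuple[str, str]] | None = None
    positions: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x SNPs)")
        n, m = self.codes.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match column count")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        bad = ~np.isin(self.codes, list(_VALID_CODES))
        if bad.any():
            raise ValueError("codes must be 0, 1, 2 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given SNPs, in the given order."""
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snp_ids]
        return GenotypeMatrix(
            codes=self.codes[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            snp_ids=list(snp_ids),
            chromosomes=[self.chromosomes[j] for j in idx] if self.chromosomes else None,
            alleles=[self.alleles[j] for j in idx] if self.alleles else None,
            positions=[self.positions[j] for j in idx] if self.positions else None,
        )

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.snp_ids.index(snp_id)]


def read_ped_map(ped_path, map_path):
    """Parse PLINK text .ped/.map into a raw allele-pair table.

    Returns ``(raw, sample_ids, labels, snp_meta)`` where ``raw`` is an
    (n_samples, n_snps, 2) array of single-character allele symbols with
    '0' marking a missing call, labels are 1=case/0=control (ped phenotype
    2 -> 1, 1 -> 0), and ``snp_meta`` is a DataFrame with columns
    snp_id / chromosome / position.
    """
    snp_meta = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position"],
        dtype={"chromosome": str, "snp_id": str},
    )
    m = len(snp_meta)
    sample_ids: list[str] = []
    labels: list[int] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * m} for {m} SNPs"
                )
            sample_ids.append(fields[1])
            pheno = fields[5]
            if pheno == "2":
                labels.append(1)
            elif pheno == "1":
                labels.append(0)
            else:
                raise ValueError(
                    f"{ped_path}: line {lineno} phenotype {pheno!r}; "
                    "unlabeled samples (0/-9) are unsupported"
                )
            rows.append(fields[6:])
    raw = np.array(rows, dtype="U1").reshape(len(rows), m, 2)
    return raw, sample_ids, np.array(labels, dtype=np.int8), snp_meta


def allele_frequencies(raw: np.ndarray) -> list[dict[str, int]]:
    """Per-SNP allele counts from an (n, m, 2) allele-pair table ('0' ignored)."""
    counts: list[dict[str, int]] = []
    for j in range(raw.shape[1]):
        col = raw[:, j, :].ravel()
        vals, cnts = np.unique(col[col != "0"], return_counts=True)
        counts.append(dict(zip(vals.tolist(), cnts.tolist())))
    return counts


def _minor_major(freq: dict[str, int], snp_id: str) -> tuple[str, str]:
    """Resolve (minor, major) from allele counts.

    Frequency ties break to the alphabetically first allele as minor; a
    monomorphic SNP records the observed allele as major and a placeholder
    symbol as minor (no 0/1 codes can arise from it).
    """
    alleles = sorted(freq)  # alphabetical; stable tie-break
    if len(alleles) > 2:
        raise ValueError(f"SNP {snp_id} has >2 alleles: {alleles}")
    if len(alleles) == 0:
        raise ValueError(f"SNP {snp_id} has no called alleles in training")
    if len(alleles) == 1:
        major = alleles[0]
        minor = next(a for a in "ACGTN" if a != major)
        return minor, major
    a, b = alleles
    if freq[a] < freq[b]:
        return a, b
    if freq[b] < freq[a]:
        return b, a
    return a, b  # exact tie -> alphabetically first is minor


def encode_genotypes(
    raw: np.ndarray,
    reference_frequencies: list[dict[str, int]],
    sample_ids: list[str],
    snp_meta: pd.DataFrame,
) -> GenotypeMatrix:
    """Encode allele pairs to 0/1/2 codes against training-cohort frequencies.

    The minor allele at each SNP is the less frequent allele in
    ``reference_frequencies`` (computed from the training cohort); both
    cohorts are encoded with that frozen mapping.  Codes: minor homozygote
    -> 0, heterozygote -> 1, major homozygote -> 2, missing call -> MISSING.
    """
    n, m, _ = raw.shape
    if len(reference_frequencies) != m:
        raise ValueError("reference_frequencies length does not match SNP count")
    codes = np.full((n, m), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for j in range(m):
        snp_id = str(snp_meta["snp_id"].iloc[j])
        minor, major = _minor_major(reference_frequencies[j], snp_id)
        alleles.append((minor, major))
        a1 = raw[:, j, 0]
        a2 = raw[:, j, 1]
        called = (a1 != "0") & (a2 != "0")
        known = np.isin(a1, (minor, major)) & np.isin(a2, (minor, major))
        if (called & ~known).any():
            i = int(np.flatnonzero(called & ~known)[0])
            raise ValueError(
                f"SNP {snp_id}: allele {raw[i, j].tolist()} absent from the "
                "training mapping"
            )
        # number of major alleles = paper code
        codes[:, j] = np.where(
            called, (a1 == major).astype(np.int8) + (a2 == major).astype(np.int8), MISSING
        )
    return GenotypeMatrix(
        codes=codes,
        sample_ids=list(sample_ids),
        snp_ids=snp_meta["snp_id"].astype(str).tolist(),
        chromosomes=snp_meta["chromosome"].astype(str).tolist(),
        alleles=alleles,
        positions=snp_meta["position"].tolist() if "position" in snp_meta else None,
    )


def majority_codes(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP most frequent non-missing code; ties break to the lowest code."""
    out = np.empty(G.n_snps, dtype=np.int8)
    for j in range(G.n_snps):
        col = G.codes[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            raise ValueError(f"SNP {G.snp_ids[j]} is entirely missing in training")
        out[j] = int(np.argmax(np.bincount(col, minlength=3)))  # argmax -> lowest on tie
    return out


def impute_missing(G: GenotypeMatrix, reference: GenotypeMatrix | None = None) -> GenotypeMatrix:
    """Replace missing codes with the per-SNP majority category.

    The majority is computed on ``reference`` (the training matrix) and
    applied to ``G``; when ``reference`` is None, G imputes from itself.
    """
    if not G.has_missing():
        return G
    ref = reference if reference is not None else G
    if ref.snp_ids != G.snp_ids:
        raise ValueError("reference SNP set/order does not match")
    fill = majority_codes(ref)
    codes = G.codes.copy()
    rows, cols = np.nonzero(codes == MISSING)
    codes[rows, cols] = fill[cols]
    return replace(G, codes=codes)


def read_tsv_matrix(path):
    """Read the TSV genotype dialect: header sample_id, label, rs-ids; codes {0,1,2,NA}.

    Returns ``(GenotypeMatrix, labels)`` with labels 1=case/0=control.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(f"{path}: first columns must be sample_id, label")
    snp_ids = [str(c) for c in df.columns[2:]]
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{path}: labels must be 0/1")
    geno = df[df.columns[2:]].to_numpy(dtype=object)
    codes = np.full(geno.shape, MISSING, dtype=np.int8)
    mask = pd.notna(geno) & (geno != "NA")
    vals = pd.to_numeric(pd.Series(geno[mask].ravel()), errors="raise").to_numpy()
    if not np.isin(vals, (0, 1, 2)).all():
        bad = vals[~np.isin(vals, (0, 1, 2))][0]
        raise ValueError(f"{path}: invalid genotype code {bad!r}")
    codes[mask] = vals.astype(np.int8)
    G = GenotypeMatrix(
        codes=codes,
        sample_ids=df["sample_id"].astype(str).tolist(),
        snp_ids=snp_ids,
    )
    return G, labels.astype(np.int8)
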