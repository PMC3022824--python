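"""Synthetic two-cohort case-control genotype studies with known causal SNPs.

Emulates the design of a genome-wide psoriasis case-control study: two
independent cohorts (a training cohort of 941 cases / 686 controls and a
test cohort of 443 cases / 728 controls), biallelic SNPs in Hardy-Weinberg
equilibrium with minor allele frequencies drawn from a common-variant
spectrum, a handful of causal SNPs acting additively on the log-odds of
disease, and a small rate of missing genotype calls.  Individuals are drawn
by rejection sampling (genotype -> disease probability -> Bernoulli label)
until the exact case/control quotas of each cohort are met, which preserves
the genotype-phenotype dependence while fixing the cohort composition, as a
quota-based case-control design does.

The default configuration is a desk-scale stand-in for the full study:
500 SNPs (instead of 451,724) with two causal SNPs of per-allele log-odds
1.1; the full SNP count is available by setting ``n_snps`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genio import MISSING, GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_cohorts", "write_cohort", "FULL_SCALE_N_SNPS"]

#: SNP count of the emulated genotyping array (documented full-scale setting).
FULL_SCALE_N_SNPS = 451_724


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated two-cohort study.

    Cohort sizes default to the emulated study's counts.  ``causal_log_odds``
    are per-minor-allele effects on the logistic scale; ``intercept`` is the
    baseline log-odds of disease; ``test_intercept_shift`` offsets the test
    cohort's intercept to emulate a prevalence difference between cohorts
    (0 by default: one source population, different sampling quotas).
    """

    n_cases_train: int = 941
    n_controls_train: int = 686
    n_cases_test: int = 443
    n_controls_test: int = 728
    n_snps: int = 500
    causal_indices: tuple[int, ...] = (100, 300)
    causal_log_odds: tuple[float, ...] = (1.1, 1.1)
    intercept: float = -1.3
    maf_low: float = 0.10
    maf_high: float = 0.50
    missing_rate: float = 0.01
    test_intercept_shift: float = 0.0
    seed: int = 0
    max_attempt_factor: int = 2000
    ld_block_rho: float = 0.0  # optional adjacent-SNP LD; 0 = independent SNPs
    ld_block_size: int = 1

    def __post_init__(self) -> None:
        if len(self.causal_indices) != len(self.causal_log_odds):
            raise ValueError("causal_indices and causal_log_odds must align")
        if any(i < 0 or i >= self.n_snps for i in self.causal_indices):
            raise ValueError("causal_indices must be < n_snps")
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal_indices must be distinct")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_cases_train", "n_controls_train", "n_cases_test",
                     "n_controls_test", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ld_block_rho < 1.0:
            raise ValueError("ld_block_rho must be in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated study, for parameter-recovery checks."""

    mafs: np.ndarray
    causal_indices: tuple[int, ...]
    causal_log_odds: tuple[float, ...]
    intercept: float
    realized_prevalence_train: float
    realized_prevalence_test: float


class RejectionCapExceeded(RuntimeError):
    """Raised when a cohort's case/control quota cannot be filled.

    Signals an unattainable configuration, e.g. an intercept so low that
    cases are practically never drawn.
    """

    def __init__(self, cohort: str, needed_cases: int, needed_controls: int):
        super().__init__(
            f"rejection sampling cap exceeded for the {cohort} cohort "
            f"(still missing {needed_cases} cases, {needed_controls} controls); "
            "check intercept / effect sizes"
        )
        self.cohort = cohort


def _draw_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray,
                  cfg: SimConfig) -> np.ndarray:
    """HWE minor-allele dosages; optional block-LD by haplotype copying."""
    m = mafs.size
    if cfg.ld_block_rho == 0.0 or cfg.ld_block_size <= 1:
        return rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    # two haplotypes per person; within a block each successive SNP copies the
    # previous SNP's allele with probability rho, else draws fresh from its MAF
    hap = np.empty((2, n, m), dtype=np.int8)
    for h in range(2):
        fresh = rng.random((n, m)) < mafs
        hap[h] = fresh
        for j in range(1, m):
            if j % cfg.ld_block_size != 0:
                copy = rng.random(n) < cfg.ld_block_rho
                hap[h, :, j] = np.where(copy, hap[h, :, j - 1], fresh[:, j])
    return (hap[0] + hap[1]).astype(np.int8)


def _sample_cohort(rng, cfg: SimConfig, mafs, n_cases, n_controls, shift, cohort):
    beta = np.zeros(cfg.n_snps)
    for i, b in zip(cfg.causal_indices, cfg.causal_log_odds):
        beta[i] = b
    need_case, need_ctrl = n_cases, n_controls
    total = n_cases + n_controls
    case_rows, ctrl_rows = [], []
    attempts = 0
    cap = cfg.max_attempt_factor * total
    n_drawn_labels = 0
    n_drawn_cases = 0
    batch = max(256, 2 * total)
    while need_case > 0 or need_ctrl > 0:
        if attempts >= cap:
            raise RejectionCapExceeded(cohort, need_case, need_ctrl)
        nb = min(batch, cap - attempts)
        attempts += nb
        g = _draw_dosages(rng, nb, mafs, cfg)
        eta = cfg.intercept + shift + g @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        is_case = rng.random(nb) < p
        n_drawn_labels += nb
        n_drawn_cases += int(is_case.sum())
        if need_case > 0:
            take = g[is_case][:need_case]
            case_rows.append(take)
            need_case -= take.shape[0]
        if need_ctrl > 0:
            take = g[~is_case][:need_ctrl]
            ctrl_rows.append(take)
            need_ctrl -= take.shape[0]
    dosages = np.vstack(
        [np.vstack(case_rows) if case_rows else np.empty((0, cfg.n_snps), np.int8),
         np.vstack(ctrl_rows) if ctrl_rows else np.empty((0, cfg.n_snps), np.int8)]
    )
    labels = np.concatenate(
        [np.ones(n_cases, np.int8), np.zeros(n_controls, np.int8)]
    )
    prevalence = n_drawn_cases / n_drawn_labels
    return dosages, labels, prevalence


def _to_matrix(rng, dosages, labels_prefix, mafs, alleles, cfg, snp_ids, chroms, positions):
    codes = (2 - dosages).astype(np.int8)  # dosage of minor alleles -> 0/1/2 coding
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING
    n = codes.shape[0]
    sample_ids = [f"{labels_prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(
        codes=codes,
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        alleles=alleles,
        positions=positions,
    )


def simulate_cohorts(config: SimConfig):
    """Simulate the training and test cohorts of one study.

    Returns ``((G_train, y_train), (G_test, y_test), truth)``.  Genotype
    codes follow the analysis convention (0 = minor homozygote, 1 =
    heterozygote, 2 = major homozygote); the causal log-odds act per minor
    allele.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(config.maf_low, config.maf_high, config.n_snps)
    nts = np.array(list("ACGT"))
    pair_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(config.n_snps)])
    alleles = [(str(nts[i]), str(nts[j])) for i, j in pair_idx]
    snp_ids = [f"rs{100000 + j}" for j in range(config.n_snps)]
    chroms = [str(1 + (j % 22)) for j in range(config.n_snps)]
    positions = [10_000 + 5_000 * j for j in range(config.n_snps)]

    d_tr, y_tr, prev_tr = _sample_cohort(
        rng, config, mafs, config.n_cases_train, config.n_controls_train, 0.0, "training"
    )
    d_te, y_te, prev_te = _sample_cohort(
        rng, config, mafs, config.n_cases_test, config.n_controls_test,
        config.test_intercept_shift, "test"
    )
    G_tr = _to_matrix(rng, d_tr, "TR", mafs, alleles, config, snp_ids, chroms, positions)
    G_te = _to_matrix(rng, d_te, "TE", mafs, alleles, config, snp_ids, chroms, positions)
    truth = SimTruth(
        mafs=mafs,
        causal_indices=tuple(config.causal_indices),
        causal_log_odds=tuple(config.causal_log_odds),
        intercept=config.intercept,
        realized_prevalence_train=prev_tr,
        realized_prevalence_test=prev_te,
    )
    return (G_tr, y_tr), (G_te, y_te), truth


def write_cohort(G: GenotypeMatrix, labels, path_prefix, format: str = "tsv"):
    """Write a cohort to disk; round-trips bit-exactly through the readers.

    ``format='tsv'`` writes ``<prefix>.tsv`` in the package's TSV dialect
    (missing -> NA).  ``format='ped_map'`` writes PLINK text ``<prefix>.ped``
    and ``<prefix>.map`` (missing -> "0 0", phenotype 2=case/1=control);
    the matrix must carry allele metadata.
    Returns the list of written paths.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    if labels.shape[0] != G.n_samples:
        raise ValueError("labels length does not match sample count")
    if format == "tsv":
        path = prefix.with_suffix(".tsv")
        with open(path, "w") as fh:
            fh.write("sample_id\tlabel\t" + "\t".join(G.snp_ids) + "\n")
            for i, sid in enumerate(G.sample_ids):
                row = G.codes[i]
                cells = ["NA" if c == MISSING else str(int(c)) for c in row]
                fh.write(f"{sid}\t{int(labels[i])}\t" + "\t".join(cells) + "\n")
        return [path]
    if format == "ped_map":
        if G.alleles is None:
            raise ValueError("ped output requires allele metadata")
        chroms = G.chromosomes or ["1"] * G.n_snps
        positions = G.positions or [1000 * (j + 1) for j in range(G.n_snps)]
        map_path = prefix.with_suffix(".map")
        ped_path = prefix.with_suffix(".ped")
        with open(map_path, "w") as fh:
            for j, sid in enumerate(G.snp_ids):
                fh.write(f"{chroms[j]}\t{sid}\t0\t{positions[j]}\n")
        # code = number of major alleles: 0 -> minor/minor ... 2 -> major/major
        with open(ped_path, "w") as fh:
            for i, sid in enumerate(G.sample_ids):
                fields = [sid, sid, "0", "0", "0", "2" if labels[i] == 1 else "1"]
                for j in range(G.n_snps):
                    c = G.codes[i, j]
                    minor, major = G.alleles[j]
                    if c == MISSING:
                        fields += ["0", "0"]
                    elif c == 0:
                        fields += [minor, minor]
                    elif c == 1:
                        fields += [minor, major]
                    else:
                        fields += [major, major]
                fh.write(" ".join(fields) + "\n")
        return [ped_path, map_path]
    raise ValueError(f"unknown format {format!r}")
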