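"""SNP quality control and dosage preparation for the genomic matrix.

Two filters are applied in a fixed, audited order: first markers whose call
rate is at or below the threshold are removed, then — with allele
frequencies recomputed on the survivors' non-missing calls — markers whose
minor allele frequency is at or below the MAF threshold.  Both thresholds
are *inclusive* (a call rate of exactly 95% or a MAF of exactly 0.05 is
removed); the bounds are configurable.

After QC, :func:`impute_and_center` mean-imputes missing calls to ``2 p_j``
and column-centres the dosage matrix, producing the ``Z`` matrix from which
the genomic relationship matrix is built.  Frequencies are computed from
the observed calls of the genotyped set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .io_formats import GenotypeMatrix, MISSING_DOSAGE


@dataclass
class QCReport:
    """Tally of the SNP filters, with removal reasons in filter order."""

    n_input_snps: int
    n_removed_callrate: int
    n_removed_maf: int
    n_retained: int
    allele_freq: np.ndarray          # per retained SNP, observed calls
    callrate_max_removed: float
    maf_max_removed: float

    def __post_init__(self) -> None:
        total = self.n_removed_callrate + self.n_removed_maf + self.n_retained
        if total != self.n_input_snps:
            raise ValueError("QC tallies do not add up")

    def to_yaml(self, path=None) -> str:
        doc = {
            "n_input_snps": int(self.n_input_snps),
            "n_removed_callrate": int(self.n_removed_callrate),
            "n_removed_maf": int(self.n_removed_maf),
            "n_retained": int(self.n_retained),
            "callrate_max_removed": float(self.callrate_max_removed),
            "maf_max_removed": float(self.maf_max_removed),
            "filter_order": ["callrate", "maf"],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _observed_freq(dosages: np.ndarray) -> np.ndarray:
    """Reference-allele frequency per SNP from non-missing calls."""
    obs = dosages != MISSING_DOSAGE
    n_obs = obs.sum(axis=0)
    totals = np.where(obs, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = totals / (2.0 * n_obs)
    return np.where(n_obs > 0, p, np.nan)


def filter_snps(
    genotypes: GenotypeMatrix,
    callrate_max_removed: float = 0.95,
    maf_max_removed: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the call-rate then MAF filters (inclusive thresholds).

    MAF is computed on the non-missing calls of the SNPs surviving the
    call-rate filter.  Returns the filtered matrix and a :class:`QCReport`.
    """
    if genotypes.n_animals == 0:
        raise ValueError("cannot run SNP QC with zero animals")
    dos = genotypes.dosages
    call_rate = (dos != MISSING_DOSAGE).mean(axis=0)
    keep_cr = call_rate > callrate_max_removed
    n_removed_cr = int((~keep_cr).sum())

    surv = dos[:, keep_cr]
    p = _observed_freq(surv)
    # MAF from allele counts, not 1-p: with p = 19/20 the float expression
    # 1-p exceeds 0.05 by rounding and would dodge the inclusive threshold
    obs = surv != MISSING_DOSAGE
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, surv, 0).sum(axis=0)
    maf = np.minimum(alt, n_alleles - alt) / np.maximum(n_alleles, 1)
    # an all-missing column cannot occur here (call rate 0 <= threshold)
    keep_maf = maf > maf_max_removed
    n_removed_maf = int((~keep_maf).sum())

    kept_cols = np.flatnonzero(keep_cr)[keep_maf]
    filtered = GenotypeMatrix(
        genotypes.animal_ids.copy(),
        dos[:, kept_cols],
        [genotypes.snp_ids[j] for j in kept_cols],
    )
    report = QCReport(
        n_input_snps=genotypes.n_snps,
        n_removed_callrate=n_removed_cr,
        n_removed_maf=n_removed_maf,
        n_retained=len(kept_cols),
        allele_freq=p[keep_maf],
        callrate_max_removed=callrate_max_removed,
        maf_max_removed=maf_max_removed,
    )
    return filtered, report


def impute_and_center(
    genotypes: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages to ``2 p_j`` and column-centre.

    Returns ``(Z, p)`` with ``Z = M - 2p`` after imputation.  A monomorphic
    column (p of 0 or 1) is a hard error: QC should have removed it.
    """
    dos = genotypes.dosages.astype(float)
    p = _observed_freq(genotypes.dosages)
    if np.any(np.isnan(p)) or np.any((p <= 0.0) | (p >= 1.0)):
        bad = np.flatnonzero(np.isnan(p) | (p <= 0.0) | (p >= 1.0))[0]
        raise ValueError(
            f"monomorphic or all-missing SNP {genotypes.snp_ids[bad]!r} "
            "after QC; rerun filter_snps"
        )
    miss = genotypes.missing_mask
    dos[miss] = (2.0 * p)[np.newaxis, :].repeat(genotypes.n_animals, 0)[miss]
    Z = dos - 2.0 * p
    return Z, p
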