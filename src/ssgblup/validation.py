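"""Accuracy experiment: deregressed phenotypes, holdout CV, agreement.

The accuracy protocol treats deregressed phenotypes ď as the "true"
breeding values: fixed-effect solutions are estimated once on the FULL
data by ordinary least squares on ``y = Xb + e``, each record is adjusted
to its residual, and an animal's residuals are averaged across its
repeated measurements.  Prediction accuracy of a method is the Pearson
correlation between ď and the predicted breeding values of a random
holdout of genotyped animals whose records were removed from training;
the holdout is redrawn per replicate, both methods are solved on identical
training data, and the method contrast is summarized by a paired t-test
across replicates.

A forward check removes the last recording period's records for a listed
set of animals and compares the two methods' ability to predict those
animals' full-data ď.  Agreement between the two evaluations over
genotyped animals is summarized by Pearson and Spearman correlations and
by the overlap of truncation-selected top fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Dataset, Pedigree, PhenotypeTable
from .mixed_model import (
    EvaluationResult,
    ModelMatrices,
    VarianceComponents,
    build_design,
    em_reml,
    solve_mme,
)
from .relationship_matrices import (
    RelationshipMatrix,
    a22,
    a_inverse,
    blend_G,
    h_inverse,
    vanraden_G,
)
from .snp_qc import filter_snps, impute_and_center

logger = logging.getLogger("ssgblup")


# ---------------------------------------------------------------------------
# deregression
# ---------------------------------------------------------------------------

@dataclass
class DeregressedSet:
    """Per-animal ď values (trait units) and the record counts behind them."""

    animals: np.ndarray              # internal IDs, sorted
    values: np.ndarray
    counts: np.ndarray

    def lookup(self, ids) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        pos = np.searchsorted(self.animals, ids)
        if np.any(pos >= len(self.animals)) or np.any(self.animals[np.minimum(pos, len(self.animals) - 1)] != ids):
            missing = ids[(pos >= len(self.animals)) | (self.animals[np.minimum(pos, len(self.animals) - 1)] != ids)]
            raise KeyError(f"no deregressed value for animals {missing[:5].tolist()}")
        return self.values[pos]


def deregress(
    phenotypes: PhenotypeTable, pedigree: Pedigree
) -> DeregressedSet:
    """Fixed-effects-only OLS adjustment averaged per animal.

    Fits ``y = Xb + e`` (the same fixed-effect structure as the full
    model), takes per-record residuals and averages them within animal.
    Animals with no records are simply absent from the output.
    """
    mm = build_design(phenotypes, pedigree)
    b, *_ = np.linalg.lstsq(mm.X, mm.y, rcond=None)
    resid = mm.y - mm.X @ b
    animals = phenotypes.data["animal"].to_numpy(dtype=np.int64)
    order = np.argsort(animals, kind="stable")
    uniq, start_counts = np.unique(animals[order], return_counts=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, np.searchsorted(uniq, animals), resid)
    return DeregressedSet(animals=uniq, values=sums / start_counts,
                          counts=start_counts)


# ---------------------------------------------------------------------------
# holdout and accuracy
# ---------------------------------------------------------------------------

def holdout_replicate(
    phenotypes: PhenotypeTable,
    genotyped_ids,
    n_test: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[PhenotypeTable, np.ndarray]:
    """Remove ALL records of a random sample of genotyped animals.

    The pedigree and genotypes are untouched — held-out animals remain in
    the relationship matrices and receive predictions through relatives
    and markers.  Returns the training table and the sorted test IDs.
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    if n_test > len(genotyped_ids):
        raise ValueError(
            f"n_test={n_test} exceeds the {len(genotyped_ids)} genotyped animals"
        )
    rng = np.random.default_rng(seed)
    test_ids = np.sort(rng.choice(genotyped_ids, size=n_test, replace=False))
    keep = ~phenotypes.data["animal"].isin(test_ids)
    return phenotypes.subset(keep), test_ids


def accuracy(
    result: EvaluationResult,
    deregressed: DeregressedSet,
    test_ids,
) -> float:
    """Pearson correlation of (ď, û) over the test animals.

    ď must come from the full data; predictions from the reduced data.
    """
    test_ids = np.asarray(test_ids, dtype=np.int64)
    if len(test_ids) < 3:
        raise ValueError("need at least 3 test animals for a correlation")
    d = deregressed.lookup(test_ids)
    u = result.u[test_ids - 1]
    if np.std(d) == 0 or np.std(u) == 0:
        raise ValueError("zero variance in ď or predictions over the test set")
    return float(np.corrcoef(d, u)[0, 1])


# ---------------------------------------------------------------------------
# kernels from a dataset
# ---------------------------------------------------------------------------

@dataclass
class Kernels:
    a_inv: RelationshipMatrix
    h_inv: RelationshipMatrix
    a22_m: RelationshipMatrix | None = None
    g_blended: RelationshipMatrix | None = None
    qc_report: object | None = None


def build_kernels(
    dataset: Dataset,
    blend_weight: float = 0.95,
    callrate_max_removed: float = 0.95,
    maf_max_removed: float = 0.05,
) -> Kernels:
    """QC genotypes and assemble A⁻¹ and H⁻¹ for a dataset (built once;
    they do not depend on which records are held out)."""
    Ainv = a_inverse(dataset.pedigree)
    if dataset.genotypes is None or dataset.genotypes.n_animals == 0:
        return Kernels(a_inv=Ainv, h_inv=h_inverse(Ainv, None, None))
    filtered, report = filter_snps(
        dataset.genotypes, callrate_max_removed, maf_max_removed
    )
    Z, p = impute_and_center(filtered)
    G = vanraden_G(Z, p, ids=filtered.animal_ids)
    A22_m = a22(dataset.pedigree, filtered.animal_ids, A_inv=Ainv)
    Gstar = blend_G(G, A22_m, w=blend_weight)
    Hinv = h_inverse(Ainv, Gstar, A22_m)
    return Kernels(a_inv=Ainv, h_inv=Hinv, a22_m=A22_m,
                   g_blended=Gstar, qc_report=report)


# ---------------------------------------------------------------------------
# replicated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    n_test: int = 100
    n_replicates: int = 50
    master_seed: int = 0
    reestimate_components: bool = True   # EM-REML per replicate per method
    components: VarianceComponents | None = None  # start / fixed values
    blend_weight: float = 0.95
    reml_tol: float = 1e-6
    reml_maxiter: int = 200


@dataclass
class CVResult:
    replicates: pd.DataFrame             # per-replicate accuracies and seeds
    mean_blup: float
    se_blup: float
    mean_ssgblup: float
    se_ssgblup: float
    mean_difference: float
    se_difference: float
    p_value: float
    p_value_flag: str
    percent_increase: float
    n_failed: int = 0

    def summary(self) -> dict:
        return {
            "n_replicates": int(len(self.replicates)),
            "mean_blup": self.mean_blup,
            "se_blup": self.se_blup,
            "mean_ssgblup": self.mean_ssgblup,
            "se_ssgblup": self.se_ssgblup,
            "mean_difference": self.mean_difference,
            "se_difference": self.se_difference,
            "p_value": self.p_value,
            "p_value_flag": self.p_value_flag,
            "percent_increase": self.percent_increase,
            "n_failed": self.n_failed,
        }


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Per-replicate seed independent of the replicate count."""
    return np.random.SeedSequence(master_seed, spawn_key=(replicate,))


def _fit_components(
    mm: ModelMatrices,
    kernel: RelationshipMatrix,
    config: CVConfig,
) -> VarianceComponents:
    if not config.reestimate_components:
        if config.components is None:
            raise ValueError(
                "reestimate_components=False requires fixed components"
            )
        return config.components
    res = em_reml(mm, kernel, start=config.components,
                  tol=config.reml_tol, maxiter=config.reml_maxiter)
    return res.components


def run_cv(dataset: Dataset, config: CVConfig,
           kernels: Kernels | None = None) -> CVResult:
    """Replicated holdout comparison of pedigree BLUP vs single-step GBLUP.

    Per replicate: draw the holdout from the genotyped animals, build the
    training design, (optionally re-)estimate variance components per
    method, solve both methods on identical training data, and score each
    against the full-data ď of the held-out animals.  Summaries include a
    paired two-sided t-test on per-replicate differences and the percent
    increase 100·(mean_ssgblup − mean_blup)/mean_blup.
    """
    if kernels is None:
        kernels = build_kernels(dataset, blend_weight=config.blend_weight)
    dereg = deregress(dataset.phenotypes, dataset.pedigree)
    genotyped = dataset.genotyped_ids
    rows = []
    n_failed = 0
    for rep in range(config.n_replicates):
        seed = replicate_seed(config.master_seed, rep)
        try:
            if len(genotyped):
                train, test_ids = holdout_replicate(
                    dataset.phenotypes, genotyped, config.n_test, seed
                )
            else:
                # degenerate: no genotypes — hold out from animals with records
                train, test_ids = holdout_replicate(
                    dataset.phenotypes,
                    dereg.animals,
                    config.n_test,
                    seed,
                )
            mm = build_design(train, dataset.pedigree)
            vc_a = _fit_components(mm, kernels.a_inv, config)
            vc_h = _fit_components(mm, kernels.h_inv, config)
            res_a = solve_mme(mm, vc_a, kernels.a_inv, kernel_label="blup",
                              trait=dataset.phenotypes.trait)
            res_h = solve_mme(mm, vc_h, kernels.h_inv, kernel_label="ssgblup",
                              trait=dataset.phenotypes.trait)
            acc_a = accuracy(res_a, dereg, test_ids)
            acc_h = accuracy(res_h, dereg, test_ids)
        except Exception as err:  # record and skip
            logger.warning("replicate %d failed: %s", rep, err)
            n_failed += 1
            continue
        rows.append(
            {
                "replicate": rep,
                "seed": int(seed.entropy),
                "accuracy_blup": acc_a,
                "accuracy_ssgblup": acc_h,
                "sigma_u2_blup": vc_a.sigma_u2,
                "sigma_c2_blup": vc_a.sigma_c2,
                "sigma_e2_blup": vc_a.sigma_e2,
                "sigma_u2_ssgblup": vc_h.sigma_u2,
                "sigma_c2_ssgblup": vc_h.sigma_c2,
                "sigma_e2_ssgblup": vc_h.sigma_e2,
            }
        )
    if n_failed >= 0.2 * config.n_replicates and config.n_replicates > 0:
        raise RuntimeError(
            f"{n_failed}/{config.n_replicates} cross-validation replicates failed"
        )
    df = pd.DataFrame(rows)
    acc_a = df["accuracy_blup"].to_numpy()
    acc_h = df["accuracy_ssgblup"].to_numpy()
    diff = acc_h - acc_a
    nrep = len(df)
    se = lambda v: float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
    if np.allclose(diff, 0.0, atol=1e-14):
        p_value, flag = 1.0, "degenerate: identical accuracies in every replicate"
    else:
        p_value = float(stats.ttest_rel(acc_h, acc_a).pvalue)
        flag = ""
    mean_a = float(acc_a.mean())
    mean_h = float(acc_h.mean())
    return CVResult(
        replicates=df,
        mean_blup=mean_a,
        se_blup=se(acc_a),
        mean_ssgblup=mean_h,
        se_ssgblup=se(acc_h),
        mean_difference=float(diff.mean()),
        se_difference=se(diff),
        p_value=p_value,
        p_value_flag=flag,
        percent_increase=percent_increase(mean_a, mean_h),
        n_failed=n_failed,
    )


def percent_increase(mean_blup: float, mean_ssgblup: float) -> float:
    """100·(mean_ssgblup − mean_blup)/mean_blup, from unrounded means."""
    if mean_blup == 0:
        raise ValueError("BLUP mean accuracy is zero; percent increase undefined")
    return 100.0 * (mean_ssgblup - mean_blup) / mean_blup


# ---------------------------------------------------------------------------
# forward validation
# ---------------------------------------------------------------------------

def _year_sort_key(level: str):
    digits = "".join(ch for ch in str(level) if ch.isdigit())
    return (int(digits) if digits else -1, str(level))


def last_period_animals(phenotypes: PhenotypeTable) -> tuple[str, np.ndarray]:
    """The last year level and the animals with records in it."""
    levels = sorted(map(str, phenotypes.data["year"].unique()), key=_year_sort_key)
    last = levels[-1]
    mask = phenotypes.data["year"].astype(str) == last
    return last, np.unique(phenotypes.data.loc[mask, "animal"].to_numpy(np.int64))


def forward_validation(
    dataset: Dataset,
    config: CVConfig,
    last_period_ids=None,
    kernels: Kernels | None = None,
) -> dict:
    """Forward check: drop the last period's records for listed animals.

    All last-period records of the listed animals (default: every animal
    recorded in the last year) are removed, both methods are refitted, and
    their predictions are correlated with the animals' full-data ď.
    Reports both correlations, the percent change, and the genotyped
    fraction of the evaluated animals.
    """
    if kernels is None:
        kernels = build_kernels(dataset, blend_weight=config.blend_weight)
    last, in_last = last_period_animals(dataset.phenotypes)
    if len(in_last) == 0:
        raise ValueError("last recording period has no records")
    ids = (
        np.asarray(last_period_ids, dtype=np.int64)
        if last_period_ids is not None
        else in_last
    )
    df = dataset.phenotypes.data
    drop = (df["year"].astype(str) == last) & df["animal"].isin(ids)
    train = dataset.phenotypes.subset(~drop)

    dereg = deregress(dataset.phenotypes, dataset.pedigree)
    eval_ids = np.intersect1d(ids, dereg.animals)
    mm = build_design(train, dataset.pedigree)
    out = {"last_period": last, "n_animals": int(len(eval_ids))}
    geno = set(dataset.genotyped_ids.tolist())
    out["genotyped_fraction"] = (
        float(np.mean([a in geno for a in eval_ids])) if len(eval_ids) else 0.0
    )
    for label, kern in (("blup", kernels.a_inv), ("ssgblup", kernels.h_inv)):
        vc = _fit_components(mm, kern, config)
        res = solve_mme(mm, vc, kern, kernel_label=label,
                        trait=dataset.phenotypes.trait)
        out[f"correlation_{label}"] = accuracy(res, dereg, eval_ids)
    out["percent_change"] = percent_increase(
        out["correlation_blup"], out["correlation_ssgblup"]
    )
    return out


# ---------------------------------------------------------------------------
# method agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    pearson: float
    spearman: float
    selection_count: int
    overlap_count: int
    overlap_percent: float
    selected_blup: np.ndarray
    selected_ssgblup: np.ndarray

    def summary(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "selection_count": int(self.selection_count),
            "overlap_count": int(self.overlap_count),
            "overlap_percent": self.overlap_percent,
        }


def selection_count(n_genotyped: int, top_fraction: float = 0.25) -> int:
    """Truncation-selection count: ceiling(top_fraction × n_genotyped)."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    return int(math.ceil(top_fraction * n_genotyped))


def method_agreement(
    result_blup: EvaluationResult,
    result_ssgblup: EvaluationResult,
    genotyped_ids,
    top_fraction: float = 0.25,
) -> AgreementResult:
    """Pearson/Spearman agreement and truncation-selection overlap.

    Both evaluations are compared over the genotyped animals; the top
    ``ceiling(top_fraction × n)`` animals per method are intersected.
    Ranking ties are broken by internal animal ID, so selection is
    deterministic.
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    k = selection_count(len(genotyped_ids), top_fraction)
    pbv = result_blup.u[genotyped_ids - 1]
    gpbv = result_ssgblup.u[genotyped_ids - 1]
    if np.std(pbv) == 0 or np.std(gpbv) == 0:
        pearson = spearman = float("nan")  # constant ranking, undefined
    else:
        pearson = float(np.corrcoef(pbv, gpbv)[0, 1])
        spearman = float(stats.spearmanr(pbv, gpbv).statistic)

    def top(values):
        order = np.lexsort((genotyped_ids, -values))
        return np.sort(genotyped_ids[order[:k]])

    sel_a = top(pbv)
    sel_h = top(gpbv)
    overlap = int(len(np.intersect1d(sel_a, sel_h)))
    return AgreementResult(
        pearson=pearson,
        spearman=spearman,
        selection_count=k,
        overlap_count=overlap,
        overlap_percent=100.0 * overlap / k,
        selected_blup=sel_a,
        selected_ssgblup=sel_h,
    )
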