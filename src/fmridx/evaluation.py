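"""Feature-set assembly, cross-validated diagnosis, baselines, comparisons.

Fifteen feature sets are evaluated per setting: the phenotypic-only set,
plus "imaging only" and "imaging + phenotypic" sets for each of the seven
feature-creation processes.  Classification uses a linear-kernel SVM
(one-vs-one in the three-class setting) with fixed 10-fold cross-validation
folds shared across feature sets.

Leakage discipline: per-subject preprocessing (standardization, averaging,
global z-normalization) uses no cross-subject statistics.  Everything that
does — the auto brain mask, the PCA/kPCA fit, phenotype imputation and
standardization — is fitted on the training portion of each fold and only
applied to the test portion.  A transductive mode (reduction and mask
fitted on all subjects, classifier still fold-honest) reproduces the
protocol reading in which the reduction saw every subject before
cross-validation.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .errors import DegenerateInputError, GridMismatchError, ValidationError
from .preprocess import BrainMask, MaskedScan, Scan4D, apply_mask, compute_brain_mask
from .reduction import (
    DEFAULT_SIGMA,
    FeatureBlock,
    ReductionModel,
    make_features,
    parse_process,
)

log = logging.getLogger(__name__)

IQ_COLUMNS = ("viq", "piq", "fiq")
SETTINGS = ("two_class", "three_class")

#: Caveat attached to fold-wise variance figures: overlapping training sets
#: make the cross-validation standard deviation an underestimate of the true
#: prediction-error variance.
CV_VARIANCE_CAVEAT = (
    "Note: cross-validation training sets overlap, so fold-wise standard "
    "deviations underestimate the variance of the prediction error."
)


@dataclass
class Cohort:
    """Preprocessed scans plus phenotypes (and an optional explicit mask).

    ``scans`` must already be standardized, averaged and normalized
    (per-subject operations); masking and reduction happen inside the
    evaluation loop so they can be fitted fold-honestly.
    """

    scans: list[Scan4D]
    phenotypes: pd.DataFrame
    mask: Optional[BrainMask] = None

    def __post_init__(self) -> None:
        if len(self.scans) != len(self.phenotypes):
            raise ValidationError("one phenotype row per scan is required")
        if "dx" not in self.phenotypes or self.phenotypes["dx"].isna().any():
            raise ValidationError("dx label required for every subject")
        if "site" not in self.phenotypes or self.phenotypes["site"].isna().any():
            raise ValidationError("site required for every subject")
        dims = {s.dims for s in self.scans}
        if len(dims) > 1:
            raise GridMismatchError(f"scans on inconsistent grids: {sorted(dims)}")

    @property
    def n(self) -> int:
        return len(self.scans)

    def labels(self, setting: str) -> np.ndarray:
        return collapse_labels(self.phenotypes["dx"].to_numpy(), setting)


@dataclass
class FeatureSpec:
    """One of the 15 feature sets: which process, and which data blocks."""

    variant: Optional[str] = None  # pca_t | pca_st | kpca_st | None
    use_fft: bool = False
    use_imaging: bool = True
    use_phenotypes: bool = False
    m: object = None  # int, variance fraction in (0, 1), or None
    sigma: float = DEFAULT_SIGMA
    include_handedness: bool = False

    def __post_init__(self) -> None:
        if not self.use_imaging and not self.use_phenotypes:
            raise ValidationError("a feature set needs imaging and/or phenotypic data")
        if self.use_imaging and self.variant is None and not self.use_fft:
            raise ValidationError(
                "raw waveforms without FFT or a PCA variant are not a feature set"
            )

    @classmethod
    def from_process(cls, process: str, use_phenotypes: bool = False, m=None,
                     sigma: float = DEFAULT_SIGMA) -> "FeatureSpec":
        variant, use_fft = parse_process(process)
        return cls(variant=variant, use_fft=use_fft, use_imaging=True,
                   use_phenotypes=use_phenotypes, m=m, sigma=sigma)

    @classmethod
    def phenotypic_only(cls, include_handedness: bool = False) -> "FeatureSpec":
        return cls(use_imaging=False, use_phenotypes=True,
                   include_handedness=include_handedness)

    @property
    def feature_id(self) -> str:
        if not self.use_imaging:
            return "phenotypic"
        name = self.variant.replace("_", "-") if self.variant else "fft"
        if self.use_fft and self.variant:
            name = f"fft+{name}"
        return name + ("+phenotypic" if self.use_phenotypes else "")


@dataclass
class FoldAssignment:
    """Fold id (1..n_folds) per subject; identical across feature sets."""

    fold_ids: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_ids = np.asarray(self.fold_ids, dtype=int)
        present = np.unique(self.fold_ids)
        if not np.all((present >= 1) & (present <= self.n_folds)):
            raise ValidationError("fold ids must lie in 1..n_folds")

    def split(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_ids == f
        return ~test, test


@dataclass
class EvalResult:
    """Per-fold accuracies for one feature set in one setting."""

    setting: str
    feature_id: str
    fold_accuracies: np.ndarray  # percent
    baseline: float  # percent
    n: int
    fold_ids: tuple = ()
    model_hashes: tuple = ()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))


def collapse_labels(labels: np.ndarray, setting: str) -> np.ndarray:
    """In the two-class setting both ADHD subtypes collapse to ``"adhd"``."""
    if setting not in SETTINGS:
        raise ValidationError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    labels = np.asarray(labels, dtype=object)
    if setting == "two_class":
        return np.where(np.isin(labels, ("combined", "inattentive")), "adhd", labels)
    return labels


def majority_baseline(labels: Sequence) -> float:
    """Accuracy (%) of always guessing the modal class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("majority_baseline needs at least one label")
    _, counts = np.unique(labels, return_counts=True)
    return 100.0 * counts.max() / labels.size


def impute_iq(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing IQ values with the column mean over observed subjects.

    This is the whole-table rule; inside cross-validation the phenotype
    encoder instead imputes from training-fold means to avoid leakage.
    """
    out = table.copy()
    for col in IQ_COLUMNS:
        observed = out[col].dropna()
        if observed.empty:
            raise DegenerateInputError(f"IQ column {col!r} has no observed values")
        out[col] = out[col].fillna(observed.mean())
    return out


class PhenotypeEncoder:
    """Numeric encoding of the phenotypic table, fitted on training rows.

    Age and the three IQ scores are standardized to training mean 0 / sd 1
    (missing IQ imputed with the training mean first); gender is binary;
    handedness (optional) is binary; site is one-hot over the training
    sites, with unseen test sites encoded all-zero with a warning.
    Column order is deterministic.
    """

    def __init__(self, include_handedness: bool = False, ddof: int = 0) -> None:
        self.include_handedness = include_handedness
        self.ddof = ddof

    def fit(self, table: pd.DataFrame) -> "PhenotypeEncoder":
        self.iq_means_ = {}
        for col in IQ_COLUMNS:
            observed = table[col].dropna()
            if observed.empty:
                raise DegenerateInputError(f"IQ column {col!r} has no observed values")
            self.iq_means_[col] = float(observed.mean())
        self.numeric_stats_ = {}
        for col in ("age",) + IQ_COLUMNS:
            vals = table[col].fillna(self.iq_means_.get(col, np.nan)).to_numpy(float)
            sd = float(np.std(vals, ddof=self.ddof))
            self.numeric_stats_[col] = (float(np.mean(vals)), sd if sd > 0 else 1.0)
        self.gender_levels_ = tuple(sorted(table["gender"].astype(str).unique()))
        self.handedness_levels_ = tuple(sorted(table["handedness"].astype(str).unique()))
        self.site_levels_ = tuple(sorted(table["site"].astype(str).unique()))
        return self

    @property
    def columns_(self) -> tuple:
        cols = ["age", *IQ_COLUMNS, "gender"]
        if self.include_handedness:
            cols.append("handedness")
        cols.extend(f"site:{s}" for s in self.site_levels_)
        return tuple(cols)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        parts = []
        for col in ("age",) + IQ_COLUMNS:
            mean, sd = self.numeric_stats_[col]
            vals = table[col].fillna(self.iq_means_.get(col, np.nan)).to_numpy(float)
            parts.append((vals - mean) / sd)
        parts.append(
            (table["gender"].astype(str) == self.gender_levels_[-1]).to_numpy(float)
        )
        if self.include_handedness:
            parts.append(
                (table["handedness"].astype(str) == self.handedness_levels_[-1]).to_numpy(float)
            )
        sites = table["site"].astype(str).to_numpy()
        unseen = set(sites) - set(self.site_levels_)
        if unseen:
            log.warning("unseen site(s) %s encoded as all-zero", sorted(unseen))
        for s in self.site_levels_:
            parts.append((sites == s).astype(float))
        return np.column_stack(parts)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for col, (mean, sd) in sorted(self.numeric_stats_.items()):
            h.update(f"{col}:{mean:.12g}:{sd:.12g}".encode())
        h.update(repr((self.gender_levels_, self.handedness_levels_, self.site_levels_)).encode())
        return h.hexdigest()


def encode_phenotypes(
    train: pd.DataFrame,
    test: Optional[pd.DataFrame] = None,
    include_handedness: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Encode a table (fit on ``train``; optionally also transform ``test``)."""
    enc = PhenotypeEncoder(include_handedness=include_handedness).fit(train)
    if test is None:
        return enc.transform(train)
    return enc.transform(train), enc.transform(test)


def make_folds(
    labels: Sequence, sites: Sequence, n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Stratified fold assignment, reproducible under ``seed``.

    Subjects are grouped by (class, site); each stratum is shuffled and its
    members dealt round-robin into folds with a counter rolling across
    strata, so fold sizes differ by at most one overall and every stratum
    is spread as evenly as its size permits.
    """
    labels = np.asarray(labels)
    sites = np.asarray(sites)
    n = labels.size
    if sites.size != n:
        raise ValidationError("labels and sites must pair one per subject")
    if n_folds < 2 or n_folds > n:
        raise ValidationError(f"n_folds must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    fold_ids = np.zeros(n, dtype=int)
    strata: dict[tuple, list[int]] = {}
    for i, key in enumerate(zip(labels, sites)):
        strata.setdefault(key, []).append(i)
    counter = 0
    fold_order = rng.permutation(n_folds) + 1
    for key in sorted(strata):
        members = np.array(strata[key])
        rng.shuffle(members)
        for idx in members:
            fold_ids[idx] = fold_order[counter % n_folds]
            counter += 1
    return FoldAssignment(fold_ids=fold_ids, n_folds=n_folds, seed=seed)


def _auto_mask(scans: Sequence[Scan4D], idx: np.ndarray) -> BrainMask:
    """Intersection of the per-subject sign-of-mean masks over ``idx``."""
    include = None
    for i in np.flatnonzero(idx):
        m = compute_brain_mask(scans[i]).include
        include = m if include is None else include & m
    from .errors import EmptyMaskError

    if include is None or not include.any():
        raise EmptyMaskError("training subjects share no in-brain voxels")
    return BrainMask(include=include)


def _fold_features(
    cohort: Cohort,
    spec: FeatureSpec,
    fit_idx: np.ndarray,
) -> tuple[np.ndarray, str]:
    """Fit mask/reduction/encoder on ``fit_idx`` rows; return the full
    ``N x d`` feature matrix plus a hash of every fitted statistic."""
    h = hashlib.sha256()
    parts: list[np.ndarray] = []
    if spec.use_imaging:
        mask = cohort.mask or _auto_mask(cohort.scans, fit_idx)
        h.update(np.packbits(mask.include).tobytes())
        masked = [apply_mask(s, mask) for s in cohort.scans]
        model, _ = make_features(
            [masked[i] for i in np.flatnonzero(fit_idx)],
            spec.variant,
            spec.use_fft,
            m=spec.m,
            sigma=spec.sigma,
        )
        _, block = make_features(
            masked, spec.variant, spec.use_fft, m=spec.m, sigma=spec.sigma, model=model
        )
        if model is not None:
            h.update(model.fingerprint().encode())
        parts.append(block.features)
    if spec.use_phenotypes:
        enc = PhenotypeEncoder(include_handedness=spec.include_handedness).fit(
            cohort.phenotypes.iloc[np.flatnonzero(fit_idx)]
        )
        h.update(enc.fingerprint().encode())
        parts.append(enc.transform(cohort.phenotypes))
    return np.hstack(parts), h.hexdigest()


def cross_validate(
    cohort: Cohort,
    spec: FeatureSpec,
    setting: str,
    folds: FoldAssignment,
    C: float = 1.0,
    transductive: bool = False,
) -> EvalResult:
    """Fixed-fold cross-validation of one feature set.

    Per fold: the brain mask (auto mode), the reduction and the phenotype
    encoder are fitted on training subjects only, test subjects are
    projected, a linear-kernel SVM is trained, and test accuracy recorded.
    With ``transductive=True`` the mask and reduction are fitted once on
    all subjects (the classifier remains fold-honest).
    """
    y = cohort.labels(setting)
    if folds.fold_ids.size != cohort.n:
        raise ValidationError("fold assignment does not cover the cohort")
    accs = []
    hashes = []
    all_idx = np.ones(cohort.n, dtype=bool)
    if transductive:
        F_t, h_t = _fold_features(cohort, spec, all_idx)
    for f in range(1, folds.n_folds + 1):
        train, test = folds.split(f)
        if not test.any():
            continue
        if np.unique(y[train]).size < 2:
            raise DegenerateInputError(
                f"fold {f}: training portion contains a single class"
            )
        if transductive:
            F, h = F_t, h_t
        else:
            F, h = _fold_features(cohort, spec, train)
        clf = SVC(kernel="linear", C=C)
        clf.fit(F[train], y[train])
        accs.append(100.0 * float(np.mean(clf.predict(F[test]) == y[test])))
        hashes.append(h)
    return EvalResult(
        setting=setting,
        feature_id=spec.feature_id,
        fold_accuracies=np.array(accs),
        baseline=majority_baseline(y),
        n=cohort.n,
        fold_ids=tuple(folds.fold_ids.tolist()),
        model_hashes=tuple(hashes),
    )


def evaluate_holdout(
    train_cohort: Cohort,
    holdout_cohort: Cohort,
    spec: FeatureSpec,
    setting: str,
    C: float = 1.0,
) -> float:
    """Fit on the full training cohort; single accuracy (%) on the holdout."""
    if train_cohort.scans[0].dims != holdout_cohort.scans[0].dims:
        raise GridMismatchError(
            f"training grid {train_cohort.scans[0].dims} != holdout grid "
            f"{holdout_cohort.scans[0].dims}"
        )
    y_train = train_cohort.labels(setting)
    y_hold = holdout_cohort.labels(setting)
    merged = Cohort(
        scans=train_cohort.scans + holdout_cohort.scans,
        phenotypes=pd.concat(
            [train_cohort.phenotypes, holdout_cohort.phenotypes], ignore_index=True
        ),
        mask=train_cohort.mask,
    )
    fit_idx = np.arange(merged.n) < train_cohort.n
    F, _ = _fold_features(merged, spec, fit_idx)
    clf = SVC(kernel="linear", C=C)
    clf.fit(F[fit_idx], y_train)
    return 100.0 * float(np.mean(clf.predict(F[~fit_idx]) == y_hold))


def compare_methods(
    result_a: EvalResult, result_b: EvalResult, test: str = "t"
) -> float:
    """Two-sided paired test over per-fold accuracy differences.

    ``test`` is ``"t"`` (paired t-test, default) or ``"wilcoxon"``.  The
    p-value is symmetric in argument order; identical results give p = 1.
    Interpret with the cross-validation variance caveat in mind
    (:data:`CV_VARIANCE_CAVEAT`).
    """
    if result_a.setting != result_b.setting:
        raise ValidationError("results come from different settings")
    if result_a.fold_ids != result_b.fold_ids:
        raise ValidationError("results were computed on different folds")
    d = np.asarray(result_a.fold_accuracies) - np.asarray(result_b.fold_accuracies)
    if np.allclose(d, 0.0):
        return 1.0
    if test == "t":
        return float(stats.ttest_rel(result_a.fold_accuracies, result_b.fold_accuracies).pvalue)
    if test == "wilcoxon":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
    raise ValidationError(f"unknown test {test!r}; expected 't' or 'wilcoxon'")


def results_table(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Tabulate results: one row per (setting, feature set)."""
    rows = []
    for r in results:
        rows.append(
            {
                "setting": r.setting,
                "fft": "+" if "fft" in r.feature_id else "-",
                "variant": r.feature_id,
                "mean_acc": round(r.mean_accuracy, 2),
                "std_acc": round(r.std_accuracy, 2),
                "baseline": round(r.baseline, 2),
                "n": r.n,
            }
        )
    return pd.DataFrame(
        rows, columns=["setting", "fft", "variant", "mean_acc", "std_acc", "baseline", "n"]
    )


def render_results_text(results: Sequence[EvalResult]) -> str:
    """Plain-text report: mean (std) per feature set, plus the CV caveat."""
    df = results_table(results)
    lines = [df.to_string(index=False)] if len(df) else ["(no results)"]
    lines.append("")
    lines.append(CV_VARIANCE_CAVEAT)
    return "\n".join(lines)
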