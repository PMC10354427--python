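"""Cross-validation designs for stability prediction and the improvement statistic.

Three designs compare multi-trait genomic prediction of the CV stability index
against plain GBLUP:

* Case 1 — within one treatment-year: 10-fold CV over genotypes, test CV
  masked, secondary traits (RRM coefficients or raw per-date VI values)
  available for everyone.
* Case 2 — reduced secondary-trait collection: as Case 1, but only a fraction
  of the *training* genotypes keep their secondary traits; the random subset
  is redrawn several times per replicate.
* Case 3 — across years within a treatment: training genotypes contribute CV
  plus train-year secondary traits, test genotypes contribute only test-year
  secondary traits; one joint multi-trait model is fitted per fold.

Accuracy is the Pearson correlation between observed and predicted CV, pooled
over folds within a replicate. The improvement of the coefficient-based model
over the raw-trajectory model is POV(%) = (PA_RRM - PA_All) / PA_All * 100.
All models at a given seed share fold partitions, so comparisons are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from droughtstab.prediction import GibbsConfig, fit_gblup, fit_mtm, predict_target
from droughtstab.rrm import fit_rrm
from droughtstab.stability import compute_cv, minmax_normalize

__all__ = [
    "CVScheme",
    "PredictionResult",
    "prediction_accuracy",
    "proportion_improvement",
    "run_case1",
    "run_case2",
    "run_case3",
]

SECONDARY_MODELS = ("MT_RRM", "MT_All", "GBLUP_only")


@dataclass
class CVScheme:
    """Settings for one cross-validation experiment."""

    case: str = "case1"
    n_folds: int = 10
    n_replicates: int = 10
    secondary_model: str = "MT_RRM"
    proportion_secondary: float = 1.0  # case2 only; study values 0.10 / 0.25 / 0.50
    n_subset_draws: int = 5  # case2 only
    train_year: str = ""
    test_year: str = ""
    seed: int = 0
    rrm_order: int = 1
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)

    def __post_init__(self) -> None:
        if self.case not in ("case1", "case2", "case3"):
            raise ValueError("case must be 'case1', 'case2' or 'case3'")
        if self.secondary_model not in SECONDARY_MODELS:
            raise ValueError(f"secondary_model must be one of {SECONDARY_MODELS}")
        if self.case == "case2" and not 0.0 < self.proportion_secondary <= 1.0:
            raise ValueError("proportion_secondary must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")


@dataclass
class PredictionResult:
    """Per-replicate accuracies with their mean and standard error."""

    per_replicate_r: list[float]
    mean_r: float
    se_r: float
    scheme: CVScheme

    @classmethod
    def from_replicates(cls, rs: list[float], scheme: CVScheme) -> "PredictionResult":
        arr = np.asarray(rs, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        return cls(per_replicate_r=list(map(float, rs)), mean_r=float(arr.mean()), se_r=se, scheme=scheme)


def prediction_accuracy(observed: pd.Series, predicted: pd.Series) -> float:
    """Pearson correlation over paired non-missing values (NaN if degenerate)."""
    df = pd.concat([observed.rename("obs"), predicted.rename("pred")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 paired non-missing values")
    if df["obs"].std() == 0 or df["pred"].std() == 0:
        warnings.warn("zero variance: prediction accuracy undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(df["obs"], df["pred"])[0, 1])


def proportion_improvement(pa_rrm: float, pa_all: float) -> float:
    """POV(%) = (PA_RRM - PA_All) / PA_All * 100."""
    if pa_all == 0:
        raise ValueError("baseline accuracy is zero: POV undefined")
    return float((pa_rrm - pa_all) / pa_all * 100.0)


# ---------------------------------------------------------------------------
# helpers


def _observed_cv(study) -> pd.Series:
    return compute_cv(minmax_normalize(study.weights)).cv


def _secondary_table(study, scheme: CVScheme) -> pd.DataFrame | None:
    """Secondary-trait table for one study: RRM coefficient BLUPs or raw VI values."""
    if scheme.secondary_model == "GBLUP_only":
        return None
    if scheme.secondary_model == "MT_RRM":
        fit = fit_rrm(study.vi_series, scheme.rrm_order)
        return fit.U.copy()
    wide = study.vi_series.values.copy()
    wide.columns = [f"VI_t{int(t)}" for t in study.vi_series.timepoints]
    return wide


def _fold_partition(ids: list[str], n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    if len(ids) < n_folds:
        raise ValueError("fewer genotypes than folds")
    perm = rng.permutation(len(ids))
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def _chain_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31 - 1))


def _replicate_r(
    cv_obs: pd.Series,
    secondary: pd.DataFrame | None,
    G,
    folds: list[np.ndarray],
    ids: list[str],
    scheme: CVScheme,
    rep: int,
    train_secondary_keep: pd.Index | None = None,
) -> float:
    """One replicate: mask test CV fold by fold, fit, pool predictions, correlate."""
    predicted = pd.Series(np.nan, index=ids, dtype=float)
    for ifold, fold in enumerate(folds):
        test_ids = [ids[i] for i in fold]
        if secondary is None:
            y = cv_obs.copy()
            y.loc[test_ids] = np.nan
            fit = fit_gblup(y, G)
        else:
            Y = pd.concat([cv_obs.rename("CV"), secondary.reindex(ids)], axis=1)
            Y.loc[test_ids, "CV"] = np.nan
            if train_secondary_keep is not None:
                sec_cols = Y.columns[1:]
                train_ids = [g for g in ids if g not in set(test_ids)]
                drop = [g for g in train_ids if g not in set(train_secondary_keep)]
                Y.loc[drop, sec_cols] = np.nan
            gibbs = replace(scheme.gibbs, seed=_chain_seed(scheme.seed, rep, ifold))
            fit = fit_mtm(Y, G, gibbs=gibbs)
        predicted.loc[test_ids] = predict_target(fit, test_ids).to_numpy()
    return prediction_accuracy(cv_obs, predicted)


# ---------------------------------------------------------------------------
# cases


def run_case1(study, scheme: CVScheme) -> PredictionResult:
    """Within-environment 10-fold cross-validation (one r per replicate)."""
    cv_obs = _observed_cv(study)
    ids = list(cv_obs.index)
    secondary = _secondary_table(study, scheme)
    G = study.kinship
    rs = []
    for rep in range(scheme.n_replicates):
        rng = np.random.default_rng([scheme.seed, rep])
        folds = _fold_partition(ids, scheme.n_folds, rng)
        rs.append(_replicate_r(cv_obs, secondary, G, folds, ids, scheme, rep))
    return PredictionResult.from_replicates(rs, scheme)


def run_case2(study, scheme: CVScheme) -> PredictionResult:
    """As Case 1, but only a fraction of training genotypes keep secondary traits.

    Per replicate, ``n_subset_draws`` independent subsets of genotypes are
    drawn; a training genotype outside the subset has its secondary traits
    masked (its CV stays). Test genotypes keep their secondary traits. Returns
    ``n_replicates * n_subset_draws`` correlations (50 at the defaults).
    """
    if scheme.secondary_model == "GBLUP_only":
        raise ValueError("case2 requires a multi-trait model")
    cv_obs = _observed_cv(study)
    ids = list(cv_obs.index)
    secondary = _secondary_table(study, scheme)
    G = study.kinship
    p = scheme.proportion_secondary
    rs = []
    for rep in range(scheme.n_replicates):
        rng = np.random.default_rng([scheme.seed, rep])
        folds = _fold_partition(ids, scheme.n_folds, rng)
        for draw in range(scheme.n_subset_draws):
            if p >= 1.0:
                keep = pd.Index(ids)
            else:
                draw_rng = np.random.default_rng([scheme.seed, rep, draw])
                n_keep = int(round(p * len(ids)))
                if n_keep < 2:
                    raise ValueError("proportion leaves < 2 genotypes with secondary data")
                keep = pd.Index([ids[i] for i in draw_rng.choice(len(ids), n_keep, replace=False)])
            rs.append(_replicate_r(cv_obs, secondary, G, folds, ids, scheme, rep,
                                   train_secondary_keep=keep))
    return PredictionResult.from_replicates(rs, scheme)


def run_case3(train_study, test_study, scheme: CVScheme) -> PredictionResult:
    """Cross-year prediction within a treatment via one joint multi-trait model.

    The target CV is shared (it pools all treatment-year combinations); the
    secondary-trait columns take train-year values for training genotypes and
    test-year values for test genotypes. For the raw-trajectory model only
    measurement dates present in both years are usable (error if none align);
    the coefficient model uses each year's full trajectory through its own RRM
    fit, so its M stays nr+1.
    """
    if train_study.vi_series.treatment != test_study.vi_series.treatment:
        raise ValueError("train and test studies must share the treatment label")
    ids = list(train_study.weights.values.index)
    if set(ids) != set(test_study.weights.values.index):
        raise ValueError("train and test studies must share the genotype panel")
    if scheme.secondary_model == "MT_All":
        t_train = np.asarray(train_study.vi_series.timepoints)
        t_test = np.asarray(test_study.vi_series.timepoints)
        aligned = np.intersect1d(t_train, t_test)
        if aligned.size == 0:
            raise ValueError("no aligned timepoints between years")
        cols_train = [int(np.nonzero(t_train == t)[0][0]) for t in aligned]
        cols_test = [int(np.nonzero(t_test == t)[0][0]) for t in aligned]
        sec_train = train_study.vi_series.values.iloc[:, cols_train]
        sec_test = test_study.vi_series.values.iloc[:, cols_test]
        names = [f"VI_t{int(t)}" for t in aligned]
        sec_train.columns = sec_test.columns = names
    elif scheme.secondary_model == "MT_RRM":
        sec_train = fit_rrm(train_study.vi_series, scheme.rrm_order).U
        sec_test = fit_rrm(test_study.vi_series, scheme.rrm_order).U
    else:
        sec_train = sec_test = None

    cv_obs = _observed_cv(train_study)
    G = train_study.kinship
    rs = []
    for rep in range(scheme.n_replicates):
        rng = np.random.default_rng([scheme.seed, rep])
        folds = _fold_partition(ids, scheme.n_folds, rng)
        predicted = pd.Series(np.nan, index=ids, dtype=float)
        for ifold, fold in enumerate(folds):
            test_ids = [ids[i] for i in fold]
            if sec_train is None:
                y = cv_obs.copy()
                y.loc[test_ids] = np.nan
                fit = fit_gblup(y, G)
            else:
                secondary = sec_train.reindex(ids).copy()
                secondary.loc[test_ids] = sec_test.reindex(test_ids).to_numpy()
                Y = pd.concat([cv_obs.rename("CV"), secondary], axis=1)
                Y.loc[test_ids, "CV"] = np.nan
                gibbs = replace(scheme.gibbs, seed=_chain_seed(scheme.seed, rep, ifold))
                fit = fit_mtm(Y, G, gibbs=gibbs)
            predicted.loc[test_ids] = predict_target(fit, test_ids).to_numpy()
        rs.append(prediction_accuracy(cv_obs, predicted))
    return PredictionResult.from_replicates(rs, scheme)
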