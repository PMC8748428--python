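"""Elastic-net epigenetic clocks and their cross-validation.

A clock is a penalized linear regression of transformed age on CpG beta
values.  The objective (scikit-learn / glmnet parametrisation, mixing
fixed at alpha = 0.5, the midpoint between ridge and lasso)::

    (1/2n) * ||y - X w||^2 + lam * ( a*||w||_1 + (1-a)/2 * ||w||_2^2 )

Predictors are standardized inside the fit; coefficients are reported on
the original beta scale and the intercept in transformed-age units.  The
penalty lam is selected by a seeded internal 10-fold cross-validation
minimizing mean squared error over a geometric path; among exact ties the
smallest lam (denser model) wins, and the path is extended downward when
the optimum sits on its lower boundary so that effectively-noiseless data
converge to the unpenalized fit.

Three outer cross-validation schemes estimate clock accuracy:

LOO      leave one sample out, the unbiased per-sample estimate;
KFOLD10  ten folds, stratified by species, seeded;
LOSO     leave one species out, estimating accuracy on a species absent
         from training (a systematic offset in such a species inflates
         its error without destroying its within-species correlation).

Every fold refits the clock from scratch, including the internal penalty
search.  Accuracy is summarised, per group and overall, as the Pearson
correlation between chronological and predicted age plus the median
absolute error in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .age_transforms import TransformSpec
from .core_io import BetaMatrix, ClockModel, SampleSheet
from .errors import (
    AlignmentError,
    DegenerateFitError,
    FoldError,
    ValidationError,
)

MIN_TRAIN_SAMPLES = 20
INTERNAL_FOLDS = 10

#: desk-scale defaults of the penalty path; see docs/methods.md
DEFAULT_N_LAMBDAS = 8
DEFAULT_LAMBDA_MIN_RATIO = 0.1
DEFAULT_TOL = 2e-3
MAX_PATH_EXTENSIONS = 4

SCHEMES = ("LOO", "KFOLD10", "LOSO")


def _check_aligned(beta: BetaMatrix, sheet: SampleSheet) -> None:
    if not beta.sample_ids.equals(sheet.sample_ids):
        raise AlignmentError("beta matrix and sample sheet must list the same "
                             "samples in the same order")


def _internal_seed(seed: int, salt: int = 0) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def fit_clock(beta: BetaMatrix, sheet: SampleSheet, spec: TransformSpec,
              *, seed: int, alpha: float = 0.5,
              n_lambdas: int = DEFAULT_N_LAMBDAS,
              lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
              tol: float = DEFAULT_TOL,
              max_iter: int = 5000,
              missing_policy: str = "strict",
              missing_values: str = "error") -> ClockModel:
    """Fit an elastic-net clock on transformed age.

    ``seed`` drives the internal 10-fold penalty search so refits are
    reproducible.  Zero-variance CpGs are excluded from the design; if no
    CpG varies the result is the intercept-only model (mean transformed
    age).  A constant response raises :class:`DegenerateFitError`.

    ``missing_values`` controls NaN betas in the training matrix:
    ``"error"`` (strict, default) raises; ``"drop_cpgs"`` removes every
    CpG column containing a missing value before fitting.
    """
    _check_aligned(beta, sheet)
    n = beta.shape[0]
    if n < MIN_TRAIN_SAMPLES:
        raise FoldError(f"need >= {MIN_TRAIN_SAMPLES} training samples, got {n}")

    y = spec.forward_array(sheet.age.to_numpy(), sheet.species.to_numpy())
    if np.ptp(y) == 0:
        raise DegenerateFitError("transformed age is constant across samples")

    if missing_values not in ("error", "drop_cpgs"):
        raise ValidationError(f"unknown missing_values mode {missing_values!r}")
    has_nan = beta.values.isna().any()
    if has_nan.any():
        if missing_values == "error":
            raise ValidationError(
                "missing beta values in training data for CpGs "
                f"{list(beta.cpg_ids[has_nan])[:10]}; drop or impute first")
        beta = beta.subset_cpgs(beta.cpg_ids[~has_nan])
    X = beta.values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    varying = sd > 0

    if not varying.any():
        return ClockModel(
            intercept=float(y.mean()), coefficients=pd.Series(dtype=float),
            alpha=alpha, penalty=float("inf"), transform=spec,
            missing_policy=missing_policy,
            training_means=pd.Series(mu, index=beta.cpg_ids),
        )

    Xs = (X[:, varying] - mu[varying]) / sd[varying]
    yc = y - y.mean()

    lam_max = float(np.max(np.abs(Xs.T @ yc)) / (n * alpha))
    if lam_max == 0:
        raise DegenerateFitError("all predictors are uncorrelated with age")
    cv = KFold(n_splits=INTERNAL_FOLDS, shuffle=True,
               random_state=_internal_seed(seed))

    # In the low-dimensional regime the unpenalized limit is well-posed, so
    # the path may be extended downward when the CV optimum sits on its
    # lower boundary (noiseless data then converge to the exact fit).  In
    # the p > n regime the path stops at lambda_min_ratio.
    extensions = MAX_PATH_EXTENSIONS if Xs.shape[1] <= n else 0
    lam_hi = lam_max
    ratio = lambda_min_ratio
    for _ in range(1 + extensions):
        path = np.geomspace(lam_hi, lam_hi * ratio, n_lambdas)
        model = ElasticNetCV(l1_ratio=alpha, alphas=path, cv=cv,
                             tol=tol, max_iter=max_iter, n_jobs=None)
        model.fit(Xs, y)
        mean_mse = model.mse_path_.mean(axis=1)
        best = mean_mse.min()
        # smallest lam among (tied) minimizers; alphas_ is descending
        chosen_idx = int(np.max(np.flatnonzero(mean_mse == best)))
        chosen = float(model.alphas_[chosen_idx])
        if chosen_idx < n_lambdas - 1:
            break
        # optimum on the lower path boundary: extend the path downward,
        # deepening the ratio so noiseless fits reach the unpenalized limit
        lam_hi = chosen
        ratio = lambda_min_ratio ** 2
    if chosen != float(model.alpha_):
        refit = ElasticNet(alpha=chosen, l1_ratio=alpha, tol=tol,
                           max_iter=max_iter)
        refit.fit(Xs, y)
        coef_std, intercept_std = refit.coef_, float(refit.intercept_)
    else:
        coef_std, intercept_std = model.coef_, float(model.intercept_)

    # back to the original beta scale
    coef = np.zeros(beta.shape[1])
    coef[varying] = coef_std / sd[varying]
    intercept = intercept_std - float(np.sum(coef_std * mu[varying] / sd[varying]))

    nonzero = coef != 0
    return ClockModel(
        intercept=intercept,
        coefficients=pd.Series(coef[nonzero], index=beta.cpg_ids[nonzero]),
        alpha=alpha,
        penalty=chosen,
        transform=spec,
        missing_policy=missing_policy,
        training_means=pd.Series(mu, index=beta.cpg_ids),
    )


def predict_age(model: ClockModel, beta: BetaMatrix,
                sheet: SampleSheet) -> pd.Series:
    """Predicted age in years: linear score, then per-species inverse transform."""
    _check_aligned(beta, sheet)
    needed = model.cpg_ids
    missing = needed.difference(beta.cpg_ids)
    if len(missing):
        if model.missing_policy == "strict":
            raise ValidationError(
                f"beta matrix lacks {len(missing)} clock CpGs: "
                f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}")
        present = needed.intersection(beta.cpg_ids)
        X = pd.DataFrame(index=beta.sample_ids, columns=needed, dtype=float)
        X.loc[:, present] = beta.values[present]
        fill = model.training_means.reindex(missing)
        X.loc[:, missing] = fill.to_numpy()[None, :]
    else:
        X = beta.values[needed]
    if X.isna().any().any():
        if model.missing_policy == "strict":
            bad = X.columns[X.isna().any()].tolist()
            raise ValidationError(f"missing beta values for clock CpGs: {bad[:10]}")
        X = X.fillna(model.training_means)
    score = model.intercept + X.to_numpy(dtype=float) @ model.coefficients.to_numpy()
    years = model.transform.inverse_array(score, sheet.species.to_numpy())
    return pd.Series(years, index=beta.sample_ids, name="dnam_age_years")


def evaluate(pred, true) -> tuple[float, float]:
    """Pearson correlation and median absolute error (years).

    A constant vector makes the correlation undefined; it is returned as
    NaN (the flag) rather than raising.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 3:
        raise ValidationError("need >= 3 aligned prediction/truth pairs")
    mae = float(np.median(np.abs(pred - true)))
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        return float("nan"), mae
    r = float(np.corrcoef(pred, true)[0, 1])
    return r, mae


@dataclass
class CVResult:
    """Out-of-fold predictions plus accuracy summaries for one CV scheme."""

    scheme: str
    predictions: pd.DataFrame  # sample_id index; age, dnam_age, species, tissue, fold
    overall: tuple[float, float]              # (pearson r, MAE years)
    per_species: pd.DataFrame = field(repr=False, default=None)
    per_tissue: pd.DataFrame = field(repr=False, default=None)

    @classmethod
    def from_predictions(cls, scheme: str, preds: pd.DataFrame) -> "CVResult":
        overall = evaluate(preds["dnam_age"], preds["age"])

        def _group(col):
            rows = []
            for name, sub in preds.groupby(col, sort=True):
                if len(sub) >= 3:
                    r, mae = evaluate(sub["dnam_age"], sub["age"])
                else:
                    r, mae = float("nan"), float(
                        np.median(np.abs(sub["dnam_age"] - sub["age"])))
                rows.append((name, len(sub), r, mae))
            return pd.DataFrame(rows, columns=[col, "n", "r", "mae"]).set_index(col)

        return cls(scheme=scheme, predictions=preds, overall=overall,
                   per_species=_group("species"), per_tissue=_group("tissue"))


def _stratified_folds(species: np.ndarray, n_folds: int,
                      seed: int) -> np.ndarray:
    """Seeded species-stratified fold labels: round-robin within species."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(species), dtype=int)
    offset = 0
    for sp in np.unique(species):
        idx = np.flatnonzero(species == sp)
        perm = rng.permutation(idx)
        fold[perm] = (np.arange(len(perm)) + offset) % n_folds
        offset += len(perm)  # stagger so small species spread across folds
    return fold


def cross_validate(beta: BetaMatrix, sheet: SampleSheet, spec: TransformSpec,
                   scheme: str, seed: int, *, alpha: float = 0.5,
                   n_folds: int = 10, **fit_kw) -> CVResult:
    """Out-of-fold clock accuracy under LOO, KFOLD10 or LOSO.

    Each fold refits :func:`fit_clock` from scratch on the training split,
    including the internal penalty search; held-out predictions are
    inverse-transformed to years.
    """
    _check_aligned(beta, sheet)
    if scheme not in SCHEMES:
        raise ValidationError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    n = beta.shape[0]
    species = sheet.species.to_numpy()

    if scheme == "LOO":
        fold = np.arange(n)
    elif scheme == "KFOLD10":
        if n < n_folds:
            raise FoldError(f"{n} samples cannot form {n_folds} folds")
        fold = _stratified_folds(species, n_folds, seed)
    else:  # LOSO
        uniq = np.unique(species)
        if len(uniq) < 2:
            raise FoldError("LOSO requires at least 2 species")
        sp_code = {sp: i for i, sp in enumerate(uniq)}
        fold = np.array([sp_code[sp] for sp in species])
        for sp, code in sp_code.items():
            if (fold != code).sum() < MIN_TRAIN_SAMPLES:
                raise FoldError(
                    f"leaving out species {sp!r} leaves fewer than "
                    f"{MIN_TRAIN_SAMPLES} training samples")

    dnam_age = pd.Series(np.nan, index=beta.sample_ids)
    for f in np.unique(fold):
        test_mask = fold == f
        train_ids = beta.sample_ids[~test_mask]
        test_ids = beta.sample_ids[test_mask]
        model = fit_clock(beta.subset_samples(train_ids),
                          sheet.subset(train_ids), spec,
                          seed=_internal_seed(seed, int(f) + 1),
                          alpha=alpha, **fit_kw)
        dnam_age[test_ids] = predict_age(
            model, beta.subset_samples(test_ids), sheet.subset(test_ids))

    preds = pd.DataFrame(
        {
            "age": sheet.age,
            "dnam_age": dnam_age,
            "species": sheet.species,
            "tissue": sheet.tissue,
            "fold": fold,
        },
        index=beta.sample_ids,
    )
    return CVResult.from_predictions(scheme, preds)
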