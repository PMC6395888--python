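"""Sequence-based prediction of editing precision.

Two regressors map the 23-nt target sequence (20-nt protospacer + NGG PAM)
to the site's commonest-indel frequency:

* :class:`PrecisionANN` — a single-hidden-layer network (86 inputs, 512 ReLU
  units, softplus output) trained with mini-batch SGD + Nesterov momentum on
  mean squared error, implemented in numpy as a scikit-learn estimator;
* LASSO — L1-regularized linear regression via scikit-learn's coordinate
  descent, minimizing ``(1/(2 n)) ||Xw - y||^2 + alpha ||w||_1``.

Inputs are one-hot encoded: 21 variable positions (protospacer -20..-1 plus
the PAM 'N') as 4 binary entries each, plus 2 constant entries for the PAM
'GG' — 86 features. Per-position influence is quantified by permutation
importance: shuffle the raw base column across test sites, re-encode,
re-predict, and record the percent reduction in R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.linear_model import Lasso, LassoCV
from sklearn.utils.validation import check_is_fitted

from .sites import TargetSite

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: L1 penalty selected by 10-fold cross-validation on the original cohort.
DEFAULT_LASSO_ALPHA = 0.002592943797404667

N_VARIABLE_POSITIONS = 21  # protospacer -20..-1 plus the PAM 'N'
N_FEATURES = 4 * N_VARIABLE_POSITIONS + 2  # + two constant PAM 'G' entries

#: Human-readable labels for the 21 variable positions, 5'->3'.
POSITION_LABELS = [str(p) for p in range(-20, 0)] + ["PAM_N"]

PRECISION_CORE_POSITIONS = (-5, -4, -3, -2)


def site_to_sequence(site: TargetSite | str) -> str:
    """23-nt target sequence (protospacer + PAM) from a site or string."""
    seq = site if isinstance(site, str) else site.protospacer + site.pam
    if len(seq) != 23:
        raise ValueError(f"expected a 23-nt protospacer+PAM sequence, got {len(seq)}")
    if any(b not in _BASE_INDEX for b in seq):
        raise ValueError(f"non-ACGT base in {seq!r}")
    if seq[21:] != "GG":
        raise ValueError("PAM must end in GG")
    return seq


class GuideOneHotEncoder(BaseEstimator, TransformerMixin):
    """One-hot encode 23-nt target sequences into 86-entry vectors.

    Feature layout: 4 entries per variable position in 5'->3' order
    (protospacer -20..-1, then the PAM 'N'), base order A,C,G,T; the final
    two entries are constant 1.0 for the invariant PAM 'GG'. Invertible on
    the 21 variable positions.
    """

    constant_value: float = 1.0

    def fit(self, X, y=None):  # stateless; nothing to learn
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        seqs = [site_to_sequence(x) for x in X]
        out = np.zeros((len(seqs), N_FEATURES))
        for i, seq in enumerate(seqs):
            for j in range(N_VARIABLE_POSITIONS):
                out[i, 4 * j + _BASE_INDEX[seq[j]]] = 1.0
        out[:, -2:] = self.constant_value
        return out

    def inverse_transform(self, X: np.ndarray) -> list[str]:
        X = np.asarray(X)
        seqs = []
        for row in X:
            chars = []
            for j in range(N_VARIABLE_POSITIONS):
                block = row[4 * j : 4 * j + 4]
                if not np.isclose(block.sum(), 1.0):
                    raise ValueError(f"one-hot block {j} does not sum to 1")
                chars.append(_BASES[int(np.argmax(block))])
            seqs.append("".join(chars) + "GG")
        return seqs


def one_hot_encode(sites) -> np.ndarray:
    """Functional shorthand for :class:`GuideOneHotEncoder`."""
    return GuideOneHotEncoder().fit([]).transform(sites)


def _softplus(z: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(z))
    return np.logaddexp(0.0, z)


class PrecisionANN(BaseEstimator, RegressorMixin):
    """86-512-1 feed-forward regressor for commonest-indel frequency.

    Hidden layer: ReLU. Output: softplus (strictly positive; can exceed 1 —
    use ``predict(X, clamp=True)`` to clip into (0, 1] for classification).
    Weights start uniform in [-c, c] with
    ``c = xavier_constant / sqrt(0.5 * (n_in + n_out))`` per layer and zero
    biases; training is plain mini-batch SGD with Nesterov momentum on the
    mean-squared-error loss, reproducible given ``random_state``.
    """

    def __init__(
        self,
        hidden_units: int = 512,
        epochs: int = 800,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        batch_size: int = 100,
        xavier_constant: float = 2.24,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.xavier_constant = xavier_constant
        self.random_state = random_state

    def _init_weights(self, n_in: int, rng: np.random.Generator):
        h = self.hidden_units
        c1 = self.xavier_constant / np.sqrt(0.5 * (n_in + h))
        c2 = self.xavier_constant / np.sqrt(0.5 * (h + 1))
        self.W1_ = rng.uniform(-c1, c1, size=(n_in, h))
        self.b1_ = np.zeros(h)
        self.W2_ = rng.uniform(-c2, c2, size=(h, 1))
        self.b2_ = np.zeros(1)

    def _forward(self, X: np.ndarray):
        z1 = X @ self.W1_ + self.b1_
        h = np.maximum(z1, 0.0)
        z2 = h @ self.W2_ + self.b2_
        return z1, h, z2, _softplus(z2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one target per row")
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) < self.batch_size:
            raise ValueError(
                f"need at least batch_size={self.batch_size} samples, got {len(X)}"
            )
        if np.any(y <= 0) or np.any(y > 1):
            raise ValueError("targets must be frequencies in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        self.n_features_in_ = d
        self._init_weights(d, rng)
        vel = [np.zeros_like(w) for w in (self.W1_, self.b1_, self.W2_, self.b2_)]
        mu, lr = self.momentum, self.learning_rate
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n - self.batch_size + 1, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                z1, h, z2, out = self._forward(xb)
                err = out.ravel() - yb
                epoch_loss += float(np.mean(err**2)) * len(idx)
                # backprop through softplus -> linear -> ReLU -> linear
                dz2 = (2.0 * err / len(idx))[:, None] * special.expit(z2)
                gW2 = h.T @ dz2
                gb2 = dz2.sum(axis=0)
                dh = dz2 @ self.W2_.T
                dz1 = dh * (z1 > 0)
                gW1 = xb.T @ dz1
                gb1 = dz1.sum(axis=0)
                params = (self.W1_, self.b1_, self.W2_, self.b2_)
                grads = (gW1, gb1, gW2, gb2)
                for p, g, v in zip(params, grads, vel):
                    v *= mu
                    v += g
                    p -= lr * (g + mu * v)  # Nesterov lookahead
            self.loss_history_.append(epoch_loss / (n - n % self.batch_size or n))
        return self

    def predict(self, X, clamp: bool = False) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        out = self._forward(X)[3].ravel()
        if clamp:
            out = np.clip(out, np.finfo(float).tiny, 1.0)
        return out


def train_ann(X, y, seed: int = 0, **hyperparams) -> PrecisionANN:
    return PrecisionANN(random_state=seed, **hyperparams).fit(X, y)


def train_lasso(
    X, y, alpha: float | None = DEFAULT_LASSO_ALPHA, cv_select: bool = False,
    seed: int = 0,
):
    """Fit the L1-regularized linear model by coordinate descent.

    With ``cv_select`` the penalty is chosen by 10-fold cross-validation
    over scikit-learn's default alpha path instead of the fixed default.
    """
    if cv_select:
        model = LassoCV(cv=10, random_state=seed, max_iter=50000)
    else:
        model = Lasso(alpha=alpha, random_state=seed, max_iter=50000)
    return model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())


@dataclass(frozen=True)
class FitMetrics:
    r: float
    r2: float
    rmse: float
    wald_p: float
    degenerate: bool = False


def evaluate_fit(predictions, observations) -> FitMetrics:
    """Pearson R, R^2 of observed-on-predicted OLS, RMSE, and Wald slope p.

    The Wald statistic is the squared t of the OLS slope referred to
    chi-square(1); zero variance in either vector yields a flagged
    degenerate result instead of an exception.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return FitMetrics(r=0.0, r2=0.0, rmse=rmse, wald_p=1.0, degenerate=True)
    r = float(stats.pearsonr(pred, obs)[0])
    res = sm.OLS(obs, sm.add_constant(pred)).fit()
    wald_chi2 = float(res.tvalues[1] ** 2)
    wald_p = float(stats.chi2.sf(wald_chi2, df=1))
    return FitMetrics(r=r, r2=float(res.rsquared), rmse=rmse, wald_p=wald_p)


def bootstrap_validate(
    estimator, X, y, n_boot: int = 20, frac: float = 0.8, seed: int = 0
) -> tuple[float, float, list[float]]:
    """Bootstrap model validation: resample-with-replacement, refit, score.

    Each replicate draws ``frac * n`` training items with replacement, refits
    a clone, and records RMSE on the items never drawn; returns
    (mean, SD, per-replicate RMSEs).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = len(y)
    rmses = []
    for _ in range(n_boot):
        idx = rng.choice(n, size=int(round(frac * n)), replace=True)
        held_out = np.setdiff1d(np.arange(n), np.unique(idx))
        if len(held_out) == 0:
            continue
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=int(rng.integers(2**31 - 1)))
        model.fit(X[idx], y[idx])
        pred = model.predict(X[held_out])
        rmses.append(float(np.sqrt(np.mean((pred - y[held_out]) ** 2))))
    return float(np.mean(rmses)), float(np.std(rmses)), rmses


def _position_index(position) -> int:
    """Map a position label (-20..-1 or 'PAM_N') to its sequence index."""
    if position == "PAM_N":
        return 20
    p = int(position)
    if not (-20 <= p <= -1):
        raise ValueError(f"position must be -20..-1 or 'PAM_N', got {position}")
    return 20 + p


def permutation_importance(
    model,
    sequences_test,
    observations,
    position_sets: dict | None = None,
    n_perm: int = 10,
    seed: int = 0,
    encoder: GuideOneHotEncoder | None = None,
) -> pd.DataFrame:
    """Per-position influence by raw-base column shuffling.

    For each position (or named set of positions) the raw base column(s) are
    shuffled independently across the test sequences — preserving each
    column's marginal base composition — then re-encoded and re-predicted.
    Reported per entry: mean percent reduction in R^2 relative to the
    unpermuted predictions (+/- SD over ``n_perm`` shuffles) and whether the
    mean Wald p rose above 0.05 (predictive significance abolished).
    """
    encoder = encoder or GuideOneHotEncoder().fit([])
    seqs = [site_to_sequence(s) for s in sequences_test]
    obs = np.asarray(observations, dtype=float).ravel()
    base_fit = evaluate_fit(model.predict(encoder.transform(seqs)), obs)
    if base_fit.r2 <= 0:
        raise ValueError("baseline R^2 is non-positive; importance undefined")
    if position_sets is None:
        position_sets = {label: [label] for label in POSITION_LABELS}
    rng = np.random.default_rng(seed)
    rows = []
    for label, positions in position_sets.items():
        indices = [_position_index(p) for p in positions]
        reductions, wald_ps = [], []
        for _ in range(n_perm):
            chars = [list(s) for s in seqs]
            for j in indices:  # columns shuffled independently, not jointly
                perm = rng.permutation(len(chars))
                col = [chars[i][j] for i in range(len(chars))]
                for i, src in enumerate(perm):
                    chars[i][j] = col[src]
            shuffled = ["".join(c) for c in chars]
            fit = evaluate_fit(model.predict(encoder.transform(shuffled)), obs)
            reductions.append(100.0 * (base_fit.r2 - fit.r2) / base_fit.r2)
            wald_ps.append(fit.wald_p)
        rows.append(
            {
                "position": label,
                "mean_pct_r2_reduction": float(np.mean(reductions)),
                "sd_pct_r2_reduction": float(np.std(reductions)),
                "mean_wald_p": float(np.mean(wald_ps)),
                "significance_abolished": bool(np.mean(wald_ps) > 0.05),
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)
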