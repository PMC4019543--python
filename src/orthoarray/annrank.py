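"""Neural-network ranking of transcripts and marker-interaction inference.

Each transcript is scored by a small feed-forward network (1 input →
``hidden_units`` logistic units → 1 logistic output) trained to predict
the 0/1 treatment class from that transcript's expression alone, under
repeated random 60/20/20 train/validation/test splits ("random sample
cross-validation").  Training uses full-batch gradient descent with
momentum on the squared error and stops early when validation error has
not improved for ``patience`` cycles; the score is the test-set squared
error at the best-validation snapshot, averaged over resamples.  Low
mean test error ranks a transcript as more predictive.

Marker interactions among the top-ranked transcripts are inferred by
training, for each marker j, a network predicting j from the remaining
markers; the signed influence of marker i on j is the mean over samples
of the partial derivative of the network output with respect to input i.

Estimators follow scikit-learn conventions (``fit``, ``get_params``,
fitted attributes with trailing underscores) and are deterministic under
``random_state``: each (transcript, resample) pair draws its split and
weight initialization from a stream keyed by the transcript *name*, so
rankings do not depend on row order and are unchanged when unrelated
transcripts are added.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AnnConfig",
    "subset_sizes",
    "split_data",
    "train_single_input_net",
    "NeuralNetRanker",
    "MarkerInteraction",
    "rank_transcripts",
    "interaction_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the ranking networks."""

    hidden_units: int = 2
    learning_rate: float = 0.5
    momentum: float = 0.9
    patience: int = 25
    max_cycles: int = 300
    n_resamples: int = 50
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    top_k: int = 100
    seed: int = 0
    early_stop_mode: str = "decrease"  # "decrease" (default) or "increase"

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1.0")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.early_stop_mode not in ("decrease", "increase"):
            raise ValueError("early_stop_mode must be 'decrease' or 'increase'")


def subset_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n samples to the three subsets.

    Ties in the remainders are broken in subset order (train, validation,
    test).
    """
    exact = [n * f for f in fractions]
    floors = [int(np.floor(e)) for e in exact]
    leftover = n - sum(floors)
    remainders = sorted(
        range(3), key=lambda i: (-(exact[i] - floors[i]), i)
    )
    for i in remainders[:leftover]:
        floors[i] += 1
    return tuple(floors)


def split_data(
    labels: np.ndarray,
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
    max_retries: int = 100,
):
    """One stratification-checked random split into train/validation/test.

    Samples are permuted and cut at the largest-remainder sizes; if the
    training subset misses a class the split is redrawn, up to
    ``max_retries`` times.
    """
    labels = np.asarray(labels)
    n = len(labels)
    n_tr, n_val, n_te = subset_sizes(n, fractions)
    if min(n_tr, n_val, n_te) < 1:
        raise ValueError(f"{n} samples cannot fill all three subsets at {fractions}")
    classes = np.unique(labels)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        train = perm[:n_tr]
        if len(np.unique(labels[train])) == len(classes):
            return train, perm[n_tr : n_tr + n_val], perm[n_tr + n_val :]
    raise RuntimeError(
        f"could not obtain a training subset containing all classes in {max_retries} draws"
    )


# ---------------------------------------------------------------------------
# Batched network training
#
# Many independent networks are trained simultaneously: parameter arrays
# carry a leading model axis M, inputs have shape (M, n_samples, d).


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _forward(X, w1, b1, w2, b2):
    a1 = _sigmoid(np.einsum("mnd,mdh->mnh", X, w1) + b1[:, None, :])
    out = _sigmoid(np.einsum("mnh,mh->mn", a1, w2) + b2[:, None])
    return a1, out


def _init_params(rngs, d, hidden):
    m = len(rngs)
    w1 = np.empty((m, d, hidden))
    b1 = np.empty((m, hidden))
    w2 = np.empty((m, hidden))
    b2 = np.empty((m,))
    for i, rng in enumerate(rngs):
        w1[i] = rng.uniform(-0.5, 0.5, (d, hidden))
        b1[i] = rng.uniform(-0.5, 0.5, hidden)
        w2[i] = rng.uniform(-0.5, 0.5, hidden)
        b2[i] = rng.uniform(-0.5, 0.5)
    return w1, b1, w2, b2


def _train_batch(Xtr, ytr, Xval, yval, params, cfg: AnnConfig):
    """Train M networks with early stopping; return best-validation params.

    Returns (best_params, best_val_error, failed_mask).
    """
    w1, b1, w2, b2 = (p.copy() for p in params)
    vels = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
    m, n, _ = Xtr.shape
    sign = 1.0 if cfg.early_stop_mode == "decrease" else -1.0

    def val_error(pw1, pb1, pw2, pb2):
        _, out = _forward(Xval, pw1, pb1, pw2, pb2)
        return ((out - yval) ** 2).mean(axis=1)

    best = [w1.copy(), b1.copy(), w2.copy(), b2.copy()]
    best_val = val_error(*best)
    since = np.zeros(m, dtype=int)
    failed = ~np.isfinite(best_val)

    for _ in range(cfg.max_cycles):
        a1, out = _forward(Xtr, w1, b1, w2, b2)
        err = out - ytr
        d2 = (2.0 / n) * err * out * (1.0 - out)
        gw2 = np.einsum("mn,mnh->mh", d2, a1)
        gb2 = d2.sum(axis=1)
        dh = d2[:, :, None] * w2[:, None, :] * a1 * (1.0 - a1)
        gw1 = np.einsum("mnd,mnh->mdh", Xtr, dh)
        gb1 = dh.sum(axis=1)
        for p, v, g in zip((w1, b1, w2, b2), vels, (gw1, gb1, gw2, gb2)):
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            p += v
        cur = val_error(w1, b1, w2, b2)
        bad = ~np.isfinite(cur)
        failed |= bad
        improved = (sign * cur < sign * best_val) & ~bad
        if improved.any():
            for bp, p in zip(best, (w1, b1, w2, b2)):
                bp[improved] = p[improved]
            best_val[improved] = cur[improved]
        since = np.where(improved, 0, since + 1)
        if np.all((since > cfg.patience) | failed):
            break
    return best, best_val, failed


def _minmax_scale(train_vals, *others):
    lo, hi = train_vals.min(), train_vals.max()
    if hi == lo:
        return tuple(np.zeros_like(v) for v in (train_vals, *others))
    return tuple((v - lo) / (hi - lo) for v in (train_vals, *others))


def train_single_input_net(
    expr_row: np.ndarray,
    labels: np.ndarray,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: AnnConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Train one single-transcript network on a given split.

    Returns (test_error, validation_error) at the best-validation
    snapshot; ``nan`` test error marks a failed (non-finite) run.
    """
    config = config or AnnConfig()
    rng = rng or np.random.default_rng(config.seed)
    expr_row = np.asarray(expr_row, dtype=float)
    labels = np.asarray(labels, dtype=float)
    tr, val, te = splits
    xtr, xval, xte = _minmax_scale(expr_row[tr], expr_row[val], expr_row[te])
    params = _init_params([rng], 1, config.hidden_units)
    best, best_val, failed = _train_batch(
        xtr[None, :, None], labels[tr][None, :],
        xval[None, :, None], labels[val][None, :],
        params, config,
    )
    if failed[0]:
        return float("nan"), float(best_val[0])
    _, out = _forward(xte[None, :, None], *best)
    return float(((out[0] - labels[te]) ** 2).mean()), float(best_val[0])


def _stream_key(name: str) -> int:
    return zlib.crc32(str(name).encode())


# ---------------------------------------------------------------------------
# Estimators


class NeuralNetRanker(BaseEstimator):
    """Rank features by mean test error of single-input class predictors.

    Parameters mirror :class:`AnnConfig`; ``fit(X, y)`` takes samples ×
    features (DataFrame columns name the transcripts) and binary labels.

    Attributes
    ----------
    feature_names_in_ : ndarray of feature names
    errors_mean_, errors_sd_ : per-feature test-error statistics
    n_failed_ : per-feature count of failed (non-finite) resamples
    ranking_ : DataFrame (probeset_id, mean_test_error, sd_test_error),
        ascending by error, ties broken by sd then id.
    """

    def __init__(
        self,
        hidden_units: int = 2,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        patience: int = 25,
        max_cycles: int = 300,
        n_resamples: int = 50,
        train_frac: float = 0.6,
        val_frac: float = 0.2,
        test_frac: float = 0.2,
        top_k: int = 100,
        early_stop_mode: str = "decrease",
        random_state: int = 0,
        chunk_size: int = 200,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.patience = patience
        self.max_cycles = max_cycles
        self.n_resamples = n_resamples
        self.train_frac = train_frac
        self.val_frac = val_frac
        self.test_frac = test_frac
        self.top_k = top_k
        self.early_stop_mode = early_stop_mode
        self.random_state = random_state
        self.chunk_size = chunk_size

    def _config(self) -> AnnConfig:
        return AnnConfig(
            hidden_units=self.hidden_units,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            patience=self.patience,
            max_cycles=self.max_cycles,
            n_resamples=self.n_resamples,
            train_frac=self.train_frac,
            val_frac=self.val_frac,
            test_frac=self.test_frac,
            top_k=self.top_k,
            seed=self.random_state,
            early_stop_mode=self.early_stop_mode,
        )

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = np.asarray([str(i) for i in range(values.shape[1])], dtype=object)
        y = np.asarray(y, dtype=float)
        if values.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must contain both classes, coded 0 and 1")
        if min(np.sum(y == 0), np.sum(y == 1)) < 2:
            raise ValueError("need at least 2 samples per class")

        n_samples, n_features = values.shape
        fractions = (cfg.train_frac, cfg.val_frac, cfg.test_frac)
        n_tr, n_val, n_te = subset_sizes(n_samples, fractions)
        R = cfg.n_resamples

        mean = np.empty(n_features)
        sd = np.empty(n_features)
        failed_counts = np.zeros(n_features, dtype=int)

        for start in range(0, n_features, self.chunk_size):
            idx = range(start, min(start + self.chunk_size, n_features))
            m = len(idx) * R
            Xtr = np.empty((m, n_tr, 1))
            ytr = np.empty((m, n_tr))
            Xval = np.empty((m, n_val, 1))
            yval = np.empty((m, n_val))
            Xte = np.empty((m, n_te, 1))
            yte = np.empty((m, n_te))
            rngs = []
            row = 0
            for t in idx:
                key = _stream_key(names[t])
                col = values[:, t]
                for r in range(R):
                    rng = np.random.default_rng(
                        (self.random_state & 0x7FFFFFFF, key, r)
                    )
                    tr, val, te = split_data(y, fractions, rng)
                    xtr, xval, xte = _minmax_scale(col[tr], col[val], col[te])
                    Xtr[row, :, 0], ytr[row] = xtr, y[tr]
                    Xval[row, :, 0], yval[row] = xval, y[val]
                    Xte[row, :, 0], yte[row] = xte, y[te]
                    rngs.append(rng)
                    row += 1
            params = _init_params(rngs, 1, cfg.hidden_units)
            best, _, failed = _train_batch(Xtr, ytr, Xval, yval, params, cfg)
            _, out = _forward(Xte, *best)
            test_err = ((out - yte) ** 2).mean(axis=1)
            test_err[failed] = np.nan
            per_t = test_err.reshape(len(idx), R)
            with np.errstate(invalid="ignore"):
                mean[list(idx)] = np.nanmean(per_t, axis=1)
                sd[list(idx)] = np.nanstd(per_t, axis=1)
            failed_counts[list(idx)] = np.isnan(per_t).sum(axis=1)

        self.feature_names_in_ = names
        self.errors_mean_ = mean
        self.errors_sd_ = sd
        self.n_failed_ = failed_counts
        table = pd.DataFrame(
            {
                "probeset_id": names,
                "mean_test_error": mean,
                "sd_test_error": sd,
                "n_failed": failed_counts,
            }
        )
        table = table.sort_values(
            ["mean_test_error", "sd_test_error", "probeset_id"],
            kind="stable",
            na_position="last",
        ).reset_index(drop=True)
        self.ranking_ = table
        return self

    def top(self, k: int | None = None) -> list[str]:
        """Ids of the k best-ranked features (default: ``top_k``)."""
        k = self.top_k if k is None else k
        return list(self.ranking_["probeset_id"].head(k))


class MarkerInteraction(BaseEstimator):
    """Signed influence matrix among a panel of markers.

    For every marker j a network predicts j (min-max scaled) from the
    remaining markers; ``influence_.loc[i, j]`` is the mean over samples
    of d(prediction of j)/d(input i).  Unlike the ranking nets these are
    function fits, not generalization estimates, so each net trains on
    all samples and stops when its training error plateaus for
    ``patience`` cycles.  Constant markers yield zero rows and columns
    with a warning.
    """

    def __init__(
        self,
        hidden_units: int = 2,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        patience: int = 50,
        max_cycles: int = 500,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.patience = patience
        self.max_cycles = max_cycles
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [str(i) for i in range(values.shape[1])]
        n, k = values.shape
        if k < 2:
            raise ValueError("need at least two markers")
        cfg = AnnConfig(
            hidden_units=self.hidden_units,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            patience=self.patience,
            max_cycles=self.max_cycles,
            n_resamples=1,
            seed=self.random_state,
        )
        spans = values.max(axis=0) - values.min(axis=0)
        constant = spans == 0
        if constant.any():
            logger.warning(
                "constant markers recorded as zero influence: %s",
                [names[i] for i in np.where(constant)[0]],
            )
        scaled = np.zeros_like(values)
        ok = ~constant
        scaled[:, ok] = (values[:, ok] - values[:, ok].min(axis=0)) / spans[ok]

        influence = np.zeros((k, k))
        for j in range(k):
            if constant[j]:
                continue
            rng = np.random.default_rng(
                (self.random_state & 0x7FFFFFFF, _stream_key(names[j]), 0x1E7)
            )
            inputs = np.delete(np.arange(k), j)
            Xj = scaled[:, inputs]
            yj = scaled[:, j]
            params = _init_params([rng], k - 1, cfg.hidden_units)
            best, _, failed = _train_batch(
                Xj[None], yj[None], Xj[None], yj[None], params, cfg,
            )
            if failed[0]:
                logger.warning("interaction net for %s diverged; zero column", names[j])
                continue
            w1, b1, w2, b2 = best
            a1, out = _forward(Xj[None], w1, b1, w2, b2)
            # d out / d x_i = out' * sum_h w2_h a1_h' w1_{i,h}
            dout = (out * (1 - out))[0][:, None]  # (n, 1)
            da1 = (a1 * (1 - a1))[0]  # (n, H)
            grads = dout * (da1 * w2[0][None, :]) @ w1[0].T  # (n, k-1)
            influence[inputs, j] = grads.mean(axis=0)
        influence[constant, :] = 0.0
        influence[:, constant] = 0.0
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.influence_ = pd.DataFrame(influence, index=names, columns=names)
        return self

    def top_edges(self, n: int = 10) -> pd.DataFrame:
        """The n most positive and n most negative off-diagonal edges."""
        inf = self.influence_
        records = [
            (i, j, inf.loc[i, j])
            for i in inf.index
            for j in inf.columns
            if i != j
        ]
        df = pd.DataFrame(records, columns=["from", "to", "influence"])
        df = df.sort_values(["influence", "from", "to"], kind="stable")
        neg = df.head(n).assign(sign="negative")
        pos = df.tail(n).iloc[::-1].assign(sign="positive")
        return pd.concat([pos, neg], ignore_index=True)


# ---------------------------------------------------------------------------
# Module-level wrappers (expression matrices are probe sets × samples)


def rank_transcripts(
    expr: pd.DataFrame, labels: pd.Series | dict, config: AnnConfig | None = None
) -> pd.DataFrame:
    """Rank all transcripts of a probe sets × samples expression matrix."""
    config = config or AnnConfig()
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without labels: {missing}")
    ranker = NeuralNetRanker(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        patience=config.patience,
        max_cycles=config.max_cycles,
        n_resamples=config.n_resamples,
        train_frac=config.train_frac,
        val_frac=config.val_frac,
        test_frac=config.test_frac,
        top_k=config.top_k,
        early_stop_mode=config.early_stop_mode,
        random_state=config.seed,
    )
    ranker.fit(expr.T, labels.to_numpy())
    return ranker.ranking_


def interaction_matrix(
    expr_topk: pd.DataFrame, seed: int = 0, **params
) -> pd.DataFrame:
    """Influence matrix over a probe sets × samples marker panel."""
    est = MarkerInteraction(random_state=seed, **params)
    est.fit(expr_topk.T)
    return est.influence_
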