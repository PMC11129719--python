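"""Sparse non-negative Bayesian triplet embedding (VICE-style).

Fits an items x dimensions non-negative loading matrix to 2AFC
match-to-sample choices using the *target-matching* likelihood: the
probability of choosing match a over match b for target t is

    p = exp(s_ta) / (exp(s_ta) + exp(s_tb)),    s_ij = x_i . x_j,

with x the non-negative embedding rows.  Inference is mean-field
variational: each weight gets a Gaussian posterior q(w) = N(mu, sigma^2),
non-negativity is imposed by rectifying sampled weights inside the
likelihood, and a spike-and-slab mixture prior (narrow + wide zero-mean
component) drives unused weights toward zero.  The objective is the
Monte-Carlo estimate of

    mean negative log choice-likelihood + (1/N_trials) * sum_w KL(q || prior),

optimized with Adam using hand-derived reparameterization gradients.
Dimension pruning keeps a dimension only if enough items are credibly
positive under the posterior; the pruned point estimate max(0, mu) is the
reported embedding, columns sorted by decreasing loading sum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from . import behavioral_stats
from .errors import DegenerateModelError, DivergenceError, ParameterError
from .triplet_design import Triplet, experimental_trials

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Embedding:
    """Non-negative item embedding; columns ("similarity dimensions")
    sorted by decreasing loading sum."""

    items: list
    loadings: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[1] < 1:
            raise ParameterError("loadings must be a 2-D matrix with >= 1 dimension")
        if len(self.items) != self.loadings.shape[0]:
            raise ParameterError("item labels do not match loading rows")
        if self.loadings.min() < -1e-12:
            raise ParameterError("embedding loadings must be non-negative")
        self.loadings = np.maximum(self.loadings, 0.0)
        order = np.argsort(-self.loadings.sum(axis=0), kind="stable")
        self.loadings = self.loadings[:, order]
        self._index = {item: i for i, item in enumerate(self.items)}

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    def row(self, item) -> np.ndarray:
        if item not in self._index:
            raise LookupError(f"unknown item {item!r}")
        return self.loadings[self._index[item]]

    def rows(self, items) -> np.ndarray:
        return np.stack([self.row(i) for i in items])


@dataclass
class VariationalPosterior:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ParameterError("mu and sigma shapes disagree")
        if (self.sigma <= 0).any():
            raise ParameterError("sigma must be strictly positive")


@dataclass
class SpikeSlabPrior:
    """Zero-mean two-component mixture prior: a narrow spike and a wide
    slab, mixed with weight ``pi`` on the spike."""

    family: str = "laplace"
    spike_scale: float = 0.125
    slab_scale: float = 1.0
    pi: float = 0.6

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "laplace"):
            raise ParameterError(f"unknown prior family {self.family!r}")
        if not 0 < self.pi < 1:
            raise ParameterError("pi must be in (0, 1)")
        if self.spike_scale <= 0 or self.slab_scale <= 0:
            raise ParameterError("prior scales must be positive")
        if self.spike_scale >= self.slab_scale:
            warnings.warn(
                "spike_scale >= slab_scale: the 'spike' is not the narrow component",
                stacklevel=2,
            )

    def log_pdf_and_grad(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """log p(w) and d log p / d w, elementwise."""
        if self.family == "gaussian":
            lf_sp = -0.5 * (w / self.spike_scale) ** 2 - np.log(self.spike_scale) - 0.5 * np.log(2 * np.pi)
            lf_sl = -0.5 * (w / self.slab_scale) ** 2 - np.log(self.slab_scale) - 0.5 * np.log(2 * np.pi)
            g_sp = -w / self.spike_scale**2
            g_sl = -w / self.slab_scale**2
        else:  # laplace
            lf_sp = -np.abs(w) / self.spike_scale - np.log(2 * self.spike_scale)
            lf_sl = -np.abs(w) / self.slab_scale - np.log(2 * self.slab_scale)
            g_sp = -np.sign(w) / self.spike_scale
            g_sl = -np.sign(w) / self.slab_scale
        a = np.log(self.pi) + lf_sp
        b = np.log1p(-self.pi) + lf_sl
        m = np.maximum(a, b)
        logp = m + np.log(np.exp(a - m) + np.exp(b - m))
        resp_sp = np.exp(a - logp)
        grad = resp_sp * g_sp + (1.0 - resp_sp) * g_sl
        return logp, grad


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 128
    mc_samples: int = 1
    d_max: int | None = None  # defaults to n_items
    seed: int = 0
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.mc_samples < 1:
            raise ParameterError("invalid optimizer settings")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def choice_probability(emb: Embedding, triplet: Triplet) -> float:
    """Target-matching choice probability p(choose match_a over match_b)."""
    xt = emb.row(triplet.target)
    s_a = float(xt @ emb.row(triplet.match_a))
    s_b = float(xt @ emb.row(triplet.match_b))
    return float(expit(s_a - s_b))


def _trial_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    exp = experimental_trials(trials)
    t = exp["target"].to_numpy(dtype=int)
    l = exp["match_left"].to_numpy(dtype=int)
    r = exp["match_right"].to_numpy(dtype=int)
    y = (exp["response"].to_numpy() == "left").astype(float)
    return t, l, r, y


def _left_logits(loadings: np.ndarray, t, l, r) -> np.ndarray:
    x = loadings
    return np.einsum("ij,ij->i", x[t], x[l]) - np.einsum("ij,ij->i", x[t], x[r])


def accuracy(emb: Embedding, trials: pd.DataFrame) -> float:
    """Fraction of trials whose response matches the higher-probability
    side; exact ties are credited 0.5."""
    t, l, r, y = _trial_arrays(trials)
    if not set(np.concatenate([t, l, r])) <= set(emb.items):
        raise LookupError("trials reference items missing from the embedding")
    idx = {item: i for i, item in enumerate(emb.items)}
    remap = np.vectorize(idx.get)
    z = _left_logits(emb.loadings, remap(t), remap(l), remap(r))
    correct = np.where(z == 0, 0.5, (z > 0) == (y == 1))
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# variational fit
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + eps))
        return out


def _softplus(x):
    return np.logaddexp(0.0, x)


def fit(
    trials: pd.DataFrame,
    prior: SpikeSlabPrior | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[VariationalPosterior, pd.DataFrame]:
    """Variational fit of the spike-and-slab non-negative embedding.

    Returns the posterior (per-weight Gaussian mean and scale) and a
    per-epoch training log (loss and training accuracy of the current
    point estimate).  Deterministic given ``cfg.seed``.  Catch and
    practice rows are dropped before fitting.
    """
    prior = prior or SpikeSlabPrior()
    cfg = cfg or TrainConfig()
    t, l, r, y = _trial_arrays(trials)
    n_trials = len(t)
    if n_trials == 0:
        raise ParameterError("no experimental trials to fit")
    n_items = int(max(t.max(), l.max(), r.max())) + 1
    seen = np.bincount(np.concatenate([t, l, r]), minlength=n_items)
    if (seen == 0).any():
        warnings.warn(f"{int((seen == 0).sum())} items appear in no trial", stacklevel=2)
    d = cfg.d_max or n_items

    rng = np.random.default_rng(cfg.seed)
    M = rng.normal(0.0, 0.1, size=(n_items, d))
    R = np.full((n_items, d), np.log(np.expm1(0.1)))  # softplus^-1(0.1)
    adam = _Adam([M.shape, R.shape], cfg.learning_rate)

    log_rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_trials)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_trials, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bt, bl, br, by = t[idx], l[idx], r[idx], y[idx]
            B = len(idx)
            S = _softplus(R)
            dS = expit(R)
            GM = np.zeros_like(M)
            GR = np.zeros_like(R)
            loss = 0.0
            for _ in range(cfg.mc_samples):
                eps_w = rng.normal(size=M.shape)
                W = M + S * eps_w
                X = np.maximum(W, 0.0)
                mask = (W > 0).astype(float)

                z = _left_logits(X, bt, bl, br)
                nll = np.mean(np.logaddexp(0.0, z) - by * z)
                g = (expit(z) - by) / B  # d(mean NLL)/dz
                GX = np.zeros_like(X)
                np.add.at(GX, bt, g[:, None] * (X[bl] - X[br]))
                np.add.at(GX, bl, g[:, None] * X[bt])
                np.subtract.at(GX, br, g[:, None] * X[bt])
                GW = GX * mask
                GM += GW
                GR += GW * eps_w * dS

                logq = -np.log(S) - 0.5 * eps_w**2 - 0.5 * np.log(2 * np.pi)
                logp, dlogp = prior.log_pdf_and_grad(W)
                kl = np.sum(logq - logp)
                # reparameterized gradient of the complexity term:
                #   d/dM [logq - logp] = -dlogp ;  d/dS = -1/S - dlogp * eps
                GM += (-dlogp) / n_trials
                GR += ((-1.0 / S) + (-dlogp) * eps_w) * dS / n_trials
                loss += nll + kl / n_trials
            loss /= cfg.mc_samples
            GM /= cfg.mc_samples
            GR /= cfg.mc_samples
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} with prior={prior}, "
                    f"learning_rate={cfg.learning_rate}"
                )
            M, R = adam.step([M, R], [GM, GR])
            epoch_loss += float(loss)
            n_batches += 1
        point = np.maximum(M, 0.0)
        z_all = _left_logits(point, t, l, r)
        train_acc = float(np.mean(np.where(z_all == 0, 0.5, (z_all > 0) == (y == 1))))
        log_rows.append((epoch, epoch_loss / n_batches, train_acc))

    posterior = VariationalPosterior(mu=M, sigma=_softplus(R))
    log = pd.DataFrame(log_rows, columns=["epoch", "loss", "train_acc"])
    return posterior, log


def extract_embedding(
    post: VariationalPosterior,
    alpha: float = 0.05,
    min_items: int = 2,
    items: list | None = None,
) -> Embedding:
    """Pruned point-estimate embedding max(0, mu).

    A dimension is retained iff at least ``min_items`` items have
    posterior probability P(w > 0) >= 1 - alpha under the Gaussian
    posterior; retained dimensions are sorted by decreasing loading sum.
    """
    p_pos = ndtr(post.mu / post.sigma)
    retained = (p_pos >= 1.0 - alpha).sum(axis=0) >= min_items
    if not retained.any():
        raise DegenerateModelError("no dimension has enough credibly-positive items")
    loadings = np.maximum(post.mu, 0.0)[:, retained]
    items = items if items is not None else list(range(post.mu.shape[0]))
    return Embedding(items=items, loadings=loadings)


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def split_trials(
    trials: pd.DataFrame, train_fraction: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split of experimental trials, stratified by
    target item so every item keeps proportional coverage."""
    exp = experimental_trials(trials)
    rng = np.random.default_rng(seed)
    train_idx = []
    test_idx = []
    for _, grp in exp.groupby("target"):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        cut = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    return exp.loc[sorted(train_idx)], exp.loc[sorted(test_idx)]


def noise_ceiling(trials: pd.DataFrame, reps: int = 4) -> float:
    """Mean repetition agreement across triplets: the best accuracy any
    model could reach given response variability (even splits score 0.5)."""
    dist = behavioral_stats.agreement_distribution(trials, reps=reps)
    return dist.mean_agreement(reps)


# ---------------------------------------------------------------------------
# hyperparameter grid search
# ---------------------------------------------------------------------------


def default_grid(
    epochs: int = 200, d_max: int | None = None, seed: int = 0
) -> list[tuple[SpikeSlabPrior, TrainConfig]]:
    """The shipped hyperparameter grid: 3 learning rates x 2 prior
    families x 3 spike scales x 3 slab scales x 3 mixture weights = 162
    configurations."""
    grid = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spike/slab crossings are part of the grid
        for lr, family, spike, slab, pi in itertools.product(
            [0.0005, 0.001, 0.002],
            ["gaussian", "laplace"],
            [0.125, 0.25, 0.75],
            [0.2, 0.5, 1.0],
            [0.4, 0.5, 0.6],
        ):
            grid.append(
                (
                    SpikeSlabPrior(family=family, spike_scale=spike, slab_scale=slab, pi=pi),
                    TrainConfig(learning_rate=lr, epochs=epochs, d_max=d_max, seed=seed),
                )
            )
    return grid


def grid_search(
    trials: pd.DataFrame,
    grid: list[tuple[SpikeSlabPrior, TrainConfig]],
    seed: int = 0,
    alpha: float = 0.05,
    min_items: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every grid point on one fixed 90/10 split and rank by test
    accuracy.  Returns the ranked table and the best point's artifacts
    (prior, config, posterior, embedding, accuracies)."""
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    train, test = split_trials(trials, grid[0][1].train_fraction, seed=seed)
    rows = []
    best = None
    for gi, (prior, cfg) in enumerate(grid):
        posterior, log = fit(train, prior, cfg)
        try:
            emb = extract_embedding(posterior, alpha=alpha, min_items=min_items)
            d_ret = emb.d
            train_acc = accuracy(emb, train)
            test_acc = accuracy(emb, test)
        except DegenerateModelError:
            emb, d_ret, train_acc, test_acc = None, 0, np.nan, np.nan
        rows.append(
            (gi, prior.family, cfg.learning_rate, prior.spike_scale, prior.slab_scale,
             prior.pi, d_ret, train_acc, test_acc)
        )
        if emb is not None and (best is None or test_acc > best["test_acc"]):
            best = {
                "grid_index": gi, "prior": prior, "cfg": cfg, "posterior": posterior,
                "embedding": emb, "train_acc": train_acc, "test_acc": test_acc,
            }
    table = pd.DataFrame(
        rows,
        columns=["grid_index", "family", "learning_rate", "spike", "slab", "pi",
                 "d_retained", "train_acc", "test_acc"],
    ).sort_values("test_acc", ascending=False, ignore_index=True)
    if best is None:
        raise DegenerateModelError("every grid point collapsed to zero dimensions")
    return table, best


# ---------------------------------------------------------------------------
# maximum-likelihood embedding and CV dimensionality estimate
# ---------------------------------------------------------------------------


def _spectral_init(t, l, r, y, n_items: int, d: int, scale: float = 4.0) -> np.ndarray:
    """Initial loadings from the empirical choice data: symmetrized
    per-pair win rates (how often a match was chosen when presented for a
    target), eigendecomposed, top-d components rectified."""
    wins = np.zeros((n_items, n_items))
    appear = np.zeros((n_items, n_items))
    chosen = np.where(y == 1, l, r)
    unchosen = np.where(y == 1, r, l)
    np.add.at(wins, (t, chosen), 1.0)
    np.add.at(appear, (t, chosen), 1.0)
    np.add.at(appear, (t, unchosen), 1.0)
    rate = np.where(appear > 0, wins / np.maximum(appear, 1.0), 0.5)
    s = (rate + rate.T) / 2.0
    np.fill_diagonal(s, 1.0)
    eigvals, eigvecs = np.linalg.eigh(s)
    order = np.argsort(eigvals)[::-1][:d]
    return scale * np.abs(eigvecs[:, order] * np.sqrt(np.maximum(eigvals[order], 1e-9)))


def fit_ml(
    trials: pd.DataFrame,
    d: int,
    epochs: int = 300,
    learning_rate: float = 0.02,
    batch_size: int = 128,
    seed: int = 0,
    n_items: int | None = None,
    n_restarts: int = 3,
) -> Embedding:
    """Plain maximum-likelihood non-negative embedding (no sparsity
    prior): point weights, rectified inside the likelihood, Adam.

    The rectified factorization has local optima at small ``d``, so the
    fit runs once from a spectral initialization (rectified top-d
    eigenvectors of the empirical win-rate similarity matrix) and
    ``n_restarts - 1`` times from random starts, keeping the solution
    with the best training likelihood.
    """
    t, l, r, y = _trial_arrays(trials)
    n_items = n_items or int(max(t.max(), l.max(), r.max())) + 1
    n_trials = len(t)
    spectral = _spectral_init(t, l, r, y, n_items, d)
    best_W, best_nll = None, np.inf
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        if restart == 0:
            W = spectral + rng.normal(0.0, 0.01, size=spectral.shape)
        else:
            W = rng.normal(0.2, 0.2, size=(n_items, d))
        adam = _Adam([W.shape], learning_rate)
        for _ in range(epochs):
            order = rng.permutation(n_trials)
            for start in range(0, n_trials, batch_size):
                idx = order[start : start + batch_size]
                bt, bl, br, by = t[idx], l[idx], r[idx], y[idx]
                X = np.maximum(W, 0.0)
                z = _left_logits(X, bt, bl, br)
                g = (expit(z) - by) / len(idx)
                GX = np.zeros_like(X)
                np.add.at(GX, bt, g[:, None] * (X[bl] - X[br]))
                np.add.at(GX, bl, g[:, None] * X[bt])
                np.subtract.at(GX, br, g[:, None] * X[bt])
                GW = GX * (W > 0)
                if not np.isfinite(GW).all():
                    raise DivergenceError("non-finite gradient in ML embedding fit")
                (W,) = adam.step([W], [GW])
        X = np.maximum(W, 0.0)
        z = _left_logits(X, t, l, r)
        nll = float(np.mean(np.logaddexp(0.0, z) - y * z))
        if nll < best_nll:
            best_W, best_nll = W, nll
    loadings = np.maximum(best_W, 0.0)
    if not loadings.any():
        loadings = np.full_like(loadings, 1e-6)
    return Embedding(items=list(range(n_items)), loadings=loadings)


def estimate_dimensionality_cv(
    trials: pd.DataFrame,
    d_list: list[int],
    folds: int = 5,
    seed: int = 0,
    epochs: int = 120,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated dimensionality estimate from triplet-embedding
    accuracy.

    Fits the plain ML embedding at each candidate dimensionality with
    k-fold cross-validation over trials and applies the one-standard-error
    rule: the estimate is the smallest d whose mean test accuracy is
    within one SE of the maximum.  Returns (d_hat, per-d table).
    """
    if not d_list:
        raise ParameterError("d_list must not be empty")
    exp = experimental_trials(trials)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exp))
    fold_of = np.arange(len(exp)) % folds
    fold_of = fold_of[np.argsort(order)]  # random fold assignment
    rows = []
    for d in sorted(d_list):
        accs = []
        for f in range(folds):
            train = exp.iloc[fold_of != f]
            test = exp.iloc[fold_of == f]
            emb = fit_ml(train, d, epochs=epochs, seed=seed + f)
            accs.append(accuracy(emb, test))
        accs = np.asarray(accs)
        rows.append((d, accs.mean(), accs.std(ddof=1) / np.sqrt(folds)))
    table = pd.DataFrame(rows, columns=["d", "mean_acc", "se"])
    best = table["mean_acc"].idxmax()
    threshold = table.loc[best, "mean_acc"] - table.loc[best, "se"]
    d_hat = int(table.loc[table["mean_acc"] >= threshold, "d"].min())
    return d_hat, table
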