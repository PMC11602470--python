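"""Discrete-observation HMM classifier for within-participant MW detection.

One two-hidden-state HMM is trained per condition (focused learning FL,
mind-wandering MW) on the concatenated training-fold state sequences with
Baum-Welch, from near-uniform initialization: exactly uniform rows are an EM
fixed point with interchangeable hidden states, so each row of A, B and pi is
perturbed by seeded 10% jitter and renormalized. A held-out sequence Y is
scored by the posterior under equal priors,

    S_FL = P(Y|lambda_FL) / (P(Y|lambda_FL) + P(Y|lambda_MW)),

computed stably from the scaled-forward log-likelihood difference. Band
choice, fold splitting and the F1 threshold (Youden point of the training
ROC) use training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .preprocess import BAND_ORDER, ValidationError

__all__ = [
    "HmmModel",
    "ClassificationResult",
    "fit_hmm",
    "forward_likelihood",
    "score_fl",
    "roc_auc",
    "crossvalidate_participant",
]

# minimum probability kept in every transition/emission cell during EM
# updates: plain maximum-likelihood estimates on short training sequences
# drive unseen cells to exact zero, which makes held-out scores explode on
# any window containing an unseen pattern
_EMISSION_FLOOR = 1e-2


@dataclass
class HmmModel:
    A: np.ndarray  # [n_hidden x n_hidden] transition matrix
    B: np.ndarray  # [n_hidden x n_obs] observation matrix
    pi: np.ndarray  # [n_hidden] initial distribution
    condition: str = ""
    train_log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return self.A.shape[0]

    @property
    def n_obs(self) -> int:
        return self.B.shape[1]


def _check_sequence(seq, n_obs: int | None) -> tuple[np.ndarray, int]:
    s = np.asarray(seq, dtype=int)
    if s.ndim != 1 or s.size == 0:
        raise ValidationError("sequence must be a non-empty 1-D symbol array")
    if s.min() < 0:
        raise ValidationError("negative symbol index")
    if n_obs is None:
        n_obs = int(s.max()) + 1
    elif s.max() >= n_obs:
        raise ValidationError(f"symbol {s.max()} outside alphabet of size {n_obs}")
    return s, max(n_obs, 2)


def _scaled_forward(model: HmmModel, seq: np.ndarray) -> float:
    """Log-likelihood by the scaled forward recursion; -inf for zero paths."""
    alpha = model.pi * model.B[:, seq[0]]
    loglik = 0.0
    for t in range(seq.size):
        if t > 0:
            alpha = (alpha @ model.A) * model.B[:, seq[t]]
        c = alpha.sum()
        if c <= 0:
            return float("-inf")
        alpha = alpha / c
        loglik += np.log(c)
    return float(loglik)


def forward_likelihood(model: HmmModel, sequence, start: str = "initial") -> float:
    """log P(O | lambda) of a symbol sequence under the model.

    ``start='initial'`` uses the trained initial distribution pi;
    ``start='stationary'`` starts the hidden chain from the stationary
    distribution of A, appropriate when the sequence is an excerpt from the
    middle of a longer recording rather than a recording start.
    """
    seq, _ = _check_sequence(sequence, model.n_obs)
    if start == "stationary":
        model = HmmModel(A=model.A, B=model.B, pi=_stationary_distribution(model.A))
    elif start != "initial":
        raise ValidationError(f"unknown start convention {start!r}")
    return _scaled_forward(model, seq)


def _perturbed_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    # 10% jitter: smaller perturbations leave EM within the symmetric
    # saddle's basin for hundreds of iterations on some draws
    m = np.ones(shape) + rng.uniform(-0.1, 0.1, size=shape)
    m = np.clip(m, 1e-6, None)
    return m / m.sum(axis=-1, keepdims=True)


def _stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(A.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, k]))
    s = pi.sum()
    return pi / s if s > 0 else np.full(A.shape[0], 1.0 / A.shape[0])


def fit_hmm(
    sequence,
    n_hidden: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_obs: int | None = None,
    condition: str = "",
    perturb: bool = True,
    n_restarts: int = 3,
) -> HmmModel:
    """Baum-Welch EM from perturbed-uniform initialization.

    ``perturb=False`` keeps the exactly uniform start (useful only to
    demonstrate the symmetric EM fixed point). The log-likelihood trace is
    recorded per iteration and is non-decreasing up to float tolerance.

    The near-uniform start sits beside a symmetric saddle of the likelihood,
    which EM leaves through many tiny steps before the hidden states
    differentiate; the tolerance must be small relative to the escape
    dynamics (hence 1e-6 with a generous iteration cap), and since escape is
    start-dependent, ``n_restarts`` seeded restarts are run and the solution
    with the highest final log-likelihood kept.
    """
    seq, n_obs = _check_sequence(sequence, n_obs)
    if seq.size < 10:
        raise ValidationError("training sequence must have >= 10 symbols")
    if not perturb:
        n_restarts = 1
    best: HmmModel | None = None
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(max(n_restarts, 1))):
        model = _fit_once(seq, n_hidden, np.random.default_rng(child), tol,
                          max_iter, n_obs, condition, perturb)
        if best is None or (
            model.train_log_likelihood_trace[-1]
            > best.train_log_likelihood_trace[-1]
        ):
            best = model
    return best


def _fit_once(
    seq: np.ndarray,
    n_hidden: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    n_obs: int,
    condition: str,
    perturb: bool,
) -> HmmModel:
    if perturb:
        A = _perturbed_uniform((n_hidden, n_hidden), rng)
        B = _perturbed_uniform((n_hidden, n_obs), rng)
        pi = _perturbed_uniform((n_hidden,), rng)
    else:
        A = np.full((n_hidden, n_hidden), 1.0 / n_hidden)
        B = np.full((n_hidden, n_obs), 1.0 / n_obs)
        pi = np.full(n_hidden, 1.0 / n_hidden)

    T = seq.size
    trace: list[float] = []
    for _ in range(max_iter):
        # scaled forward-backward
        alpha = np.empty((T, n_hidden))
        scale = np.empty(T)
        a = pi * B[:, seq[0]]
        scale[0] = a.sum()
        alpha[0] = a / scale[0]
        for t in range(1, T):
            a = (alpha[t - 1] @ A) * B[:, seq[t]]
            scale[t] = a.sum()
            if scale[t] <= 0:
                scale[t] = _EMISSION_FLOOR
            alpha[t] = a / scale[t]
        beta = np.empty((T, n_hidden))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (A @ (B[:, seq[t + 1]] * beta[t + 1])) / scale[t + 1]
        loglik = float(np.sum(np.log(scale)))
        trace.append(loglik)

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # xi summed over time:
        # xi_t[i,j] = alpha[t,i] A[i,j] B[j,o_{t+1}] beta[t+1,j] / scale[t+1]
        g = B[:, seq[1:]].T * beta[1:] / scale[1:, None]
        xi_sum = (alpha[:-1].T @ g) * A
        pi = gamma[0]
        A = xi_sum / np.maximum(gamma[:-1].sum(axis=0)[:, None], _EMISSION_FLOOR)
        A = np.maximum(A, _EMISSION_FLOOR)
        A /= A.sum(axis=1, keepdims=True)
        B_new = np.zeros((n_hidden, n_obs))
        for o in range(n_obs):
            B_new[:, o] = gamma[seq == o].sum(axis=0)
        B = np.maximum(B_new, _EMISSION_FLOOR)
        B /= B.sum(axis=1, keepdims=True)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return HmmModel(A=A, B=B, pi=pi, condition=condition, train_log_likelihood_trace=trace)


def score_fl(sequence, model_fl: HmmModel, model_mw: HmmModel,
             start: str = "initial") -> float:
    """Posterior probability of the FL model under equal priors."""
    if model_fl.n_obs != model_mw.n_obs:
        raise ValidationError("models must share the observation alphabet")
    ll_fl = forward_likelihood(model_fl, sequence, start=start)
    ll_mw = forward_likelihood(model_mw, sequence, start=start)
    if np.isinf(ll_fl) and np.isinf(ll_mw):
        warnings.warn("both likelihoods are zero; score undefined", stacklevel=2)
        return float("nan")
    if np.isinf(ll_fl):
        return 0.0
    if np.isinf(ll_mw):
        return 1.0
    # S = 1 / (1 + exp(ll_mw - ll_fl)), stable for large |diff|
    d = ll_mw - ll_fl
    if d > 700:
        return 0.0
    return float(1.0 / (1.0 + np.exp(d)))


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC; ties contribute 1/2; NaN if one class absent."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(s)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing TPR - FPR on (score >= threshold -> positive)."""
    order = np.argsort(scores)[::-1]
    s, y = scores[order], labels[order].astype(bool)
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((~y).sum()), 1)
    best_t, best_j = s[0] + 1e-12, -np.inf
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:
            tp += bool(y[j])
            fp += not y[j]
            j += 1
        jstat = tp / n_pos - fp / n_neg
        if jstat > best_j:
            best_j, best_t = jstat, s[i]
        i = j
    return float(best_t)


def _f1(pred: np.ndarray, labels: np.ndarray) -> float:
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class FoldResult:
    fold: int
    band: str
    scores: np.ndarray
    labels: np.ndarray
    auc: float
    f1: float
    threshold: float
    train_blocks: list[int]  # audit: block indices the fit and band choice used


@dataclass
class ClassificationResult:
    participant_id: str
    folds: list[FoldResult]
    auc_mean: float
    auc_sd: float
    f1_mean: float
    f1_sd: float


def _windows(block: np.ndarray, n_win: int) -> list[np.ndarray]:
    return [w for w in np.array_split(block, n_win) if w.size >= 2]


def _train_and_score(
    train_fl: np.ndarray,
    train_mw: np.ndarray,
    test_items: list[tuple[np.ndarray, int]],
    n_obs: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, HmmModel, HmmModel]:
    m_fl = fit_hmm(train_fl, seed=seed, n_obs=n_obs, condition="FL")
    m_mw = fit_hmm(train_mw, seed=seed + 1, n_obs=n_obs, condition="MW")
    # test items are mid-sequence windows, so the hidden chain is scored
    # from its stationary distribution rather than the trained pi
    scores = np.array([score_fl(w, m_fl, m_mw, start="stationary") for w, _ in test_items])
    labels = np.array([lab for _, lab in test_items])
    return scores, labels, m_fl, m_mw


def crossvalidate_participant(
    sequences: dict[str, dict[str, list[np.ndarray]]],
    k: int = 8,
    seed: int = 0,
    windows_per_fold: int = 4,
    inner_folds: int = 4,
    participant_id: str = "unknown",
) -> ClassificationResult:
    """k-fold CV of the two-HMM posterior classifier with in-fold band choice.

    ``sequences[band][condition]`` holds the per-trial symbol sequences of one
    participant. Trials of a condition are concatenated and split into ``k``
    contiguous blocks; each fold trains on k-1 blocks per condition, picks the
    band by inner CV on those blocks only, and scores ``windows_per_fold``
    sub-sequences of each held-out block (FL labeled 1). F1 uses the Youden
    threshold of the training-window ROC.
    """
    bands = [b for b in BAND_ORDER if b in sequences] or list(sequences)
    concat = {}
    n_obs = 0
    for band in bands:
        for cond in ("FL", "MW"):
            trials = sequences[band].get(cond, [])
            if not trials:
                raise ValidationError(f"no {cond} sequences for band {band}")
            c = np.concatenate([np.asarray(t, dtype=int) for t in trials])
            if c.size < max(2 * k, 10):
                raise ValidationError(
                    f"band {band} {cond}: {c.size} symbols is too short for {k} folds"
                )
            concat[(band, cond)] = c
            n_obs = max(n_obs, int(c.max()) + 1)

    blocks = {
        key: np.array_split(c, k) for key, c in concat.items()
    }
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(k)]

    folds: list[FoldResult] = []
    for f in range(k):
        train_idx = [i for i in range(k) if i != f]
        fseed = fold_seeds[f]

        def train_concat(band: str, cond: str) -> np.ndarray:
            return np.concatenate([blocks[(band, cond)][i] for i in train_idx])

        # band selection by inner CV on training blocks only
        if len(bands) == 1:
            chosen = bands[0]
        else:
            best_auc, chosen = -np.inf, bands[0]
            for band in bands:
                tr_fl = train_concat(band, "FL")
                tr_mw = train_concat(band, "MW")
                in_fl = np.array_split(tr_fl, inner_folds)
                in_mw = np.array_split(tr_mw, inner_folds)
                aucs = []
                for g in range(inner_folds):
                    fit_fl = np.concatenate([in_fl[i] for i in range(inner_folds) if i != g])
                    fit_mw = np.concatenate([in_mw[i] for i in range(inner_folds) if i != g])
                    if fit_fl.size < 10 or fit_mw.size < 10:
                        continue
                    items = [(w, 1) for w in _windows(in_fl[g], windows_per_fold)]
                    items += [(w, 0) for w in _windows(in_mw[g], windows_per_fold)]
                    sc, lb, _, _ = _train_and_score(fit_fl, fit_mw, items, n_obs, fseed)
                    a = roc_auc(sc, lb)
                    if np.isfinite(a):
                        aucs.append(a)
                mean_auc = float(np.mean(aucs)) if aucs else -np.inf
                if mean_auc > best_auc:  # ties keep the lower-frequency band
                    best_auc, chosen = mean_auc, band

        tr_fl = train_concat(chosen, "FL")
        tr_mw = train_concat(chosen, "MW")
        test_items = [(w, 1) for w in _windows(blocks[(chosen, "FL")][f], windows_per_fold)]
        test_items += [(w, 0) for w in _windows(blocks[(chosen, "MW")][f], windows_per_fold)]
        if not test_items or tr_fl.size < 10 or tr_mw.size < 10:
            warnings.warn(f"fold {f} skipped: insufficient data", stacklevel=2)
            continue
        scores, labels, m_fl, m_mw = _train_and_score(tr_fl, tr_mw, test_items, n_obs, fseed)
        auc = roc_auc(scores, labels)
        # threshold from training windows only
        train_items = []
        for i in train_idx:
            train_items += [(w, 1) for w in _windows(blocks[(chosen, "FL")][i], windows_per_fold)]
            train_items += [(w, 0) for w in _windows(blocks[(chosen, "MW")][i], windows_per_fold)]
        tr_scores = np.array([score_fl(w, m_fl, m_mw, start="stationary")
                              for w, _ in train_items])
        tr_labels = np.array([lab for _, lab in train_items])
        thr = _youden_threshold(tr_scores, tr_labels)
        f1 = _f1(scores >= thr, labels.astype(bool))
        folds.append(
            FoldResult(
                fold=f,
                band=chosen,
                scores=scores,
                labels=labels,
                auc=auc,
                f1=f1,
                threshold=thr,
                train_blocks=train_idx,
            )
        )
    if not folds:
        raise ValidationError("all folds skipped")
    aucs = np.array([fr.auc for fr in folds])
    f1s = np.array([fr.f1 for fr in folds])
    return ClassificationResult(
        participant_id=participant_id,
        folds=folds,
        auc_mean=float(np.nanmean(aucs)),
        auc_sd=float(np.nanstd(aucs)),
        f1_mean=float(np.nanmean(f1s)),
        f1_sd=float(np.nanstd(f1s)),
    )
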