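"""First-order linear-chain conditional random field.

The model assigns each (feature, label) pair an emission weight and each
(label, label) pair a transition weight; the conditional probability of a
label sequence y for a sentence x is

    p(y | x) = exp( sum_t [ s(x_t, y_t) + T[y_{t-1}, y_t] ] ) / Z(x)

with s(x_t, y) the sum of emission weights of the features active at
position t, plus start/end potentials. Training maximises the penalised
log-likelihood (L2, Gaussian prior) with L-BFGS; inference uses Viterbi
for the best sequence and forward-backward for per-position marginals.

Features are binary string keys interned into a vocabulary; sentences are
stored as one sparse indicator matrix so each objective evaluation is a
single sparse matrix product plus per-sentence 3x3 dynamic programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp


@dataclass
class _Dataset:
    """Featurised sentences packed for the objective."""

    X: sp.csr_matrix          # (total_tokens, n_features) 0/1 indicators
    labels: np.ndarray        # (total_tokens,) int label ids, -1 if unlabeled
    offsets: np.ndarray       # (n_sentences + 1,) token offsets per sentence


class LinearChainCRF:
    """A trainable first-order CRF over string-keyed binary features."""

    def __init__(self, label_set: Sequence[str] = ("B", "I", "O")):
        self.labels = list(label_set)
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        self.feature_index: dict[str, int] = {}
        self.W: np.ndarray | None = None        # (n_features, L) emissions
        self.T: np.ndarray | None = None        # (L, L) transitions
        self.start: np.ndarray | None = None    # (L,) start potentials
        self.end: np.ndarray | None = None      # (L,) end potentials
        self.n_iter_: int | None = None
        self.converged_: bool | None = None

    # -- featurisation -----------------------------------------------------

    def _build_dataset(
        self,
        sentences: Sequence[Sequence[set[str]]],
        label_seqs: Sequence[Sequence[str]] | None,
        grow_vocab: bool,
    ) -> _Dataset:
        indptr = [0]
        indices: list[int] = []
        labels: list[int] = []
        offsets = [0]
        for si, sent in enumerate(sentences):
            for ti, feats in enumerate(sent):
                for key in feats:
                    idx = self.feature_index.get(key)
                    if idx is None:
                        if not grow_vocab:
                            continue
                        idx = len(self.feature_index)
                        self.feature_index[key] = idx
                    indices.append(idx)
                indptr.append(len(indices))
                if label_seqs is not None:
                    labels.append(self.label_index[label_seqs[si][ti]])
                else:
                    labels.append(-1)
            offsets.append(offsets[-1] + len(sent))
        n_feat = max(len(self.feature_index), 1)
        X = sp.csr_matrix(
            (np.ones(len(indices)), np.asarray(indices, dtype=np.int64),
             np.asarray(indptr, dtype=np.int64)),
            shape=(len(labels), n_feat),
        )
        return _Dataset(X, np.asarray(labels), np.asarray(offsets))

    # -- parameter packing -------------------------------------------------

    def _pack(self) -> np.ndarray:
        return np.concatenate(
            [self.W.ravel(), self.T.ravel(), self.start, self.end]
        )

    def _unpack(self, theta: np.ndarray) -> None:
        L = len(self.labels)
        F = len(self.feature_index)
        self.W = theta[: F * L].reshape(F, L)
        o = F * L
        self.T = theta[o : o + L * L].reshape(L, L)
        o += L * L
        self.start = theta[o : o + L]
        self.end = theta[o + L : o + 2 * L]

    # -- objective ---------------------------------------------------------

    def _neg_log_likelihood(
        self, theta: np.ndarray, data: _Dataset, l2: float
    ) -> tuple[float, np.ndarray]:
        L = len(self.labels)
        F = data.X.shape[1]
        W = theta[: F * L].reshape(F, L)
        o = F * L
        T = theta[o : o + L * L].reshape(L, L)
        start = theta[o + L * L : o + L * L + L]
        end = theta[o + L * L + L :]

        emissions = data.X @ W  # (total_tokens, L)
        nll = 0.0
        d_em = np.zeros_like(emissions)
        dT = np.zeros_like(T)
        d_start = np.zeros(L)
        d_end = np.zeros(L)

        for s in range(len(data.offsets) - 1):
            a, b = data.offsets[s], data.offsets[s + 1]
            if a == b:
                continue
            em = emissions[a:b]
            y = data.labels[a:b]
            n = b - a

            # log-potential path score of the gold sequence
            gold = em[np.arange(n), y].sum() + start[y[0]] + end[y[-1]]
            if n > 1:
                gold += T[y[:-1], y[1:]].sum()

            # forward
            alpha = np.empty((n, L))
            alpha[0] = start + em[0]
            for t in range(1, n):
                alpha[t] = em[t] + logsumexp(alpha[t - 1][:, None] + T, axis=0)
            logZ = logsumexp(alpha[-1] + end)

            # backward
            beta = np.empty((n, L))
            beta[-1] = end
            for t in range(n - 2, -1, -1):
                beta[t] = logsumexp(T + (em[t + 1] + beta[t + 1])[None, :], axis=1)

            nll += logZ - gold

            # expected counts
            marg = np.exp(alpha + beta - logZ)  # (n, L) position marginals
            d_em[a:b] = marg
            d_em[a + np.arange(n), y] -= 1.0
            d_start += marg[0]
            d_start[y[0]] -= 1.0
            d_end += marg[-1]
            d_end[y[-1]] -= 1.0
            for t in range(1, n):
                pair = np.exp(
                    alpha[t - 1][:, None] + T + (em[t] + beta[t])[None, :] - logZ
                )
                dT += pair
            if n > 1:
                np.add.at(dT, (y[:-1], y[1:]), -1.0)

        dW = np.asarray((data.X.T @ d_em))
        grad = np.concatenate([dW.ravel(), dT.ravel(), d_start, d_end])
        nll += 0.5 * l2 * float(theta @ theta)
        grad += l2 * theta
        return nll, grad

    # -- training ----------------------------------------------------------

    def fit(
        self,
        sentences: Sequence[Sequence[set[str]]],
        label_seqs: Sequence[Sequence[str]],
        l2_penalty: float = 1.0,
        max_iterations: int = 100,
        tol: float = 1e-5,
    ) -> "LinearChainCRF":
        """Train by penalised maximum likelihood with L-BFGS.

        ``sentences`` is a list of sentences, each a list of per-token
        feature-key sets; ``label_seqs`` the matching label sequences.
        """
        if len(sentences) != len(label_seqs):
            raise ValueError("sentences and label sequences differ in length")
        data = self._build_dataset(sentences, label_seqs, grow_vocab=True)
        # rebuild with the final vocabulary so the matrix has full width
        data = self._build_dataset(sentences, label_seqs, grow_vocab=False)
        L = len(self.labels)
        F = len(self.feature_index)
        theta0 = np.zeros(F * L + L * L + 2 * L)
        res = scipy.optimize.minimize(
            self._neg_log_likelihood,
            theta0,
            args=(data, l2_penalty),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": tol, "gtol": 1e-6},
        )
        self._unpack(res.x)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        return self

    @property
    def is_fitted(self) -> bool:
        return self.W is not None

    # -- inference ---------------------------------------------------------

    def _emissions(self, sentence: Sequence[set[str]]) -> np.ndarray:
        L = len(self.labels)
        em = np.zeros((len(sentence), L))
        for t, feats in enumerate(sentence):
            idxs = [self.feature_index[k] for k in feats if k in self.feature_index]
            if idxs:
                em[t] = self.W[idxs].sum(axis=0)
        return em

    def viterbi(self, sentence: Sequence[set[str]]) -> list[str]:
        """Most probable label sequence for one sentence."""
        if not self.is_fitted:
            raise RuntimeError("model is not trained")
        n = len(sentence)
        if n == 0:
            return []
        L = len(self.labels)
        em = self._emissions(sentence)
        delta = self.start + em[0]
        back = np.zeros((n, L), dtype=np.int64)
        for t in range(1, n):
            scores = delta[:, None] + self.T
            back[t] = scores.argmax(axis=0)
            delta = em[t] + scores.max(axis=0)
        delta = delta + self.end
        path = [int(delta.argmax())]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def marginals(self, sentence: Sequence[set[str]]) -> np.ndarray:
        """Per-position label marginal probabilities, shape (n, L)."""
        if not self.is_fitted:
            raise RuntimeError("model is not trained")
        n = len(sentence)
        L = len(self.labels)
        if n == 0:
            return np.zeros((0, L))
        em = self._emissions(sentence)
        alpha = np.empty((n, L))
        alpha[0] = self.start + em[0]
        for t in range(1, n):
            alpha[t] = em[t] + logsumexp(alpha[t - 1][:, None] + self.T, axis=0)
        logZ = logsumexp(alpha[-1] + self.end)
        beta = np.empty((n, L))
        beta[-1] = self.end
        for t in range(n - 2, -1, -1):
            beta[t] = logsumexp(self.T + (em[t + 1] + beta[t + 1])[None, :], axis=1)
        return np.exp(alpha + beta - logZ)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        if not self.is_fitted:
            raise RuntimeError("model is not trained")
        return {
            "labels": self.labels,
            "features": sorted(self.feature_index, key=self.feature_index.get),
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "start": self.start.tolist(),
            "end": self.end.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearChainCRF":
        try:
            model = cls(d["labels"])
            model.feature_index = {k: i for i, k in enumerate(d["features"])}
            model.W = np.asarray(d["W"], dtype=float)
            model.T = np.asarray(d["T"], dtype=float)
            model.start = np.asarray(d["start"], dtype=float)
            model.end = np.asarray(d["end"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"corrupt CRF state: {exc}") from exc
        if model.W.shape != (len(model.feature_index), len(model.labels)):
            raise ValueError("corrupt CRF state: weight shape mismatch")
        return model
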