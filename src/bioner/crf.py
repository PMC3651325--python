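"""Linear-chain conditional random field with string-valued token features.

The model defines a log-linear conditional distribution over label sequences
y given an observation sequence x:

    p(y | x, lambda) = (1 / Z(x)) * exp( sum_j lambda_j F_j(y, x) )

where each global feature function F_j(y, x) = sum_i f_j(y_{i-1}, y_i, x, i)
is either a *state* function pairing an observed token feature with the label
at that position, or a *transition* function pairing consecutive labels, and
Z(x) normalizes over all label sequences.  The weights lambda are estimated
by maximizing the L2-regularized conditional log-likelihood with L-BFGS;
the objective is convex, so training from zero initialisation is
deterministic and reproducible.

Inference uses the standard dynamic programs: Viterbi for the best path (and
its posterior probability), forward-backward for the partition function and
per-position posterior marginals.  All recursions run in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = ["LinearChainCRF"]


def _logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis) if axis is not None else out.reshape(()).item()


@dataclass
class _EncodedSeq:
    """A training sequence encoded as flat feature-id arrays."""

    feat_ids: np.ndarray      # concatenated active feature ids
    row_index: np.ndarray     # position t of each entry of feat_ids
    labels: np.ndarray        # label ids, shape (n,)
    n: int


class LinearChainCRF:
    """First-order linear-chain CRF over string features.

    Parameters
    ----------
    c2:
        L2 regularization weight (penalty ``c2/2 * ||lambda||^2``).
    max_iterations:
        L-BFGS iteration cap.
    seed:
        Recorded for provenance; the convex objective is optimized from zero
        initialisation, so the fit itself involves no randomness.
    """

    def __init__(self, c2: float = 1.0, max_iterations: int = 500, seed: int = 0):
        if c2 < 0:
            raise ValueError("c2 must be non-negative")
        self.c2 = float(c2)
        self.max_iterations = int(max_iterations)
        self.seed = int(seed)
        self.feature_index: dict[str, int] = {}
        self.labels: list[str] = []
        self.W: np.ndarray | None = None       # (F, L) state weights
        self.T: np.ndarray | None = None       # (L, L) transition weights
        self.pi: np.ndarray | None = None      # (L,) start weights

    # -- encoding -----------------------------------------------------------

    def _encode(
        self, seq_features: Sequence[Sequence[str]], train: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        ids: list[int] = []
        rows: list[int] = []
        for t, feats in enumerate(seq_features):
            for f in feats:
                j = self.feature_index.get(f)
                if j is None:
                    if not train:
                        continue  # unseen feature at tag time: no weight, ignore
                    j = len(self.feature_index)
                    self.feature_index[f] = j
                ids.append(j)
                rows.append(t)
        return np.asarray(ids, dtype=np.int64), np.asarray(rows, dtype=np.int64)

    def _emissions(self, feat_ids: np.ndarray, row_index: np.ndarray, n: int) -> np.ndarray:
        E = np.zeros((n, len(self.labels)))
        if len(feat_ids):
            np.add.at(E, row_index, self.W[feat_ids])
        return E

    # -- training -----------------------------------------------------------

    def fit(
        self,
        sequences: Iterable[tuple[Sequence[Sequence[str]], Sequence[str]]],
    ) -> "LinearChainCRF":
        """Fit to ``(per-token feature lists, label sequence)`` pairs."""
        data: list[_EncodedSeq] = []
        label_index: dict[str, int] = {}
        raw = list(sequences)
        if not raw:
            raise ValueError("cannot fit on an empty corpus")
        for feats, labels in raw:
            if len(feats) != len(labels):
                raise ValueError("feature/label length mismatch")
            for y in labels:
                if y not in label_index:
                    label_index[y] = len(label_index)
        # stable, input-order-independent label ids
        self.labels = sorted(label_index)
        label_index = {y: k for k, y in enumerate(self.labels)}
        for feats, labels in raw:
            ids, rows = self._encode(feats, train=True)
            data.append(
                _EncodedSeq(
                    ids, rows,
                    np.asarray([label_index[y] for y in labels], dtype=np.int64),
                    len(labels),
                )
            )

        L = len(self.labels)
        F = len(self.feature_index)
        nW, nT, npi = F * L, L * L, L

        def unpack(theta: np.ndarray):
            W = theta[:nW].reshape(F, L)
            T = theta[nW : nW + nT].reshape(L, L)
            pi = theta[nW + nT :]
            return W, T, pi

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            self.W, self.T, self.pi = unpack(theta)
            nll = 0.0
            gW = np.zeros_like(self.W)
            gT = np.zeros_like(self.T)
            gpi = np.zeros_like(self.pi)
            for seq in data:
                E = self._emissions(seq.feat_ids, seq.row_index, seq.n)
                alpha, beta, logZ = self._forward_backward(E)
                marg = np.exp(alpha + beta - logZ)  # (n, L)
                # sequence log-likelihood
                y = seq.labels
                score = self.pi[y[0]] + E[np.arange(seq.n), y].sum()
                if seq.n > 1:
                    score += self.T[y[:-1], y[1:]].sum()
                nll += logZ - score
                # gradient: expected minus empirical counts
                M = marg.copy()
                M[np.arange(seq.n), y] -= 1.0
                if len(seq.feat_ids):
                    np.add.at(gW, seq.feat_ids, M[seq.row_index])
                gpi += M[0]
                if seq.n > 1:
                    # pairwise posteriors for all positions at once
                    P = np.exp(
                        alpha[:-1, :, None]
                        + self.T[None, :, :]
                        + (E[1:] + beta[1:])[:, None, :]
                        - logZ
                    )
                    gT += P.sum(axis=0)
                    np.add.at(gT, (y[:-1], y[1:]), -1.0)
            nll += 0.5 * self.c2 * float(theta @ theta)
            grad = np.concatenate([gW.ravel(), gT.ravel(), gpi])
            grad += self.c2 * theta
            return nll, grad

        theta0 = np.zeros(nW + nT + npi)
        res = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iterations, "maxfun": 3 * self.max_iterations},
        )
        self.W, self.T, self.pi = unpack(res.x)
        self._fit_result = res
        return self

    # -- inference ----------------------------------------------------------

    def _check_fitted(self) -> None:
        if self.W is None:
            raise RuntimeError("model is not fitted")

    def _forward_backward(self, E: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        n, L = E.shape
        alpha = np.empty((n, L))
        beta = np.zeros((n, L))
        alpha[0] = self.pi + E[0]
        for t in range(1, n):
            alpha[t] = E[t] + _logsumexp(alpha[t - 1][:, None] + self.T, axis=0)
        for t in range(n - 2, -1, -1):
            beta[t] = _logsumexp(self.T + E[t + 1] + beta[t + 1], axis=1)
        logZ = _logsumexp(alpha[-1])
        return alpha, beta, float(logZ)

    def _encode_predict(self, seq_features: Sequence[Sequence[str]]) -> np.ndarray:
        ids, rows = self._encode(seq_features, train=False)
        return self._emissions(ids, rows, len(seq_features))

    def predict(
        self, seq_features: Sequence[Sequence[str]]
    ) -> tuple[list[str], float, np.ndarray]:
        """Viterbi-decode one sequence.

        Returns ``(labels, path_probability, marginals)`` where
        ``path_probability`` is the posterior probability of the decoded path
        and ``marginals[t, k]`` the posterior probability of label *k* at
        position *t*.
        """
        self._check_fitted()
        if not len(seq_features):
            raise ValueError("empty sequence")
        E = self._encode_predict(seq_features)
        n, L = E.shape
        delta = np.empty((n, L))
        back = np.zeros((n, L), dtype=np.int64)
        delta[0] = self.pi + E[0]
        for t in range(1, n):
            scores = delta[t - 1][:, None] + self.T
            back[t] = np.argmax(scores, axis=0)
            delta[t] = E[t] + scores[back[t], np.arange(L)]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        alpha, beta, logZ = self._forward_backward(E)
        marginals = np.exp(alpha + beta - logZ)
        path_logprob = float(delta[-1, path[-1]] - logZ)
        prob = float(np.clip(np.exp(path_logprob), np.finfo(float).tiny, 1.0))
        return [self.labels[k] for k in path], prob, marginals

    def marginals(self, seq_features: Sequence[Sequence[str]]) -> np.ndarray:
        """Posterior per-position label marginals for one sequence."""
        self._check_fitted()
        E = self._encode_predict(seq_features)
        alpha, beta, logZ = self._forward_backward(E)
        return np.exp(alpha + beta - logZ)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        np.savez_compressed(
            path,
            W=self.W,
            T=self.T,
            pi=self.pi,
            labels=np.asarray(self.labels, dtype=object),
            features=np.asarray(list(self.feature_index), dtype=object),
            params=np.asarray([self.c2, self.max_iterations, self.seed]),
        )

    @classmethod
    def load(cls, path) -> "LinearChainCRF":
        with np.load(path, allow_pickle=True) as blob:
            c2, max_iter, seed = blob["params"]
            model = cls(c2=float(c2), max_iterations=int(max_iter), seed=int(seed))
            model.W = blob["W"]
            model.T = blob["T"]
            model.pi = blob["pi"]
            model.labels = [str(x) for x in blob["labels"]]
            model.feature_index = {
                str(f): i for i, f in enumerate(blob["features"])
            }
        return model
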