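"""Linear-chain conditional random field with string-valued features.

A compact CRF implementation sufficient for clinical sequence labeling:
string features per position (indicator features conjoined with the label),
label-pair transition weights, and start/end weights.  Training maximizes
the L2-penalized conditional log-likelihood with L-BFGS; the forward and
backward passes are vectorized across all sequences (padded to the longest
sequence with a mask), which keeps training fast for corpora of a few
thousand short sentences.

Deterministic: parameters start at zero and L-BFGS is deterministic given
the data, so refitting on the same data reproduces the same model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

__all__ = ["LinearChainCRF"]


class LinearChainCRF:
    """CRF over sequences of feature-string lists.

    Parameters
    ----------
    l2:
        Gaussian prior strength (coefficient of ||w||^2 / 2).
    max_iter:
        L-BFGS iteration cap.
    """

    def __init__(self, l2: float = 0.1, max_iter: int = 200):
        self.l2 = float(l2)
        self.max_iter = int(max_iter)
        self.labels_: list[str] = []
        self.feature_index_: dict[str, int] = {}
        self.W_: np.ndarray | None = None       # (F, L) emission weights
        self.trans_: np.ndarray | None = None   # (L, L)
        self.start_: np.ndarray | None = None   # (L,)
        self.end_: np.ndarray | None = None     # (L,)
        self.n_iter_: int = 0

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[Sequence[Sequence[str]]],
            y: Sequence[Sequence[str]]) -> "LinearChainCRF":
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be non-empty and parallel")
        for feats, labels in zip(X, y):
            if len(feats) != len(labels) or not labels:
                raise ValueError("each sequence needs parallel, non-empty "
                                 "features and labels")
        self.labels_ = sorted({lab for seq in y for lab in seq})
        L = len(self.labels_)
        lab_idx = {lab: i for i, lab in enumerate(self.labels_)}

        findex: dict[str, int] = {}
        rows: list[int] = []
        cols: list[int] = []
        lens = np.array([len(seq) for seq in X], dtype=int)
        S, Tmax, N = len(X), int(lens.max()), int(lens.sum())
        r = 0
        ycode = np.empty(N, dtype=int)
        for feats, labels in zip(X, y):
            for t, (pos_feats, lab) in enumerate(zip(feats, labels)):
                for f in pos_feats:
                    idx = findex.setdefault(f, len(findex))
                    rows.append(r)
                    cols.append(idx)
                ycode[r] = lab_idx[lab]
                r += 1
        self.feature_index_ = findex
        F = len(findex)
        Xm = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(N, F))

        mask = np.zeros((S, Tmax), dtype=bool)
        for s, n in enumerate(lens):
            mask[s, :n] = True
        first_rows = np.concatenate(([0], np.cumsum(lens)[:-1]))
        last_rows = np.cumsum(lens) - 1

        # observed sufficient statistics
        obs_unary = np.zeros((N, L))
        obs_unary[np.arange(N), ycode] = 1.0
        obs_W = np.asarray(Xm.T @ obs_unary)
        obs_trans = np.zeros((L, L))
        for s in range(S):
            a = ycode[first_rows[s]:last_rows[s] + 1]
            np.add.at(obs_trans, (a[:-1], a[1:]), 1.0)
        obs_start = np.bincount(ycode[first_rows], minlength=L).astype(float)
        obs_end = np.bincount(ycode[last_rows], minlength=L).astype(float)

        n_params = F * L + L * L + 2 * L

        def unpack(theta: np.ndarray):
            W = theta[:F * L].reshape(F, L)
            trans = theta[F * L:F * L + L * L].reshape(L, L)
            start = theta[F * L + L * L:F * L + L * L + L]
            end = theta[F * L + L * L + L:]
            return W, trans, start, end

        def objective(theta: np.ndarray):
            W, trans, start, end = unpack(theta)
            E_flat = np.asarray(Xm @ W)                      # (N, L)
            E = np.zeros((S, Tmax, L))
            E[mask] = E_flat

            # forward
            alphas = np.empty((S, Tmax, L))
            alpha = start[None, :] + E[:, 0]
            alphas[:, 0] = alpha
            for t in range(1, Tmax):
                cand = logsumexp(alpha[:, :, None] + trans[None], axis=1)
                cand = cand + E[:, t]
                alpha = np.where(mask[:, t, None], cand, alpha)
                alphas[:, t] = alpha
            logZ = logsumexp(alpha + end[None, :], axis=1)   # (S,)

            # backward
            betas = np.empty((S, Tmax, L))
            beta = np.broadcast_to(end, (S, L)).copy()
            betas[:, Tmax - 1] = beta
            for t in range(Tmax - 2, -1, -1):
                cand = logsumexp(
                    trans[None] + (E[:, t + 1] + beta)[:, None, :], axis=2)
                beta = np.where(mask[:, t + 1, None], cand, beta)
                betas[:, t] = beta

            # marginals
            P = np.exp(alphas + betas - logZ[:, None, None])
            P *= mask[:, :, None]
            P_flat = P[mask]                                 # (N, L)

            if Tmax > 1:
                M = (alphas[:, :-1, :, None] + trans[None, None]
                     + (E[:, 1:] + betas[:, 1:])[:, :, None, :]
                     - logZ[:, None, None, None])
                P2 = np.exp(M) * mask[:, 1:, None, None]
                exp_trans = P2.sum(axis=(0, 1))
            else:
                exp_trans = np.zeros((L, L))

            gold = (E_flat[np.arange(N), ycode].sum()
                    + (obs_trans * trans).sum()
                    + (obs_start * start).sum()
                    + (obs_end * end).sum())
            nll = logZ.sum() - gold + 0.5 * self.l2 * theta @ theta

            g_W = np.asarray(Xm.T @ (P_flat - obs_unary))
            g_trans = exp_trans - obs_trans
            g_start = P[:, 0].sum(axis=0) - obs_start
            g_end = P[np.arange(S), lens - 1].sum(axis=0) - obs_end
            grad = np.concatenate(
                [g_W.ravel(), g_trans.ravel(), g_start, g_end])
            grad += self.l2 * theta
            return nll, grad

        res = scipy.optimize.minimize(
            objective, np.zeros(n_params), jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter})
        W, trans, start, end = unpack(res.x)
        self.W_, self.trans_, self.start_, self.end_ = W, trans, start, end
        self.n_iter_ = int(res.nit)
        return self

    # -- decoding -----------------------------------------------------------

    def _emissions(self, feats: Sequence[Sequence[str]]) -> np.ndarray:
        assert self.W_ is not None, "model not fitted"
        L = len(self.labels_)
        E = np.zeros((len(feats), L))
        for t, pos_feats in enumerate(feats):
            for f in pos_feats:
                idx = self.feature_index_.get(f)
                if idx is not None:
                    E[t] += self.W_[idx]
        return E

    def predict(self, feats: Sequence[Sequence[str]]) -> list[str]:
        """Viterbi decoding of one sequence of per-position feature lists."""
        if not feats:
            return []
        E = self._emissions(feats)
        T, L = E.shape
        delta = self.start_ + E[0]
        back = np.zeros((T, L), dtype=int)
        for t in range(1, T):
            scores = delta[:, None] + self.trans_
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + E[t]
        delta = delta + self.end_
        path = [int(delta.argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels_[i] for i in path]

    def predict_many(self, seqs: Sequence[Sequence[Sequence[str]]],
                     ) -> list[list[str]]:
        return [self.predict(s) for s in seqs]
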