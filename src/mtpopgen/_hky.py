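"""HKY85 substitution model: rate matrix, transition probabilities, kappa estimate.

The rate matrix is normalised so that the expected number of substitutions per
site per unit branch length is 1; branch lengths are therefore in
substitutions-per-site units wherever these matrices are applied.  The model
is reversible, so transition probabilities are computed from the symmetrised
eigendecomposition, which is numerically stable and lets a whole vector of
branch lengths be exponentiated at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HKYModel", "estimate_kappa", "BASES"]

BASES = "ACGT"
_PURINE = np.array([True, False, True, False])  # A, G


@dataclass
class HKYModel:
    freqs: tuple[float, float, float, float]
    kappa: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.min() <= 0 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = f[j]
                if _PURINE[i] == _PURINE[j]:  # transition
                    rate *= self.kappa
                Q[i, j] = rate
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(f * np.diag(Q)).sum()
        Q /= mu  # mean rate 1 per site per unit branch length
        self.Q = Q
        # reversible: D^{1/2} Q D^{-1/2} is symmetric
        sq = np.sqrt(f)
        S = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((S + S.T) / 2.0)
        self._lam = lam
        self._U = V / sq[:, None]  # D^{-1/2} V
        self._Vinv = V.T * sq[None, :]  # V^T D^{1/2}

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(b) for each branch length b (substitutions/site); shape (B, 4, 4)."""
        t = np.atleast_1d(np.asarray(lengths, dtype=float))
        E = np.exp(t[:, None] * self._lam[None, :])  # (B, 4)
        P = np.einsum("ik,bk,kj->bij", self._U, E, self._Vinv)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def stationary(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


def estimate_kappa(P_ts: float, Q_tv: float, freqs) -> float:
    """Moment estimate of the HKY transition/transversion rate ratio.

    From mean observed proportions of transitions (``P_ts``) and transversions
    (``Q_tv``) between sequence pairs, the instantaneous-rate ratio is
    approximately ``(P/Q) * gR*gY / (gA*gG + gC*gT)``, the factor correcting
    for the unequal numbers of transition- and transversion-prone site pairs.
    """
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    if Q_tv <= 0:
        return 20.0  # no transversions observed: fall back to a high ratio
    return max((P_ts / Q_tv) * (gR * gY) / (gA * gG + gC * gT), 1e-3)
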