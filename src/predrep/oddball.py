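"""Analytic model of oddball (two-tone Bernoulli) sequences.

The world emits an i.i.d. sequence of two tones; on each draw the "high"
tone occurs with probability ``p`` fixed within a block, and ``p`` itself is
drawn once per block from a prior (uniform on [0, 1] by default).  Marginal
over ``p``, the last ``N`` tones and the next tone are exchangeably
dependent: the count ``k`` of high tones in the past window is a minimal
sufficient statistic for predicting the next tone.

Under the uniform prior the joint distribution of ``(k, future)`` has the
closed form

    P(k, high) = (k + 1) / ((N + 1)(N + 2))
    P(k, low)  = (N - k + 1) / ((N + 1)(N + 2))

so the marginal of ``k`` is uniform on {0..N} and the posterior predictive
probability of the high tone is the Laplace rule of succession,
``(k + 1) / (N + 2)``.  All information quantities are in bits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "OddballWorld",
    "JointTable",
    "joint_suffstat",
    "posterior_next",
    "sequence_joint",
    "info_quantities",
    "binary_entropy",
]

#: Maximum N for which the full 2^N-past joint may be enumerated.
_SEQUENCE_N_MAX = 20


@dataclass(frozen=True)
class OddballWorld:
    """A two-tone world with memory duration ``n`` and a Beta prior on p.

    Parameters
    ----------
    n : int
        Number of past stimuli retained (the memory duration). Must be >= 1.
    symbols : tuple of str
        Ordered pair of tone labels ``(low, high)``; ``p`` is the
        probability of the *second* (high) symbol.
    prior : tuple of float
        ``(a, b)`` parameters of the Beta prior on p.  The default (1, 1)
        is the uniform prior used throughout; it is exposed as a hook only.
    """

    n: int
    symbols: tuple[str, str] = ("low", "high")
    prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or isinstance(self.n, bool):
            raise ValueError(f"memory duration must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ValueError(f"memory duration must be >= 1, got {self.n}")
        if len(self.symbols) != 2 or self.symbols[0] == self.symbols[1]:
            raise ValueError("exactly two distinct symbols are required")
        a, b = self.prior
        if a <= 0 or b <= 0:
            raise ValueError("Beta prior parameters must be positive")

    @property
    def is_uniform_prior(self) -> bool:
        return self.prior == (1.0, 1.0)


@dataclass(frozen=True)
class JointTable:
    """Joint distribution of (k, future) on the sufficient-statistic alphabet.

    ``p_joint[k, j]`` is the probability that the past window holds ``k``
    high tones and the next tone is ``symbols[j]`` (j=0 low, j=1 high).
    """

    n: int
    p_joint: np.ndarray
    symbols: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        pj = np.asarray(self.p_joint, dtype=float)
        if pj.shape != (self.n + 1, 2):
            raise ValueError(f"p_joint must have shape {(self.n + 1, 2)}")
        if (pj < 0).any():
            raise ValueError("joint probabilities must be nonnegative")
        if abs(pj.sum() - 1.0) > 1e-12:
            raise ValueError("joint table must sum to 1 within 1e-12")
        object.__setattr__(self, "p_joint", pj)

    @property
    def p_k(self) -> np.ndarray:
        """Marginal distribution of the past count k."""
        return self.p_joint.sum(axis=1)

    @property
    def p_future_given_k(self) -> np.ndarray:
        """Rows P(future | k), shape (n+1, 2)."""
        return self.p_joint / self.p_k[:, None]

    @property
    def p_future(self) -> np.ndarray:
        return self.p_joint.sum(axis=0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "symbols": list(self.symbols),
                "p_joint": self.p_joint.ravel().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "JointTable":
        d = json.loads(text)
        pj = np.asarray(d["p_joint"], dtype=float).reshape(d["n"] + 1, 2)
        return cls(n=d["n"], p_joint=pj, symbols=tuple(d["symbols"]))


def joint_suffstat(world: OddballWorld) -> JointTable:
    """Joint distribution of (past count k, next tone).

    For the uniform prior the closed form is used; for a general Beta(a, b)
    prior the Beta-binomial integral is evaluated in log space.
    """
    n = world.n
    k = np.arange(n + 1)
    if world.is_uniform_prior:
        high = (k + 1.0) / ((n + 1.0) * (n + 2.0))
        low = (n - k + 1.0) / ((n + 1.0) * (n + 2.0))
    else:
        a, b = world.prior
        # P(k, high) = C(n,k) B(k+a+1, n-k+b) / B(a, b), and symmetrically.
        logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        high = np.exp(logc + betaln(k + a + 1, n - k + b) - betaln(a, b))
        low = np.exp(logc + betaln(k + a, n - k + b + 1) - betaln(a, b))
        s = high.sum() + low.sum()
        high, low = high / s, low / s
    return JointTable(n=n, p_joint=np.stack([low, high], axis=1),
                      symbols=world.symbols)


def posterior_next(k: int, world: OddballWorld) -> float:
    """Predictive probability of the high tone after observing k highs.

    Equals ``(k + a) / (N + a + b)`` for a Beta(a, b) prior; the uniform
    prior gives the Laplace rule ``(k + 1) / (N + 2)``.
    """
    if not 0 <= k <= world.n:
        raise ValueError(f"k must be in [0, {world.n}], got {k}")
    a, b = world.prior
    return (k + a) / (world.n + a + b)


@dataclass(frozen=True)
class SequenceJoint:
    """Joint over full binary pasts of length n and the next tone.

    Enumeration oracle for small n only: ``pasts[i]`` is the i-th binary
    past (tuple of 0/1, 1 = high) and ``p_joint[i, j]`` its joint
    probability with future symbol j.
    """

    n: int
    pasts: list[tuple[int, ...]] = field(repr=False)
    p_joint: np.ndarray = field(repr=False)

    @property
    def p_past(self) -> np.ndarray:
        return self.p_joint.sum(axis=1)

    def entropy_past(self) -> float:
        """Shannon entropy of the full-past marginal, in bits."""
        p = self.p_past
        return float(-(p * np.log2(p)).sum())

    def mutual_information(self) -> float:
        """I(past; future) in bits."""
        p = self.p_joint
        px = self.p_past
        py = p.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p / np.outer(px, py)), 0.0)
        return float(t.sum())

    def marginalize_to_counts(self) -> np.ndarray:
        """Sum orderings with equal k; reproduces :func:`joint_suffstat`."""
        out = np.zeros((self.n + 1, 2))
        for past, row in zip(self.pasts, self.p_joint):
            out[sum(past)] += row
        return out


def sequence_joint(world: OddballWorld) -> SequenceJoint:
    """Enumerate the joint over all 2^N past sequences and the next tone.

    Exact but exponential in N; refuses N > 20.  By exchangeability every
    ordering with k high tones has probability ``P(k, future) / C(N, k)``.
    """
    n = world.n
    if n > _SEQUENCE_N_MAX:
        raise ValueError(
            f"full-sequence enumeration needs 2^N states; N={n} exceeds the "
            f"supported maximum {_SEQUENCE_N_MAX}"
        )
    table = joint_suffstat(world)
    pasts = []
    rows = np.empty((2 ** n, 2))
    for i in range(2 ** n):
        past = tuple((i >> j) & 1 for j in range(n))
        k = sum(past)
        pasts.append(past)
        rows[i] = table.p_joint[k] / math.comb(n, k)
    return SequenceJoint(n=n, pasts=pasts, p_joint=rows)


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Entropy of a Bernoulli(p) variable in bits, with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0) - np.where(q > 0, q * np.log2(q), 0.0)
    return h if h.ndim else float(h)


def info_quantities(joint: JointTable) -> dict[str, float]:
    """Entropies and mutual information of a (k, future) joint, in bits.

    Returns ``H_past_summary`` = H(k), ``H_future``, and ``I_k_future`` =
    H(future) − Σ_k p(k) H_b(P(high|k)).
    """
    p_k = joint.p_k
    with np.errstate(divide="ignore", invalid="ignore"):
        h_k = float(-np.where(p_k > 0, p_k * np.log2(p_k), 0.0).sum())
    h_future = float(binary_entropy(joint.p_future[1]))
    cond = float((p_k * binary_entropy(joint.p_future_given_k[:, 1])).sum())
    return {
        "H_past_summary": h_k,
        "H_future": h_future,
        "I_k_future": h_future - cond,
    }
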