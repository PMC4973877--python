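"""Per-trial prediction errors under a reduced representation.

A trial's prediction error is the surprise −log2 P(tone | m) of the tone
that actually occurred, where m is the (latent, possibly probabilistic)
state of the reduced representation given the preceding N tones.  Because
the state is latent, each trial carries a *set* of errors — one per state —
with weights P(m | k); the expected error is their weighted mean.

Averaged over the stationary joint of (past, future), the expected error
equals H(future) − I(m; future), the information-theoretic complement of
the representation's predictive power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from predrep.ib import ReducedRepresentation

__all__ = [
    "PETrace",
    "per_state_errors",
    "expected_error",
    "trace_sequence",
    "trace_trials",
    "tone_codes",
]

_WEIGHT_FLOOR = 1e-12


def tone_codes(tones, symbols: tuple[str, str] = ("low", "high")) -> np.ndarray:
    """Map tone labels to 0/1 codes (0 = low, 1 = high)."""
    arr = np.asarray(tones)
    if arr.dtype.kind in "iub":
        codes = arr.astype(int)
        if ((codes != 0) & (codes != 1)).any():
            raise ValueError("numeric tones must be 0 or 1")
        return codes
    codes = np.where(arr == symbols[1], 1, np.where(arr == symbols[0], 0, -1))
    if (codes < 0).any():
        bad = sorted(set(arr[codes < 0]))
        raise ValueError(f"unknown tone labels {bad}; expected {symbols}")
    return codes


@dataclass(frozen=True)
class PETrace:
    """Prediction errors for the retained trials of one or more blocks.

    Attributes
    ----------
    trial_index : ndarray of int
        Original within-block index of each retained trial.
    block_id : ndarray
        Block of each retained trial.
    tone : ndarray of int
        0 = low tone, 1 = high tone.
    k : ndarray of int
        Count of high tones among the N preceding within-block stimuli.
    weights : ndarray, shape (n_trials, n_states)
        P(m | k) per trial.
    errors : ndarray, shape (n_trials, n_states)
        −log2 P(tone | m) per trial and state.
    expected_error : ndarray, shape (n_trials,)
        Weight-averaged prediction error, in bits.
    """

    n: int
    trial_index: np.ndarray = field(repr=False)
    block_id: np.ndarray = field(repr=False)
    tone: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    errors: np.ndarray = field(repr=False)

    @property
    def expected_error(self) -> np.ndarray:
        return (self.weights * self.errors).sum(axis=1)

    def __len__(self) -> int:
        return len(self.tone)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_id": self.block_id,
                "trial_index": self.trial_index,
                "tone": self.tone,
                "k": self.k,
                "expected_error": self.expected_error,
                "n_states": (self.weights > _WEIGHT_FLOOR).sum(axis=1),
            }
        )


def per_state_errors(
    rep: ReducedRepresentation, k: int, tone: int | str
) -> list[tuple[int, float, float]]:
    """Prediction errors of one trial, one entry per latent state.

    Returns ``(state, weight, error_bits)`` triples with
    ``weight = P(m|k)`` and ``error = −log2 P(tone|m)``; states with
    negligible weight (< 1e-12) are dropped.
    """
    if not 0 <= k <= rep.n:
        raise ValueError(f"k must be in [0, {rep.n}], got {k}")
    code = int(tone_codes([tone])[0]) if isinstance(tone, str) else int(tone)
    if code not in (0, 1):
        raise ValueError(f"tone must be 0/1 or a symbol label, got {tone!r}")
    w = rep.encoder[k]
    err = rep.expected_errors()[:, code]
    keep = w > _WEIGHT_FLOOR
    if not np.isclose(w[keep].sum(), 1.0, atol=1e-9):
        raise AssertionError("dropped states carried non-negligible weight")
    return [(int(m), float(w[m]), float(err[m])) for m in np.nonzero(keep)[0]]


def expected_error(rep: ReducedRepresentation, k: int, tone: int | str) -> float:
    """Weight-averaged prediction error of one trial, in bits."""
    entries = per_state_errors(rep, k, tone)
    return float(sum(w * e for _, w, e in entries))


def _past_counts(codes: np.ndarray, n: int) -> np.ndarray:
    """k[t] = number of high tones among the n stimuli preceding t."""
    cum = np.concatenate([[0], np.cumsum(codes)])
    k = np.full(len(codes), -1, dtype=int)
    idx = np.arange(n, len(codes))
    k[idx] = cum[idx] - cum[idx - n]
    return k


def trace_sequence(
    rep: ReducedRepresentation,
    sequence,
    burn_in: int = 50,
    block_id=0,
) -> PETrace:
    """Prediction-error trace of one block's tone sequence.

    The first ``burn_in`` trials are dropped so every retained trial has a
    fully defined past of N stimuli; ``burn_in`` must therefore be at least
    ``rep.n``.
    """
    if burn_in < rep.n:
        raise ValueError(
            f"burn_in ({burn_in}) must be >= memory duration ({rep.n}): "
            "earlier trials have an ill-defined past"
        )
    codes = tone_codes(sequence)
    if len(codes) <= burn_in:
        raise ValueError("sequence must be longer than burn_in")
    k_all = _past_counts(codes, rep.n)
    idx = np.arange(burn_in, len(codes))
    k = k_all[idx]
    tones = codes[idx]
    weights = rep.encoder[k]
    errors = rep.expected_errors()[:, tones].T
    return PETrace(
        n=rep.n,
        trial_index=idx,
        block_id=np.full(len(idx), block_id),
        tone=tones,
        k=k,
        weights=weights,
        errors=errors,
    )


def trace_trials(
    rep: ReducedRepresentation,
    trials: pd.DataFrame,
    burn_in: int = 50,
) -> PETrace:
    """Prediction-error trace over a multi-block trial table.

    ``trials`` needs columns ``block_id``, ``trial_index`` and ``tone``;
    each block is traced independently (the representation state never
    crosses block boundaries) and the traces concatenated in block order.
    """
    parts = []
    for block, grp in trials.groupby("block_id", sort=True):
        grp = grp.sort_values("trial_index")
        if not (np.diff(grp["trial_index"].to_numpy()) == 1).all():
            raise ValueError(f"block {block!r} has gaps in trial_index")
        parts.append(trace_sequence(rep, grp["tone"].to_numpy(), burn_in,
                                    block_id=block))
    return PETrace(
        n=rep.n,
        trial_index=np.concatenate([p.trial_index for p in parts]),
        block_id=np.concatenate([p.block_id for p in parts]),
        tone=np.concatenate([p.tone for p in parts]),
        k=np.concatenate([p.k for p in parts]),
        weights=np.concatenate([p.weights for p in parts]),
        errors=np.concatenate([p.errors for p in parts]),
    )
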