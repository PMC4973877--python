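"""Information Bottleneck solver for the oddball prediction problem.

Given the joint distribution of the past-count ``k`` and the next tone, the
IB principle defines a one-parameter family of optimal reduced
representations ``m`` of the past, each trading *complexity* I(k; m)
against *predictive power* I(m; future).  A representation is the triple
(encoder P(m|k), marginal P(m), decoder P(future|m)) satisfying the
self-consistent equations

    P(m|k) ∝ P(m) exp(−β KL[P(future|k) ‖ P(future|m)])
    P(m)    = Σ_k P(k) P(m|k)
    P(future|m) = Σ_k P(future|k) P(k|m)

with Lagrange multiplier β ≥ 0 controlling the tradeoff.

The solver runs on the sufficient-statistic alphabet {0..N} rather than on
the 2^N raw pasts: any encoder over full pasts that depends only on the
count has the same complexity measured against either alphabet, and
optimal solutions factor through the sufficient statistic, so the curves
are exact while N = 50 stays tractable.

The β-sweep uses *reverse deterministic annealing*: it starts at a large β
from the exactly known maximum-complexity solution (the identity encoder on
the count alphabet) and descends.  Along the descending path clusters merge
continuously, so the sweep never relies on cluster splits — the fragile
step of ascending annealing.  A fixed deterministic perturbation is applied
between steps to dislodge marginally stable iterates; there is no random
number use anywhere in the solver, so a sweep is reproducible bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from predrep.oddball import JointTable, OddballWorld, joint_suffstat

__all__ = [
    "ReducedRepresentation",
    "TradeoffCurve",
    "RepresentationBank",
    "ib_fixed_point",
    "sweep_beta",
    "curve_at_complexity",
    "effective_states",
    "sufficient_statistic_representation",
    "full_past_representation",
    "build_bank",
]

_TINY = 1e-300


@dataclass(frozen=True)
class ReducedRepresentation:
    """One solution of the complexity / predictive-power tradeoff.

    Attributes
    ----------
    n : int
        Memory duration of the underlying world.
    beta : float
        Tradeoff multiplier at which this solution was obtained
        (``inf`` for analytically constructed deterministic encoders).
    encoder : ndarray, shape (n_inputs, n_states)
        Rows P(m | k).
    decoder : ndarray, shape (n_states, 2)
        Rows P(future | m), columns ordered (low, high).
    marginal : ndarray, shape (n_states,)
        P(m).
    complexity, predictive_power : float
        I(k; m) and I(m; future), in bits.
    converged : bool
        False if the fixed-point iteration stopped at ``max_iter``.
    residual : float
        Last per-row total-variation change of the encoder.
    """

    n: int
    beta: float
    encoder: np.ndarray = field(repr=False)
    decoder: np.ndarray = field(repr=False)
    marginal: np.ndarray = field(repr=False)
    complexity: float
    predictive_power: float
    converged: bool = True
    residual: float = 0.0
    n_iter: int = 0

    @property
    def n_states(self) -> int:
        return self.encoder.shape[1]

    def expected_errors(self) -> np.ndarray:
        """−log2 P(future|m) for every (state, tone), shape (n_states, 2)."""
        return -np.log2(np.clip(self.decoder, _TINY, None))


def _information(px: np.ndarray, enc: np.ndarray, py_x: np.ndarray):
    """Complexity and predictive power of an encoder, plus (pm, dec)."""
    pm = px @ enc
    safe_pm = np.clip(pm, _TINY, None)
    dec = (enc * px[:, None]).T @ py_x / safe_pm[:, None]
    # states with vanishing mass get the stationary future marginal
    py = px @ py_x
    dec = np.where(pm[:, None] > 1e-250, dec, py[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(enc > 0, enc * np.log2(enc / safe_pm[None, :]), 0.0)
        complexity = float((px[:, None] * r).sum())
        r2 = np.where(dec > 0, dec * np.log2(dec / py[None, :]), 0.0)
        power = float((pm[:, None] * r2).sum())
    return max(complexity, 0.0), max(power, 0.0), pm, dec


def ib_fixed_point(
    joint: JointTable,
    beta: float,
    n_states: int | None = None,
    init: np.ndarray | str = "uniform",
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> ReducedRepresentation:
    """Iterate the three self-consistent IB equations to a fixed point.

    Parameters
    ----------
    joint : JointTable
        Joint distribution of (k, future) on the count alphabet.
    beta : float
        Tradeoff multiplier, >= 0.
    n_states : int, optional
        Cardinality of m; defaults to the input alphabet size (exceeding it
        cannot help for this problem).
    init : ndarray or {"uniform", "identity"}
        Initial encoder, rows P(m|k).  Must be row-stochastic.
    tol : float
        Convergence threshold on the per-row total-variation change of the
        encoder between successive iterates.
    max_iter : int
        Iteration cap; hitting it yields a *flagged* (``converged=False``)
        result carrying the last iterate and residual, never an exception.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    n_in = joint.n + 1
    if n_states is None:
        n_states = n_in
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    px = joint.p_k
    py_x = joint.p_future_given_k

    if isinstance(init, str):
        if init == "uniform":
            # the exactly uniform encoder is an (unstable) symmetric fixed
            # point; perturb deterministically so iteration can leave it
            enc = _perturb(np.full((n_in, n_states), 1.0 / n_states))
        elif init == "identity":
            enc = np.eye(n_in, n_states)
            enc[:, -1] += 1.0 - enc.sum(axis=1)  # fold overflow rows
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        enc = np.array(init, dtype=float)
        if enc.shape != (n_in, n_states):
            raise ValueError(
                f"init must have shape {(n_in, n_states)}, got {enc.shape}"
            )
        if (enc < 0).any() or np.abs(enc.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("init must be a row-stochastic matrix")
        enc = enc / enc.sum(axis=1, keepdims=True)

    log_py_x = np.log(np.clip(py_x, _TINY, None))
    neg_h_x = (py_x * log_py_x).sum(axis=1)  # −H[P(y|x)] in nats
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        pm = px @ enc
        safe_pm = np.clip(pm, _TINY, None)
        dec = (enc * px[:, None]).T @ py_x / safe_pm[:, None]
        dec = np.clip(dec, _TINY, None)
        kl = neg_h_x[:, None] - py_x @ np.log(dec).T
        logits = np.log(safe_pm)[None, :] - beta * kl
        logits -= logits.max(axis=1, keepdims=True)
        new = np.exp(logits)
        new /= new.sum(axis=1, keepdims=True)
        residual = 0.5 * np.abs(new - enc).sum(axis=1).max()
        enc = new
        if residual < tol:
            break
    complexity, power, pm, dec = _information(px, enc, py_x)
    return ReducedRepresentation(
        n=joint.n,
        beta=float(beta),
        encoder=enc,
        decoder=dec,
        marginal=pm,
        complexity=complexity,
        predictive_power=power,
        converged=bool(residual < tol),
        residual=float(residual),
        n_iter=it,
    )


def sufficient_statistic_representation(
    world_or_joint: OddballWorld | JointTable,
) -> ReducedRepresentation:
    """The deterministic count encoder: m = k, decoder = Laplace posterior."""
    joint = (
        world_or_joint
        if isinstance(world_or_joint, JointTable)
        else joint_suffstat(world_or_joint)
    )
    n_in = joint.n + 1
    enc = np.eye(n_in)
    complexity, power, pm, dec = _information(joint.p_k, enc, joint.p_future_given_k)
    return ReducedRepresentation(
        n=joint.n, beta=math.inf, encoder=enc, decoder=dec, marginal=pm,
        complexity=complexity, predictive_power=power,
    )


def full_past_representation(world: OddballWorld) -> ReducedRepresentation:
    """Identity encoder over all 2^N past sequences (small-N oracle).

    Complexity equals H(past); predictive power equals I(past; future) =
    I(k; future) by sufficiency of the count.
    """
    from predrep.oddball import sequence_joint

    seq = sequence_joint(world)
    n_in = len(seq.pasts)
    enc = np.eye(n_in)
    px = seq.p_past
    py_x = seq.p_joint / px[:, None]
    complexity, power, pm, dec = _information(px, enc, py_x)
    return ReducedRepresentation(
        n=world.n, beta=math.inf, encoder=enc, decoder=dec, marginal=pm,
        complexity=complexity, predictive_power=power,
    )


def effective_states(
    rep: ReducedRepresentation,
    mass_threshold: float = 1e-3,
    merge_tol: float = 1e-6,
) -> int:
    """Count the distinct states a representation actually uses.

    Numerically the solver may carry *duplicate* clusters — states with the
    same decoder whose encoder columns are proportional, i.e. the same
    cluster split across two labels.  Those are merged (their marginal mass
    pooled) before counting states with mass above ``mass_threshold``.
    States with equal decoders but genuinely different encoder usage (e.g.
    two past sequences with the same count in the full-past identity
    encoder) are *not* duplicates and are counted separately.
    """
    pm = rep.marginal
    dec = rep.decoder
    # posterior P(k|m) distinguishes genuinely different states that happen
    # to share a decoder
    post = rep.encoder / np.clip(rep.encoder.sum(axis=0), _TINY, None)[None, :]
    n_states = rep.n_states
    labels = -np.ones(n_states, dtype=int)
    groups = 0
    for m in range(n_states):
        if labels[m] >= 0:
            continue
        labels[m] = groups
        for m2 in range(m + 1, n_states):
            if labels[m2] >= 0:
                continue
            if (
                0.5 * np.abs(dec[m] - dec[m2]).sum() < merge_tol
                and 0.5 * np.abs(post[:, m] - post[:, m2]).sum() < merge_tol
            ):
                labels[m2] = groups
        groups += 1
    mass = np.zeros(groups)
    np.add.at(mass, labels, pm)
    return int((mass > mass_threshold).sum())


@dataclass(frozen=True)
class TradeoffCurve:
    """The per-N family of optimal representations, sorted by complexity."""

    n: int
    points: list[ReducedRepresentation]

    @property
    def complexities(self) -> np.ndarray:
        return np.array([p.complexity for p in self.points])

    @property
    def powers(self) -> np.ndarray:
        return np.array([p.predictive_power for p in self.points])

    def at_complexity(self, bits: float) -> ReducedRepresentation:
        return curve_at_complexity(self, bits)

    def power_at(self, bits: float) -> float:
        """Predictive power at a complexity, linearly interpolated."""
        c = self.complexities
        if not (min(0.0, c.min()) - 1e-9 <= bits <= c.max() + 1e-9):
            raise ValueError(
                f"complexity {bits} outside curve range [0, {c.max():.4f}]"
            )
        order = np.argsort(c)
        return float(np.interp(bits, c[order], self.powers[order]))


def curve_at_complexity(curve: TradeoffCurve, bits: float) -> ReducedRepresentation:
    """Representation at the requested complexity (nearest curve point)."""
    c = curve.complexities
    if not (-1e-9 <= bits <= c.max() + 1e-9):
        raise ValueError(
            f"complexity {bits} outside allowed interval [0, {c.max():.4f}]"
        )
    return curve.points[int(np.argmin(np.abs(c - bits)))]


def _perturb(enc: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Fixed deterministic multiplicative perturbation of an encoder."""
    x = np.arange(enc.shape[0], dtype=float)[:, None]
    m = np.arange(enc.shape[1], dtype=float)[None, :]
    out = enc * (1.0 + eps * np.sin((x + 1.0) * (m + 1.0)))
    return out / out.sum(axis=1, keepdims=True)


def _calibrate_beta_max(joint: JointTable, tol: float, max_iter: int) -> float:
    """Smallest power-of-4 β whose solution reaches 99.9% of max complexity."""
    target = 0.999 * math.log2(joint.n + 1)
    beta = 64.0 * (joint.n + 2)
    for _ in range(12):
        rep = ib_fixed_point(joint, beta, init="identity", tol=tol,
                             max_iter=max_iter)
        if rep.complexity >= target:
            return beta
        beta *= 4.0
    return beta


def sweep_beta(
    joint: JointTable,
    n_points: int = 200,
    tol: float = 1e-10,
    max_iter: int = 4000,
    gap_target: float = 0.1,
    max_refine: int = 200,
) -> TradeoffCurve:
    """Trace the optimal tradeoff curve with a reverse-annealed β sweep.

    β descends on a log grid from an auto-calibrated maximum (where the
    solution attains > 99.9% of the maximal complexity log2(N+1)) down to 1
    (where the encoder collapses to a single state).  Each β is warm-started
    from the previous solution after a small deterministic perturbation.
    Complexity gaps larger than ``gap_target`` bits are closed by bisecting
    β; finally exactly ``n_points`` representations are selected, closest
    to uniformly spaced complexity targets over [0, log2(N+1)].
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    beta_max = _calibrate_beta_max(joint, tol, max_iter)
    n_grid = max(n_points, 64)
    betas = np.logspace(math.log10(beta_max), 0.0, n_grid)

    path: list[ReducedRepresentation] = []
    enc = np.eye(joint.n + 1)
    for b in betas:
        enc = _perturb(enc)
        rep = ib_fixed_point(joint, b, init=enc, tol=tol, max_iter=max_iter)
        path.append(rep)
        enc = rep.encoder

    # ascending complexity
    sols = sorted(path, key=lambda r: r.complexity)

    # close complexity gaps by bisecting in beta (warm start from the
    # more complex side, descending as in the main sweep)
    refinements = 0
    i = 0
    while i < len(sols) - 1 and refinements < max_refine:
        lo, hi = sols[i], sols[i + 1]
        if hi.complexity - lo.complexity > gap_target and hi.beta != lo.beta:
            b_mid = math.sqrt(lo.beta * hi.beta)
            rep = ib_fixed_point(
                joint, b_mid, init=_perturb(hi.encoder), tol=tol,
                max_iter=max_iter,
            )
            refinements += 1
            if lo.complexity < rep.complexity < hi.complexity:
                sols.insert(i + 1, rep)
                continue  # re-examine the same (possibly still wide) gap
        i += 1

    comp = np.array([s.complexity for s in sols])
    targets = np.linspace(0.0, math.log2(joint.n + 1), n_points)
    chosen = [sols[int(np.argmin(np.abs(comp - t)))] for t in targets]
    return TradeoffCurve(n=joint.n, points=chosen)


@dataclass
class RepresentationBank:
    """Tradeoff curves for N = 1..n_max, n_beta points each."""

    curves: dict[int, TradeoffCurve]

    @property
    def n_values(self) -> list[int]:
        return sorted(self.curves)

    @property
    def size(self) -> int:
        return sum(len(c.points) for c in self.curves.values())

    def members(self):
        """Iterate (n, index-along-curve, representation)."""
        for n in self.n_values:
            for j, rep in enumerate(self.curves[n].points):
                yield n, j, rep

    def save(self, path: str) -> None:
        payload = {
            "format": "predrep-bank-v1",
            "curves": {
                str(n): [
                    {
                        "beta": rep.beta if math.isfinite(rep.beta) else None,
                        "encoder": rep.encoder.tolist(),
                        "decoder": rep.decoder.tolist(),
                        "marginal": rep.marginal.tolist(),
                        "complexity": rep.complexity,
                        "predictive_power": rep.predictive_power,
                        "converged": bool(rep.converged),
                    }
                    for rep in curve.points
                ]
                for n, curve in self.curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "RepresentationBank":
        with open(path) as fh:
            payload = json.load(fh)
        curves = {}
        for n_str, pts in payload["curves"].items():
            n = int(n_str)
            points = [
                ReducedRepresentation(
                    n=n,
                    beta=math.inf if d["beta"] is None else d["beta"],
                    encoder=np.asarray(d["encoder"]),
                    decoder=np.asarray(d["decoder"]),
                    marginal=np.asarray(d["marginal"]),
                    complexity=d["complexity"],
                    predictive_power=d["predictive_power"],
                    converged=d["converged"],
                )
                for d in pts
            ]
            curves[n] = TradeoffCurve(n=n, points=points)
        return cls(curves=curves)


def build_bank(
    n_max: int = 50,
    n_beta: int = 200,
    tol: float = 1e-10,
    max_iter: int = 4000,
    prior: tuple[float, float] = (1.0, 1.0),
    progress: bool = False,
) -> RepresentationBank:
    """Build the full representation bank over N = 1..n_max."""
    curves = {}
    for n in range(1, n_max + 1):
        joint = joint_suffstat(OddballWorld(n=n, prior=prior))
        curves[n] = sweep_beta(joint, n_points=n_beta, tol=tol,
                               max_iter=max_iter)
        if progress:
            print(f"bank: N={n} done ({len(curves[n].points)} points)")
    return RepresentationBank(curves=curves)
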