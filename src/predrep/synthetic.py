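"""Synthetic oddball experiments with surprise-modulated spike counts.

The generator emulates the structure of an oddball electrophysiology
session: blocks of 400 pure-tone trials at probability conditions
10/30/50/70/90%, two frequencies per neuron, and spike counts whose mean is
affine in the prediction error of the tone that occurred,

    count ~ noise(a * error + b)

with Poisson or Gaussian noise.  The latent state m of the generating
representation is *sampled* per trial from P(m|k) (not averaged), so the
latent-state weighting of the analysis stage is genuinely exercised.

Block sequences default to fixed-count random permutations (exactly
round(p·400) high tones, as in the experimental design); the analytic
world assumes i.i.d. Bernoulli draws.  That mild model/experiment mismatch
is intentional and preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from predrep.ib import RepresentationBank, ReducedRepresentation

__all__ = [
    "BlockSpec",
    "SyntheticNeuron",
    "SyntheticExperiment",
    "generate_block",
    "generate_counts",
    "experiment_suite",
    "MAIN_CONDITIONS",
    "ALL_CONDITIONS",
]

#: probability of the high tone per block in the main (3-block) design
MAIN_CONDITIONS = (0.1, 0.5, 0.9)
ALL_CONDITIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class BlockSpec:
    """One stimulation block: ``p_high`` is the high-tone probability."""

    p_high: float
    n_stimuli: int = 400
    mode: str = "fixed_count_permutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_high < 1.0:
            raise ValueError("p_high must be strictly between 0 and 1")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.mode not in ("bernoulli", "fixed_count_permutation"):
            raise ValueError(f"unknown mode {self.mode!r}")


def generate_block(spec: BlockSpec) -> np.ndarray:
    """Tone sequence of one block as 0/1 codes (1 = high tone).

    ``bernoulli`` draws i.i.d.; ``fixed_count_permutation`` places exactly
    round(p_high * n) high tones in random order.  Reproducible from the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "bernoulli":
        return (rng.random(spec.n_stimuli) < spec.p_high).astype(int)
    n_high = int(round(spec.p_high * spec.n_stimuli))
    seq = np.zeros(spec.n_stimuli, dtype=int)
    seq[:n_high] = 1
    return rng.permutation(seq)


@dataclass(frozen=True)
class SyntheticNeuron:
    """Ground-truth response model: count ~ noise(a * error + b).

    ``rep`` is the generating reduced representation (a bank member at the
    neuron's true memory duration and complexity).
    """

    a: float  # slope, spikes per bit
    b: float  # baseline, spikes
    rep: ReducedRepresentation = field(repr=False)
    noise: str = "gaussian"
    sigma: float = 1.0
    neuron_id: str = "syn0"

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def generate_counts(
    sequences: dict,
    neuron: SyntheticNeuron,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table for one neuron over a set of blocks.

    ``sequences`` maps block_id -> (p_high, codes array).  Per trial the
    latent state is sampled from P(m|k); the count mean is
    ``a * (−log2 P(tone|m)) + b``, clipped at zero (clip events are counted
    in the frame's ``attrs['clip_rate']``).  Trials whose past window is
    incomplete (index < N) draw the state from the marginal P(m); they are
    discarded by every analysis stage via the burn-in anyway.
    """
    rng = np.random.default_rng(seed)
    rep = neuron.rep
    err = rep.expected_errors()
    rows = []
    n_clipped = 0
    n_total = 0
    for block_id in sorted(sequences):
        p_high, codes = sequences[block_id]
        codes = np.asarray(codes, dtype=int)
        cum = np.concatenate([[0], np.cumsum(codes)])
        for t, tone in enumerate(codes):
            if t >= rep.n:
                k = int(cum[t] - cum[t - rep.n])
                m = rng.choice(rep.n_states, p=rep.encoder[k])
            else:
                m = rng.choice(rep.n_states, p=rep.marginal)
            mu = neuron.a * err[m, tone] + neuron.b
            if mu < 0:
                n_clipped += 1
                mu = 0.0
            n_total += 1
            if neuron.noise == "poisson":
                count = float(rng.poisson(mu))
            else:
                count = max(0.0, mu + neuron.sigma * rng.standard_normal())
            rows.append((neuron.neuron_id, block_id, p_high, t,
                         "high" if tone else "low", count))
    df = pd.DataFrame(
        rows,
        columns=["neuron_id", "block_id", "condition", "trial_index",
                 "tone", "spike_count"],
    )
    df.attrs["clip_rate"] = n_clipped / n_total
    return df


@dataclass(frozen=True)
class SyntheticExperiment:
    """One simulated neuron: trial table plus serialized ground truth."""

    trials: pd.DataFrame = field(repr=False)
    ground_truth: dict = field(repr=False)

    def save(self, trials_path, truth_path) -> None:
        from predrep.fitting import write_trials

        df = self.trials.copy()
        if "freq_label" not in df.columns:
            df = pd.concat(
                [df.assign(freq_label=f) for f in ("low", "high")],
                ignore_index=True,
            )
        write_trials(df, trials_path,
                     header_comments=[f"ground_truth: {truth_path}"])
        with open(truth_path, "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)


def experiment_suite(
    bank: RepresentationBank,
    design: str = "main",
    n_neurons: int = 1,
    seed: int = 0,
    a: float = 2.0,
    b: float = 3.0,
    noise: str = "gaussian",
    sigma: float = 1.0,
    n_star: int = 10,
    complexity_star: float = 2.0,
    n_stimuli: int = 400,
    mode: str = "fixed_count_permutation",
) -> list[SyntheticExperiment]:
    """Simulate a population of neurons under the standard block layout.

    ``main`` uses the 3-block design (10/50/90% high-tone probability);
    ``all_conditions`` adds the 30% and 70% blocks.  The generating
    representation is the bank member for memory duration ``n_star``
    nearest to ``complexity_star`` bits.  All randomness derives from
    ``seed`` (one substream per neuron and block).
    """
    if design == "main":
        conditions = MAIN_CONDITIONS
    elif design == "all_conditions":
        conditions = ALL_CONDITIONS
    else:
        raise ValueError(f"unknown design {design!r}")
    rep = bank.curves[n_star].at_complexity(complexity_star)
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_neurons)):
        block_seed, count_seed = child.generate_state(2) >> np.uint32(1)
        sequences = {}
        for j, p in enumerate(conditions):
            spec = BlockSpec(p_high=p, n_stimuli=n_stimuli, mode=mode,
                             seed=int(block_seed) + j)
            sequences[j] = (p, generate_block(spec))
        neuron = SyntheticNeuron(a=a, b=b, rep=rep, noise=noise, sigma=sigma,
                                 neuron_id=f"syn{i}")
        trials = generate_counts(sequences, neuron, seed=int(count_seed))
        truth = {
            "neuron_id": neuron.neuron_id,
            "a": a, "b": b, "noise": noise, "sigma": sigma,
            "n_star": n_star,
            "complexity_star": float(rep.complexity),
            "predictive_power_star": float(rep.predictive_power),
            "design": design,
            "conditions": list(conditions),
            "mode": mode,
            "seed": seed,
            "clip_rate": trials.attrs["clip_rate"],
        }
        out.append(SyntheticExperiment(trials=trials, ground_truth=truth))
    return out
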