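"""Regression of spike counts on prediction errors across a bank.

For one neuron and one test frequency, each retained trial whose tone
equals the test frequency contributes, for every latent state m, the pair
(−log2 P(tone|m), spike count) with weight P(m|k).  Weighted least squares
on this expanded set gives a weighted r² per representation; the maximum
over the bank (rmax²) summarizes how well prediction error explains the
responses, and representations within 90% of rmax² form the neuron's
*good set*.

Significance of rmax² cannot be judged against standard tables because it
is a maximum over thousands of correlated fits; it is instead compared
against rmax² recomputed on sequences randomly permuted within block,
which preserve the tone probabilities but break the short-term
sequence/response relationship.

Because all fitted trials share one tone, the expanded-set sums collapse
onto the histogram of past counts: with ``n_k`` trials and count sum
``s_k`` at past-count k, the weighted sums are contractions of (n_k, s_k)
with the encoder — the grid over 10,000 representations costs seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from predrep.ib import RepresentationBank, ReducedRepresentation
from predrep.prediction import PETrace, tone_codes

__all__ = [
    "FitResult",
    "GridResult",
    "PermutationResult",
    "PopulationMaps",
    "weighted_regression",
    "grid_search",
    "permutation_test",
    "response_significance",
    "population_maps",
    "read_trials",
    "write_trials",
    "counts_from_times",
]

CONDITIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class FitResult:
    """Weighted linear fit of spike counts against prediction errors."""

    slope: float
    intercept: float
    weighted_r2: float
    n_trials: int


def _wls_from_sums(sw, sx, sxx, sy, syy, sxy, n_trials) -> FitResult:
    var_x = sxx - sx * sx / sw
    ss_tot = syy - sy * sy / sw
    if ss_tot <= 1e-12:
        warnings.warn("spike counts have zero variance; r2 set to 0")
        return FitResult(np.nan, sy / sw, 0.0, n_trials)
    if var_x <= 1e-12:
        # no predictor variance: slope unidentified
        return FitResult(np.nan, sy / sw, 0.0, n_trials)
    slope = (sxy - sx * sy / sw) / var_x
    intercept = (sy - slope * sx) / sw
    ss_res = (
        syy + slope**2 * sxx + intercept**2 * sw
        - 2 * slope * sxy - 2 * intercept * sy + 2 * slope * intercept * sx
    )
    r2 = 1.0 - ss_res / ss_tot
    return FitResult(float(slope), float(intercept),
                     float(min(max(r2, 0.0), 1.0)), n_trials)


def weighted_regression(trials: pd.DataFrame, trace: PETrace) -> FitResult:
    """Fit spike counts of one test tone against a prediction-error trace.

    ``trials`` must contain ``block_id``, ``trial_index`` and
    ``spike_count`` for the trials of a single tone; they are aligned to
    the trace entries by (block, trial index).  Each trial expands into its
    per-state (error, count) pairs weighted by P(m|k).
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials to fit a line")
    key = pd.MultiIndex.from_arrays([trace.block_id, trace.trial_index])
    lookup = pd.Series(np.arange(len(trace)), index=key)
    want = pd.MultiIndex.from_arrays(
        [trials["block_id"].to_numpy(), trials["trial_index"].to_numpy()]
    )
    if not want.isin(lookup.index).all():
        raise ValueError("trials contain entries outside the trace")
    rows = lookup.loc[want].to_numpy()
    w = trace.weights[rows]
    e = trace.errors[rows]
    c = trials["spike_count"].to_numpy(dtype=float)
    sw = float(w.sum())
    sx = float((w * e).sum())
    sxx = float((w * e * e).sum())
    sy = float(c.sum())
    syy = float((c * c).sum())
    sxy = float((c[:, None] * w * e).sum())
    return _wls_from_sums(sw, sx, sxx, sy, syy, sxy, len(trials))


@dataclass(frozen=True)
class GridResult:
    """Weighted-r² surface over the whole representation bank.

    ``r2[i, j]`` is the fit of the j-th point on the curve for the i-th
    memory duration in ``n_values``; ``complexity`` and ``power`` hold the
    matching coordinates of each bank member.
    """

    n_values: np.ndarray
    r2: np.ndarray = field(repr=False)
    complexity: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    rmax2: float = 0.0
    argmax: tuple[int, int] = (0, 0)  # (N, curve index)
    good_frac: float = 0.9

    @property
    def good_set(self) -> np.ndarray:
        return self.r2 >= self.good_frac * self.rmax2


def _k_histograms(trials: pd.DataFrame, n_values, test_code: int,
                  burn_in: int):
    """Per-N histogram of past counts and count sums for the fitted tone.

    Returns dict n -> (n_k, s_k) built from retained trials whose tone is
    ``test_code``; k never crosses block boundaries.
    """
    out = {n: (np.zeros(n + 1), np.zeros(n + 1)) for n in n_values}
    for _, grp in trials.groupby("block_id", sort=True):
        grp = grp.sort_values("trial_index")
        codes = tone_codes(grp["tone"].to_numpy())
        counts = grp["spike_count"].to_numpy(dtype=float)
        cum = np.concatenate([[0], np.cumsum(codes)])
        t = np.arange(len(codes))
        for n in n_values:
            sel = (t >= burn_in) & (codes == test_code)
            k = cum[t[sel]] - cum[t[sel] - n]
            n_k, s_k = out[n]
            np.add.at(n_k, k, 1.0)
            np.add.at(s_k, k, counts[sel])
    return out


def _grid_from_histograms(hists, syy, bank: RepresentationBank,
                          test_code: int, good_frac: float) -> GridResult:
    n_values = bank.n_values
    n_beta = max(len(bank.curves[n].points) for n in n_values)
    r2 = np.zeros((len(n_values), n_beta))
    comp = np.zeros_like(r2)
    power = np.zeros_like(r2)
    for i, n in enumerate(n_values):
        n_k, s_k = hists[n]
        sw = n_k.sum()
        sy = s_k.sum()
        for j, rep in enumerate(bank.curves[n].points):
            u = n_k @ rep.encoder
            v = s_k @ rep.encoder
            e = rep.expected_errors()[:, test_code]
            fit = _wls_from_sums(
                sw, float(u @ e), float(u @ (e * e)), sy, syy,
                float(v @ e), int(sw),
            )
            r2[i, j] = fit.weighted_r2
            comp[i, j] = rep.complexity
            power[i, j] = rep.predictive_power
    # ties broken toward the most parsimonious representation:
    # smallest N, then smallest complexity
    rmax2 = float(r2.max())
    cand = np.argwhere(np.isclose(r2, rmax2, rtol=0, atol=0))
    i_best, j_best = min(cand, key=lambda ij: (n_values[ij[0]], comp[tuple(ij)]))
    return GridResult(
        n_values=np.asarray(n_values),
        r2=r2,
        complexity=comp,
        power=power,
        rmax2=rmax2,
        argmax=(int(n_values[i_best]), int(j_best)),
        good_frac=good_frac,
    )


def grid_search(
    trials: pd.DataFrame,
    bank: RepresentationBank,
    test_tone: int | str,
    burn_in: int = 50,
    good_frac: float = 0.9,
) -> GridResult:
    """Weighted-r² surface of one neuron/test-frequency over the bank.

    ``trials`` holds all trials of one neuron (both tones); only trials
    whose tone equals ``test_tone`` enter the fit, while prediction errors
    use the full sequence context.
    """
    test_code = int(tone_codes([test_tone])[0])
    if burn_in < max(bank.n_values):
        raise ValueError(
            f"burn_in ({burn_in}) must cover the longest memory duration "
            f"in the bank ({max(bank.n_values)})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hists = _k_histograms(trials, bank.n_values, test_code, burn_in)
        sel = (tone_codes(trials["tone"].to_numpy()) == test_code) & (
            trials["trial_index"].to_numpy() >= burn_in
        )
        c = trials.loc[sel, "spike_count"].to_numpy(dtype=float)
        return _grid_from_histograms(hists, float((c * c).sum()), bank,
                                     test_code, good_frac)


@dataclass(frozen=True)
class PermutationResult:
    observed_rmax2: float
    permuted_rmax2: np.ndarray
    significant: bool


def permutation_test(
    trials: pd.DataFrame,
    bank: RepresentationBank,
    test_tone: int | str,
    n_perm: int = 20,
    seed: int = 0,
    burn_in: int = 50,
) -> PermutationResult:
    """Permutation significance of rmax² for one neuron/test-frequency.

    Each permutation shuffles the tone sequence independently within each
    block (spike counts stay attached to their trial slots, so tone
    probabilities per block are preserved) and recomputes the full-grid
    rmax².  The effect is significant iff the observed rmax² strictly
    exceeds all ``n_perm`` permuted values (nominal p < 1/(n_perm+1)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = grid_search(trials, bank, test_tone, burn_in=burn_in)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = trials.copy()
        for _, grp in trials.groupby("block_id", sort=True):
            order = grp.sort_values("trial_index").index
            tones = trials.loc[order, "tone"].to_numpy()
            shuffled.loc[order, "tone"] = rng.permutation(tones)
        permuted[p] = grid_search(shuffled, bank, test_tone,
                                  burn_in=burn_in).rmax2
    return PermutationResult(
        observed_rmax2=observed.rmax2,
        permuted_rmax2=permuted,
        significant=bool(observed.rmax2 > permuted.max()),
    )


def response_significance(evoked, spontaneous, alpha: float = 0.05) -> bool:
    """Whether evoked counts significantly exceed spontaneous counts.

    One-sided Mann-Whitney rank test at level ``alpha``.
    """
    evoked = np.asarray(evoked, dtype=float)
    spontaneous = np.asarray(spontaneous, dtype=float)
    if len(evoked) == 0 or len(spontaneous) == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([evoked, spontaneous])) == 0:
        return False  # identical constant samples
    res = mannwhitneyu(evoked, spontaneous, alternative="greater")
    return bool(res.pvalue < alpha)


@dataclass(frozen=True)
class PopulationMaps:
    """Fraction-of-cases maps of good representations, as in a population
    summary: each cell holds the fraction of passing cases whose good set
    includes a representation falling in that cell."""

    n_values: np.ndarray
    complexity_edges: np.ndarray
    power_edges: np.ndarray
    by_complexity_power: np.ndarray = field(repr=False)
    by_n_complexity: np.ndarray = field(repr=False)
    by_n_power: np.ndarray = field(repr=False)
    n_cases: int = 0


def population_maps(
    grids: list[GridResult],
    min_rmax2: float = 0.1,
    n_complexity_bins: int = 24,
    n_power_bins: int = 24,
) -> PopulationMaps:
    """Aggregate good-representation sets over a population of cases.

    Cases with rmax² below ``min_rmax2`` are excluded.  For the binned
    axes a case marks a cell if *any* of its good representations falls in
    that cell.
    """
    passing = [g for g in grids if g.rmax2 >= min_rmax2]
    if not passing:
        raise ValueError(f"no case passes the rmax2 >= {min_rmax2} filter")
    ref = passing[0]
    n_values = ref.n_values
    cmax = max(g.complexity.max() for g in passing)
    pmax = max(g.power.max() for g in passing)
    c_edges = np.linspace(0.0, cmax + 1e-9, n_complexity_bins + 1)
    p_edges = np.linspace(0.0, pmax + 1e-9, n_power_bins + 1)

    cp = np.zeros((n_complexity_bins, n_power_bins))
    nc = np.zeros((len(n_values), n_complexity_bins))
    npow = np.zeros((len(n_values), n_power_bins))
    for g in passing:
        good = g.good_set
        ci = np.clip(np.digitize(g.complexity, c_edges) - 1, 0,
                     n_complexity_bins - 1)
        pi = np.clip(np.digitize(g.power, p_edges) - 1, 0, n_power_bins - 1)
        m_cp = np.zeros_like(cp, dtype=bool)
        m_nc = np.zeros_like(nc, dtype=bool)
        m_np = np.zeros_like(npow, dtype=bool)
        ii, jj = np.nonzero(good)
        m_cp[ci[ii, jj], pi[ii, jj]] = True
        m_nc[ii, ci[ii, jj]] = True
        m_np[ii, pi[ii, jj]] = True
        cp += m_cp
        nc += m_nc
        npow += m_np
    k = len(passing)
    return PopulationMaps(
        n_values=n_values,
        complexity_edges=c_edges,
        power_edges=p_edges,
        by_complexity_power=cp / k,
        by_n_complexity=nc / k,
        by_n_power=npow / k,
        n_cases=k,
    )


# ---------------------------------------------------------------------------
# trial-table I/O


_TRIAL_COLUMNS = [
    "neuron_id", "freq_label", "block_id", "condition", "trial_index",
    "tone", "spike_count",
]


def read_trials(path) -> pd.DataFrame:
    """Read the TSV trial dialect (tab-separated, '#' comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if (df["spike_count"] < 0).any():
        raise ValueError("spike counts must be nonnegative")
    bad = set(df["condition"].round(6)) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown probability conditions {sorted(bad)}")
    return df


def write_trials(df: pd.DataFrame, path, header_comments: list[str] = ()):
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def counts_from_times(spike_times: str, window: tuple[float, float] = (0.0, 330.0)) -> int:
    """Spike count in a half-open [t0, t1) ms window from a ';'-separated list."""
    t0, t1 = window
    if not spike_times or spike_times in ("nan", "-"):
        return 0
    times = np.array([float(x) for x in str(spike_times).split(";") if x != ""])
    return int(((times >= t0) & (times < t1)).sum())
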