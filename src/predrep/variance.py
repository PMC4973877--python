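"""Noise / explainable variance partition and SSA indices.

The fraction of response variance explained by prediction error can be
small either because the model is poor or because much of the variance is
noise — trial-to-trial variability not reproducible from the stimulus
sequence at all.  The noise variance is estimated by conditioning the
spike-count variance on the exact sequence of the preceding ``context_len``
tones (7 by default, at most 128 contexts) *and* on the block, then taking
the group-size-weighted average of the within-group variances.  Two
schemes are reported: *unbiased* (n−1 divisors; can over-correct) and
*biased/conservative* (n divisors; guaranteed not to exceed the total
variance).  Subtracting noise from total variance gives the explainable
variance, the ceiling for any stimulus-driven model.

The SSA index is the classical per-frequency contrast between a tone's
mean response when rare (deviant, 10% block) and when common (standard,
90% block): SI(f) = (d(f) − s(f)) / (d(f) + s(f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from predrep.fitting import FitResult
from predrep.prediction import tone_codes

__all__ = [
    "VarianceDecomposition",
    "SSAResult",
    "noise_variance",
    "explainable_fraction",
    "ssa_index",
]


def noise_variance(
    trials: pd.DataFrame,
    context_len: int = 7,
    burn_in: int = 50,
    tone: int | str | None = None,
) -> dict:
    """Noise-variance estimates conditioned on short stimulus context.

    Retained trials (index >= ``burn_in``) are grouped by (block, exact
    preceding ``context_len``-gram of tones, current tone); contexts never
    cross block boundaries.  The estimate is the group-size-weighted
    average of within-group variances.  Singleton groups contribute zero
    spread to the biased estimate and are excluded from the unbiased one.
    If ``tone`` is given, only trials of that tone are grouped (their
    contexts still use the full sequence).

    Returns ``{"unbiased": float|nan, "biased": float, "n_groups": int,
    "flags": list[str]}``.
    """
    if burn_in < context_len:
        raise ValueError("burn_in must be >= context_len for full contexts")
    want = None if tone is None else int(tone_codes([tone])[0])
    groups: dict[tuple, list] = {}
    for block, grp in trials.groupby("block_id", sort=True):
        grp = grp.sort_values("trial_index")
        codes = tone_codes(grp["tone"].to_numpy())
        counts = grp["spike_count"].to_numpy(dtype=float)
        for t in range(burn_in, len(codes)):
            if want is not None and codes[t] != want:
                continue
            ctx = tuple(codes[t - context_len:t])
            groups.setdefault((block, ctx, codes[t]), []).append(counts[t])

    flags: list[str] = []
    w_unb = v_unb = 0.0
    w_bia = v_bia = 0.0
    for vals in groups.values():
        arr = np.asarray(vals)
        n = len(arr)
        ssd = float(((arr - arr.mean()) ** 2).sum())
        w_bia += n
        v_bia += ssd  # = n * (ssd / n): weight n times biased variance
        if n >= 2:
            w_unb += n
            v_unb += n * ssd / (n - 1)
    if w_unb == 0:
        flags.append("all context groups are singletons; unbiased estimate undefined")
        unbiased = float("nan")
    else:
        unbiased = v_unb / w_unb
    return {
        "unbiased": unbiased,
        "biased": v_bia / w_bia if w_bia else float("nan"),
        "n_groups": len(groups),
        "flags": flags,
    }


@dataclass(frozen=True)
class VarianceDecomposition:
    """Partition of spike-count variance around a linear prediction-error fit.

    ``fraction_explainable_unbiased`` may legitimately fall outside [0, 1]
    when the unbiased noise estimate over-corrects; it is reported as-is
    with a flag rather than clipped.
    """

    total_variance: float
    predictor_variance: float
    noise_unbiased: float
    noise_biased: float
    fraction_explained: float
    fraction_explainable_unbiased: float
    fraction_explainable_conservative: float
    flags: tuple[str, ...] = ()


def explainable_fraction(
    fit: FitResult,
    noise: dict,
    counts,
) -> VarianceDecomposition:
    """Fractions of explained and explainable variance for one case.

    ``fit`` supplies the fraction of explained variance (weighted r²);
    ``counts`` the spike counts whose (population) variance is the total;
    ``noise`` the estimates from :func:`noise_variance`.
    """
    counts = np.asarray(counts, dtype=float)
    total = float(counts.var())
    predictor = fit.weighted_r2 * total
    flags: list[str] = []

    def _frac(noise_var: float) -> float:
        if np.isnan(noise_var):
            flags.append("noise estimate undefined")
            return float("nan")
        denom = total - noise_var
        if denom <= 0:
            flags.append("noise estimate >= total variance; fraction undefined")
            return float("inf") if predictor > 0 else float("nan")
        return predictor / denom

    f_unb = _frac(noise["unbiased"])
    f_con = _frac(noise["biased"])
    if np.isfinite(f_unb) and not 0.0 <= f_unb <= 1.0:
        flags.append("unbiased explainable fraction outside [0, 1]")
    return VarianceDecomposition(
        total_variance=total,
        predictor_variance=predictor,
        noise_unbiased=noise["unbiased"],
        noise_biased=noise["biased"],
        fraction_explained=fit.weighted_r2,
        fraction_explainable_unbiased=f_unb,
        fraction_explainable_conservative=f_con,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class SSAResult:
    """Per-frequency deviant/standard means and SSA indices."""

    deviant_mean: dict
    standard_mean: dict
    si: dict
    flags: tuple[str, ...] = ()


def ssa_index(
    trials: pd.DataFrame,
    rare_p: float = 0.1,
    common_p: float = 0.9,
    burn_in: int = 0,
) -> SSAResult:
    """SSA index per frequency from paired rare/common blocks.

    For each tone f: d(f) is its mean count in blocks where f is the rare
    tone (probability ``rare_p``) and s(f) its mean count where f is the
    common tone (probability ``common_p``); SI(f) = (d−s)/(d+s).  The
    ``condition`` column is the probability of the *high* tone, so the low
    tone is rare where condition == ``common_p``.
    """
    t = trials[trials["trial_index"] >= burn_in]
    codes = tone_codes(t["tone"].to_numpy())
    cond = t["condition"].to_numpy(dtype=float)
    counts = t["spike_count"].to_numpy(dtype=float)
    d, s, si = {}, {}, {}
    flags: list[str] = []
    for label, code in (("low", 0), ("high", 1)):
        p_rare = common_p if code == 0 else rare_p
        p_common = rare_p if code == 0 else common_p
        dev = counts[(codes == code) & np.isclose(cond, p_rare)]
        std = counts[(codes == code) & np.isclose(cond, p_common)]
        if len(dev) == 0 or len(std) == 0:
            raise ValueError(
                f"tone {label!r} must be observed both as rare and as common"
            )
        d[label] = float(dev.mean())
        s[label] = float(std.mean())
        denom = d[label] + s[label]
        if denom == 0:
            flags.append(f"SI undefined for {label}: zero mean responses")
            si[label] = float("nan")
        else:
            si[label] = (d[label] - s[label]) / denom
    return SSAResult(deviant_mean=d, standard_mean=s, si=si, flags=tuple(flags))
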