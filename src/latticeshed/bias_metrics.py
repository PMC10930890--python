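"""Blood-vs-tissue distortion measures.

Clone-fraction differences (blood minus tissue), inverse Simpson diversity,
detectable-driver counts under assay detection limits, the percent change in
detectable drivers attributable to spatially biased shedding, and the
analytic two-compartment upper bound on the clone-fraction difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "BiasReport",
    "inverse_simpson",
    "clone_fraction_differences",
    "mean_signed_differences",
    "analytic_difference",
    "max_difference",
    "count_detectable",
    "ever_detected_fraction",
    "percent_spatial_bias",
    "normalize_and_bin",
]


def inverse_simpson(fractions) -> float:
    """Inverse Simpson diversity D = 1 / sum f_i^2, an effective clone number.

    Input must be a normalized abundance vector (non-negative, summing to 1).
    """
    f = np.asarray(list(fractions), dtype=float)
    if f.size == 0:
        raise ValueError("empty fraction vector")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be non-negative and sum to 1")
    return 1.0 / float((f**2).sum())


def clone_fraction_differences(
    blood: pd.Series,
    tissue: pd.Series,
    min_tissue_fraction: float = 0.10,
    clone_ages: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-clone difference blood fraction - tissue fraction.

    Returns one row per clone with columns delta, tissue_fraction,
    blood_fraction, included (tissue fraction >= ``min_tissue_fraction``,
    the cut used when averaging positive/negative differences) and, if
    given, age.  Blood and tissue must cover the same clone set.
    """
    if set(blood.index) != set(tissue.index):
        raise ValueError("blood and tissue fractions cover different clone sets")
    tissue = tissue.reindex(blood.index)
    delta = blood - tissue
    out = pd.DataFrame(
        {
            "blood_fraction": blood,
            "tissue_fraction": tissue,
            "delta": delta,
            "included": tissue >= min_tissue_fraction,
        }
    )
    if clone_ages is not None:
        out["age"] = clone_ages.reindex(blood.index)
    return out


def mean_signed_differences(diff: pd.DataFrame) -> tuple[float, float]:
    """Mean positive and mean negative delta over the included clones.

    NaN when no included clone has a difference of that sign.
    """
    d = diff.loc[diff["included"], "delta"]
    pos = d[d > 0]
    neg = d[d < 0]
    return (
        float(pos.mean()) if len(pos) else float("nan"),
        float(neg.mean()) if len(neg) else float("nan"),
    )


def analytic_difference(x: float, S: float, d1: float, d2: float) -> float:
    """Expected blood-tissue fraction difference in the two-compartment limit.

    A resident population of constant size S sheds at rate d1 while a single
    invasive subclone of size x sheds at rate d2:

        f(x) = d2*x / (d2*x + d1*S) - x / (x + S)
    """
    if x <= 0 or S <= 0 or d1 <= 0 or d2 <= 0:
        raise ValueError("x, S, d1, d2 must all be positive")
    return d2 * x / (d2 * x + d1 * S) - x / (x + S)


def max_difference(S: float, d1: float, d2: float) -> tuple[float, float]:
    """Numerically maximize the two-compartment difference over the subclone size.

    Returns (x_star, f_star).  The maximum is found by bounded scalar search;
    analytically it sits at x* = S*sqrt(d1/d2) with
    f* = (sqrt(d2)-sqrt(d1))/(sqrt(d2)+sqrt(d1)), independent of S — the
    numeric result is authoritative and tested against that closed form.
    """
    if S <= 0 or d1 <= 0 or d2 <= 0:
        raise ValueError("S, d1, d2 must be positive")
    hi = max(1e6, 100.0 * S)
    res = minimize_scalar(
        lambda x: -analytic_difference(x, S, d1, d2),
        bounds=(1e-12 * S, hi),
        method="bounded",
        options={"xatol": 1e-10 * S},
    )
    return float(res.x), float(-res.fun)


def count_detectable(vaf_table: pd.DataFrame, limit: float) -> dict[str, int]:
    """Number of driver mutations whose sampled VAF meets a detection limit.

    Counts distinct mutations with VAF >= limit, separately for the biased
    and unbiased columns; missing (NaN) VAFs count as undetected.
    """
    if not 0.0 < limit < 1.0:
        raise ValueError("detection limit must lie in (0, 1)")
    out = {}
    for key, col in (("biased", "vaf_biased"), ("unbiased", "vaf_unbiased")):
        v = vaf_table[col]
        detected = vaf_table.loc[v.notna() & (v >= limit), "mutation_id"]
        out[key] = int(detected.nunique())
    return out


def ever_detected_fraction(
    vaf_table: pd.DataFrame,
    limit: float,
    n_mutations: int,
    column: str = "vaf_biased",
) -> float:
    """Fraction of all distinct drivers whose VAF ever reaches a limit.

    ``vaf_table`` is a long per-sweep VAF table; ``n_mutations`` is the total
    number of distinct drivers the tumor ever produced (the denominator
    includes mutations extinct before any recorded draw).  Missing VAFs are
    undetected.
    """
    if n_mutations <= 0:
        raise ValueError("n_mutations must be positive")
    if len(vaf_table) == 0:
        return 0.0
    v = vaf_table[column]
    ever = vaf_table.loc[v.notna() & (v >= limit), "mutation_id"].nunique()
    return ever / n_mutations


def percent_spatial_bias(n_biased: int, n_unbiased: int) -> float:
    """Percent change in detectable drivers due to spatially biased shedding.

    100*(n_biased - n_unbiased)/n_unbiased; NaN when the unbiased count is
    zero (the comparison is undefined, not an error).
    """
    if n_unbiased < 0 or n_biased < 0:
        raise ValueError("counts must be non-negative")
    if n_unbiased == 0:
        return float("nan")
    return 100.0 * (n_biased - n_unbiased) / n_unbiased


@dataclass
class BiasReport:
    """Distortion summary at one timepoint of one run."""

    normalized_time: float
    deltas: pd.DataFrame
    mean_positive_delta: float
    mean_negative_delta: float
    d_blood: float
    d_tissue: float
    n_detect_biased: dict[float, int]
    n_detect_unbiased: dict[float, int]
    percent_bias: dict[float, float]


def normalize_and_bin(
    trajectory: pd.DataFrame,
    n_bins: int,
    *,
    run_col: str = "run",
    time_col: str = "sweep",
    value_col: str = "value",
) -> pd.DataFrame:
    """Normalize each run's time to [0, 1], bin, and average across runs.

    Each run's timepoints are mapped to normalized time t/t_final, values are
    averaged within ``n_bins`` equal-width bins per run, and the cross-run
    mean and sample s.d. are reported per bin.  Returns columns bin_mid,
    mean, sd, n_runs.
    """
    if trajectory.empty:
        raise ValueError("empty trajectory")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    per_run = []
    for run, grp in trajectory.groupby(run_col):
        t = grp[time_col].to_numpy(dtype=float)
        tmax = t.max()
        norm = t / tmax if tmax > 0 else np.zeros_like(t)
        idx = np.clip(np.digitize(norm, edges[1:-1]), 0, n_bins - 1)
        means = (
            pd.Series(grp[value_col].to_numpy(), index=idx).groupby(level=0).mean()
        )
        per_run.append(means.reindex(range(n_bins)))
    stacked = pd.concat(per_run, axis=1)
    return pd.DataFrame(
        {
            "bin_mid": mids,
            "mean": stacked.mean(axis=1).to_numpy(),
            "sd": stacked.std(axis=1, ddof=1).to_numpy(),
            "n_runs": stacked.notna().sum(axis=1).to_numpy(),
        }
    )
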