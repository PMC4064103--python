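"""Accuracy metrics, resampling statistics and the robustness experiment.

Prediction accuracy is measured per structure by base-pair sensitivity,
positive predictive value (PPV) and their harmonic mean (F-measure); a
predicted pair is correct only if the identical (i, j) pair is in the
reference.  Uncertainty over a dataset is summarised by the bootstrap 95%
percentile confidence interval of the average F-measure, and method
differences are assessed with a two-sided permutation test on mean
F-measure difference.

The robustness experiment feeds a predictor α-sampled subsets of G_big —
the maximum pseudoknot-free subset of the reference — and traces how
accuracy grows with the amount of true structural information provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .structures import RnaSequence, SecondaryStructure

__all__ = [
    "AccuracyRecord",
    "BootstrapCI",
    "RobustnessGrid",
    "accuracy",
    "extract_gbig",
    "sample_substructure",
    "bootstrap_ci",
    "permutation_test",
    "robustness_experiment",
    "DEFAULT_ALPHAS",
]

#: default α grid: 1%, 5%..95% in 0.05 steps, and 99% (21 values)
DEFAULT_ALPHAS: tuple[float, ...] = (0.01,) + tuple(
    round(0.05 * k, 2) for k in range(1, 20)
) + (0.99,)


@dataclass(frozen=True)
class AccuracyRecord:
    sensitivity: float
    ppv: float
    f_measure: float


def accuracy(pred: SecondaryStructure, ref: SecondaryStructure) -> AccuracyRecord:
    """Sensitivity, PPV and F-measure of ``pred`` against ``ref``.

    All three are defined as 0 when their denominators are 0; a prediction
    identical to a nonempty reference scores 1 on all three.
    """
    correct = sum(1 for p in pred.pairs if p in ref)
    sens = correct / len(ref) if len(ref) else 0.0
    ppv = correct / len(pred) if len(pred) else 0.0
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else 0.0
    return AccuracyRecord(sensitivity=sens, ppv=ppv, f_measure=f)


def extract_gbig(
    ref: SecondaryStructure,
) -> tuple[SecondaryStructure, SecondaryStructure]:
    """Split a reference into (G_big, G_small).

    G_big is a maximum-cardinality pseudoknot-free subset of the reference
    (equivalently: the minimum number of pseudoknotted pairs removed);
    G_small is the remainder.  Among equal-cardinality optima the
    lexicographically smallest pair list is chosen.  A pseudoknot-free
    reference returns (ref, empty).
    """
    pairs = list(ref.pairs)
    if not pairs:
        return ref, SecondaryStructure()
    n = ref.max_index()
    partner = {p.i: p for p in pairs}

    # interval DP over [i, j]: best = (count, negated-lex pair tuple)
    memo: dict[tuple[int, int], tuple[int, tuple]] = {}

    def best(i: int, j: int) -> tuple[int, tuple]:
        if i > j:
            return 0, ()
        key = (i, j)
        if key in memo:
            return memo[key]
        # option 1: skip i
        cnt, chosen = best(i + 1, j)
        res = (cnt, chosen)
        # option 2: keep the pair opening at i (if it fits in the window)
        p = partner.get(i)
        if p is not None and p.j <= j:
            c1, s1 = best(i + 1, p.j - 1)
            c2, s2 = best(p.j + 1, j)
            cand = (1 + c1 + c2, tuple(sorted(((p.i, p.j),) + s1 + s2)))
            if cand[0] > res[0] or (cand[0] == res[0] and cand[1] < res[1]):
                res = cand
        memo[key] = res
        return res

    _, keep = best(1, n)
    gbig = SecondaryStructure(keep)
    gsmall = ref.difference(gbig)
    return gbig, gsmall


def sample_substructure(
    gbig: SecondaryStructure, alpha: float, rng: np.random.Generator
) -> SecondaryStructure:
    """Independent Bernoulli(α) inclusion of each pair of ``gbig``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return SecondaryStructure(p for p in gbig.pairs if rng.random() < alpha)


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    resamples: int
    seed: Optional[int] = None


def bootstrap_ci(
    f: Sequence[float],
    resamples: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> BootstrapCI:
    """Bootstrap 95% percentile confidence interval of the mean of ``f``.

    Resamples with replacement at the original sample size, takes the mean
    of each resample, and reports the 2.5th and 97.5th percentiles of the
    resulting distribution (linear interpolation between order statistics).
    Deterministic given a seed / generator.
    """
    values = np.asarray(f, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_ci requires a non-empty vector")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(resamples, values.size))
    means = values[idx].mean(axis=1)
    lower, upper = np.percentile(means, [2.5, 97.5])
    return BootstrapCI(lower=float(lower), upper=float(upper), resamples=resamples, seed=seed)


def permutation_test(
    fa: Sequence[float],
    fb: Sequence[float],
    permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    exhaustive_limit: int = 10**6,
) -> float:
    """Two-sided permutation test on the difference of mean F-measures.

    The p-value is the proportion of label reassignments whose absolute
    mean difference is >= the observed absolute difference.  When the
    number of distinct splits is at most ``exhaustive_limit`` all splits
    are enumerated (the identity split included), making tiny-sample tests
    exact; otherwise ``permutations`` random splits are drawn.
    """
    a = np.asarray(fa, dtype=float)
    b = np.asarray(fb, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("permutation_test requires non-empty samples")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na = a.size

    total = math.comb(a.size + b.size, na)
    if total <= exhaustive_limit:
        hits = 0
        idx_all = range(pooled.size)
        target = pooled.sum()
        for pick in combinations(idx_all, na):
            sa = pooled[list(pick)].mean()
            sb = (target - pooled[list(pick)].sum()) / b.size
            if abs(sa - sb) >= observed - 1e-12:
                hits += 1
        return hits / total

    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-12:
            hits += 1
    return hits / permutations


@dataclass(frozen=True)
class RobustnessGrid:
    """Tidy per-replicate results plus per-α summaries.

    ``table`` has one row per (molecule, alpha, replicate) with the
    F-measure of the prediction against the full reference; ``summary``
    aggregates per α: the mean F over all replicates and molecules and the
    bootstrap CI of the per-replicate mean F-measures.
    """

    alphas: tuple[float, ...]
    replicates: int
    table: pd.DataFrame
    summary: pd.DataFrame


def robustness_experiment(
    dataset: Sequence[tuple[str, RnaSequence, SecondaryStructure]],
    predictor: Callable[[RnaSequence, SecondaryStructure], SecondaryStructure],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    replicates: int = 100,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    bootstrap_resamples: int = 2000,
) -> RobustnessGrid:
    """α-sampled partial-information robustness protocol.

    For each molecule and each α, draw ``replicates`` Bernoulli(α)
    subsets of G_big, run the predictor with each subset as input
    structure, and score F-measure against the full reference.  A
    predictor failure on one input is recorded as F = 0 with a warning and
    the run continues.
    """
    if not dataset:
        raise ValueError("robustness_experiment requires a non-empty dataset")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for name, seq, ref in dataset:
        gbig, _ = extract_gbig(ref)
        for alpha in alphas:
            for rep in range(replicates):
                sub = sample_substructure(gbig, alpha, rng)
                try:
                    pred = predictor(seq, sub)
                    f = accuracy(pred, ref).f_measure
                except Exception as exc:  # noqa: BLE001 - driver must continue
                    warnings.warn(
                        f"predictor failed on {name} (alpha={alpha}, rep={rep}): {exc}"
                    )
                    f = 0.0
                rows.append(
                    {"molecule": name, "alpha": alpha, "replicate": rep, "f_measure": f}
                )
    table = pd.DataFrame(rows)
    summaries = []
    for alpha, group in table.groupby("alpha"):
        per_rep = group.groupby("replicate")["f_measure"].mean().to_numpy()
        ci = bootstrap_ci(per_rep, resamples=bootstrap_resamples, rng=rng)
        summaries.append(
            {
                "alpha": alpha,
                "mean_f": group["f_measure"].mean(),
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
            }
        )
    summary = pd.DataFrame(summaries).sort_values("alpha").reset_index(drop=True)
    return RobustnessGrid(
        alphas=tuple(alphas), replicates=replicates, table=table, summary=summary
    )
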