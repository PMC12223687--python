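"""Ranked prescreening and workload accounting.

Given per-patient validity probabilities, candidates are screened in order of
descending probability. The efficiency question: how many candidates must be
screened before M valid ones are found, and how does that compare with
screening in random order? Under a uniformly random order the number of draws
needed to find M of the K valid patients in a pool of N follows a negative
hypergeometric distribution with mean M*(N+1)/(K+1); the Monte-Carlo baseline
here reproduces that, and the workload reduction is
(random screens - ranked screens) / random screens.

Pools are also tagged by difficulty class from their valid rate:
case 1 below 50%, case 2 from 50% to 60% inclusive, case 3 above 60%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CaseLabel",
    "ProbabilityHistogram",
    "ScreeningOutcome",
    "rank_candidates",
    "screens_until",
    "random_baseline",
    "expected_random_screens",
    "workload_reduction",
    "classify_case",
    "probability_histogram",
    "accumulation_curve",
    "evaluate_screening",
]


@dataclass(frozen=True)
class CaseLabel:
    case_number: int
    valid_rate: float  # percent


@dataclass(frozen=True)
class ProbabilityHistogram:
    bin_edges: np.ndarray
    valid_counts: np.ndarray
    invalid_counts: np.ndarray


@dataclass(frozen=True)
class ScreeningOutcome:
    ordering: list[str]
    target_m: int
    screens_needed: int
    random_baseline_mean: float
    random_baseline_sd: float
    workload_reduction: float
    random_baseline_closed_form: float = field(default=float("nan"))


def rank_candidates(probabilities: Mapping[str, float]) -> list[str]:
    """Patients sorted by descending probability; ties broken by patient id."""
    if not probabilities:
        raise ValueError("candidate pool is empty")
    for pid, p in probabilities.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for {pid!r} outside [0, 1]: {p}")
    return sorted(probabilities, key=lambda pid: (-probabilities[pid], pid))


def screens_until(ordering: Sequence[str], validity: Mapping[str, int], m: int) -> int:
    """Smallest prefix of the ordering that contains m valid patients."""
    if m < 1:
        raise ValueError("m must be >= 1")
    total_valid = sum(int(validity[pid]) for pid in ordering)
    if m > total_valid:
        raise ValueError(
            f"cannot find {m} valid patients: the pool holds only {total_valid} "
            f"(shortfall {m - total_valid})"
        )
    found = 0
    for i, pid in enumerate(ordering, start=1):
        found += int(validity[pid])
        if found == m:
            return i
    raise AssertionError("unreachable")


def expected_random_screens(n_total: int, n_valid: int, m: int) -> float:
    """Closed-form mean screens under random order: M*(N+1)/(K+1)."""
    return m * (n_total + 1) / (n_valid + 1)


def random_baseline(
    validity: Mapping[str, int], m: int, n_reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo (mean, sd) of screens-to-m-valid under random ordering."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    valid = np.asarray([int(v) for v in validity.values()], dtype=int)
    if m > valid.sum():
        raise ValueError(
            f"cannot find {m} valid patients: the pool holds only {int(valid.sum())} "
            f"(shortfall {m - int(valid.sum())}))"
        )
    rng = np.random.default_rng(seed)
    draws = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        perm = rng.permutation(valid)
        draws[r] = int(np.searchsorted(np.cumsum(perm), m) + 1)
    return float(draws.mean()), float(draws.std(ddof=1)) if n_reps > 1 else 0.0


def workload_reduction(screens_ranked: float, screens_random: float) -> float:
    """Fractional saving of ranked over random screening (negative = worse)."""
    if screens_random <= 0:
        raise ValueError("screens_random must be positive")
    return (screens_random - screens_ranked) / screens_random


def classify_case(valid_rate: float) -> CaseLabel:
    """Difficulty class from the pool valid rate (percent)."""
    if not (0.0 <= valid_rate <= 100.0):
        raise ValueError(f"valid rate must be a percentage in [0, 100], got {valid_rate}")
    if valid_rate < 50.0:
        case = 1
    elif valid_rate <= 60.0:
        case = 2
    else:
        case = 3
    return CaseLabel(case_number=case, valid_rate=float(valid_rate))


def probability_histogram(
    probabilities: Mapping[str, float], validity: Mapping[str, int], n_bins: int = 20
) -> ProbabilityHistogram:
    """Stacked histogram data: valid and invalid patient counts per probability bin."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    probs = np.asarray([probabilities[p] for p in probabilities], dtype=float)
    if probs.size and not ((probs >= 0).all() and (probs <= 1).all()):
        raise ValueError("probabilities must lie in [0, 1]")
    is_valid = np.asarray([bool(validity[p]) for p in probabilities])
    valid_counts, _ = np.histogram(probs[is_valid], bins=edges)
    invalid_counts, _ = np.histogram(probs[~is_valid], bins=edges)
    return ProbabilityHistogram(bin_edges=edges, valid_counts=valid_counts, invalid_counts=invalid_counts)


def accumulation_curve(ordering: Sequence[str], validity: Mapping[str, int]) -> np.ndarray:
    """Cumulative valid-found count after each screen along the ordering."""
    flags = np.asarray([int(validity[pid]) for pid in ordering], dtype=int)
    return np.cumsum(flags)


def evaluate_screening(
    probabilities: Mapping[str, float],
    validity: Mapping[str, int],
    target_m: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> ScreeningOutcome:
    """Rank the pool, count screens to the target, and compare with random order."""
    ordering = rank_candidates(probabilities)
    needed = screens_until(ordering, validity, target_m)
    mean, sd = random_baseline(validity, target_m, n_reps=n_reps, seed=seed)
    n_total = len(ordering)
    n_valid = int(sum(int(validity[p]) for p in ordering))
    return ScreeningOutcome(
        ordering=ordering,
        target_m=target_m,
        screens_needed=needed,
        random_baseline_mean=mean,
        random_baseline_sd=sd,
        workload_reduction=workload_reduction(needed, mean),
        random_baseline_closed_form=expected_random_screens(n_total, n_valid, target_m),
    )
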