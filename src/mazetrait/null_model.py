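"""Stochastic null models of arm choice.

Under the simplest null -- each entry drawn uniformly at random from all nine
arms, re-entries allowed, nine entries per trial -- the pooled distribution of
repeat-free sequence lengths has its mode at two.  Real mice sit well above
that chance benchmark.  The module also carries the exact first-segment length
distribution for the iid kernel as an analytic oracle, so simulation output
can be checked against a closed form (and so first-segment statistics are
never confused with pooled-segment statistics: the first-segment mode for nine
arms is three, not two).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ValidationError
from .maze_metrics import decompose_unique_sequences

KERNELS = ("uniform", "no_immediate_repeat", "offset_biased")


@dataclass
class NullModelSpec:
    """Configuration of a simulated random-choice cohort."""

    n_agents: int
    n_trials_per_agent: int = 16
    n_arms: int = 9
    kernel: str = "uniform"
    offset_weights: np.ndarray | None = None  # over offsets -n//2..+n//2
    max_entries: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.n_trials_per_agent < 1:
            raise ValidationError("agent and trial counts must be >= 1")
        if self.kernel not in KERNELS:
            raise ValidationError(f"unknown kernel {self.kernel!r}; one of {KERNELS}")
        if self.kernel == "offset_biased":
            w = np.asarray(self.offset_weights, dtype=float)
            if w.shape != (self.n_arms,):
                raise ValidationError(
                    f"offset_weights must have length {self.n_arms}"
                )
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("offset_weights must be non-negative, not all zero")
            self.offset_weights = w / w.sum()


def _transition_matrix(spec: NullModelSpec) -> np.ndarray:
    """Row-stochastic next-arm probabilities given the current arm."""
    n = spec.n_arms
    if spec.kernel == "uniform":
        return np.full((n, n), 1.0 / n)
    if spec.kernel == "no_immediate_repeat":
        mat = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(mat, 0.0)
        return mat
    # offset_biased: weights indexed by circular offset -(n//2)..+(n//2)
    half = n // 2
    mat = np.zeros((n, n))
    for a in range(n):
        for off_idx, w in enumerate(spec.offset_weights):
            offset = off_idx - half
            mat[a, (a + offset) % n] = w
    return mat


def simulate_null_cohort(spec: NullModelSpec) -> list[list[list[int]]]:
    """Draw arm-entry sequences for every agent and trial.

    Each trial starts from a uniformly chosen arm and applies the kernel until
    ``max_entries`` entries have been made.  Reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    mat = _transition_matrix(spec)
    cum = np.cumsum(mat, axis=1)
    cohort = []
    for _ in range(spec.n_agents):
        trials = []
        for _ in range(spec.n_trials_per_agent):
            arm = int(rng.integers(spec.n_arms))
            seq = [arm]
            u = rng.random(spec.max_entries - 1)
            for step in range(spec.max_entries - 1):
                arm = int(np.searchsorted(cum[arm], u[step], side="right"))
                seq.append(arm)
            trials.append(seq)
        cohort.append(trials)
    return cohort


def null_length_histogram(
    cohort: list[list[list[int]]],
) -> tuple[dict[int, int], int, list[int]]:
    """Pool repeat-free segment lengths over all trials.

    Returns (histogram over lengths, modal length, tied modes).  Ties are
    broken toward the smaller length but reported explicitly.  The same
    decomposition code path scores real and null data.
    """
    if not cohort or not any(cohort):
        raise ValidationError("empty null cohort")
    max_len = max(len(t) for trials in cohort for t in trials)
    counts = {k: 0 for k in range(1, max_len + 1)}
    for trials in cohort:
        for seq in trials:
            for length in decompose_unique_sequences(seq).lengths:
                counts[length] += 1
    peak = max(counts.values())
    ties = sorted(k for k, v in counts.items() if v == peak)
    return counts, ties[0], ties


def analytic_first_segment_pmf(n_arms: int) -> np.ndarray:
    """Exact law of the first repeat-free segment length under iid choice.

    P(L = k) = [prod_{j=1..k-1} (n-j)/n] * k/n for k < n; the no-repeat event
    (all n arms in the first n entries) is folded into k = n, so the pmf sums
    to one.  Index 0 is unused; pmf[k] is P(L = k).
    """
    if n_arms < 2:
        raise ValidationError("analytic_first_segment_pmf needs n_arms >= 2")
    n = n_arms
    pmf = np.zeros(n + 1)
    distinct_prob = 1.0  # P(first k entries all distinct)
    for k in range(1, n):
        pmf[k] = distinct_prob * k / n
        distinct_prob *= (n - k) / n
    pmf[n] = distinct_prob
    return pmf


def first_segment_lengths(cohort: list[list[list[int]]]) -> list[int]:
    """First parsed segment length of every trial (for pmf cross-checks)."""
    return [
        decompose_unique_sequences(seq).lengths[0]
        for trials in cohort
        for seq in trials
        if seq
    ]
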