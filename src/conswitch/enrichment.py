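"""Permutation-based gene-class and pathway enrichment.

Two tests, both drawing random gene sets *with replacement* from the
expressed-gene universe:

* transcription-factor frequency in nested top-N fold-change bins,
  against draws of N genes (the with-replacement null is exactly
  Binomial(N, f), so the analytic tail is exposed alongside the Monte
  Carlo estimate);
* mean fold change of a pathway (or the cone-specific set, treated as a
  pathway) against means of equal-sized random draws, two-sided on the
  absolute mean.

p-values use the add-one rule p = (k + 1) / (n_draws + 1) so they are
never zero; the "< 1/n_draws" reporting convention is carried as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BIN_SIZES = (100, 200, 300, 400, 500, 600)
DEFAULT_N_DRAWS = 1_000_000
DRAW_SCHEDULE = (10 ** 2, 10 ** 3, 10 ** 4, 10 ** 5, 10 ** 6)
_CHUNK = 200_000


@dataclass
class PermutationResult:
    """Monte Carlo permutation test outcome (add-one p-value)."""

    observed_stat: float
    n_draws: int
    n_as_extreme: int
    p_value: float
    direction: str                 # 'greater' or 'two_sided_abs'
    seed: int
    below_floor: bool = False      # no draw as extreme: report "< 1/n_draws"
    exact_p: float | None = None   # analytic tail where one exists

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_draws + 1)


@dataclass
class BinSeries:
    """TF frequency in nested top-N bins plus the universe frequency."""

    bin_sizes: tuple
    frequency: np.ndarray
    p_per_bin: np.ndarray | None
    total_frequency: float
    direction: str

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.bin_sizes) + ["total"]
        freq = list(self.frequency) + [self.total_frequency]
        p = list(self.p_per_bin) + [np.nan] if self.p_per_bin is not None \
            else [np.nan] * len(rows)
        return pd.DataFrame({"bin": rows, "frequency": freq, "p_value": p})


def tf_bin_frequencies(ranked_genes, is_tf: pd.Series,
                       bin_sizes=DEFAULT_BIN_SIZES,
                       direction: str = "off") -> BinSeries:
    """TF fraction in the top-N bins of a fold-change ranking.

    ``ranked_genes`` must be the complete expressed-gene ranking,
    ascending fold change for direction='off' (strongest downregulation
    first) or descending for 'on'; callers typically pass an already
    direction-sorted list.
    """
    ranked_genes = list(ranked_genes)
    labels = is_tf.loc[ranked_genes].to_numpy(dtype=bool)
    if max(bin_sizes) > len(ranked_genes):
        raise ValueError(
            f"bin {max(bin_sizes)} exceeds universe of {len(ranked_genes)}")
    csum = np.cumsum(labels)
    freq = np.array([csum[n - 1] / n for n in bin_sizes])
    return BinSeries(tuple(bin_sizes), freq, None,
                     float(labels.mean()), direction)


def permutation_frequency_test(observed_count: int, bin_size: int,
                               universe_labels: np.ndarray,
                               n_draws: int = DEFAULT_N_DRAWS,
                               seed: int = 0) -> PermutationResult:
    """MC test of a TF count in a bin against with-replacement draws.

    Each draw samples ``bin_size`` genes with replacement from the
    universe; the statistic is the TF count.  The exact Binomial(bin_size,
    f) upper tail is reported alongside as ``exact_p``.
    """
    if observed_count > bin_size:
        raise ValueError("observed count exceeds bin size")
    labels = np.asarray(universe_labels, dtype=bool)
    n_universe = labels.size
    rng = np.random.default_rng(seed)
    k = 0
    done = 0
    while done < n_draws:
        m = min(_CHUNK, n_draws - done)
        idx = rng.integers(0, n_universe, size=(m, bin_size))
        k += int((labels[idx].sum(axis=1) >= observed_count).sum())
        done += m
    p = (k + 1) / (n_draws + 1)
    f = labels.mean()
    exact = float(stats.binom.sf(observed_count - 1, bin_size, f))
    return PermutationResult(float(observed_count), n_draws, k, p,
                             "greater", seed, below_floor=(k == 0),
                             exact_p=exact)


def pathway_switch_test(fold_changes: pd.Series, pathway_genes,
                        n_draws: int = DEFAULT_N_DRAWS,
                        seed: int = 0) -> PermutationResult:
    """Is a pathway's mean fold change more extreme than random sets?

    Statistic: mean log2 FC over the pathway's expressed members.  Null:
    means of equal-sized with-replacement draws from all expressed
    genes' fold changes.  Two-sided via |null mean| >= |observed mean|;
    the observed sign carries the direction.
    """
    # sorted so the observed mean is independent of input container order
    members = sorted(g for g in pathway_genes if g in fold_changes.index)
    if len(members) < len(list(pathway_genes)):
        import warnings
        warnings.warn("pathway members outside the expressed universe "
                      "were dropped", stacklevel=2)
    if not members:
        raise ValueError("pathway has no expressed members")
    fc = fold_changes.to_numpy(dtype=float)
    observed = float(fold_changes.loc[members].mean())
    n_set = len(members)
    rng = np.random.default_rng(seed)
    k = 0
    done = 0
    chunk = max(1, _CHUNK // n_set)
    while done < n_draws:
        m = min(chunk, n_draws - done)
        idx = rng.integers(0, fc.size, size=(m, n_set))
        null_means = fc[idx].mean(axis=1)
        k += int((np.abs(null_means) >= abs(observed)).sum())
        done += m
    p = (k + 1) / (n_draws + 1)
    return PermutationResult(observed, n_draws, k, p, "two_sided_abs",
                             seed, below_floor=(k == 0))


def convergence_diagnostic(test_closure, draw_schedule=DRAW_SCHEDULE,
                           seed: int = 0,
                           stability_rel_tol: float = 0.10) -> pd.DataFrame:
    """p-value of a permutation test at increasing draw counts.

    ``test_closure(n_draws, seed)`` must return a PermutationResult.
    Each schedule point uses a child seed from one stream.  The ``stable``
    flag marks points whose p differs from the previous one by less than
    ``stability_rel_tol`` relatively.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(draw_schedule))
    rows = []
    prev_p = None
    for n, child in zip(draw_schedule, children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        res = test_closure(n_draws=n, seed=child_seed)
        stable = (prev_p is not None and prev_p > 0
                  and abs(res.p_value - prev_p) / prev_p < stability_rel_tol)
        rows.append({"n_draws": n, "p_value": res.p_value,
                     "below_floor": res.below_floor, "stable": stable})
        prev_p = res.p_value
    return pd.DataFrame(rows)
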