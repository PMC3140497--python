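"""Inferential procedures for paired transect prey data.

Three procedures:

1. the pseudocount ratio statistic ``(x + 1) / (y + 1)`` comparing prey
   without swimbladders to prey with swimbladders, defined even when a
   sample has zero individuals in either group;
2. an exact paired Wilcoxon signed-rank test computed by full enumeration
   of all ``2^n`` sign assignments (no normal approximation) — with 7
   paired transects and every difference positive this yields W = 28 and
   a two-sided p of 2/128 = 0.015625;
3. a Monte Carlo family-resampling test that draws a fixed number of prey
   families with replacement from the full candidate universe and asks how
   often the swimbladderless count is at least as extreme as observed,
   cross-checked against the exact binomial tail (a uniform draw with
   replacement of m families from a universe with k swimbladderless out of
   N makes the swimbladderless count Binomial(m, k/N)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .prey_data import AbundanceTable, FamilyUniverse

__all__ = [
    "TwoTailMode",
    "DegenerateSampleError",
    "EnumerationCapError",
    "MissingAnnotationError",
    "RatioConfig",
    "PairedSample",
    "WilcoxonResult",
    "ResamplingResult",
    "swimbladder_ratio",
    "transect_ratio_pairs",
    "extracted_family_abundance_pairs",
    "wilcoxon_signed_rank_exact",
    "exact_binomial_twotail",
    "family_resampling_test",
    "observed_sponging_families",
]

TwoTailMode = Literal["deviation", "doubling"]

ENUMERATION_CAP = 20


class DegenerateSampleError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class EnumerationCapError(ValueError):
    """Sample too large for exact sign-vector enumeration."""


class MissingAnnotationError(KeyError):
    """A family in the abundance table has no swimbladder annotation."""


@dataclass(frozen=True)
class RatioConfig:
    """Pseudocount added to both counts before forming the ratio.

    The default offset of 1 keeps the ratio finite and positive when either
    count is zero.
    """

    offset: float = 1.0

    def __post_init__(self) -> None:
        if not self.offset > 0:
            raise ValueError("offset must be > 0")


@dataclass(frozen=True)
class PairedSample:
    """Per-unit paired values: condition A (sponging) vs B (non-sponging)."""

    unit_ids: tuple[str, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.unit_ids) == len(self.values_a) == len(self.values_b)):
            raise ValueError("unit_ids, values_a, values_b must have equal lengths")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")

    def differences(self) -> np.ndarray:
        return np.asarray(self.values_a, dtype=float) - np.asarray(
            self.values_b, dtype=float
        )

    def __len__(self) -> int:
        return len(self.unit_ids)


@dataclass(frozen=True)
class WilcoxonResult:
    """Exact signed-rank test result.

    ``w_statistic`` is the sum of ranks of positive differences;
    ``p_two_sided`` the exact enumeration p; ``n_effective`` the number of
    nonzero differences.
    """

    w_statistic: float
    p_two_sided: float
    n_effective: int
    method: str = "exact-enumeration"

    def __post_init__(self) -> None:
        w_max = self.n_effective * (self.n_effective + 1) / 2
        if not 0 <= self.w_statistic <= w_max:
            raise ValueError(f"W={self.w_statistic} outside [0, {w_max}]")
        if not 0 < self.p_two_sided <= 1:
            raise ValueError("p must be in (0, 1]")


@dataclass(frozen=True)
class ResamplingResult:
    """Monte Carlo family-resampling result with its analytic cross-check."""

    p_mc: float
    p_exact: float
    reps: int
    n_draw: int
    observed_no_sb: int
    universe_size: int
    k_no_sb: int
    seed: int
    two_tail_mode: str = "deviation"

    def mc_standard_error(self) -> float:
        """Binomial standard error of the Monte Carlo p estimate."""
        return float(np.sqrt(self.p_exact * (1 - self.p_exact) / self.reps))


def swimbladder_ratio(
    count_no_sb: float, count_sb: float, cfg: RatioConfig = RatioConfig()
) -> float:
    """Pseudocount ratio of swimbladderless to swimbladdered prey counts.

    Returns ``(count_no_sb + offset) / (count_sb + offset)``; always finite
    and positive.  Counts may be rational (post replicate averaging).
    """
    if count_no_sb < 0 or count_sb < 0:
        raise ValueError("counts must be non-negative")
    return (count_no_sb + cfg.offset) / (count_sb + cfg.offset)


def _split_by_swimbladder(
    pooled: Mapping[tuple[str, str], float], universe: FamilyUniverse, mode: str
) -> tuple[float, float]:
    no_sb = sb = 0.0
    for (family, m), count in pooled.items():
        if m != mode:
            continue
        try:
            has_sb = universe.has_swimbladder(family)
        except KeyError:
            raise MissingAnnotationError(
                f"family {family!r} has no swimbladder annotation"
            ) from None
        if has_sb:
            sb += count
        else:
            no_sb += count
    return no_sb, sb


def transect_ratio_pairs(
    table: AbundanceTable,
    universe: FamilyUniverse,
    cfg: RatioConfig = RatioConfig(),
) -> PairedSample:
    """Per-transect swimbladder ratios under sponging vs non-sponging.

    The table must be replicate-averaged and transects-only; every family
    present must be annotated in ``universe``.  Yields one pair per transect
    (7 in the study design); a transect empty in both modes contributes the
    degenerate pair (1.0, 1.0) forced by the pseudocount.
    """
    cells = table.cells
    values_a: list[float] = []
    values_b: list[float] = []
    transects = table.transect_ids()
    for tid in transects:
        sub = cells[cells["transect_id"] == tid]
        pooled = {
            (row.family, row.mode): row.count for row in sub.itertuples(index=False)
        }
        a_no, a_sb = _split_by_swimbladder(pooled, universe, "sponging")
        b_no, b_sb = _split_by_swimbladder(pooled, universe, "non_sponging")
        values_a.append(swimbladder_ratio(a_no, a_sb, cfg))
        values_b.append(swimbladder_ratio(b_no, b_sb, cfg))
    return PairedSample(tuple(transects), tuple(values_a), tuple(values_b))


def extracted_family_abundance_pairs(table: AbundanceTable) -> PairedSample:
    """Per-transect abundance of the sponging-extracted family set.

    Restricts to families with nonzero total sponging abundance, then sums,
    per transect, the sponging abundance (values_a) and the non-sponging
    abundance of the *same* family set (values_b).  Families never extracted
    during sponging are excluded even if abundant during non-sponging.
    """
    cells = table.cells
    sponging_totals = (
        cells[cells["mode"] == "sponging"].groupby("family")["count"].sum()
    )
    family_set = set(sponging_totals[sponging_totals > 0].index)
    transects = table.transect_ids()
    values_a: list[float] = []
    values_b: list[float] = []
    for tid in transects:
        sub = cells[(cells["transect_id"] == tid) & cells["family"].isin(family_set)]
        values_a.append(float(sub.loc[sub["mode"] == "sponging", "count"].sum()))
        values_b.append(float(sub.loc[sub["mode"] == "non_sponging", "count"].sum()))
    return PairedSample(tuple(transects), tuple(values_a), tuple(values_b))


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of sign vectors per value of 2*W', by polynomial convolution.

    ``ranks2`` holds doubled midranks (integers).  Entry ``c[s]`` of the
    result is the number of the 2^n sign assignments whose positive-rank sum
    equals ``s/2``.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(
    pairs: PairedSample, *, enumeration_cap: int = ENUMERATION_CAP
) -> WilcoxonResult:
    """Exact paired Wilcoxon signed-rank test by sign-vector enumeration.

    Differences ``d_i = a_i - b_i``; zero differences are dropped; |d| is
    ranked with midranks for ties; W is the rank sum over positive d.  The
    exact two-sided p enumerates all ``2^n`` sign assignments and doubles
    the smaller tail, capped at 1:  ``p = min(1, 2 * min(Pr(W' <= W),
    Pr(W' >= W)))``.

    Raises :class:`DegenerateSampleError` when every difference is zero and
    :class:`EnumerationCapError` beyond ``enumeration_cap`` nonzero
    differences (use a large-sample method instead; none is provided here).
    """
    d = pairs.differences()
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    if n > enumeration_cap:
        raise EnumerationCapError(
            f"n_effective={n} exceeds the exact-enumeration cap "
            f"({enumeration_cap}); this package provides no large-sample "
            "approximation — reduce the sample or raise the cap explicitly"
        )
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w = float(ranks[d > 0].sum())
    # Doubled ranks are exact integers, so the null distribution of 2W' is a
    # lattice distribution computable by convolution over rank polynomials.
    ranks2 = np.rint(2 * ranks).astype(np.int64)
    counts = _signed_rank_distribution(ranks2)
    w2 = int(round(2 * w))
    denom = float(2**n)
    p_lower = counts[: w2 + 1].sum() / denom
    p_upper = counts[w2:].sum() / denom
    p = float(min(1.0, 2.0 * min(p_lower, p_upper)))
    return WilcoxonResult(w_statistic=w, p_two_sided=p, n_effective=n)


def exact_binomial_twotail(
    universe_size: int,
    k_no_sb: int,
    n_draw: int,
    observed: int,
    *,
    two_tail_mode: TwoTailMode = "deviation",
) -> float:
    """Exact two-tailed tail probability for the family-resampling null.

    Drawing ``n_draw`` families uniformly with replacement from a universe
    of ``universe_size`` families of which ``k_no_sb`` lack swimbladders
    makes the swimbladderless count X ~ Binomial(n_draw, k/N).  Under the
    ``deviation`` rule the p-value sums the mass of every x with
    ``|x - E[X]| >= |observed - E[X]|``; under ``doubling`` it is twice the
    smaller of the two tails at ``observed``, capped at 1.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if not 0 <= k_no_sb <= universe_size:
        raise ValueError("k_no_sb must be in [0, universe_size]")
    if not 0 <= observed <= n_draw:
        raise ValueError("observed must be in [0, n_draw]")
    dist = sps.binom(n_draw, k_no_sb / universe_size)
    if two_tail_mode == "doubling":
        p = 2.0 * min(dist.cdf(observed), dist.sf(observed - 1))
        return float(min(1.0, p))
    if two_tail_mode != "deviation":
        raise ValueError(f"unknown two_tail_mode {two_tail_mode!r}")
    # integer-scaled deviations avoid float ties: |x*N - m*k| vs |obs*N - m*k|
    x = np.arange(n_draw + 1)
    dev = np.abs(x * universe_size - n_draw * k_no_sb)
    dev_obs = abs(observed * universe_size - n_draw * k_no_sb)
    p = dist.pmf(x)[dev >= dev_obs].sum()
    return float(min(1.0, p))


def family_resampling_test(
    universe: FamilyUniverse,
    n_draw: int,
    observed_no_sb: int,
    reps: int = 10_000,
    seed: int = 0,
    *,
    two_tail_mode: TwoTailMode = "deviation",
) -> ResamplingResult:
    """Monte Carlo two-tailed test of the swimbladderless-family count.

    Each of ``reps`` resamples draws ``n_draw`` families uniformly with
    replacement from ``universe`` and counts how many lack swimbladders;
    ``p_mc`` is the proportion of resamples at least as extreme as
    ``observed_no_sb`` (extremeness per ``two_tail_mode``, measured against
    the null expectation ``n_draw * k / N``).  The analytic binomial tail
    ``p_exact`` is computed alongside as a cross-check.  Deterministic for
    a given seed.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if universe.size == 0:
        raise ValueError("universe must be non-empty")
    if not 0 <= observed_no_sb <= n_draw:
        raise ValueError("observed_no_sb must be in [0, n_draw]")
    n_u = universe.size
    k = universe.n_no_swimbladder
    no_sb_mask = np.array(
        [not universe.has_swimbladder(f) for f in universe.families], dtype=bool
    )
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_u, size=(reps, n_draw))
    x = no_sb_mask[draws].sum(axis=1)
    if two_tail_mode == "doubling":
        p_lo = float(np.mean(x <= observed_no_sb))
        p_hi = float(np.mean(x >= observed_no_sb))
        p_mc = min(1.0, 2.0 * min(p_lo, p_hi))
    elif two_tail_mode == "deviation":
        dev = np.abs(x * n_u - n_draw * k)
        dev_obs = abs(observed_no_sb * n_u - n_draw * k)
        p_mc = float(np.mean(dev >= dev_obs))
    else:
        raise ValueError(f"unknown two_tail_mode {two_tail_mode!r}")
    p_exact = exact_binomial_twotail(
        n_u, k, n_draw, observed_no_sb, two_tail_mode=two_tail_mode
    )
    return ResamplingResult(
        p_mc=p_mc,
        p_exact=p_exact,
        reps=reps,
        n_draw=n_draw,
        observed_no_sb=observed_no_sb,
        universe_size=n_u,
        k_no_sb=k,
        seed=seed,
        two_tail_mode=two_tail_mode,
    )


def observed_sponging_families(
    pooled: Mapping[tuple[str, str], float], universe: FamilyUniverse
) -> tuple[int, int]:
    """Count families extracted during sponging, and those lacking swimbladders.

    Returns ``(n_families, n_no_swimbladder)`` over the families with
    nonzero pooled sponging abundance — the observed statistic fed to the
    family-resampling test (8 families, 6 swimbladderless, in the study
    data).
    """
    extracted = {
        family
        for (family, mode), count in pooled.items()
        if mode == "sponging" and count > 0
    }
    missing = [f for f in extracted if f not in universe]
    if missing:
        raise MissingAnnotationError(
            f"families without swimbladder annotation: {sorted(missing)}"
        )
    n_no_sb = sum(1 for f in extracted if not universe.has_swimbladder(f))
    return len(extracted), n_no_sb
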