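"""Differential W(A+T)/A/T profiles between two nucleosome populations.

The sign convention is fixed: delta = reference minus comparison (e.g. the
wild-type population minus a tailless-histone population), per 1-based
nucleosome position 1..147.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .profiles import MONO_LEN, PROFILE_HALF_SPAN, PositionalProfile, SHLMap

logger = logging.getLogger(__name__)

#: default baseline regions (1-based inclusive), flanking the known
#: tail-contact window around position 30-34 and bounded by the dyad
DEFAULT_BASELINE_REGIONS: tuple[tuple[int, int], ...] = ((10, 29), (35, 74))


@dataclass
class DifferentialProfile:
    """Per-position frequency difference between two populations.

    ``delta[i]`` corresponds to 1-based position ``i + 1``.
    """

    delta: np.ndarray
    motif: str
    reference_label: str = "ref"
    comparison_label: str = "cmp"
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    baseline_regions: tuple[tuple[int, int], ...] = ()
    pvalues: np.ndarray | None = None

    @property
    def positions_1based(self) -> np.ndarray:
        return np.arange(1, len(self.delta) + 1)


def delta_profile(
    profile_ref: PositionalProfile,
    profile_cmp: PositionalProfile,
    reference_label: str = "ref",
    comparison_label: str = "cmp",
) -> DifferentialProfile:
    """Element-wise reference-minus-comparison frequency difference."""
    if profile_ref.motif != profile_cmp.motif:
        raise ConfigurationError(
            f"motif mismatch: {profile_ref.motif} vs {profile_cmp.motif}"
        )
    if not profile_ref.same_state(profile_cmp):
        raise ConfigurationError(
            "profiles must share kind and smoothing/symmetrization state"
        )
    return DifferentialProfile(
        delta=profile_ref.values - profile_cmp.values,
        motif=profile_ref.motif,
        reference_label=reference_label,
        comparison_label=comparison_label,
    )


def _region_indices(
    regions: tuple[tuple[int, int], ...], n: int
) -> np.ndarray:
    idx: list[int] = []
    for lo, hi in regions:
        if not (1 <= lo <= hi <= n):
            raise ConfigurationError(f"region {lo}-{hi} outside 1..{n}")
        idx.extend(range(lo - 1, hi))
    if not idx:
        raise ConfigurationError("empty region union")
    return np.unique(idx)


def baseline_stats(
    diff: DifferentialProfile,
    regions: tuple[tuple[int, int], ...] = DEFAULT_BASELINE_REGIONS,
) -> tuple[float, float]:
    """Mean and population standard deviation of delta over the region union.

    Regions are 1-based inclusive intervals; the result is stored on the
    profile and returned.
    """
    idx = _region_indices(tuple(tuple(r) for r in regions), len(diff.delta))
    vals = diff.delta[idx]
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population sd, ddof=0
    diff.baseline_mean = mean
    diff.baseline_sd = sd
    diff.baseline_regions = tuple(tuple(r) for r in regions)
    return mean, sd


def two_proportion_z(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled two-proportion z statistic and two-sided p-value, vectorized.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with the pooled
    phat = (k1 + k2)/(n1 + n2).  Positions with zero coverage in either
    population, or a degenerate pooled proportion, get z = 0, p = 1.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 > 0) & (n2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, k1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(ok, k2 / np.maximum(n2, 1), 0.0)
        pooled = np.where(ok, (k1 + k2) / np.maximum(n1 + n2, 1), 0.0)
        se = np.sqrt(pooled * (1 - pooled) * (1 / np.maximum(n1, 1) + 1 / np.maximum(n2, 1)))
        z = np.where(ok & (se > 0), (p1 - p2) / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(ok & (se > 0), p, 1.0)
    return z, p


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ConfigurationError(f"unknown adjustment {method!r}")


def positionwise_significance(
    counts_ref: np.ndarray,
    coverage_ref: np.ndarray,
    counts_cmp: np.ndarray,
    coverage_cmp: np.ndarray,
    method: str = "bonferroni",
) -> np.ndarray:
    """Adjusted p-value per position from a two-proportion z-test.

    Operates on raw (unsmoothed, unsymmetrized) per-position numerators and
    denominators so the binomial model stays valid.  Zero-coverage positions
    are recorded as p = 1 and logged.
    """
    shapes = {len(counts_ref), len(coverage_ref), len(counts_cmp), len(coverage_cmp)}
    if len(shapes) != 1:
        raise ConfigurationError("count/coverage vectors must share length")
    _, p = two_proportion_z(counts_ref, coverage_ref, counts_cmp, coverage_cmp)
    zero = (np.asarray(coverage_ref) == 0) | (np.asarray(coverage_cmp) == 0)
    if zero.any():
        logger.warning("%d positions with zero coverage; p set to 1", int(zero.sum()))
    return _adjust(p, method)


def antiphase_correlation(
    diff: DifferentialProfile,
    w_profile: PositionalProfile,
    rel_range: tuple[int, int] | None = None,
    shl_map: SHLMap | None = None,
) -> float:
    """Pearson correlation between a delta profile and the W(A+T) profile.

    Default range is the central SHL -2.5..+2.5 region.  A negative value is
    the counterphase signature (delta peaks where W dips).  Returns NaN when
    either vector is constant over the range.
    """
    if not (w_profile.smoothed and w_profile.symmetrized):
        raise ConfigurationError("expected a smoothed, symmetrized W profile")
    if len(diff.delta) != len(w_profile.values):
        raise ConfigurationError("profile lengths differ")
    shl_map = shl_map or SHLMap()
    if rel_range is None:
        rel_range = (shl_map.position_of(-2.5), shl_map.position_of(2.5))
    lo, hi = rel_range
    sl = slice(lo + PROFILE_HALF_SPAN, hi + PROFILE_HALF_SPAN + 1)
    x = diff.delta[sl]
    y = w_profile.values[sl]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector over range; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def differential_to_tsv(diff: DifferentialProfile, path, alpha: float = 0.05) -> None:
    """Columns: position, delta, adjusted p, significance flag."""
    with open(path, "w") as fh:
        fh.write("position\tdelta\tp_adjusted\tsignificant\n")
        for i, pos in enumerate(diff.positions_1based):
            p = diff.pvalues[i] if diff.pvalues is not None else float("nan")
            sig = int(p < alpha) if diff.pvalues is not None else 0
            fh.write(f"{pos}\t{diff.delta[i]:.6g}\t{p:.6g}\t{sig}\n")
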