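"""Synthetic nucleosome fragment populations with planted, known structure.

Fragments are sampled base-by-base from a position-specific composition
model in the dyad-aligned frame (not cut from a genome), so every planted
parameter -- periodic W modulation phased to half-integer SHLs, localized
off-peak bumps with optional A-over-T bias, strand splits, length jitter,
occurrence counts and inter-population 10n / 10n+5 dyad shifts -- is exact,
analytically known ground truth for the downstream statistics.

Base sampling is independent across positions; WW/SS dinucleotide signals
are induced through the mononucleotide W probabilities, which is a
documented simplification sufficient to drive every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .fragment_io import DyadTable, Fragment, build_dyad_table

logger = logging.getLogger(__name__)

_EPS = 1e-6
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Bump:
    """Gaussian W-enrichment bump mirrored at +/-``shl`` (single bump at SHL 0).

    ``width`` is the Gaussian standard deviation in bp; ``a_over_t_bias`` is
    the fraction of the bump's extra W probability assigned to A on the
    negative-SHL side (1.0 plants an adenine-only enrichment there).  The
    mirrored copy at +SHL uses the complementary split (A at -SHL maps to T
    at +SHL on the reference-forward strand), keeping the planted structure
    invariant under the nucleosome's two-fold dyad symmetry.
    """

    shl: float
    height: float
    width: float = 3.0
    a_over_t_bias: float = 0.5


@dataclass(frozen=True)
class CompositionModel:
    """Position-specific base composition in the dyad-aligned frame.

    P(W at rel position x) = clip(w_baseline
                                  + periodic_amplitude * cos(2 pi x / period + phi)
                                  + sum of bumps(x), eps, 1 - eps)
    with phi chosen so the W maxima sit at half-integer SHLs (minor-groove
    bending sites); ``phase_flip`` shifts phi by half a period, moving the
    maxima to integer SHLs (the anti-WW/SS setting).  ``end_bias`` is an
    optional (k, delta) pair adding delta to P(W) in the terminal k bp.
    """

    w_baseline: float = 0.5
    periodic_amplitude: float = 0.0
    period: float = 10.4
    offpeak_bumps: tuple[Bump, ...] = ()
    at_split: float = 0.5
    gc_split: float = 0.5
    phase_flip: bool = False
    end_bias: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.w_baseline < 1:
            raise ConfigurationError("w_baseline must be in (0, 1)")
        if self.periodic_amplitude < 0:
            raise ConfigurationError("periodic_amplitude must be >= 0")
        for s in (self.at_split, self.gc_split):
            if not 0 <= s <= 1:
                raise ConfigurationError("at_split/gc_split must be in [0, 1]")


def build_probability_matrix(
    model: CompositionModel, length: int
) -> np.ndarray:
    """Per-position base-probability matrix, shape (length, 4), columns ACGT.

    Rows sum to 1.  Probabilities escaping [eps, 1-eps] before clipping are
    counted and logged as a warning.
    """
    if length < 1:
        raise ConfigurationError("length must be positive")
    local_dyad = (length - 1) // 2
    rel = np.arange(length, dtype=float) - local_dyad

    # -cos(...) has maxima at half-integer SHLs; phase_flip adds half a period
    phase = 0.0 if model.phase_flip else np.pi
    p_w_base = model.w_baseline + model.periodic_amplitude * np.cos(
        2 * np.pi * rel / model.period + phase
    )
    if model.end_bias is not None:
        k, delta = model.end_bias
        k = min(int(k), length)
        p_w_base = p_w_base.copy()
        p_w_base[:k] += delta
        p_w_base[length - k :] += delta

    bump_total = np.zeros(length)
    bump_a = np.zeros(length)  # A-assigned share of the bump mass
    for bump in model.offpeak_bumps:
        if bump.shl == 0:
            centers = [(0.0, bump.a_over_t_bias)]
        else:
            # two-fold dyad symmetry: the +SHL mirror carries the
            # complementary A/T split on the reference-forward strand
            mag = abs(bump.shl)
            centers = [(-mag, bump.a_over_t_bias), (mag, 1.0 - bump.a_over_t_bias)]
        for shl, a_bias in centers:
            c = shl * model.period
            g = bump.height * np.exp(-((rel - c) ** 2) / (2 * bump.width**2))
            bump_total += g
            bump_a += g * a_bias

    p_w_raw = p_w_base + bump_total
    escaped = int(np.sum((p_w_raw < _EPS) | (p_w_raw > 1 - _EPS)))
    if escaped:
        logger.warning("%d positions clipped to [%g, %g]", escaped, _EPS, 1 - _EPS)
    p_w = np.clip(p_w_raw, _EPS, 1 - _EPS)

    # split W into A/T: baseline mass by at_split, bump mass by its own bias
    w_a_mass = np.clip(p_w_base, 0, None) * model.at_split + bump_a
    w_mass = np.clip(p_w_base, 0, None) + bump_total
    frac_a = np.where(w_mass > 0, w_a_mass / np.maximum(w_mass, _EPS), model.at_split)
    p_a = p_w * np.clip(frac_a, 0, 1)
    p_t = p_w - p_a
    p_s = 1.0 - p_w
    p_g = p_s * model.gc_split
    p_c = p_s - p_g

    matrix = np.stack([p_a, p_c, p_g, p_t], axis=1)
    assert np.allclose(matrix.sum(axis=1), 1.0)
    return matrix


@dataclass(frozen=True)
class OccurrenceLaw:
    """Occurrence count per dyad site: fixed value or rounded lognormal."""

    law: str = "fixed"  # fixed | lognormal
    value: int = 1
    mu: float = 0.0
    sigma: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.law == "fixed":
            return np.full(n, int(self.value), dtype=np.int64)
        if self.law == "lognormal":
            occ = np.maximum(1, np.round(rng.lognormal(self.mu, self.sigma, n)))
            return occ.astype(np.int64)
        raise ConfigurationError(f"unknown occurrence law {self.law!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to draw one synthetic nucleosome population."""

    n_positions: int
    composition: CompositionModel = field(default_factory=CompositionModel)
    occurrence: OccurrenceLaw = field(default_factory=OccurrenceLaw)
    contig: str = "chrS"
    contig_length: int = 1_000_000
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: {147: 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ConfigurationError("n_positions must be >= 1")
        if self.contig_length < 2 * 74 + 2:
            raise DataError("contig too short for any dyad site")
        for length in self.length_weights:
            if not 100 <= length <= 200:
                raise ConfigurationError(f"unsupported fragment length {length}")


@dataclass
class SyntheticPopulation:
    fragments: list[Fragment]
    dyad_table: DyadTable
    dyad_sites: np.ndarray
    occurrences: np.ndarray
    spec: PopulationSpec
    truth: dict


def _site_bounds(spec: PopulationSpec) -> tuple[int, int]:
    # dyad at least 74 bp from either contig end (covers lengths up to 149)
    return 74, spec.contig_length - 75


def _draw_distinct_sites(
    rng: np.random.Generator, lo: int, hi: int, n: int
) -> np.ndarray:
    """n distinct integers in [lo, hi] without materializing the range."""
    n_valid = hi - lo + 1
    if n > n_valid:
        raise DataError(f"cannot draw {n} distinct sites from {n_valid} candidates")
    if n_valid <= 4 * n:  # dense case: permutation is cheap enough
        return np.sort(rng.permutation(n_valid)[:n] + lo)
    chosen = np.unique(rng.integers(lo, hi + 1, size=int(n * 1.2) + 10))
    while len(chosen) < n:
        extra = rng.integers(lo, hi + 1, size=n)
        chosen = np.unique(np.concatenate([chosen, extra]))
    # unbiased subset of the unique draws
    keep = np.sort(rng.choice(len(chosen), size=n, replace=False))
    return chosen[keep]


def _sample_sequences(
    matrix: np.ndarray, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw n sequences from a (L, 4) probability matrix, one base per column."""
    length = matrix.shape[0]
    cum = np.cumsum(matrix, axis=1)[:, :3]  # (L, 3)
    u = rng.random((n, length))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)
    raw = _BASE_BYTES[codes]
    return [row.tobytes().decode("ascii") for row in raw]


def _materialize(
    sites: np.ndarray,
    occurrences: np.ndarray,
    composition: CompositionModel,
    spec: PopulationSpec,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Expand (site, occurrence) into sequenced fragments with length jitter."""
    lengths = np.array(sorted(spec.length_weights), dtype=np.int64)
    weights = np.array([spec.length_weights[l] for l in lengths], dtype=float)
    weights = weights / weights.sum()

    frag_sites = np.repeat(sites, occurrences)
    frag_lengths = rng.choice(lengths, size=len(frag_sites), p=weights)

    fragments: list[Fragment] = [None] * len(frag_sites)  # type: ignore[list-item]
    for length in lengths:
        sel = np.flatnonzero(frag_lengths == length)
        if len(sel) == 0:
            continue
        matrix = build_probability_matrix(composition, int(length))
        seqs = _sample_sequences(matrix, len(sel), rng)
        local_dyad = (int(length) - 1) // 2
        for k, seq in zip(sel, seqs):
            start = int(frag_sites[k]) - local_dyad
            fragments[k] = Fragment(
                spec.contig,
                start,
                start + int(length),
                strand="+",
                sequence=seq,
                name=f"frag{k}",
            )
    return fragments


def sample_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Draw dyad sites, occurrences and fragment sequences for one population.

    The seed fully determines the output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = _site_bounds(spec)
    n_valid = hi - lo + 1
    if spec.n_positions > n_valid:
        raise DataError(
            f"contig of length {spec.contig_length} holds at most "
            f"{n_valid} distinct dyad sites"
        )
    sites = _draw_distinct_sites(rng, lo, hi, spec.n_positions)
    occurrences = spec.occurrence.draw(spec.n_positions, rng)
    fragments = _materialize(sites, occurrences, spec.composition, spec, rng)
    table = build_dyad_table(fragments)
    truth = {
        "kind": "population",
        "seed": spec.seed,
        "n_positions": int(spec.n_positions),
        "n_fragments": int(occurrences.sum()),
        "contig": spec.contig,
        "contig_length": int(spec.contig_length),
        "length_weights": {int(k): float(v) for k, v in spec.length_weights.items()},
        "composition": _composition_dict(spec.composition),
        "dyad_sites": [int(s) for s in sites],
        "occurrences": [int(o) for o in occurrences],
    }
    return SyntheticPopulation(fragments, table, sites, occurrences, spec, truth)


@dataclass(frozen=True)
class ShiftSpec:
    """How a second population's dyads move relative to the first.

    Each dyad site is independently left unmoved, shifted by 10n bp
    (in-phase, rotational setting preserved) or by 10n + 5 bp (counterphase,
    rotational setting inverted); n is drawn from ``shift_ns`` and the sign
    is random.  The three fractions must sum to 1.
    """

    unmoved_fraction: float = 0.0
    inphase_fraction: float = 1.0
    counterphase_fraction: float = 0.0
    shift_ns: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    seed: int = 1

    def __post_init__(self) -> None:
        total = self.unmoved_fraction + self.inphase_fraction + self.counterphase_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("shift fractions must sum to 1")
        for frac in (
            self.unmoved_fraction,
            self.inphase_fraction,
            self.counterphase_fraction,
        ):
            if frac < 0:
                raise ConfigurationError("shift fractions must be non-negative")


def make_shifted_population(
    base: SyntheticPopulation,
    shifts: ShiftSpec,
    composition_override: CompositionModel | None = None,
) -> SyntheticPopulation:
    """Derive a second population by shifting the base population's dyads.

    Fragment sequences are resampled in the new dyad frame under the base
    composition (or ``composition_override``, e.g. bump-removed or
    phase-flipped).  A shift that would push a site off-contig is redrawn
    and logged.  The truth record stores the per-site shift.
    """
    rng = np.random.default_rng(shifts.seed)
    spec = base.spec
    lo, hi = _site_bounds(spec)
    ns = np.array(sorted(shifts.shift_ns), dtype=np.int64)
    n_weights = np.array([shifts.shift_ns[n] for n in ns], dtype=float)
    n_weights = n_weights / n_weights.sum()

    categories = rng.choice(
        3,
        size=len(base.dyad_sites),
        p=[
            shifts.unmoved_fraction,
            shifts.inphase_fraction,
            shifts.counterphase_fraction,
        ],
    )
    new_sites = np.empty_like(base.dyad_sites)
    applied_shifts = np.zeros(len(base.dyad_sites), dtype=np.int64)
    redrawn = 0
    for i, (site, cat) in enumerate(zip(base.dyad_sites, categories)):
        for _attempt in range(1000):
            if cat == 0:
                shift = 0
            else:
                n = int(rng.choice(ns, p=n_weights))
                magnitude = 10 * n + (5 if cat == 2 else 0)
                shift = int(rng.choice([-1, 1])) * magnitude
            if lo <= site + shift <= hi:
                break
            redrawn += 1
        else:
            shift = 0
        new_sites[i] = site + shift
        applied_shifts[i] = shift
    if redrawn:
        logger.info("redrew %d off-contig shifts", redrawn)

    composition = composition_override or spec.composition
    fragments = _materialize(new_sites, base.occurrences, composition, spec, rng)
    table = build_dyad_table(fragments)
    truth = {
        "kind": "shifted_population",
        "seed": shifts.seed,
        "base_seed": spec.seed,
        "fractions": {
            "unmoved": shifts.unmoved_fraction,
            "inphase": shifts.inphase_fraction,
            "counterphase": shifts.counterphase_fraction,
        },
        "composition": _composition_dict(composition),
        "dyad_sites": [int(s) for s in new_sites],
        "occurrences": [int(o) for o in base.occurrences],
        "site_shifts": [int(s) for s in applied_shifts],
        "site_categories": [
            ["unmoved", "inphase", "counterphase"][c] for c in categories
        ],
    }
    derived_spec = replace(spec, composition=composition, seed=shifts.seed)
    return SyntheticPopulation(
        fragments, table, new_sites, base.occurrences.copy(), derived_spec, truth
    )


def _composition_dict(model: CompositionModel) -> dict:
    return {
        "w_baseline": model.w_baseline,
        "periodic_amplitude": model.periodic_amplitude,
        "period": model.period,
        "at_split": model.at_split,
        "gc_split": model.gc_split,
        "phase_flip": model.phase_flip,
        "end_bias": list(model.end_bias) if model.end_bias else None,
        "offpeak_bumps": [
            {
                "shl": b.shl,
                "height": b.height,
                "width": b.width,
                "a_over_t_bias": b.a_over_t_bias,
            }
            for b in model.offpeak_bumps
        ],
    }


def composition_from_dict(d: Mapping) -> CompositionModel:
    bumps = tuple(
        Bump(
            shl=float(b["shl"]),
            height=float(b["height"]),
            width=float(b.get("width", 3.0)),
            a_over_t_bias=float(b.get("a_over_t_bias", 0.5)),
        )
        for b in d.get("offpeak_bumps", [])
    )
    end_bias = d.get("end_bias")
    return CompositionModel(
        w_baseline=float(d.get("w_baseline", 0.5)),
        periodic_amplitude=float(d.get("periodic_amplitude", 0.0)),
        period=float(d.get("period", 10.4)),
        offpeak_bumps=bumps,
        at_split=float(d.get("at_split", 0.5)),
        gc_split=float(d.get("gc_split", 0.5)),
        phase_flip=bool(d.get("phase_flip", False)),
        end_bias=(int(end_bias[0]), float(end_bias[1])) if end_bias else None,
    )
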