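"""Dyad-aligned positional nucleotide and dinucleotide frequency profiles.

Profiles are indexed by dyad-relative position: -73..+73 for mononucleotides
(147 entries) and -73..+72 for dinucleotide start positions (146 entries).
User-facing reports use 1-based nucleosome positions 1..147 with the dyad at
position 74.  Fragments longer than 147 bp contribute only to the positions
they cover in the dyad frame (coverage-weighted denominators); bases/dimers
containing N are excluded from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .fragment_io import Fragment

logger = logging.getLogger(__name__)

PROFILE_HALF_SPAN = 73  # dyad-relative extent of the canonical 147-bp frame
MONO_LEN = 2 * PROFILE_HALF_SPAN + 1  # 147
DI_LEN = MONO_LEN - 1  # 146

WW_SET = frozenset({"AA", "AT", "TA", "TT"})
SS_SET = frozenset({"GG", "GC", "CG", "CC"})

# byte-code lookup: A,C,G,T -> 0..3, anything else -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class PositionalProfile:
    """Per-dyad-relative-position frequency vector for one motif class.

    ``values[i] == counts[i] / coverage[i]`` before smoothing/symmetrization;
    positions with zero coverage carry value NaN.
    """

    motif: str
    kind: str  # "mono" or "di"
    values: np.ndarray
    counts: np.ndarray
    coverage: np.ndarray
    smoothed: bool = False
    symmetrized: bool = False

    def __post_init__(self) -> None:
        expected = MONO_LEN if self.kind == "mono" else DI_LEN
        if len(self.values) != expected:
            raise ConfigurationError(
                f"{self.kind} profile must have {expected} entries, "
                f"got {len(self.values)}"
            )

    @property
    def rel_positions(self) -> np.ndarray:
        """Dyad-relative positions (mono: -73..73; di: start -73..72)."""
        return np.arange(len(self.values)) - PROFILE_HALF_SPAN

    @property
    def positions_1based(self) -> np.ndarray:
        """1-based nucleosome positions (dyad at 74)."""
        return self.rel_positions + PROFILE_HALF_SPAN + 1

    def same_state(self, other: "PositionalProfile") -> bool:
        return (
            self.kind == other.kind
            and self.smoothed == other.smoothed
            and self.symmetrized == other.symmetrized
        )


@dataclass(frozen=True)
class SHLMap:
    """Superhelix-location coordinate system around the dyad (SHL 0).

    Minor-groove bending sites sit at half-integer SHLs, major-groove sites
    at integer SHLs; one helical turn spans ``period`` bp (default 10.4).
    """

    period: float = 10.4

    def shl_of(self, position: float) -> float:
        """SHL of a dyad-relative position."""
        return position / self.period

    def position_of(self, shl: float) -> int:
        """Dyad-relative position of an SHL (round half away from zero)."""
        x = shl * self.period
        return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class OffPeak:
    """One off-peak call: present iff a strict interior local maximum exists
    in the search window with positive amplitude above baseline."""

    name: str
    window: tuple[int, int]  # 1-based inclusive
    position_1based: int | None
    amplitude: float
    a_minus_t: float | None = None

    @property
    def present(self) -> bool:
        return self.position_1based is not None and self.amplitude > 0


@dataclass
class OffPeakReport:
    p1: OffPeak
    p2: OffPeak


# ---------------------------------------------------------------------------
# counting


def _stack_by_length(fragments: Sequence[Fragment]) -> dict[int, np.ndarray]:
    """Group fragment sequences by length into uint8 code matrices."""
    groups: dict[int, list[str]] = {}
    for frag in fragments:
        if frag.sequence is None:
            raise DataError("fragment without sequence cannot be profiled")
        groups.setdefault(frag.length, []).append(frag.sequence)
    out = {}
    for length, seqs in groups.items():
        raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        out[length] = _CODE[raw].reshape(len(seqs), length)
    return out


def _frame_offsets(length: int) -> tuple[int, int, int]:
    """(profile index of fragment base 0, first valid base, last valid base + 1).

    Fragment base j sits at dyad-relative position j - floor((L-1)/2); only
    positions within -73..+73 land in the profile.
    """
    local_dyad = (length - 1) // 2
    offset = PROFILE_HALF_SPAN - local_dyad  # profile index of fragment base 0
    j_lo = max(0, -offset)
    j_hi = min(length, MONO_LEN - offset)
    return offset, j_lo, j_hi


def mono_profile(
    fragments: Sequence[Fragment], base_set: Iterable[str], motif: str | None = None
) -> PositionalProfile:
    """Frequency of ``base_set`` bases at each dyad-relative position.

    coverage[i] counts fragments with a non-N base at position i; counts[i]
    those whose base there is in ``base_set``.
    """
    fragments = list(fragments)
    if not fragments:
        raise DataError("no fragments")
    base_set = frozenset(b.upper() for b in base_set)
    if not base_set or not base_set <= set("ACGT"):
        raise ConfigurationError(f"invalid base set {sorted(base_set)}")
    is_member = np.zeros(5, dtype=bool)
    for b in base_set:
        is_member[_CODE[ord(b)]] = True

    counts = np.zeros(MONO_LEN, dtype=np.int64)
    coverage = np.zeros(MONO_LEN, dtype=np.int64)
    for length, codes in _stack_by_length(fragments).items():
        offset, j_lo, j_hi = _frame_offsets(length)
        block = codes[:, j_lo:j_hi]
        valid = block < 4
        sl = slice(j_lo + offset, j_hi + offset)
        coverage[sl] += valid.sum(axis=0)
        counts[sl] += (is_member[block] & valid).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(coverage > 0, counts / np.maximum(coverage, 1), np.nan)
    label = motif or "".join(sorted(base_set))
    return PositionalProfile(label, "mono", values, counts, coverage)


def di_profile(
    fragments: Sequence[Fragment], dimer_set: Iterable[str], motif: str | None = None
) -> PositionalProfile:
    """Frequency of ``dimer_set`` dinucleotides starting at each position.

    The dimer at position i spans bases (i, i+1); dimers containing N are
    excluded from numerator and denominator.
    """
    fragments = list(fragments)
    if not fragments:
        raise DataError("no fragments")
    dimer_set = frozenset(d.upper() for d in dimer_set)
    if not dimer_set:
        raise ConfigurationError("empty dimer set")
    for d in dimer_set:
        if len(d) != 2 or not set(d) <= set("ACGT"):
            raise ConfigurationError(f"invalid dimer {d!r}")
    is_member = np.zeros(16, dtype=bool)
    for d in dimer_set:
        is_member[_CODE[ord(d[0])] * 4 + _CODE[ord(d[1])]] = True

    counts = np.zeros(DI_LEN, dtype=np.int64)
    coverage = np.zeros(DI_LEN, dtype=np.int64)
    for length, codes in _stack_by_length(fragments).items():
        offset, j_lo, j_hi = _frame_offsets(length)
        # dimer start j valid while j and j+1 are in-fragment and in-frame
        d_hi = min(length - 1, DI_LEN - offset)
        if d_hi <= j_lo:
            continue
        left = codes[:, j_lo:d_hi]
        right = codes[:, j_lo + 1 : d_hi + 1]
        valid = (left < 4) & (right < 4)
        dimer_idx = (left.astype(np.int16) * 4 + right).clip(0, 15)
        sl = slice(j_lo + offset, d_hi + offset)
        coverage[sl] += valid.sum(axis=0)
        counts[sl] += (is_member[dimer_idx] & valid).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(coverage > 0, counts / np.maximum(coverage, 1), np.nan)
    label = motif or "|".join(sorted(dimer_set))
    return PositionalProfile(label, "di", values, counts, coverage)


def w_profile(fragments: Sequence[Fragment]) -> PositionalProfile:
    """Mononucleotide W(A+T) frequency profile."""
    return mono_profile(fragments, "AT", motif="W")


# ---------------------------------------------------------------------------
# transforms


def smooth3(profile: PositionalProfile) -> PositionalProfile:
    """3-bp running average; the window shrinks at edges and skips
    zero-coverage positions."""
    if profile.smoothed:
        raise ConfigurationError("profile already smoothed")
    v = profile.values
    ok = (profile.coverage > 0) & ~np.isnan(v)
    num = np.where(ok, v, 0.0)
    acc = num.copy()
    cnt = ok.astype(float)
    acc[:-1] += num[1:]
    cnt[:-1] += ok[1:]
    acc[1:] += num[:-1]
    cnt[1:] += ok[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return replace(profile, values=smoothed, smoothed=True)


def _mirror(arr: np.ndarray) -> np.ndarray:
    # mono: rel i <-> -i; di start: rel i <-> -i-1 -- both reverse the array
    return arr[::-1]


def symmetrize(
    profile: PositionalProfile,
    complement_aware: bool = False,
    complement_profile: PositionalProfile | None = None,
) -> PositionalProfile:
    """Average the profile with its mirror image through the dyad.

    For complement-closed motif sets (W, WW, SS, ...) the profile is averaged
    with its own reflection.  With ``complement_aware=True`` a strand-specific
    profile (e.g. A) is averaged with the reflected profile of its complement
    motif (e.g. T), preserving A-vs-T asymmetry.
    """
    if complement_aware:
        if complement_profile is None:
            raise ConfigurationError(
                "complement_aware symmetrization requires the complement profile"
            )
        if not profile.same_state(complement_profile):
            raise ConfigurationError("profiles differ in kind or processing state")
        other = complement_profile
    else:
        other = profile
    values = (profile.values + _mirror(other.values)) / 2.0
    counts = (profile.counts + _mirror(other.counts)) / 2.0
    coverage = (profile.coverage + _mirror(other.coverage)) / 2.0
    return replace(
        profile, values=values, counts=counts, coverage=coverage, symmetrized=True
    )


def strand_asymmetry(
    profile_a: PositionalProfile, profile_t: PositionalProfile
) -> np.ndarray:
    """Element-wise A-minus-T frequency difference per position."""
    if len(profile_a.values) != len(profile_t.values):
        raise ConfigurationError("profile lengths differ")
    if not profile_a.same_state(profile_t):
        raise ConfigurationError("profiles differ in processing state")
    return profile_a.values - profile_t.values


# ---------------------------------------------------------------------------
# off-peak detection


def _interp_baseline(profile: PositionalProfile, x: int, lo: int, hi: int) -> float:
    idx = lambda rel: rel + PROFILE_HALF_SPAN  # noqa: E731
    v_lo = profile.values[idx(lo)]
    v_hi = profile.values[idx(hi)]
    t = (x - lo) / (hi - lo)
    return float(v_lo + t * (v_hi - v_lo))


def _call_off_peak(
    profile: PositionalProfile,
    shl_map: SHLMap,
    shl_center: float,
    window: int,
    asym: np.ndarray | None,
) -> tuple[int | None, float, float | None, tuple[int, int]]:
    center = shl_map.position_of(shl_center)
    lo_rel = max(-PROFILE_HALF_SPAN + 1, center - window)
    hi_rel = min(PROFILE_HALF_SPAN - 1, center + window)
    flank_lo = shl_map.position_of(shl_center - 1)
    flank_hi = shl_map.position_of(shl_center + 1)
    v = profile.values
    best_pos, best_amp = None, 0.0
    for rel in range(lo_rel, hi_rel + 1):
        i = rel + PROFILE_HALF_SPAN
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):  # strict interior local max
            continue
        amp = float(v[i]) - _interp_baseline(profile, rel, flank_lo, flank_hi)
        if best_pos is None or amp > best_amp:
            best_pos, best_amp = rel, amp
    a_minus_t = None
    if best_pos is not None and asym is not None:
        a_minus_t = float(asym[best_pos + PROFILE_HALF_SPAN])
    window_1based = (lo_rel + PROFILE_HALF_SPAN + 1, hi_rel + PROFILE_HALF_SPAN + 1)
    pos_1based = None if best_pos is None else best_pos + PROFILE_HALF_SPAN + 1
    return pos_1based, best_amp, a_minus_t, window_1based


def detect_off_peaks(
    profile: PositionalProfile,
    shl_map: SHLMap | None = None,
    window: int = 3,
    profile_a: PositionalProfile | None = None,
    profile_t: PositionalProfile | None = None,
) -> OffPeakReport:
    """Call the P1 (near SHL +/-4) and P2 (near SHL +/-1) off-peaks.

    Within ``position_of(k) +/- window`` the strongest strict interior local
    maximum is reported; its amplitude is measured above the straight line
    between the flanking same-phase canonical sites at SHL k-1 and k+1.
    Amplitude <= 0 (or no interior local maximum) means the off-peak is
    absent.  Both signs of each SHL are searched; the stronger side wins.
    """
    if not (profile.smoothed and profile.symmetrized):
        raise ConfigurationError("off-peak detection expects a smoothed, symmetrized profile")
    if profile.kind != "mono":
        raise ConfigurationError("off-peak detection operates on mononucleotide profiles")
    shl_map = shl_map or SHLMap()
    asym = None
    if profile_a is not None and profile_t is not None:
        asym = strand_asymmetry(profile_a, profile_t)

    peaks = []
    for name, shl in (("P1", 4.0), ("P2", 1.0)):
        candidates = []
        for signed in (-shl, shl):
            pos, amp, am_t, win = _call_off_peak(profile, shl_map, signed, window, asym)
            candidates.append(OffPeak(name, win, pos, amp, am_t))
        present = [c for c in candidates if c.present]
        best = max(present, key=lambda c: c.amplitude) if present else candidates[1]
        peaks.append(best)
    return OffPeakReport(p1=peaks[0], p2=peaks[1])


# ---------------------------------------------------------------------------
# I/O


def profile_to_tsv(
    profile: PositionalProfile, path, shl_map: SHLMap | None = None
) -> None:
    """Columns: 1-based position, dyad-relative position, SHL, frequency,
    counts, coverage, smoothed, symmetrized."""
    shl_map = shl_map or SHLMap()
    with open(path, "w") as fh:
        fh.write(
            "position\trel_position\tshl\tfrequency\tcounts\tcoverage"
            "\tsmoothed\tsymmetrized\n"
        )
        for i, rel in enumerate(profile.rel_positions):
            fh.write(
                f"{rel + PROFILE_HALF_SPAN + 1}\t{rel}\t{shl_map.shl_of(rel):.4f}\t"
                f"{profile.values[i]:.6g}\t{profile.counts[i]:.6g}\t"
                f"{profile.coverage[i]:.6g}\t{int(profile.smoothed)}\t"
                f"{int(profile.symmetrized)}\n"
            )


def profile_from_tsv(path, motif: str, kind: str = "mono") -> PositionalProfile:
    data = np.loadtxt(path, skiprows=1, usecols=(3, 4, 5, 6, 7), ndmin=2)
    return PositionalProfile(
        motif,
        kind,
        values=data[:, 0],
        counts=data[:, 1],
        coverage=data[:, 2],
        smoothed=bool(data[0, 3]),
        symmetrized=bool(data[0, 4]),
    )
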