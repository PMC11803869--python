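import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucpos import (
    ConfigurationError,
    DataError,
    Fragment,
    SHLMap,
    SS_SET,
    WW_SET,
    detect_off_peaks,
    di_profile,
    mono_profile,
    smooth3,
    strand_asymmetry,
    symmetrize,
    w_profile,
)
from nucpos.profiles import MONO_LEN, PROFILE_HALF_SPAN, PositionalProfile

from conftest import random_fragments, revcomp


def _poly(base, n=1, length=147):
    return [Fragment("c", 0, length, sequence=base * length) for _ in range(n)]


# ---------------------------------------------------------------------------
# mono profiles


def test_mono_poly_a_w_profile_is_one():
    prof = mono_profile(_poly("A", 10), "AT")
    assert np.allclose(prof.values, 1.0)
    assert prof.counts.sum() == 10 * 147


def test_mono_mixture_half():
    prof = mono_profile(_poly("A", 5) + _poly("G", 5), "A")
    assert np.allclose(prof.values, 0.5)


def test_mono_matches_bruteforce_tally(rng):
    frags = random_fragments(rng, 200)
    prof = mono_profile(frags, "AT")
    # independent per-position letter tally, pure python
    counts = [0] * MONO_LEN
    coverage = [0] * MONO_LEN
    for frag in frags:
        c = (frag.length - 1) // 2
        for j, base in enumerate(frag.sequence):
            i = j - c + PROFILE_HALF_SPAN
            if 0 <= i < MONO_LEN and base != "N":
                coverage[i] += 1
                if base in "AT":
                    counts[i] += 1
    assert prof.counts.tolist() == counts
    assert prof.coverage.tolist() == coverage


def test_mono_mixed_lengths_coverage(rng):
    frags = random_fragments(rng, 10, length=147) + random_fragments(
        rng, 5, length=149
    )
    prof = mono_profile(frags, "A")
    assert prof.coverage.min() == 15  # 149-mers cover the whole 147 frame
    frags146 = random_fragments(rng, 4, length=146)
    prof2 = mono_profile(frags146, "A")
    assert prof2.coverage[0] == 0  # rel -73 not covered by 146-mers
    assert prof2.coverage[1] == 4


def test_mono_n_excluded():
    seq = "A" * 73 + "N" + "A" * 73
    prof = mono_profile([Fragment("c", 0, 147, sequence=seq)], "A")
    assert prof.coverage[PROFILE_HALF_SPAN] == 0
    assert np.isnan(prof.values[PROFILE_HALF_SPAN])
    assert prof.coverage[0] == 1


def test_mono_empty_errors():
    with pytest.raises(DataError):
        mono_profile([], "A")
    with pytest.raises(ConfigurationError):
        mono_profile(_poly("A"), "X")


def test_base_frequency_closure(rng):
    frags = random_fragments(rng, 300)
    total = sum(mono_profile(frags, b).values for b in "ACGT")
    assert np.allclose(total, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# dinucleotide profiles


def test_di_poly_a_ww_one():
    prof = di_profile(_poly("A", 3), WW_SET)
    assert np.allclose(prof.values, 1.0)


def test_di_poly_g_ss_one_ww_zero():
    assert np.allclose(di_profile(_poly("G", 3), SS_SET).values, 1.0)
    assert np.allclose(di_profile(_poly("G", 3), WW_SET).values, 0.0)


def test_di_alternating_ag_all_zero():
    seq = ("AG" * 74)[:147]
    frags = [Fragment("c", 0, 147, sequence=seq)]
    # every dimer is AG or GA: neither WW nor SS, verified by enumeration
    dimers = {seq[i : i + 2] for i in range(146)}
    assert dimers == {"AG", "GA"}
    assert np.allclose(di_profile(frags, WW_SET).values, 0.0)
    assert np.allclose(di_profile(frags, SS_SET).values, 0.0)


def test_di_closure(rng):
    frags = random_fragments(rng, 200)
    ww = di_profile(frags, WW_SET)
    ss = di_profile(frags, SS_SET)
    mixed = di_profile(
        frags, {"AC", "AG", "TC", "TG", "CA", "GA", "CT", "GT"}
    )
    assert np.allclose(ww.values + ss.values + mixed.values, 1.0, atol=1e-12)


def test_di_empty_set_errors():
    with pytest.raises(ConfigurationError):
        di_profile(_poly("A"), set())


def test_di_matches_bruteforce_tally(rng):
    frags = random_fragments(rng, 100)
    prof = di_profile(frags, WW_SET)
    counts = [0] * (MONO_LEN - 1)
    for frag in frags:
        c = (frag.length - 1) // 2
        for j in range(frag.length - 1):
            i = j - c + PROFILE_HALF_SPAN
            if 0 <= i < MONO_LEN - 1 and frag.sequence[j : j + 2] in WW_SET:
                counts[i] += 1
    assert prof.counts.tolist() == counts


# ---------------------------------------------------------------------------
# smoothing


def _profile_from_values(values, kind="mono", motif="W", **flags):
    values = np.asarray(values, dtype=float)
    return PositionalProfile(
        motif,
        kind,
        values=values,
        counts=(values * 1000).astype(int),
        coverage=np.full(len(values), 1000, dtype=int),
        **flags,
    )


def test_smooth3_constant_invariant():
    prof = _profile_from_values(np.full(MONO_LEN, 0.37))
    assert np.allclose(smooth3(prof).values, 0.37)


def test_smooth3_impulse():
    values = np.zeros(MONO_LEN)
    values[1] = 1.0
    sm = smooth3(_profile_from_values(values)).values
    # hand-computed shrinking-window averages
    assert sm[0] == pytest.approx(0.5)
    assert sm[1] == pytest.approx(1 / 3)
    assert sm[2] == pytest.approx(1 / 3)
    assert np.allclose(sm[3:], 0.0)


def test_smooth3_edge_impulse():
    values = np.zeros(MONO_LEN)
    values[-1] = 1.0
    sm = smooth3(_profile_from_values(values)).values
    assert sm[-1] == pytest.approx(0.5)  # window shrinks to 2 terms at the edge
    assert sm[-2] == pytest.approx(1 / 3)


def test_smooth3_rejects_double_smoothing():
    prof = smooth3(_profile_from_values(np.zeros(MONO_LEN)))
    with pytest.raises(ConfigurationError):
        smooth3(prof)


# ---------------------------------------------------------------------------
# symmetrization


def test_symmetrize_reflection_average():
    values = np.full(MONO_LEN, 0.5)
    x, y = 0.7, 0.1
    values[-50 + PROFILE_HALF_SPAN] = x
    values[50 + PROFILE_HALF_SPAN] = y
    sym = symmetrize(_profile_from_values(values))
    assert sym.values[-50 + PROFILE_HALF_SPAN] == pytest.approx((x + y) / 2)
    assert sym.values[50 + PROFILE_HALF_SPAN] == pytest.approx((x + y) / 2)


def test_symmetrize_idempotent(rng):
    prof = _profile_from_values(rng.random(MONO_LEN))
    once = symmetrize(prof)
    twice = symmetrize(once)
    assert np.allclose(once.values, twice.values)


def test_symmetrize_di_mirror(rng):
    # dinucleotide start mirror: rel i <-> -i-1
    values = np.zeros(MONO_LEN - 1)
    values[10 + PROFILE_HALF_SPAN] = 1.0  # start rel +10
    sym = symmetrize(_profile_from_values(values, kind="di"))
    assert sym.values[-11 + PROFILE_HALF_SPAN] == pytest.approx(0.5)
    assert sym.values[10 + PROFILE_HALF_SPAN] == pytest.approx(0.5)


def test_complement_aware_equals_revcomp_retally(rng):
    """A averaged with mirrored T must equal averaging with the A profile of
    reverse-complemented fragments (exact count identity)."""
    frags = random_fragments(rng, 150)
    prof_a = mono_profile(frags, "A")
    prof_t = mono_profile(frags, "T")
    sym_a = symmetrize(prof_a, complement_aware=True, complement_profile=prof_t)

    rc = [
        Fragment(f.contig, f.start, f.end, sequence=revcomp(f.sequence))
        for f in frags
    ]
    prof_a_rc = mono_profile(rc, "A")
    expected = (prof_a.values + prof_a_rc.values) / 2
    assert np.allclose(sym_a.values, expected, atol=1e-15)


def test_complement_aware_requires_partner():
    prof = _profile_from_values(np.zeros(MONO_LEN))
    with pytest.raises(ConfigurationError):
        symmetrize(prof, complement_aware=True)


def test_smooth_symmetrize_commute(rng):
    prof = _profile_from_values(rng.random(MONO_LEN))
    a = symmetrize(smooth3(prof)).values
    b = smooth3(symmetrize(prof)).values
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# SHL map


def test_shl_dyad():
    m = SHLMap()
    assert m.position_of(0) == 0
    assert m.shl_of(0) == 0.0


def test_shl_minus4_is_position_32():
    m = SHLMap(10.4)
    rel = m.position_of(-4)
    assert rel == -42  # round(-4 * 10.4)
    assert rel + PROFILE_HALF_SPAN + 1 == 32  # 1-based


def test_shl_1p5():
    assert SHLMap(10.4).position_of(1.5) == 16  # round(15.6)
    assert SHLMap(10.4).position_of(-1.5) == -16  # symmetric rounding


def test_shl_roundtrip():
    m = SHLMap(10.4)
    for shl in [-6.5, -4, -1.5, 0, 1, 2.5, 6]:
        assert m.shl_of(m.position_of(shl)) == pytest.approx(shl, abs=0.05)


# ---------------------------------------------------------------------------
# off-peak detection


def _cosine_profile(amplitude, bumps=(), w0=0.25, period=10.4):
    """W-like profile: maxima at half-integer SHLs, plus Gaussian bumps
    given as (rel_center, height, sd)."""
    rel = np.arange(MONO_LEN) - PROFILE_HALF_SPAN
    values = w0 + amplitude * -np.cos(2 * np.pi * rel / period)
    for center, height, sd in bumps:
        values = values + height * np.exp(-((rel - center) ** 2) / (2 * sd**2))
    return _profile_from_values(values, smoothed=True, symmetrized=True)


def test_off_peaks_absent_on_pure_cosine():
    report = detect_off_peaks(_cosine_profile(0.05))
    assert not report.p1.present
    assert not report.p2.present
    assert report.p1.amplitude <= 0
    assert report.p2.amplitude <= 0


@pytest.mark.parametrize("b", [0.01, 0.02])
def test_off_peak_p1_recovers_planted_bump(b):
    # bump at position_of(-4) = -42, mirrored; small cosine so the bump
    # forms a strict interior local maximum
    prof = _cosine_profile(0.004, bumps=[(-42, b, 2.0), (42, b, 2.0)])
    report = detect_off_peaks(prof)
    assert report.p1.present
    assert report.p1.amplitude == pytest.approx(b, rel=0.2)
    assert report.p1.position_1based in (31, 32, 33, 115, 116, 117)


def test_off_peak_p2_only():
    prof = _cosine_profile(0.004, bumps=[(-10, 0.02, 2.0)])  # position_of(-1)
    report = detect_off_peaks(prof)
    assert report.p2.present
    assert not report.p1.present


def test_off_peaks_require_processed_profile():
    with pytest.raises(ConfigurationError):
        detect_off_peaks(_profile_from_values(np.zeros(MONO_LEN)))


# ---------------------------------------------------------------------------
# strand asymmetry


def test_asymmetry_identical_profiles_zero(rng):
    frags = random_fragments(rng, 50)
    a = mono_profile(frags, "A")
    assert np.allclose(strand_asymmetry(a, a), 0.0)


def test_asymmetry_planted_spike(rng):
    frags = random_fragments(rng, 2000)
    # enrich A at rel position +5 (sequence index 78) in every fragment
    frags = [
        Fragment(f.contig, f.start, f.end,
                 sequence=f.sequence[:78] + "A" + f.sequence[79:])
        for f in frags
    ]
    diff = strand_asymmetry(mono_profile(frags, "A"), mono_profile(frags, "T"))
    idx = 5 + PROFILE_HALF_SPAN
    assert diff[idx] == pytest.approx(1.0)
    rest = np.delete(diff, idx)
    assert np.abs(rest).max() < 5 * np.sqrt(0.5 / 2000)


def test_asymmetry_negated_by_revcomp(rng):
    frags = random_fragments(rng, 100)
    diff = strand_asymmetry(mono_profile(frags, "A"), mono_profile(frags, "T"))
    rc = [
        Fragment(f.contig, f.start, f.end, sequence=revcomp(f.sequence))
        for f in frags
    ]
    diff_rc = strand_asymmetry(mono_profile(rc, "A"), mono_profile(rc, "T"))
    assert np.allclose(diff_rc, -diff[::-1], atol=1e-15)


def test_asymmetry_length_mismatch(rng):
    frags = random_fragments(rng, 10)
    a = mono_profile(frags, "A")
    ww = di_profile(frags, WW_SET)
    with pytest.raises(ConfigurationError):
        strand_asymmetry(a, ww)


# ---------------------------------------------------------------------------
# flatness on position-independent composition


def test_flat_profile_within_binomial_error():
    from nucpos import CompositionModel, OccurrenceLaw, PopulationSpec, sample_population

    spec = PopulationSpec(
        n_positions=100,
        occurrence=OccurrenceLaw("fixed", 1000),
        contig_length=100_000,
        composition=CompositionModel(w_baseline=0.5, periodic_amplitude=0.0),
        seed=7,
    )
    pop = sample_population(spec)  # 100,000 fragments, flat composition
    prof = w_profile(pop.fragments)
    se = np.sqrt(0.5 * 0.5 / prof.coverage)
    assert np.max(np.abs(prof.values - 0.5)) < 5 * se.min()
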