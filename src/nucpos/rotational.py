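"""Rotational-setting classification of nucleosome sequences.

Each fragment is scored by the Pearson correlation between its WW-minus-SS
dinucleotide indicator signal and a fixed cosine template whose maxima sit at
the minor-groove bending sites (half-integer SHLs) in the dyad-aligned frame.
Positive scores indicate the canonical WW/SS rotational setting, negative
scores the counter-phased anti-WW/SS setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .fragment_io import Fragment
from .profiles import (
    PositionalProfile,
    _CODE,
    smooth3,
    symmetrize,
    w_profile,
)

logger = logging.getLogger(__name__)

#: dimer codes (4*left + right) for WW = {AA, AT, TA, TT} and SS = {GG, GC, CG, CC}
_WW_CODES = frozenset({0, 3, 12, 15})
_SS_CODES = frozenset({10, 9, 6, 5})

_X_LOOKUP = np.zeros(17, dtype=np.float64)  # index 16 = invalid (contains N)
for _c in _WW_CODES:
    _X_LOOKUP[_c] = 1.0
for _c in _SS_CODES:
    _X_LOOKUP[_c] = -1.0


@dataclass(frozen=True)
class PhaseTemplate:
    """Cosine template with maxima at half-integer SHLs, minima at integer SHLs.

    Evaluated at dinucleotide centres (dyad-relative position + 0.5); the
    support covers |SHL| <= ``max_shl``.
    """

    period: float = 10.4
    max_shl: float = 6.5

    def value(self, rel_center: np.ndarray) -> np.ndarray:
        # maxima where the minor groove faces the octamer (half-integer SHL)
        return -np.cos(2 * np.pi * np.asarray(rel_center, dtype=float) / self.period)

    def support(self, rel_center: np.ndarray) -> np.ndarray:
        return np.abs(rel_center) <= self.max_shl * self.period


@dataclass
class PhaseScore:
    """Normalized phase correlation in [-1, 1] with its label."""

    score: float
    label: str  # canonical | anti | weak
    threshold: float


@dataclass
class PopulationClassification:
    scores: np.ndarray
    labels: list[str]
    threshold: float
    fraction_canonical: float
    fraction_anti: float
    fraction_weak: float
    fraction_canonical_typed: float
    fraction_anti_typed: float
    canonical_profile: PositionalProfile | None = None
    anti_profile: PositionalProfile | None = None

    def summary(self) -> dict:
        return {
            "n_fragments": int(len(self.scores)),
            "threshold": self.threshold,
            "fraction_canonical": self.fraction_canonical,
            "fraction_anti": self.fraction_anti,
            "fraction_weak": self.fraction_weak,
            "fraction_canonical_typed": self.fraction_canonical_typed,
            "fraction_anti_typed": self.fraction_anti_typed,
        }


def _label(score: float, threshold: float) -> str:
    if score > threshold:
        return "canonical"
    if score < -threshold:
        return "anti"
    return "weak"


def _dimer_signal(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x signal, validity mask, dyad-relative dimer centres) for one sequence."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    left, right = codes[:-1], codes[1:]
    valid = (left < 4) & (right < 4)
    dimer = np.where(valid, left.astype(np.int64) * 4 + right, 16)
    x = _X_LOOKUP[dimer]
    local_dyad = (len(sequence) - 1) // 2
    centers = np.arange(len(sequence) - 1) - local_dyad + 0.5
    return x, valid, centers


def phase_score(
    sequence: str | Fragment,
    template: PhaseTemplate | None = None,
    threshold: float = 0.1,
) -> PhaseScore:
    """Score one fragment's WW/SS phase agreement with the canonical template.

    The per-dimer signal x = [dimer in WW] - [dimer in SS] is correlated
    (Pearson) with the template over the supported dinucleotide positions in
    the dyad-aligned frame; N-containing dimers are skipped.  Zero variance
    in x yields score 0, label "weak".
    """
    template = template or PhaseTemplate()
    seq = sequence.sequence if isinstance(sequence, Fragment) else sequence
    if seq is None:
        raise DataError("fragment has no sequence")
    seq = seq.upper()
    if len(seq) < 2:
        raise DataError("sequence too short to score")
    x, valid, centers = _dimer_signal(seq)
    mask = valid & template.support(centers)
    if mask.sum() < 3:
        return PhaseScore(0.0, "weak", threshold)
    xs = x[mask]
    ts = template.value(centers[mask])
    if np.ptp(xs) == 0 or np.ptp(ts) == 0:
        logger.debug("zero-variance signal; score set to 0")
        return PhaseScore(0.0, "weak", threshold)
    r = float(np.corrcoef(xs, ts)[0, 1])
    return PhaseScore(r, _label(r, threshold), threshold)


def classify_population(
    fragments: Sequence[Fragment],
    template: PhaseTemplate | None = None,
    threshold: float = 0.1,
    subset_profiles: bool = True,
) -> PopulationClassification:
    """Score every fragment and summarize the rotational-setting mixture.

    Fractions are reported both over all fragments and over confidently
    typed (non-weak) fragments.  When requested and a subset is non-empty,
    its smoothed, symmetrized W(A+T) profile is attached; empty subsets get
    ``None`` rather than a zero profile.
    """
    fragments = list(fragments)
    if not fragments:
        raise DataError("no fragments to classify")
    template = template or PhaseTemplate()
    scores = np.empty(len(fragments))
    labels: list[str] = []
    for i, frag in enumerate(fragments):
        ps = phase_score(frag, template, threshold)
        scores[i] = ps.score
        labels.append(ps.label)

    n = len(fragments)
    n_can = labels.count("canonical")
    n_anti = labels.count("anti")
    n_typed = n_can + n_anti

    def _subset_profile(label: str) -> PositionalProfile | None:
        subset = [f for f, lab in zip(fragments, labels) if lab == label]
        if not subset:
            return None
        return symmetrize(smooth3(w_profile(subset)))

    return PopulationClassification(
        scores=scores,
        labels=labels,
        threshold=threshold,
        fraction_canonical=n_can / n,
        fraction_anti=n_anti / n,
        fraction_weak=labels.count("weak") / n,
        fraction_canonical_typed=n_can / n_typed if n_typed else float("nan"),
        fraction_anti_typed=n_anti / n_typed if n_typed else float("nan"),
        canonical_profile=_subset_profile("canonical") if subset_profiles else None,
        anti_profile=_subset_profile("anti") if subset_profiles else None,
    )


def classification_to_tsv(
    fragments: Sequence[Fragment], result: PopulationClassification, path
) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tscore\tlabel\n")
        for i, (frag, score, label) in enumerate(
            zip(fragments, result.scores, result.labels)
        ):
            name = frag.name or f"frag{i}"
            fh.write(f"{name}\t{score:.6g}\t{label}\n")
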