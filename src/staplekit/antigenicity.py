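"""Kolaskar-Tongaonkar antigenic-segment prediction.

The method slides a 7-residue window along the sequence, averages the
per-residue antigenic propensities and assigns the mean to the window
centre (position i+3).  Maximal runs of centre scores above threshold at
least 8 residues long are reported as predicted antigenic segments.

The embedded propensity table is the published Kolaskar-Tongaonkar (1990)
set (``TABLE_VERSION``).  The original method renormalizes the threshold
to the whole-sequence mean when that mean is below 1; this is available
behind ``renormalize=True`` but defaults off (plain > 1 threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide import Peptide

__all__ = [
    "PROPENSITY",
    "TABLE_VERSION",
    "NONNATURAL_MAP",
    "AntigenicScan",
    "kolaskar_scan",
    "map_nonnatural",
]

TABLE_VERSION = "kolaskar-tongaonkar-1990"

#: per-residue antigenic propensity (Kolaskar & Tongaonkar, 1990)
PROPENSITY = {
    "A": 1.064, "C": 1.412, "D": 0.866, "E": 0.851, "F": 1.091,
    "G": 0.874, "H": 1.105, "I": 1.152, "K": 0.930, "L": 1.250,
    "M": 0.826, "N": 0.776, "P": 1.064, "Q": 1.015, "R": 0.873,
    "S": 1.012, "T": 0.909, "V": 1.383, "W": 0.893, "Y": 1.161,
}

#: natural surrogates for non-natural residues (propensity table coverage)
NONNATURAL_MAP = {"Nle": "L", "Sar": "G", "Aib": "A",
                  "R8": "A", "S5": "A", "B5": "A", "S8": "A"}

WINDOW = 7
_HALF = WINDOW // 2


@dataclass(frozen=True)
class AntigenicScan:
    """Result of a propensity scan.

    ``scores`` maps 1-based positions 4..L-3 to the centred 7-mer mean;
    ``segments`` are (start, end) spans, inclusive, of maximal runs of
    above-threshold scores with length >= ``min_len``.
    """

    sequence: str
    scores: dict[int, float]
    segments: tuple[tuple[int, int], ...]
    threshold: float
    table_version: str = TABLE_VERSION
    provenance: tuple[tuple[int, str, str], ...] = ()  # (pos, original, mapped)


def map_nonnatural(p: Peptide) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Map a peptide to a natural-residue string for propensity scanning.

    Non-naturals take their surrogate letter, D-residues their L
    equivalent.  Returns the string plus a provenance record of every
    replaced position ``(position, original_code, mapped_letter)``.
    """
    letters = []
    provenance = []
    for n, r in enumerate(p.residues, 1):
        if r.code in NONNATURAL_MAP:
            mapped = NONNATURAL_MAP[r.code]
            provenance.append((n, r.code, mapped))
        else:
            mapped = r.code
            if r.stereo == "D":
                provenance.append((n, r.code.lower(), mapped))
        letters.append(mapped)
    return "".join(letters), tuple(provenance)


def kolaskar_scan(seq, threshold: float = 1.0, min_len: int = 8,
                  renormalize: bool = False) -> AntigenicScan:
    """Scan a sequence (string or Peptide) for predicted antigenic segments."""
    provenance: tuple = ()
    if isinstance(seq, Peptide):
        seq, provenance = map_nonnatural(seq)
    seq = str(seq).upper()
    if len(seq) < WINDOW:
        raise ValueError(f"sequence of length {len(seq)} shorter than the "
                         f"{WINDOW}-residue window")
    try:
        props = np.array([PROPENSITY[c] for c in seq])
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in the propensity table") from None

    # centred moving average: score at position i (1-based), 4 <= i <= L-3
    kernel = np.ones(WINDOW) / WINDOW
    centred = np.convolve(props, kernel, mode="valid")
    scores = {i + _HALF + 1: float(s) for i, s in enumerate(centred)}

    thr = threshold
    if renormalize:
        mean = float(np.mean(list(scores.values())))
        thr = threshold if mean >= threshold else mean

    segments = []
    run_start = None
    scored_positions = sorted(scores)
    for pos in scored_positions + [None]:
        above = pos is not None and scores[pos] > thr
        if above and run_start is None:
            run_start = pos
        elif not above and run_start is not None:
            end = pos - 1 if pos is not None else scored_positions[-1]
            if end - run_start + 1 >= min_len:
                segments.append((run_start, end))
            run_start = None

    return AntigenicScan(sequence=seq, scores=scores, segments=tuple(segments),
                         threshold=thr, provenance=provenance)
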