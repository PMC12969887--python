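"""Classical hydropathy profiling and transmembrane-segment calling.

Used to contrast membrane-anchored and secreted isoforms of one locus: the
membrane form carries a hydrophobic C-terminal segment that the alternative
polyadenylation event truncates away. Kyte-Doolittle with a 19-residue
window, threshold 1.6 and minimum run 15 is the documented default; the
Hopp-Woods hydrophilicity scale (negated) is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

# Hopp-Woods is a hydrophilicity scale; negate it to score hydrophobicity.
HOPP_WOODS_NEG = {
    "R": -3.0, "K": -3.0, "D": -3.0, "E": -3.0, "S": -0.3, "N": -0.2,
    "Q": -0.2, "G": 0.0, "P": 0.0, "T": 0.4, "A": 0.5, "H": 0.5, "C": 1.0,
    "M": 1.3, "V": 1.5, "I": 1.8, "L": 1.8, "Y": 2.3, "F": 2.5, "W": 3.4,
    "X": 0.0,
}

SCALES = {"kd": KYTE_DOOLITTLE, "hw": HOPP_WOODS_NEG}

# The negated Hopp-Woods scale spans a narrower range than Kyte-Doolittle
# (max 3.4 vs 4.5), so its TM threshold sits proportionally lower.
SCALE_TM_THRESHOLD = {"kd": 1.6, "hw": 1.0}


@dataclass
class HydropathyProfile:
    sequence_id: str
    window: int
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class TMSegment:
    """A candidate transmembrane segment, 0-based half-open on the protein."""

    start: int
    end: int
    peak_score: float

    def __len__(self) -> int:
        return self.end - self.start


def hydropathy_profile(
    protein_seq: str,
    scale: str | dict = "kd",
    window: int = 19,
    sequence_id: str = "",
) -> HydropathyProfile:
    """Sliding-window mean of per-residue scale values (center positions).

    Unknown residues score 0 (the X convention). Profile length is
    ``len(seq) - window + 1``; the window must be odd and fit the sequence.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = protein_seq.upper()
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    table = SCALES[scale] if isinstance(scale, str) else scale
    vals = np.array([table.get(aa, 0.0) for aa in seq])
    kernel = np.ones(window) / window
    scores = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(sequence_id=sequence_id, window=window, scores=scores)


def call_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 15,
) -> list[TMSegment]:
    """Maximal runs of center scores >= threshold of length >= min_len.

    Positions are the center residues of the qualifying windows (0-based
    half-open on the protein), which keeps reported segments disjoint and
    sorted by construction.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    above = profile.scores >= threshold
    half = profile.window // 2
    segments: list[TMSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_len:
                segments.append(
                    TMSegment(
                        start=i + half,
                        end=j + half,
                        peak_score=float(profile.scores[i:j].max()),
                    )
                )
            i = j
        else:
            i += 1
    return segments


def compare_isoform_topology(
    seq_a: str,
    seq_b: str,
    scale: str = "kd",
    window: int = 19,
    threshold: float | None = None,
    min_len: int = 15,
    cterm_span: int = 40,
) -> dict:
    """Contrast two isoforms of one locus for a C-terminal TM segment.

    The sequences must share a common prefix covering >= 50% of the shorter
    (they are isoforms of one gene, not unrelated proteins). A C-terminal TM
    flag is set when a called segment ends within the final ``cterm_span``
    residues. The differing tail is measured past the longest common prefix.
    """
    if threshold is None:
        threshold = SCALE_TM_THRESHOLD.get(scale, 1.6) if isinstance(scale, str) else 1.6
    a, b = seq_a.upper(), seq_b.upper()
    lcp = 0
    for x, y in zip(a, b):
        if x != y:
            break
        lcp += 1
    if lcp < 0.5 * min(len(a), len(b)):
        raise ValueError(
            "sequences share too short a prefix to be isoforms of one locus"
        )

    def cterm_tm(seq: str) -> bool:
        if len(seq) < window:
            return False
        prof = hydropathy_profile(seq, scale=scale, window=window)
        segs = call_tm_segments(prof, threshold=threshold, min_len=min_len)
        return any(seg.end >= len(seq) - cterm_span for seg in segs)

    return {
        "A_has_Cterm_TM": cterm_tm(a),
        "B_has_Cterm_TM": cterm_tm(b),
        "common_prefix": lcp,
        "tail_a": len(a) - lcp,
        "tail_b": len(b) - lcp,
        "differing_tail_length": abs(len(a) - len(b)),
    }
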