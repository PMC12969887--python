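"""PolyA windows, instance-to-consensus mapping, hexamer scanning, the
paired co-occurrence test, and isoform grouping by terminal-exon TE overlap.

DNA is the working alphabet throughout: the canonical polyadenylation signal
AAUAAA is scanned as AATAAA, and RNA motifs are transcribed on input. The
motif set defaults to the single core hexamer; the common PAS variants are
available as an extended set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement
from scipy import stats

from .intervals import TEInstance, TranscriptModel, overlap_join

logger = logging.getLogger(__name__)

CORE_PAS = "AATAAA"
# The 12 common polyadenylation signal hexamers (DNA alphabet)
EXTENDED_PAS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)


@dataclass
class PolyAWindow:
    """Sense-strand sequence around a transcript's polyA site."""

    source_id: str
    sequence: str
    site_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.site_offset <= len(self.sequence):
            raise ValueError("site_offset must lie within the window")


@dataclass
class ConsensusMapping:
    """Position lift from an instance window onto the family consensus."""

    window_id: str
    pairs: list[tuple[int, int]]
    identity: float
    consensus_region: tuple[int, int]
    low_confidence: bool = False

    def lift(self, window_pos: int) -> Optional[int]:
        """Consensus position aligned to ``window_pos`` (None if gapped)."""
        for w, c in self.pairs:
            if w == window_pos:
                return c
        return None


def extract_polya_window(
    genome_sequences: dict[str, str],
    transcript: TranscriptModel,
    chrom: str,
    strand: str,
    w: int = 200,
) -> PolyAWindow:
    """The ``w``-nt window centred on the transcript's polyA site, read on the
    transcript's sense strand; clipped at sequence ends."""
    if transcript.polya_site is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no polya_site")
    if w % 2:
        raise ValueError("window size must be even")
    seq = genome_sequences[chrom]
    site = transcript.polya_site
    start = max(0, site - w // 2)
    end = min(len(seq), site + w // 2)
    window = seq[start:end].upper()
    if strand == "-":
        window = reverse_complement(window)
        offset = end - site
    else:
        offset = site - start
    return PolyAWindow(
        source_id=transcript.transcript_id, sequence=window, site_offset=offset
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # free end gaps: the window is a fragment of the consensus
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_to_consensus(
    window: PolyAWindow,
    consensus_seq: str,
    identity_floor: float = 0.5,
) -> ConsensusMapping:
    """Global alignment with free end gaps (+2/-2, gap open -5, extend -1)
    of an instance window onto the family consensus.

    The mapping lists matched/mismatched columns only; identity is computed
    over those columns. Mappings below ``identity_floor`` are returned
    flagged low-confidence rather than rejected. Ties between co-optimal
    alignments are broken deterministically (first alignment in the
    aligner's enumeration order).
    """
    if not window.sequence or not consensus_seq:
        raise ValueError("both window and consensus must be non-empty")
    aln = _ALIGNER.align(consensus_seq.upper(), window.sequence.upper())[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            cpos, wpos = t0 + k, q0 + k
            pairs.append((wpos, cpos))
            if consensus_seq[cpos].upper() == window.sequence[wpos].upper():
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    region = (pairs[0][1], pairs[-1][1] + 1) if pairs else (0, 0)
    return ConsensusMapping(
        window_id=window.source_id,
        pairs=pairs,
        identity=identity,
        consensus_region=region,
        low_confidence=identity < identity_floor,
    )


def scan_polya_hexamers(
    sequence: str,
    motif_set: Sequence[str] = (CORE_PAS,),
    sequence_id: str = "",
) -> pd.DataFrame:
    """All occurrences (overlapping included) of each motif in the sequence.

    RNA motifs are transcribed to DNA on input. Columns: sequence_id,
    position (0-based), hexamer, is_core.
    """
    if not motif_set:
        raise ValueError("motif set must be non-empty")
    seq = sequence.upper().replace("U", "T")
    rows = []
    for motif in motif_set:
        m = motif.upper().replace("U", "T")
        start = seq.find(m)
        while start != -1:
            rows.append(
                {
                    "sequence_id": sequence_id,
                    "position": start,
                    "hexamer": m,
                    "is_core": m == CORE_PAS,
                }
            )
            start = seq.find(m, start + 1)
    out = pd.DataFrame(rows, columns=["sequence_id", "position", "hexamer", "is_core"])
    return out.sort_values(["position", "hexamer"]).reset_index(drop=True)


def count_motif(sequence: str, motif: str = CORE_PAS) -> int:
    return len(scan_polya_hexamers(sequence, (motif,)))


def paired_t(differences: np.ndarray) -> tuple[float, float]:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), sd with n-1
    denominator, df = n-1, two-sided p. All-zero differences give (nan, 1)."""
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            warnings.warn("all paired differences zero; t undefined, p = 1")
            return float("nan"), 1.0
        # constant non-zero differences: the infinite-t limit
        return float(np.copysign(np.inf, d.mean())), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def cooccurrence_paired_test(
    windows: Sequence[PolyAWindow],
    mappings: Sequence[ConsensusMapping],
    consensus_seq: str,
    motif: str = CORE_PAS,
) -> tuple[pd.DataFrame, float, float]:
    """Motif count in each instance window paired against the count in the
    consensus region its alignment covers; paired t on the differences.

    Returns (per-pair table, t, two-sided p). Using the motif COUNT rather
    than a presence flag keeps the t statistic well defined when windows
    carry multiple signals.
    """
    if len(windows) != len(mappings):
        raise ValueError("windows and mappings must pair up")
    if len(windows) < 3:
        raise ValueError("need >= 3 windows for the paired test")
    rows = []
    for win, mp in zip(windows, mappings):
        c_in_window = count_motif(win.sequence, motif)
        lo, hi = mp.consensus_region
        c_in_consensus = count_motif(consensus_seq[lo:hi], motif)
        rows.append(
            {
                "window_id": win.source_id,
                "count_window": c_in_window,
                "count_consensus": c_in_consensus,
                "difference": c_in_window - c_in_consensus,
                "identity": mp.identity,
            }
        )
    table = pd.DataFrame(rows)
    t, p = paired_t(table["difference"].to_numpy())
    return table, t, p


DEFAULT_GROUP_LABELS = ("TE-proximal", "TE-distal")


@dataclass
class IsoformTEClass:
    transcript_id: str
    group: str
    te_id: Optional[str] = None


def classify_isoform_groups(
    transcripts: Sequence[tuple[TranscriptModel, str]],
    te_instances: Sequence[TEInstance],
    family_filter: Optional[str] = None,
    labels: Sequence[str] = DEFAULT_GROUP_LABELS,
) -> list[IsoformTEClass]:
    """Group transcript isoforms by which family copy their terminal exon
    overlaps.

    ``transcripts`` are (model, strand) pairs. Copies are ranked
    proximal -> distal along the gene's 5'->3' direction; rank r takes
    ``labels[r-1]`` (falling back to ``TE-<r>``), and transcripts whose
    terminal exon overlaps no copy are labelled ``no-TE``. A terminal exon
    overlapping two copies is labelled by the larger overlap, logged.
    """
    copies = [
        t for t in te_instances if family_filter is None or t.family == family_filter
    ]
    out: list[IsoformTEClass] = []
    for tm, strand in transcripts:
        term = tm.terminal_exon(strand)
        # rank family copies 5'->3' along this transcript's reading direction
        ordered = sorted(
            (c for c in copies if c.interval.chrom == term.chrom),
            key=lambda c: c.interval.start,
            reverse=(strand == "-"),
        )
        hits = [
            (j, ov)
            for _, j, ov in overlap_join([term], ordered)
        ]
        if not hits:
            out.append(IsoformTEClass(tm.transcript_id, "no-TE", None))
            continue
        if len(hits) > 1:
            logger.info(
                "terminal exon of %s overlaps %d copies; using largest overlap",
                tm.transcript_id, len(hits),
            )
        j, _ = max(hits, key=lambda h: (h[1], -h[0]))
        rank = j + 1
        label = labels[rank - 1] if rank <= len(labels) else f"TE-{rank}"
        out.append(IsoformTEClass(tm.transcript_id, label, ordered[j].id))
    return out
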