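"""Classify sequenced target-site alleles and summarise indel spectra.

Amplicon reads spanning the gRNA cut site are globally aligned to the
reference amplicon with affine gap penalties; insertions and deletions
intersecting a +/-20 bp window around the cut site determine the net indel
length and hence the category (in-frame vs frameshift, deletion vs
insertion by the sign of the net change).  Reads containing the recoded
diagnostic subsequence of the drive cassette are called ``drive`` without
alignment; reads aligning below 70% identity (or with excessive ambiguous
bases) are ``unalignable``.  Classification is strand-aware: a
reverse-complemented read yields the identical call.

For in-frame calls the translated sequence at designated critical codons
(e.g. the carboxy-terminal prenylation cysteines of Rab proteins) is
compared against the reference to flag alleles whose single-amino-acid
changes are likely to abolish function.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

__all__ = [
    "CATEGORIES",
    "NHEJ_CATEGORIES",
    "TargetLocus",
    "AlleleCall",
    "classify_allele",
    "allele_spectrum",
    "read_sequences",
]

CATEGORIES = (
    "WT",
    "in_frame_deletion",
    "frameshift_deletion",
    "insertion_in_frame",
    "insertion_frameshift",
    "drive",
    "unalignable",
)

#: Categories arising from NHEJ repair (the resistant-allele classes).
NHEJ_CATEGORIES = (
    "in_frame_deletion",
    "frameshift_deletion",
    "insertion_in_frame",
    "insertion_frameshift",
)


@dataclass(frozen=True)
class TargetLocus:
    """Reference amplicon with cut-site and reading-frame annotation.

    ``cut_site`` is the 0-based offset of the scissile phosphate (the cut
    falls between positions ``cut_site - 1`` and ``cut_site``);
    ``frame_offset`` is the position of the first in-frame coding base
    within the amplicon; ``critical_codons`` are 1-based codon indices
    (relative to ``frame_offset``) whose amino acids are required for
    function; ``drive_signature`` is a recoded-cassette subsequence
    diagnostic for drive alleles.
    """

    name: str
    reference: str
    cut_site: int
    frame_offset: int = 0
    critical_codons: Tuple[int, ...] = ()
    drive_signature: Optional[str] = None

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        if not 20 <= self.cut_site <= len(ref) - 20:
            raise ValueError("cut site must have >=20 bp flanks inside the amplicon")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame offset must be 0, 1 or 2")
        if self.drive_signature is not None:
            object.__setattr__(self, "drive_signature", self.drive_signature.upper())

    def codon_span(self, codon_index: int) -> Tuple[int, int]:
        """Reference coordinates [start, end) of a 1-based codon index."""
        start = self.frame_offset + 3 * (codon_index - 1)
        return (start, start + 3)


@dataclass(frozen=True)
class AlleleCall:
    """Classification of one read against a target locus."""

    category: str
    net_length: int = 0                      # signed net indel length (nt)
    span: Optional[Tuple[int, int]] = None   # reference span touched by indels
    critical_codon_altered: bool = False
    identity: float = 1.0


# affine-gap global aligner; one gap of any length is cheaper than scattered
# single-base gaps, so contiguous indels are recovered as single events
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2.0
_aligner.mismatch_score = -3.0
_aligner.open_gap_score = -8.0
_aligner.extend_gap_score = -1.0


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _alignment_events(alignment) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int, int]], List[Tuple[Tuple[int, int], Tuple[int, int]]]]:
    """Deletions [(ref_start, ref_end)], insertions [(ref_pos, length)] and
    the matched blocks of an alignment."""
    ref_blocks, read_blocks = alignment.aligned
    deletions: List[Tuple[int, int]] = []
    insertions: List[Tuple[int, int, int]] = []
    blocks = list(zip(map(tuple, ref_blocks), map(tuple, read_blocks)))
    for (r0, q0), (r1, q1) in zip(blocks, blocks[1:]):
        dr = r1[0] - r0[1]
        dq = q1[0] - q0[1]
        if dr > 0:
            deletions.append((r0[1], r0[1] + dr))
        if dq > 0:
            insertions.append((r0[1], dq, q0[1]))
    return deletions, insertions, blocks


def _identity(alignment, ref: str, read: str) -> float:
    ref_blocks, read_blocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (r0, r1), (q0, q1) in zip(map(tuple, ref_blocks), map(tuple, read_blocks)):
        aligned_cols += r1 - r0
        matches += sum(1 for a, b in zip(ref[r0:r1], read[q0:q1]) if a == b)
    span = max(len(ref), len(read))
    return matches / span if span else 0.0


def _codon_altered(
    locus: TargetLocus,
    read: str,
    deletions: Sequence[Tuple[int, int]],
    insertions: Sequence[Tuple[int, int, int]],
    blocks,
) -> bool:
    """True if any critical codon is structurally disrupted or translates to
    a different amino acid in the read."""
    ref = locus.reference
    # ref -> read coordinate map over matched columns
    ref2read: Dict[int, int] = {}
    for (r0, r1), (q0, q1) in blocks:
        for k in range(r1 - r0):
            ref2read[r0 + k] = q0 + k
    for ci in locus.critical_codons:
        s, e = locus.codon_span(ci)
        if any(ds < e and de > s for ds, de in deletions):
            return True
        if any(s < pos < e for pos, _, _ in insertions):
            return True
        try:
            read_codon = "".join(read[ref2read[p]] for p in range(s, e))
        except KeyError:
            return True
        ref_aa = str(Seq(ref[s:e]).translate())
        read_aa = str(Seq(read_codon).translate())
        if read_aa != ref_aa:
            return True
    return False


def classify_allele(
    read: str,
    locus: TargetLocus,
    window: int = 20,
    min_identity: float = 0.70,
    max_ambiguous_fraction: float = 0.05,
) -> AlleleCall:
    """Classify one read (sequence string) against the target locus.

    Only indels intersecting the +/-``window`` bp audit window around the
    cut site contribute to the net length; indels outside it are ignored as
    sequencing/PCR artifacts.  With multiple indels in the window the net
    length decides the frame, and deletion vs insertion follows the sign of
    the net change (a net change of zero with indels present is counted
    with the in-frame class).
    """
    seq = read.upper().replace("U", "T")
    if len(seq) < 40:
        raise ValueError("reads shorter than 40 nt cannot be audited")
    ambiguous = sum(1 for c in seq if c not in "ACGT")
    if ambiguous / len(seq) > max_ambiguous_fraction:
        return AlleleCall("unalignable", identity=0.0)

    sig = locus.drive_signature
    if sig and (sig in seq or sig in _revcomp(seq)):
        return AlleleCall("drive")

    best = None
    for candidate in (seq, _revcomp(seq)):
        aln = _aligner.align(locus.reference, candidate)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, candidate)
    alignment, oriented = best
    identity = _identity(alignment, locus.reference, oriented)
    if identity < min_identity:
        return AlleleCall("unalignable", identity=identity)

    deletions, insertions, blocks = _alignment_events(alignment)
    lo, hi = locus.cut_site - window, locus.cut_site + window
    del_in = [(s, e) for s, e in deletions if s < hi and e > lo]
    ins_in = [(p, n, q) for p, n, q in insertions if lo <= p <= hi]
    net = sum(n for _, n, _ in ins_in) - sum(e - s for s, e in del_in)

    if not del_in and not ins_in:
        return AlleleCall("WT", 0, None, False, identity)

    span_lo = min([s for s, _ in del_in] + [p for p, _, _ in ins_in])
    span_hi = max([e for _, e in del_in] + [p for p, _, _ in ins_in])
    in_frame = net % 3 == 0
    if net > 0:
        category = "insertion_in_frame" if in_frame else "insertion_frameshift"
    else:
        category = "in_frame_deletion" if in_frame else "frameshift_deletion"

    altered = False
    if in_frame and locus.critical_codons:
        altered = _codon_altered(locus, oriented, del_in, ins_in, blocks)
    return AlleleCall(category, int(net), (int(span_lo), int(span_hi)), altered, identity)


def read_sequences(path, min_mean_quality: Optional[float] = None) -> List[str]:
    """Load read sequences from a FASTA or FASTQ file (.gz accepted).

    For FASTQ input, ``min_mean_quality`` (e.g. 20) drops reads whose mean
    Phred quality falls below the threshold; qualities are not used
    otherwise.
    """
    import gzip

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    stem = path[:-3] if path.endswith(".gz") else path
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    out: List[str] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            if fmt == "fastq" and min_mean_quality is not None:
                quals = rec.letter_annotations.get("phred_quality", [])
                if quals and sum(quals) / len(quals) < min_mean_quality:
                    continue
            out.append(str(rec.seq))
    return out


def allele_spectrum(
    reads: Iterable[str],
    locus: TargetLocus,
    window: int = 20,
) -> pd.DataFrame:
    """Classify a collection of reads and tabulate the allele spectrum.

    Returns a frame with one row per category: ``count``,
    ``fraction_total`` (of classifiable, i.e. non-unalignable, reads) and
    ``fraction_nhej`` (of NHEJ indel reads only).  Raises ``ValueError`` if
    no read is classifiable.
    """
    counts: Counter = Counter()
    n = 0
    for read in reads:
        call = classify_allele(read, locus, window=window)
        counts[call.category] += 1
        n += 1
    if n == 0:
        raise ValueError("no reads supplied")
    classifiable = n - counts.get("unalignable", 0)
    if classifiable == 0:
        raise ValueError("all reads unalignable")
    nhej = sum(counts.get(c, 0) for c in NHEJ_CATEGORIES)
    rows = []
    for cat in CATEGORIES:
        c = counts.get(cat, 0)
        rows.append(
            {
                "category": cat,
                "count": c,
                "fraction_total": (c / classifiable) if cat != "unalignable" else math.nan,
                "fraction_nhej": (c / nhej) if (cat in NHEJ_CATEGORIES and nhej) else math.nan,
            }
        )
    return pd.DataFrame(rows)
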