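"""Genomic G+C content, emendation checks, and HSP-based genome distances.

G+C content computed directly from a genome assembly is far more precise than
the thermal-denaturation or HPLC values found in older species descriptions;
within a species the genome-based value varies by less than one percentage
point.  A discrepancy of more than one point between the description and the
genome therefore signals that the description should be emended, and the
genus description should be revisited if the corrected value falls outside
the genus range.

Overall genome relatedness is summarized from high-scoring segment pairs
(HSPs) — ungapped local alignments between two genomes — through three
distance-related fractions: (1) total HSP length over total genome length,
(2) summed identities over total HSP length, and (3) summed identities over
total genome length.  Formula 2 is robust to incomplete draft assemblies
because unaligned sequence does not enter its denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GCResult",
    "HSP",
    "DistanceFormulas",
    "read_genome",
    "gc_content",
    "emendation_flag",
    "range_check",
    "find_hsps",
    "distance_formulas",
    "literature_gc_table",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A genome assembly: one or more nucleotide records."""

    records: tuple  # of (id, sequence)

    def __init__(self, records):
        object.__setattr__(
            self, "records",
            tuple((rid, seq.upper()) for rid, seq in records),
        )
        if not self.records:
            raise ValueError("empty genome")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


def read_genome(path) -> GenomeSequence:
    recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(recs)


@dataclass(frozen=True)
class GCResult:
    gc_count: int
    counted_length: int

    @property
    def percent(self) -> float:
        return 100.0 * self.gc_count / self.counted_length


def gc_content(genome: GenomeSequence) -> GCResult:
    """Percent G+C among unambiguous bases.

    Ambiguity codes and gaps are excluded from both numerator and
    denominator, so only A/C/G/T positions are counted.
    """
    gc = counted = 0
    for _, seq in genome.records:
        g = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        gc += g
        counted += g + at
    if counted == 0:
        raise ValueError("no unambiguous bases to count")
    return GCResult(gc, counted)


@dataclass(frozen=True)
class EmendationDecision:
    reported_low: float
    reported_high: float
    computed: float
    discrepancy: float
    flag: bool
    emended_value: int  # nearest whole percent, for "about NN%" wording


def emendation_flag(reported, computed: float,
                    threshold: float = 1.0) -> EmendationDecision:
    """Whether a species description's G+C value needs emendation.

    ``reported`` is a single percentage or a ``(low, high)`` range (a value
    with a stated uncertainty becomes the range value±sd).  The flag is
    raised iff the genome-computed value lies more than ``threshold``
    percentage points outside the reported range.
    """
    if np.isscalar(reported):
        low = high = float(reported)
    else:
        low, high = map(float, reported)
    if low > high:
        raise ValueError(f"inverted range ({low}, {high})")
    for v in (low, high, computed):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage {v} outside [0, 100]")
    if computed < low:
        discrepancy = low - computed
    elif computed > high:
        discrepancy = computed - high
    else:
        discrepancy = 0.0
    return EmendationDecision(
        reported_low=low, reported_high=high, computed=computed,
        discrepancy=discrepancy, flag=discrepancy > threshold,
        emended_value=int(round(computed)),
    )


def range_check(values: dict, grouping: dict,
                description_range=None) -> pd.DataFrame:
    """Per-group min/max of G+C values, with outliers vs. a described range.

    ``values`` maps taxon -> percent; ``grouping`` maps group name -> list of
    taxa.  If ``description_range`` (low, high) is given, taxa falling
    outside it are listed in the ``outliers`` column.
    """
    rows = []
    for group, taxa in grouping.items():
        if not taxa:
            raise ValueError(f"empty group {group!r}")
        missing = [t for t in taxa if t not in values]
        if missing:
            raise ValueError(f"unknown taxa in group {group!r}: {missing}")
        vals = [values[t] for t in taxa]
        outliers = []
        if description_range is not None:
            low, high = description_range
            outliers = [t for t in taxa
                        if not low <= values[t] <= high]
        rows.append({
            "group": group, "n": len(taxa),
            "min": min(vals), "max": max(vals),
            "outliers": ",".join(sorted(outliers)),
        })
    return pd.DataFrame(rows).set_index("group")


def literature_gc_table() -> pd.DataFrame:
    """Literature-compiled G+C contents of Planctomycetaceae type strains.

    Columns: the range given in each species description (``reported_low``,
    ``reported_high``, in percent; a point value has low == high) and the
    value computed from the genome assembly (``genome_percent``).  The
    outgroup *Phycisphaera mikurensis* is included and marked.
    """
    path = resources.files("planctotaxa.data") / "planctomycetaceae_gc.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", index_col="taxon", comment="#")
    df["outgroup"] = df["outgroup"].astype(bool)
    return df


# -- HSPs -----------------------------------------------------------------------


@dataclass(frozen=True)
class HSP:
    """Ungapped local alignment segment (0-based, half-open coordinates).

    Coordinates on genome A always refer to the plus strand; a minus-strand
    HSP means the segment of B was reverse-complemented for the alignment,
    and ``startB``/``endB`` are plus-strand coordinates of B.
    """

    startA: int
    endA: int
    startB: int
    endB: int
    strand: str
    length: int
    identities: int
    score: int

    def __post_init__(self):
        if self.identities > self.length:
            raise ValueError("identities exceed HSP length")
        if (self.endA - self.startA != self.length
                or self.endB - self.startB != self.length):
            raise ValueError("HSP coordinates inconsistent with length")


def _extend(a: np.ndarray, b: np.ndarray, i: int, j: int, k: int,
            xdrop: int):
    """X-drop ungapped extension of an exact k-word seed at (i, j).

    Returns (startA, endA, length, identities, score) with startB = startA
    implied through the fixed diagonal.
    """
    n, m = a.size, b.size
    # rightward from the seed end
    right = min(n - (i + k), m - (j + k))
    score = k
    best_score = k
    best_right = 0
    if right > 0:
        eq = a[i + k:i + k + right] == b[j + k:j + k + right]
        run = score + np.cumsum(np.where(eq, 1, -1))
        peak = np.maximum.accumulate(run)
        drop = np.nonzero(peak - run > xdrop)[0]
        stop = drop[0] if drop.size else right
        if stop:
            seg = run[:stop]
            best_idx = int(np.argmax(seg))
            best_score = int(seg[best_idx])
            best_right = best_idx + 1
    # leftward from the seed start
    left = min(i, j)
    best_left = 0
    if left > 0:
        eq = a[i - left:i][::-1] == b[j - left:j][::-1]
        run = best_score + np.cumsum(np.where(eq, 1, -1))
        peak = np.maximum.accumulate(run)
        drop = np.nonzero(peak - run > xdrop)[0]
        stop = drop[0] if drop.size else left
        if stop:
            seg = run[:stop]
            best_idx = int(np.argmax(seg))
            if seg[best_idx] > best_score:
                best_score = int(seg[best_idx])
                best_left = best_idx + 1
    start = i - best_left
    end = i + k + best_right
    length = end - start
    ident = int(np.count_nonzero(
        a[start:end] == b[j - best_left:j - best_left + length]))
    score = 2 * ident - length
    return start, end, length, ident, score


def _encode_seq(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hsps_one_strand(seq_a: str, seq_b: str, k: int, xdrop: int,
                     min_score: int):
    """Seed-and-extend HSPs of b against a (plus orientation of both)."""
    if len(seq_a) < k or len(seq_b) < k:
        return []
    index: dict = {}
    for i in range(len(seq_a) - k + 1):
        word = seq_a[i:i + k]
        if "N" not in word:
            index.setdefault(word, []).append(i)
    a = _encode_seq(seq_a)
    b = _encode_seq(seq_b)
    covered: dict = {}  # diagonal -> list of (startA, endA) already explained
    out = []
    for j in range(len(seq_b) - k + 1):
        word = seq_b[j:j + k]
        hits = index.get(word)
        if not hits:
            continue
        for i in hits:
            diag = i - j
            spans = covered.setdefault(diag, [])
            if any(s <= i and i + k <= e for s, e in spans):
                continue
            start, end, length, ident, score = _extend(a, b, i, j, k, xdrop)
            spans.append((start, end))
            if score >= min_score:
                out.append((start, end, start - diag, end - diag,
                            length, ident, score))
    return out


def find_hsps(genome_a: GenomeSequence, genome_b: GenomeSequence,
              k: int = 11, xdrop: int = 20, min_score: int = 30) -> list:
    """High-scoring segment pairs between two genomes, both strands.

    Exact k-word seeds are extended without gaps (match +1, mismatch -1)
    until the running score drops ``xdrop`` below its maximum, then trimmed
    back to the maximum-scoring segment.  Seeds falling inside an already
    extended segment on the same diagonal are skipped, which merges
    overlapping seeds into a single HSP.  Records of multi-record (draft)
    assemblies are compared independently; extensions never cross record
    boundaries.
    """
    if k < 8:
        raise ValueError("word size k must be at least 8")
    hsps = []
    offs_a = 0
    for _, seq_a in genome_a.records:
        offs_b = 0
        for _, seq_b in genome_b.records:
            for (sa, ea, sb, eb, ln, ident, score) in _hsps_one_strand(
                    seq_a, seq_b, k, xdrop, min_score):
                hsps.append(HSP(offs_a + sa, offs_a + ea,
                                offs_b + sb, offs_b + eb,
                                "+", ln, ident, score))
            rc = reverse_complement(seq_b)
            for (sa, ea, sb, eb, ln, ident, score) in _hsps_one_strand(
                    seq_a, rc, k, xdrop, min_score):
                # map reverse-complement coordinates back to B's plus strand
                true_sb = len(seq_b) - eb
                true_eb = len(seq_b) - sb
                hsps.append(HSP(offs_a + sa, offs_a + ea,
                                offs_b + true_sb, offs_b + true_eb,
                                "-", ln, ident, score))
            offs_b += len(seq_b)
        offs_a += len(seq_a)
    hsps.sort(key=lambda h: (h.startA, h.startB, h.strand))
    return hsps


@dataclass(frozen=True)
class DistanceFormulas:
    """The three HSP-based genome distance fractions, each in [0, 1]."""

    f1: float  # total HSP length / total genome length
    f2: float  # identities / total HSP length
    f3: float  # identities / total genome length

    def __post_init__(self):
        for name in ("f1", "f2", "f3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def distance_formulas(hsps, len_a: int, len_b: int,
                      total: str = "mean") -> DistanceFormulas:
    """Compute the three HSP fractions from an HSP set.

    ``total`` length is the mean of the two genome lengths by default, so
    that identical genomes score 1.0 on all three formulas; set
    ``total="sum"`` for the sum of lengths instead.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    L = sum(h.length for h in hsps)
    I = sum(h.identities for h in hsps)
    if L == 0:
        raise ValueError("no HSPs: formula 2 (identities / HSP length) "
                         "is undefined")
    T = (len_a + len_b) / 2.0 if total == "mean" else float(len_a + len_b)
    return DistanceFormulas(
        f1=min(L / T, 1.0), f2=I / L, f3=min(I / T, 1.0),
    )


def hsp_table(hsps) -> pd.DataFrame:
    """BLAST-tabular-like frame of an HSP list."""
    return pd.DataFrame(
        [(h.startA, h.endA, h.startB, h.endB, h.strand,
          h.length, h.identities, h.score) for h in hsps],
        columns=["qstart", "qend", "sstart", "send", "strand",
                 "length", "identities", "score"],
    )
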