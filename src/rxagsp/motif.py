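"""Position-weight-matrix scanning of promoter sequences.

A window of the motif's length matches when its additive score reaches a
stated fraction (default 85%) of the maximal achievable score.  Matrices
may be supplied as TRANSFAC-style count tables or derived from an IUPAC
consensus (weight 1 for every base the code allows, 0 otherwise).  Both
orientations are scanned; reverse-strand hits are reported in forward
coordinates (0-based, half-open).  Duplicate hits arising from overlapping
transcript regions are collapsed on (sequence_id, start, strand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_consensus",
    "read_pwm",
    "scan",
    "scan_fasta",
    "dedup_hits",
    "write_bed",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class PWM:
    """4 x L non-negative weight matrix over (A, C, G, T)."""

    matrix: np.ndarray
    id: str = "pwm"
    consensus: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM must be a 4 x L matrix, L >= 1")
        if (m < 0).any():
            raise ValueError("PWM weights must be non-negative")
        if (m.max(axis=0) <= 0).any():
            raise ValueError("every PWM position needs a positive max weight")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1].copy()
        cons = self.consensus.translate(_COMPLEMENT)[::-1] if self.consensus else None
        return PWM(rc, id=self.id + "_rc", consensus=cons)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int          # 0-based
    end: int            # exclusive; end - start == motif length
    strand: str         # '+' or '-'
    score: float
    frac_of_max: float


def pwm_from_consensus(iupac: str, motif_id: str | None = None) -> PWM:
    """0/1 weight matrix from an IUPAC consensus string."""
    iupac = iupac.upper()
    if not iupac:
        raise ValueError("empty consensus")
    m = np.zeros((4, len(iupac)))
    for j, code in enumerate(iupac):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC character {code!r} at position {j}")
        for base in IUPAC[code]:
            m[_BASE_INDEX[base], j] = 1.0
    return PWM(m, id=motif_id or iupac, consensus=iupac)


def read_pwm(path, motif_id: str | None = None) -> PWM:
    """Read a PWM from TRANSFAC-like or plain 4-column text.

    Accepted layouts: rows ``01  cA cC cG cT  [consensus]`` (TRANSFAC body,
    ``ID``/``PO``/``XX``/``//`` lines ignored) or bare 4-column numeric rows,
    one row per motif position.
    """
    rows = []
    mid = motif_id
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0].upper()
            if tag in ("XX", "//", "PO", "P0", "BF", "AC", "NA", "DE", "CC"):
                continue
            if tag == "ID" and len(parts) > 1:
                mid = mid or parts[1]
                continue
            indexed = parts[0].rstrip(":").isdigit() and len(parts) >= 5
            numeric = parts[1:5] if indexed else parts[:4]
            if len(numeric) < 4:
                continue
            try:
                rows.append([float(x) for x in numeric])
            except ValueError:
                continue
    if not rows:
        raise ValueError(f"{path}: no PWM rows found")
    return PWM(np.array(rows).T, id=mid or str(path))


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3; anything else (incl. N) -> 4, scored as 0
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(codes: np.ndarray, pwm: PWM, strand: str,
                     threshold: float, seq_id: str) -> list[MotifHit]:
    L = pwm.length
    n = codes.size
    if n < L:
        return []
    weights = np.vstack([pwm.matrix, np.zeros((1, L))])  # row 4 scores N as 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = weights[windows, np.arange(L)].sum(axis=1)
    max_score = pwm.max_score
    hits = np.flatnonzero(scores >= threshold * max_score - 1e-12)
    return [
        MotifHit(seq_id, int(s), int(s) + L, strand,
                 float(scores[s]), float(scores[s] / max_score))
        for s in hits
    ]


def scan(seq: str, pwm: PWM, threshold_frac: float = 0.85,
         both_strands: bool = True, sequence_id: str = "seq") -> list[MotifHit]:
    """All windows scoring at least ``threshold_frac`` of the maximum.

    Reverse-strand hits are found by scanning the reverse-complement matrix
    over the forward sequence, so their coordinates stay in forward
    orientation.  Hits are ordered by (start, strand).
    """
    if not 0.0 < threshold_frac:
        raise ValueError("threshold_frac must be positive")
    codes = _encode(seq)
    hits = _scan_one_strand(codes, pwm, "+", threshold_frac, sequence_id)
    if both_strands:
        hits += _scan_one_strand(codes, pwm.reverse_complement(), "-", threshold_frac, sequence_id)
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_fasta(path, pwm: PWM, threshold_frac: float = 0.85,
               both_strands: bool = True) -> list[MotifHit]:
    """Scan every record of a FASTA file of promoter sequences."""
    from Bio import SeqIO

    hits: list[MotifHit] = []
    for record in SeqIO.parse(str(path), "fasta"):
        hits += scan(str(record.seq), pwm, threshold_frac, both_strands,
                     sequence_id=record.id)
    return hits


def dedup_hits(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse hits identical in (sequence_id, start, strand), keeping order.

    Overlapping upstream regions of multiple transcripts of a gene produce
    the same genomic hit repeatedly; opposite-strand hits at one position
    are distinct and kept.
    """
    seen = set()
    out = []
    for h in hits:
        key = (h.sequence_id, h.start, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def write_bed(hits: list[MotifHit], path, motif_id: str = "motif") -> None:
    """BED6: chrom, start, end, name, score (frac_of_max scaled to 0-1000), strand."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(round(min(1.0, h.frac_of_max) * 1000))
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\t{motif_id}\t{score}\t{h.strand}\n")
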