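"""Position-weight-matrix motif models and log-odds scanning.

A motif is built from a 4xL base-count matrix (rows A, C, G, T), smoothed
with a pseudocount and scored as log2 odds against a background base
composition (uniform by default). Scanning reports every window whose
score reaches a fraction of the motif's maximum attainable score, on both
strands; this mirrors how repository motifs (e.g. Factorbook models) are
matched inside TF-bound regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# two-base IUPAC degeneracy codes, keyed by the sorted base pair
_IUPAC_PAIRS = {
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S", ("A", "T"): "W",
    ("G", "T"): "K", ("A", "C"): "M",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A TF binding motif as a smoothed position weight matrix.

    ``counts`` is a 4xL non-negative matrix (rows A, C, G, T). Column
    probabilities are (count + pseudocount) / (colsum + 4*pseudocount);
    log-odds are log2(p / background).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.name!r}: counts must be 4xL with L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.name!r}: negative counts")
        if (self.counts.sum(axis=0) == 0).any() and self.pseudocount == 0:
            raise ValueError(
                f"motif {self.name!r}: all-zero column with pseudocount 0"
            )
        if self.pseudocount < 0:
            raise ValueError(f"motif {self.name!r}: negative pseudocount")
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"motif {self.name!r}: background must be a length-4 probability vector")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0) + 4 * self.pseudocount
        return (self.counts + self.pseudocount) / col_tot

    @property
    def log_odds(self) -> np.ndarray:
        """4xL log2-odds matrix vs background, in bits.

        With pseudocount 0 a zero-count base legitimately scores -inf.
        """
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        """Score of the maximum-likelihood word, in bits."""
        return float(self.log_odds.max(axis=0).sum())

    def information_per_column(self) -> float:
        """Mean per-column information content in bits (uniform background)."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return float((2.0 + h).mean())

    def max_likelihood_word(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))


def pwm_from_counts(
    counts, pseudocount: float = 0.5, background=None, name: str = "motif"
) -> MotifModel:
    """Construct a :class:`MotifModel` from a raw 4xL count matrix."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return MotifModel(name=name, counts=np.asarray(counts, dtype=float),
                      pseudocount=pseudocount, background=bg)


def consensus_string(
    motif: MotifModel, heavy_threshold: float = 0.6, pair_threshold: float = 0.8
) -> str:
    """IUPAC consensus of a motif.

    Per column: the single base if its probability reaches
    ``heavy_threshold``; a two-base degeneracy code if the top two sum to
    ``pair_threshold``; otherwise N.
    """
    p = motif.probabilities
    out = []
    for col in p.T:
        order = np.argsort(col)[::-1]
        if col[order[0]] >= heavy_threshold:
            out.append(BASES[order[0]])
        elif col[order[0]] + col[order[1]] >= pair_threshold:
            pair = tuple(sorted((BASES[order[0]], BASES[order[1]])))
            out.append(_IUPAC_PAIRS[pair])
        else:
            out.append("N")
    return "".join(out)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a scanned sequence.

    ``offset`` is the 0-based window start in + coordinates regardless of
    strand; ``matched_sequence`` is the + strand window content.
    """

    seq_id: str
    offset: int
    strand: str
    score: float
    matched_sequence: str


def _window_scores(seq: str, log_odds: np.ndarray) -> np.ndarray:
    """Score of every length-L window of seq on the given matrix.

    N (or any non-ACGT symbol) contributes the background-expected score 0.
    """
    L = log_odds.shape[1]
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(idx.shape, 4, dtype=np.int8)  # 4 == unknown/N
    for b, i in _BASE_INDEX.items():
        code[idx == ord(b)] = i
    lo = np.vstack([log_odds, np.zeros((1, L))])  # row 4: N scores 0
    n_win = len(seq) - L + 1
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lo[code[j:j + n_win], j]
    return scores


def scan_sequence(
    seq: str,
    motif: MotifModel,
    min_score_frac: float = 0.8,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All windows scoring >= ``min_score_frac`` x the motif's maximum score.

    Minus-strand windows are scored on the reverse complement but reported
    at their + strand coordinates with strand "-". Hits are sorted by
    (offset, strand). Sequences shorter than the motif yield no hits.
    """
    if not (0 < min_score_frac <= 1):
        raise ValueError(f"min_score_frac must be in (0, 1], got {min_score_frac}")
    L = motif.length
    if len(seq) < L:
        log.info("sequence %s shorter than motif %s (%d < %d); no hits",
                 seq_id, motif.name, len(seq), L)
        return []
    seq = seq.upper()
    threshold = min_score_frac * motif.max_score
    lo = motif.log_odds
    hits: list[MotifHit] = []
    fwd = _window_scores(seq, lo)
    for off in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(seq_id, int(off), "+", float(fwd[off]), seq[off:off + L]))
    if both_strands:
        rc = reverse_complement(seq)
        rev = _window_scores(rc, lo)
        n_win = len(seq) - L + 1
        for off_rc in np.nonzero(rev >= threshold)[0]:
            off = n_win - 1 - int(off_rc)  # map back to + coordinates
            hits.append(MotifHit(seq_id, off, "-", float(rev[off_rc]), seq[off:off + L]))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_peaks(
    sequences: dict[str, str],
    peaks,
    motif: MotifModel,
    min_score_frac: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Peak-restricted scan: motif occurrences only inside TF-bound intervals.

    Offsets in the returned hits are genomic (chromosome) coordinates.
    """
    hits: list[MotifHit] = []
    for p in peaks:
        iv = p.interval
        chrom_seq = sequences.get(iv.chrom)
        if chrom_seq is None:
            log.warning("no sequence for chromosome %s; peak skipped", iv.chrom)
            continue
        sub = chrom_seq[iv.start:iv.end]
        for h in scan_sequence(sub, motif, min_score_frac, both_strands, seq_id=iv.chrom):
            hits.append(MotifHit(iv.chrom, h.offset + iv.start, h.strand,
                                 h.score, h.matched_sequence))
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_counts_matrix(path: str | Path, name: str | None = None) -> MotifModel:
    """Read a 4-row tab/space-separated count matrix (JASPAR-style .pfm).

    Accepts an optional ``>`` header line, an optional header row of
    position numbers, and optional ``A [ ... ]`` row decorations.
    """
    rows: list[list[float]] = []
    motif_name = name
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_name = motif_name or line[1:].split()[0]
                continue
            line = line.replace("[", " ").replace("]", " ")
            toks = line.split()
            if toks and toks[0].rstrip(":").upper() in _BASE_INDEX:
                toks = toks[1:]
            try:
                vals = [float(t) for t in toks]
            except ValueError:
                continue  # header row of position numbers mixed with text
            if vals:
                rows.append(vals)
    if len(rows) == 5 and all(v == int(v) for v in rows[0]):
        rows = rows[1:]  # leading position-number row
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 count rows (A,C,G,T), found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: count rows have unequal lengths")
    return pwm_from_counts(np.array(rows), name=motif_name or Path(path).stem)


def write_counts_matrix(motif: MotifModel, path: str | Path) -> None:
    lines = [f">{motif.name}"]
    for i, base in enumerate(BASES):
        lines.append(base + "\t" + "\t".join(
            str(int(v)) if float(v).is_integer() else repr(float(v))
            for v in motif.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_hits_bed(hits: list[MotifHit], motif: MotifModel, path: str | Path) -> None:
    """Write motif hits as BED6; score = bits x 100, capped at 1000."""
    lines = []
    for h in hits:
        score = min(1000, max(0, int(round(h.score * 100))))
        lines.append("\t".join([
            h.seq_id, str(h.offset), str(h.offset + motif.length),
            motif.name, str(score), h.strand,
        ]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
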