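"""Coding-potential assessment: seven scorers, the 5-of-7 consensus, and the
protein-domain final filter.

Each scorer captures one classical feature family used by published
coding-potential tools: longest-ORF length and coverage, the Fickett
TESTCODE statistic, in-frame hexamer usage bias, a logistic model over
k = 1..5 k-mer spectra, adjacent codon-pair (triplet) log-odds, and
stop-codon density combined with GC content. Every scorer returns a raw
score oriented so that *higher = more coding-like* and votes ``coding`` when
the score reaches its calibrated threshold (equal-error-rate point on a
fixed-seed synthetic calibration set; see :mod:`lncreg.calibration`).

A transcript's consensus is *noncoding* iff at least 5 of the 7 votes are
noncoding; consensus-noncoding transcripts are finally screened against a
small bundled PSSM motif library (a desk-scale stand-in for a full protein
domain database -- any library file in the documented format can be
substituted), and only motif-free transcripts are classed ``novel_lncRNA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._tables import (
    FICKETT_CONTENT_PARA,
    FICKETT_CONTENT_PROB,
    FICKETT_CONTENT_WEIGHT,
    FICKETT_POSITION_PARA,
    FICKETT_POSITION_PROB,
    FICKETT_POSITION_WEIGHT,
    STOP_CODONS,
)
from .core import ValidationError

SCORER_NAMES = (
    "orf_length",
    "orf_coverage",
    "fickett",
    "hexamer",
    "kmer_spectrum",
    "triplet_frame",
    "stop_density",
)

NONCODING_VOTES_REQUIRED = 5

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class ConfigurationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass(frozen=True)
class OrfHit:
    """One open reading frame: 0-based [start, end) on the input sequence.

    ``length`` counts ATG through the stop codon inclusive; an ORF without an
    in-frame stop runs to the last complete codon and has ``complete=False``.
    """

    frame: int
    start: int
    end: int
    complete: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(seq: str, min_length: int = 1) -> list[OrfHit]:
    """All maximal ATG-initiated ORFs >= ``min_length`` nt in 3 forward frames."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i + 3
                end, complete = None, False
                while j + 3 <= n:
                    if seq[j : j + 3] in STOP_CODONS:
                        end, complete = j + 3, True
                        break
                    j += 3
                if end is None:
                    end = i + ((n - i) // 3) * 3
                if end - i >= min_length:
                    orfs.append(OrfHit(frame, i, end, complete))
                i = end if complete else n
            else:
                i += 3
    return orfs


def longest_orf(seq: str) -> OrfHit | None:
    orfs = find_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.length, -o.start))


def longest_orf_per_frame(seq: str) -> dict[int, OrfHit]:
    best: dict[int, OrfHit] = {}
    for o in find_orfs(seq):
        if o.frame not in best or o.length > best[o.frame].length:
            best[o.frame] = o
    return best


# ---------------------------------------------------------------------------
# individual scorers


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic from the bundled lookup tables.

    For each base: the position parameter is max/(min+1) over the three codon
    positions, the content parameter is the base fraction; each is converted
    to a probability by threshold lookup and the eight probabilities are
    combined with the published weights. Higher = more coding-like.
    """
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        counts = [sum(1 for i in range(k, n, 3) if seq[i] == base) for k in range(3)]
        pos_val = max(counts) / (min(counts) + 1)
        score += (
            _lookup(pos_val, FICKETT_POSITION_PARA, FICKETT_POSITION_PROB[base])
            * FICKETT_POSITION_WEIGHT[base]
        )
        content = (counts[0] + counts[1] + counts[2]) / max(n, 1)
        score += (
            _lookup(content, FICKETT_CONTENT_PARA, FICKETT_CONTENT_PROB[base])
            * FICKETT_CONTENT_WEIGHT[base]
        )
    return score


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> -1."""
    return np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-windows; windows containing non-ACGT are dropped."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (win[valid] * pows).sum(axis=1)


def inframe_hexamers(seq: str, frame: int) -> np.ndarray:
    codes = encode(seq)
    if len(codes) < frame + 6:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, 6)[frame::3]
    valid = (win >= 0).all(axis=1)
    pows = 4 ** np.arange(5, -1, -1, dtype=np.int64)
    return (win[valid] * pows).sum(axis=1)


def hexamer_score(seq: str, coding_table: np.ndarray, noncoding_table: np.ndarray) -> float:
    """Mean ln(coding/noncoding) likelihood over the in-frame hexamers of the
    longest-ORF frame (frame 0 when the sequence has no ORF)."""
    for table in (coding_table, noncoding_table):
        if (np.asarray(table) <= 0).any():
            raise ValidationError("hexamer tables must have all entries > 0")
    orf = longest_orf(seq)
    frame = orf.frame if orf else 0
    hexes = inframe_hexamers(seq, frame)
    if len(hexes) == 0:
        return 0.0
    return float(np.mean(np.log(np.asarray(coding_table)[hexes])
                         - np.log(np.asarray(noncoding_table)[hexes])))


def kmer_features(seq: str, kmax: int = 5) -> np.ndarray:
    """Concatenated normalized k-mer frequency vectors for k = 1..kmax (1364 dims)."""
    codes = encode(seq)
    parts = []
    for k in range(1, kmax + 1):
        w = _window_codes(codes, k)
        vec = np.bincount(w, minlength=4**k).astype(float)
        total = vec.sum()
        parts.append(vec / total if total > 0 else vec)
    return np.concatenate(parts)


def codon_codes(seq: str, frame: int) -> np.ndarray:
    codes = encode(seq)
    usable = codes[frame : frame + (len(codes) - frame) // 3 * 3]
    if len(usable) < 3:
        return np.empty(0, dtype=np.int64)
    tri = usable.reshape(-1, 3)
    valid = (tri >= 0).all(axis=1)
    return tri[valid] @ np.array([16, 4, 1], dtype=np.int64)


def triplet_frame_score(seq: str, logodds: np.ndarray) -> float:
    """Max over the 3 forward frames of the mean adjacent-codon-pair log-odds."""
    best = -np.inf
    for frame in range(3):
        c = codon_codes(seq, frame)
        if len(c) < 2:
            continue
        best = max(best, float(np.mean(logodds[c[:-1], c[1:]])))
    return best if np.isfinite(best) else 0.0


_STOP_SET = {int("".join(str(_BASE_CODE[b]) for b in s), 4) for s in STOP_CODONS}
_STOP_CODES = np.array(sorted(
    _BASE_CODE[s[0]] * 16 + _BASE_CODE[s[1]] * 4 + _BASE_CODE[s[2]] for s in STOP_CODONS
))


def stop_density_score(seq: str) -> float:
    """-(min over frames of the stop-codon rate) + 0.3 * GC fraction.

    A long ORF depresses one frame's stop rate, and coding sequences here are
    GC-richer; both push the score up for coding-like input."""
    rates = []
    for frame in range(3):
        c = codon_codes(seq, frame)
        if len(c) == 0:
            continue
        rates.append(float(np.isin(c, _STOP_CODES).mean()))
    min_rate = min(rates) if rates else 0.0
    codes = encode(seq)
    acgt = codes[codes >= 0]
    gc = float(((acgt == 1) | (acgt == 2)).mean()) if len(acgt) else 0.0
    return -min_rate + 0.3 * gc


# ---------------------------------------------------------------------------
# assessment container and the consensus


@dataclass(frozen=True)
class ScorerResult:
    scorer_name: str
    raw_score: float
    vote: str  # coding | noncoding


@dataclass
class CodingAssessment:
    transcript_id: str
    results: list[ScorerResult]
    noncoding_votes: int
    consensus: str                      # coding | noncoding
    domain_hit: str | None = None
    final_class: str | None = None      # novel_lncRNA | coding

    @staticmethod
    def consensus_from_votes(noncoding_votes: int) -> str:
        return "noncoding" if noncoding_votes >= NONCODING_VOTES_REQUIRED else "coding"


def score_all(seq: str, transcript_id: str = "", calibration=None) -> CodingAssessment:
    """Run the seven scorers and record the consensus vote (no domain filter)."""
    if calibration is None:
        from .calibration import get_calibration

        calibration = get_calibration()
    orf = longest_orf(seq)
    orf_len = orf.length if orf else 0
    raw = {
        "orf_length": float(orf_len),
        "orf_coverage": orf_len / len(seq) if seq else 0.0,
        "fickett": fickett_score(seq),
        "hexamer": hexamer_score(seq, calibration.hexamer_coding,
                                 calibration.hexamer_noncoding),
        "kmer_spectrum": float(kmer_features(seq) @ calibration.kmer_weights
                               + calibration.kmer_bias),
        "triplet_frame": triplet_frame_score(seq, calibration.triplet_logodds),
        "stop_density": stop_density_score(seq),
    }
    results = []
    n_noncoding = 0
    for name in SCORER_NAMES:
        vote = "coding" if raw[name] >= calibration.thresholds[name] else "noncoding"
        n_noncoding += vote == "noncoding"
        results.append(ScorerResult(name, raw[name], vote))
    return CodingAssessment(
        transcript_id=transcript_id,
        results=results,
        noncoding_votes=n_noncoding,
        consensus=CodingAssessment.consensus_from_votes(n_noncoding),
    )


# ---------------------------------------------------------------------------
# domain (motif) filter


@dataclass(frozen=True)
class Motif:
    name: str
    threshold: float
    matrix: np.ndarray  # L x 20, alphabet ACDEFGHIKLMNPQRSTVWY

    def best_score(self, peptide: str) -> float:
        from ._tables import AA_ALPHABET

        idx = np.array([AA_ALPHABET.find(a) for a in peptide])
        L = self.matrix.shape[0]
        if len(idx) < L:
            return -np.inf
        best = -np.inf
        col_mean = self.matrix.mean(axis=1)
        for off in range(len(idx) - L + 1):
            window = idx[off : off + L]
            s = 0.0
            for p, a in enumerate(window):
                s += self.matrix[p, a] if a >= 0 else col_mean[p]
            best = max(best, s)
        return best


def load_motif_library(path: str | Path | None = None) -> list[Motif]:
    """Read the PSSM motif library.

    Format: blocks of ``MOTIF <name> THRESH <t>`` followed by L lines of 20
    whitespace-separated log-odds values (alphabet ACDEFGHIKLMNPQRSTVWY)."""
    if path is None:
        path = resources.files("lncreg").joinpath("data/motifs.tsv")
    text = Path(str(path)).read_text() if not hasattr(path, "read_text") else path.read_text()
    motifs = []
    name, threshold, rows = None, None, []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("MOTIF"):
            if name is not None:
                motifs.append(Motif(name, threshold, np.array(rows)))
            parts = line.split()
            name, threshold, rows = parts[1], float(parts[3]), []
        else:
            row = [float(x) for x in line.split()]
            if len(row) != 20:
                raise ValidationError(f"motif {name}: expected 20 columns, got {len(row)}")
            rows.append(row)
    if name is not None:
        motifs.append(Motif(name, threshold, np.array(rows)))
    return motifs


def translate(cds: str) -> str:
    aa = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    return aa.rstrip("*")


def domain_filter(
    assessment: CodingAssessment,
    seq: str,
    motif_library: Sequence[Motif],
    min_orf_nt: int = 90,
) -> str:
    """Final classification: consensus-noncoding + no domain hit => novel lncRNA.

    Every ORF >= ``min_orf_nt`` in the 3 forward frames is translated and
    scanned against the motif library; any motif scoring at or above its
    threshold marks the transcript coding. Consensus-coding transcripts stay
    coding regardless of motifs.
    """
    if not motif_library:
        raise ConfigurationError("motif library is empty; refusing to pass-through")
    if assessment.consensus == "coding":
        assessment.final_class = "coding"
        return assessment.final_class
    hit = None
    for orf in find_orfs(seq, min_length=min_orf_nt):
        peptide = translate(seq[orf.start : orf.end])
        for motif in motif_library:
            if motif.best_score(peptide) >= motif.threshold:
                hit = motif.name
                break
        if hit:
            break
    assessment.domain_hit = hit
    assessment.final_class = "coding" if hit else "novel_lncRNA"
    return assessment.final_class
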