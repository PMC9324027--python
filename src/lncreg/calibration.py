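"""Fixed-seed calibration of the coding-potential scorers.

All estimated artifacts -- the coding/noncoding hexamer frequency tables, the
k-mer-spectrum logistic weights, the adjacent-codon-pair log-odds matrix and
the per-scorer vote thresholds -- are pure functions of a fixed seed (2022)
and a fixed calibration-set size, recomputed deterministically at first use
and memoized per process. Thresholds sit at each scorer's equal-error-rate
point on the calibration set, so every scorer's vote is a priori symmetric
between the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import coding, simulate

CALIBRATION_SEED = 2022
N_PER_CLASS = 2000


@dataclass
class CodingCalibration:
    hexamer_coding: np.ndarray      # 4096 probabilities, all > 0
    hexamer_noncoding: np.ndarray
    kmer_weights: np.ndarray        # 1364 logistic weights (logit scale)
    kmer_bias: float
    triplet_logodds: np.ndarray     # 64 x 64 adjacent codon-pair log-odds
    thresholds: dict[str, float]    # scorer -> vote-coding-at-or-above


def make_calibration_sequences(
    n_per_class: int, seed: int
) -> tuple[list[tuple[str, tuple[int, int]]], list[str]]:
    """(coding sequences with ORF spans, noncoding sequences) from the generator."""
    rng = np.random.default_rng(seed)
    coding_seqs = []
    for _ in range(n_per_class):
        seq, a, b = simulate.make_coding_sequence(rng)
        coding_seqs.append((seq, (a, b)))
    noncoding_seqs = [
        simulate.make_noncoding_sequence(rng, int(rng.integers(250, 901)))
        for _ in range(n_per_class)
    ]
    return coding_seqs, noncoding_seqs


def _hexamer_table(chunks: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4096)  # +1 pseudocount keeps every entry > 0
    for h in chunks:
        counts += np.bincount(h, minlength=4096)
    return counts / counts.sum()


def _pair_counts(codon_arrays: list[np.ndarray]) -> np.ndarray:
    m = np.ones((64, 64))
    for c in codon_arrays:
        if len(c) >= 2:
            np.add.at(m, (c[:-1], c[1:]), 1)
    return m


def equal_error_threshold(coding_scores: np.ndarray, noncoding_scores: np.ndarray) -> float:
    """Threshold t minimizing |FNR - FPR| for the rule 'coding iff score >= t'."""
    allv = np.unique(np.concatenate([coding_scores, noncoding_scores]))
    cuts = np.concatenate([[allv[0] - 1], (allv[:-1] + allv[1:]) / 2, [allv[-1] + 1]])
    fnr = np.array([(coding_scores < t).mean() for t in cuts])
    fpr = np.array([(noncoding_scores >= t).mean() for t in cuts])
    return float(cuts[np.argmin(np.abs(fnr - fpr))])


@lru_cache(maxsize=2)
def get_calibration(
    n_per_class: int = N_PER_CLASS, seed: int = CALIBRATION_SEED
) -> CodingCalibration:
    coding_seqs, noncoding_seqs = make_calibration_sequences(n_per_class, seed)

    # Hexamer tables: in-frame hexamers of the ORF for coding, frame 0 for
    # noncoding -- the same convention the scorer applies at run time.
    cod_hex = [
        coding.inframe_hexamers(seq[a:b], 0) for seq, (a, b) in coding_seqs
    ]
    non_hex = [coding.inframe_hexamers(seq, 0) for seq in noncoding_seqs]
    hex_c = _hexamer_table(cod_hex)
    hex_n = _hexamer_table(non_hex)

    cod_codons = [coding.codon_codes(seq[a:b], 0) for seq, (a, b) in coding_seqs]
    non_codons = [coding.codon_codes(seq, 0) for seq in noncoding_seqs]
    pc = _pair_counts(cod_codons)
    pn = _pair_counts(non_codons)
    triplet = np.log(pc / pc.sum()) - np.log(pn / pn.sum())

    X = np.array(
        [coding.kmer_features(seq) for seq, _ in coding_seqs]
        + [coding.kmer_features(seq) for seq in noncoding_seqs]
    )
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    lr = LogisticRegression(C=1.0, max_iter=2000)
    lr.fit(X, y)
    kmer_w, kmer_b = lr.coef_[0], float(lr.intercept_[0])

    partial = CodingCalibration(
        hexamer_coding=hex_c,
        hexamer_noncoding=hex_n,
        kmer_weights=kmer_w,
        kmer_bias=kmer_b,
        triplet_logodds=triplet,
        thresholds={name: 0.0 for name in coding.SCORER_NAMES},
    )
    score_rows_c = np.array(
        [_raw_scores(seq, partial) for seq, _ in coding_seqs]
    )
    score_rows_n = np.array([_raw_scores(seq, partial) for seq in noncoding_seqs])
    thresholds = {
        name: equal_error_threshold(score_rows_c[:, i], score_rows_n[:, i])
        for i, name in enumerate(coding.SCORER_NAMES)
    }
    partial.thresholds = thresholds
    return partial


def _raw_scores(seq: str, cal: CodingCalibration) -> list[float]:
    orf = coding.longest_orf(seq)
    orf_len = orf.length if orf else 0
    return [
        float(orf_len),
        orf_len / len(seq) if seq else 0.0,
        coding.fickett_score(seq),
        coding.hexamer_score(seq, cal.hexamer_coding, cal.hexamer_noncoding),
        float(coding.kmer_features(seq) @ cal.kmer_weights + cal.kmer_bias),
        coding.triplet_frame_score(seq, cal.triplet_logodds),
        coding.stop_density_score(seq),
    ]
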