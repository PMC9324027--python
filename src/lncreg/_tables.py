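"""Bundled constant tables: Fickett TESTCODE lookups, codon-usage weights,
nearest-neighbor duplex stack energies, and amino-acid propensity scales.

These are small, versioned-with-the-code reference tables; everything that is
*estimated* (hexamer tables, classifier weights, thresholds) lives in the
calibration modules instead and is a pure function of a fixed seed.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Fickett (1982) TESTCODE lookup tables, as used by CPAT-style tools.
# Position parameter: for each base, max positional count / (min + 1); the
# probability is looked up at the first threshold the value reaches.

FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
FICKETT_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

# Content parameter: base composition fraction, same lookup mechanics.
FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
FICKETT_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.15, 0.0]

# ---------------------------------------------------------------------------
# Codon-usage weights for generating coding ORFs (typical vertebrate bias,
# relative weights per sense codon; stops excluded). The absolute values are
# only used as sampling weights.

CODON_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

STOP_CODONS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# RNA-RNA duplex nearest-neighbor stack free energies (kcal/mol, 37 C).
# DNA letters with T standing for U. Keyed by the top-strand 5'->3'
# dinucleotide of a stack of two Watson-Crick pairs (Turner-style values);
# stacks involving one or two G.T (G.U) wobble pairs take the flat terms
# below. More negative = more stable.

WC_STACK_DG = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "CT": -2.08, "AG": -2.08,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

# One wobble pair in the stack / both pairs wobble.
WOBBLE_STACK_DG = -1.00
DOUBLE_WOBBLE_STACK_DG = -0.50

# Allowed base pairs (x from one strand, y from the other, antiparallel).
RNA_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Free energy of stacking ``pair2`` (x[i+1]:y[j']) on ``pair1`` (x[i]:y[j]).

    Both pairs must be valid (Watson-Crick or G.T wobble); the caller checks.
    """
    w1, w2 = pair1 not in WC_PAIRS, pair2 not in WC_PAIRS
    if w1 and w2:
        return DOUBLE_WOBBLE_STACK_DG
    if w1 or w2:
        return WOBBLE_STACK_DG
    return WC_STACK_DG[pair1[0] + pair2[0]]


# ---------------------------------------------------------------------------
# Amino-acid propensity scales used by the RNA-protein interaction scorer.
# Alphabet order for matrices/profiles:

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Hydrogen-bonding propensity (relative donor+acceptor capacity of the side
# chain; arbitrary units, higher = more H-bond capable).
AA_HBOND = {
    "A": 0.10, "C": 0.35, "D": 0.85, "E": 0.80, "F": 0.08,
    "G": 0.12, "H": 0.75, "I": 0.05, "K": 0.78, "L": 0.05,
    "M": 0.15, "N": 0.90, "P": 0.10, "Q": 0.88, "R": 0.95,
    "S": 0.70, "T": 0.66, "V": 0.06, "W": 0.40, "Y": 0.62,
}

# Van der Waals interaction propensity (normalized side-chain volume).
AA_VDW = {
    "A": 0.31, "C": 0.44, "D": 0.45, "E": 0.56, "F": 0.77,
    "G": 0.22, "H": 0.61, "I": 0.66, "K": 0.67, "L": 0.66,
    "M": 0.66, "N": 0.46, "P": 0.41, "Q": 0.57, "R": 0.78,
    "S": 0.33, "T": 0.44, "V": 0.55, "W": 0.92, "Y": 0.80,
}

# Helix propensity (Chou-Fasman style P_alpha, rescaled to ~[0,1.5]).
AA_HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

# Background amino-acid frequencies (approximately vertebrate proteome).
AA_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.042,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

# Karlin-Altschul parameters for ungapped +2/-3 nucleotide scoring.
KA_LAMBDA = 0.625
KA_K = 0.41
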