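"""Seeded generator of a synthetic multi-tissue RNA-seq study with planted truth.

The generator emulates the study design the pipeline targets: three male
reproductive-tract tissues (testis T, epididymis E, ductus deferens DD) with
six biological replicates each, a mixed transcriptome of protein-coding mRNAs
(long codon-biased ORFs), known lncRNAs (present in a reference lncRNA set),
novel lncRNAs (no ORF >= 100 nt), and filter-bait decoys each violating
exactly one structural filter. On top of the transcriptome it plants the four
kinds of regulatory structure the interaction engine looks for: CIS neighbors
at a configured genomic gap, TRANS co-expressed DEL-DEG pairs (shared tissue
effect plus a shared per-sample latent factor), exact reverse-complement
duplex windows, and RNA-protein partner pairs whose proteins carry elevated
hydrogen-bonding composition.

Counts are negative binomial with mean m and variance m + alpha*m^2. All
outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import core
from ._tables import AA_BACKGROUND, AA_HBOND, CODON_USAGE, STOP_CODONS
from .core import CountMatrix, GeneModel, GenomicInterval, TranscriptModel

BASES = np.array(list("ACGT"))
COMPARISONS = ("E_vs_T", "DD_vs_T", "E_vs_DD")
BAIT_REASONS = ("mono_exonic", "too_short", "low_expression")


class CapacityError(ValueError):
    """Chromosomes too short for the requested gene content."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the target study: 3 tissues x 6 replicates, NB counts
    with dispersion 0.1, and a transcriptome large enough to exercise every
    filter and interaction tier while staying desk-scale.
    """

    seed: int = 42
    n_chromosomes: int = 3
    chromosome_length: int = 1_600_000
    n_coding_genes: int = 110
    n_known_lncrnas: int = 30
    n_novel_lncrnas: int = 60
    n_bait_transcripts: int = 9
    replicates_per_tissue: int = 6
    nb_dispersion: float = 0.1
    de_fraction: float = 0.3
    planted_log2fc: tuple[float, ...] = (2.0, 3.0)
    n_cis_pairs: int = 6
    cis_gap_bp: int = 50_000
    n_trans_pairs: int = 8
    trans_factor_sd: float = 0.8
    trans_log2fc: tuple[float, float] = (5.0, 7.0)
    n_duplex_pairs: int = 6
    duplex_length: int = 60
    n_protein_partners: int = 6  # positive pairs; an equal number of negatives is added
    tissues: tuple[str, ...] = ("T", "E", "DD")

    def validate(self) -> None:
        if min(
            self.n_chromosomes, self.n_coding_genes, self.n_known_lncrnas,
            self.n_novel_lncrnas, self.n_bait_transcripts,
        ) < 0:
            raise ValueError("counts must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.duplex_length < 10:
            raise ValueError("duplex_length must be >= 10")
        n_planted_lnc = (
            self.n_cis_pairs + self.n_trans_pairs + self.n_duplex_pairs
            + 2 * self.n_protein_partners
        )
        if n_planted_lnc > self.n_novel_lncrnas:
            raise ValueError("not enough novel lncRNAs for the planted pairs")
        if n_planted_lnc > self.n_coding_genes:
            raise ValueError("not enough coding genes for the planted pairs")


@dataclass
class TruthManifest:
    """Planted ground truth, one flat table per category."""

    classes: pd.DataFrame      # transcript_id, gene_id, true_class, bait_reason
    expression: pd.DataFrame   # gene_id, base_mean, de_tissue, log2fc, trans_group
    orfs: pd.DataFrame         # gene_id, transcript_id, orf_start, orf_end (spliced, 1-based)
    cis_pairs: pd.DataFrame    # del_gene, deg_gene, gap_bp
    trans_pairs: pd.DataFrame  # del_gene, deg_gene, trans_group
    duplex_pairs: pd.DataFrame # del_transcript, deg_transcript, window coords
    protein_pairs: pd.DataFrame  # del_transcript, deg_gene, label (positive/negative)

    def true_log2fc(self, gene_id: str, comparison: str) -> float:
        """Planted log2 fold change for one gene in one tissue comparison."""
        row = self.expression.loc[self.expression["gene_id"] == gene_id]
        if row.empty:
            return 0.0
        tissue, lfc = row.iloc[0]["de_tissue"], row.iloc[0]["log2fc"]
        if not tissue or tissue == "none":
            return 0.0
        num, den = comparison.split("_vs_")
        if tissue == num:
            return lfc
        if tissue == den:
            return -lfc
        return 0.0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("classes", "expression", "orfs", "cis_pairs", "trans_pairs",
                     "duplex_pairs", "protein_pairs"):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthManifest":
        outdir = Path(outdir)
        kw = {}
        for name in ("classes", "expression", "orfs", "cis_pairs", "trans_pairs",
                     "duplex_pairs", "protein_pairs"):
            kw[name] = pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t",
                                   keep_default_na=False)
        return cls(**kw)


# ---------------------------------------------------------------------------
# sequence building blocks

_CODONS = sorted(CODON_USAGE)
_CODON_W = np.array([CODON_USAGE[c] for c in _CODONS])
_CODON_W = _CODON_W / _CODON_W.sum()

_AA_OF = {c: str(Seq(c).translate()) for c in _CODONS}
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c, _a in _AA_OF.items():
    _CODONS_FOR_AA.setdefault(_a, []).append(_c)

_AAS = sorted(AA_BACKGROUND)
_AA_BG_W = np.array([AA_BACKGROUND[a] for a in _AAS])
_AA_BG_W = _AA_BG_W / _AA_BG_W.sum()
# Hydrogen-bond enriched composition for planted positive protein partners.
_AA_POS_W = _AA_BG_W * np.exp(2.5 * np.array([AA_HBOND[a] for a in _AAS]))
_AA_POS_W = _AA_POS_W / _AA_POS_W.sum()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _scan_orfs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """0-based [start, end) spans of ORFs >= min_len nt in 3 forward frames.

    An ORF runs ATG..stop (stop included); without a stop it runs to the last
    complete codon.
    """
    spans = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i
                end = None
                while j + 3 <= n:
                    if seq[j : j + 3] in STOP_CODONS and j > i:
                        end = j + 3
                        break
                    j += 3
                if end is None:
                    end = i + ((n - i) // 3) * 3
                if end - i >= min_len:
                    spans.append((i, end))
                i = end
            else:
                i += 3
    return spans


def break_long_orfs(
    seq: str,
    rng: np.random.Generator,
    max_orf: int = 99,
    protected: tuple[int, int] | None = None,
) -> str:
    """Destroy every ORF longer than ``max_orf`` nt by in-frame stop insertion.

    ``protected`` is a 0-based [start, end) window left untouched (used to
    preserve planted duplex windows)."""
    s = list(seq)
    for _ in range(300):
        spans = _scan_orfs("".join(s), max_orf + 1)
        if not spans:
            return "".join(s)
        start, end = spans[0]
        # candidate codon positions inside the ORF, past the ATG
        candidates = [
            p for p in range(start + 3, end - 2, 3)
            if protected is None or p + 3 <= protected[0] or p >= protected[1]
        ]
        if not candidates:
            # ORF only survives inside the protected window (< max_orf wide):
            # cannot happen for windows shorter than max_orf, guard anyway
            return "".join(s)
        p = candidates[rng.integers(0, len(candidates))]
        s[p : p + 3] = "TAA"
    raise RuntimeError("ORF breaking did not converge")


def make_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no ORF >= 100 nt (lncRNA-like)."""
    return break_long_orfs(random_dna(rng, length), rng)


def make_coding_sequence(
    rng: np.random.Generator,
    n_codons: int | None = None,
    aa_weights: np.ndarray | None = None,
) -> tuple[str, int, int]:
    """mRNA-like sequence: UTR5 + codon-biased ORF + UTR3.

    Returns (sequence, orf_start, orf_end) with a 0-based [start, end) ORF
    span on the spliced sequence. The ORF is ATG + sense codons + stop, drawn
    from the bundled codon-usage weights (or from per-amino-acid weights with
    synonymous-codon usage when ``aa_weights`` is given).
    """
    if n_codons is None:
        n_codons = int(rng.integers(100, 301))
    utr5 = break_long_orfs(random_dna(rng, int(rng.integers(30, 121))), rng, max_orf=60)
    utr3 = break_long_orfs(random_dna(rng, int(rng.integers(80, 251))), rng, max_orf=60)
    codons = ["ATG"]
    if aa_weights is None:
        idx = rng.choice(len(_CODONS), size=n_codons, p=_CODON_W)
        body = [_CODONS[i] for i in idx if _AA_OF[_CODONS[i]] != "M"]
        codons += body
    else:
        aas = rng.choice(len(_AAS), size=n_codons, p=aa_weights)
        for k in aas:
            opts = _CODONS_FOR_AA[_AAS[k]]
            w = np.array([CODON_USAGE[c] for c in opts])
            codons.append(opts[rng.choice(len(opts), p=w / w.sum())])
    codons.append(str(rng.choice(list(STOP_CODONS))))
    orf = "".join(codons)
    # make sure the ORF is not broken by upstream in-frame starts: it begins
    # at the first ATG of its own frame by construction of the UTR
    seq = utr5 + orf + utr3
    return seq, len(utr5), len(utr5) + len(orf)


def make_rna_protein_pairs(
    n_pos: int, n_neg: int, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    """Synthetic (RNA, protein, label) pairs for scorer calibration.

    Positive-pair proteins are drawn from the hydrogen-bond enriched
    composition; negatives from the background composition."""
    pairs = []
    for label, n in ((1, n_pos), (0, n_neg)):
        for _ in range(n):
            rna = make_noncoding_sequence(rng, int(rng.integers(200, 501)))
            w = _AA_POS_W if label else _AA_BG_W
            plen = int(rng.integers(120, 301))
            prot = "".join(_AAS[i] for i in rng.choice(len(_AAS), size=plen, p=w))
            pairs.append((rna, prot, label))
    return pairs


def draw_nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw: variance = m + dispersion*m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion < 1e-10:
        out[pos] = rng.poisson(mean[pos])
        return out
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean[pos] * dispersion)
    out[pos] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# annotation generation


def _split_exons(rng: np.random.Generator, seq_len: int, n_exons: int) -> list[int]:
    """Exon lengths summing to seq_len, each >= 30 nt."""
    if n_exons == 1:
        return [seq_len]
    while True:
        cuts = np.sort(rng.choice(np.arange(30, seq_len - 29), size=n_exons - 1,
                                  replace=False))
        lens = np.diff(np.concatenate([[0], cuts, [seq_len]]))
        if (lens >= 30).all():
            return [int(x) for x in lens]


@dataclass
class _GenePlan:
    gene_id: str
    transcript_id: str
    true_class: str
    sequence: str
    n_exons: int
    bait_reason: str = ""
    orf: tuple[int, int] | None = None
    duplex_window: tuple[int, int] | None = None
    strand: str = "+"
    cis_partner_of: str | None = None  # gene to place cis_gap_bp downstream of


def generate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthManifest, dict[str, str]]:
    """Build the genome, gene models and truth manifest.

    Returns (genome, genes, manifest, reference_lncrnas). Transcript
    sequences are filled in; the genome contains each transcript's exons so
    that re-extracting sequences from genome+GTF reproduces them exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    plans: list[_GenePlan] = []
    coding_ids = [f"CG{i:04d}" for i in range(config.n_coding_genes)]
    novel_ids = [f"NL{i:04d}" for i in range(config.n_novel_lncrnas)]
    known_ids = [f"KL{i:04d}" for i in range(config.n_known_lncrnas)]
    bait_ids = [f"BT{i:04d}" for i in range(config.n_bait_transcripts)]

    # Reserve planted-pair members from the front of each list.
    novel_cursor = coding_cursor = 0

    def take_novel() -> str:
        nonlocal novel_cursor
        nid = novel_ids[novel_cursor]
        novel_cursor += 1
        return nid

    def take_coding() -> str:
        nonlocal coding_cursor
        cid = coding_ids[coding_cursor]
        coding_cursor += 1
        return cid

    cis = [(take_novel(), take_coding()) for _ in range(config.n_cis_pairs)]
    trans = [(take_novel(), take_coding()) for _ in range(config.n_trans_pairs)]
    duplex = [(take_novel(), take_coding()) for _ in range(config.n_duplex_pairs)]
    prot_pos = [(take_novel(), take_coding()) for _ in range(config.n_protein_partners)]
    prot_neg = [(take_novel(), take_coding()) for _ in range(config.n_protein_partners)]
    pos_partner_genes = {c for _, c in prot_pos}

    # --- coding genes
    coding_plans: dict[str, _GenePlan] = {}
    for gid in coding_ids:
        aa_w = _AA_POS_W if gid in pos_partner_genes else None
        seq, ostart, oend = make_coding_sequence(rng, aa_weights=aa_w)
        coding_plans[gid] = _GenePlan(
            gene_id=gid, transcript_id=f"{gid}.t1", true_class="coding",
            sequence=seq, n_exons=int(rng.integers(3, 7)), orf=(ostart, oend),
            strand="+" if rng.random() < 0.5 else "-",
        )

    # --- lncRNAs
    lnc_plans: dict[str, _GenePlan] = {}
    for gid in novel_ids + known_ids:
        seq = make_noncoding_sequence(rng, int(rng.integers(300, 901)))
        lnc_plans[gid] = _GenePlan(
            gene_id=gid, transcript_id=f"{gid}.t1",
            true_class="novel_lncRNA" if gid.startswith("NL") else "known_lncRNA",
            sequence=seq, n_exons=int(rng.integers(2, 5)),
            strand="+" if rng.random() < 0.5 else "-",
        )

    # --- plant duplex windows: lncRNA carries the exact reverse complement of
    # a window from the partner mRNA's 3' UTR
    duplex_rows = []
    for lnc_gid, cod_gid in duplex:
        cp, lp = coding_plans[cod_gid], lnc_plans[lnc_gid]
        w = config.duplex_length
        utr3_start = cp.orf[1]
        if len(cp.sequence) - utr3_start < w + 10:
            raise CapacityError("mRNA 3' UTR too short for the duplex window")
        m0 = utr3_start + int(rng.integers(0, len(cp.sequence) - utr3_start - w + 1))
        window = cp.sequence[m0 : m0 + w]
        l0 = int(rng.integers(20, len(lp.sequence) - w - 20))
        new = lp.sequence[:l0] + core.reverse_complement(window) + lp.sequence[l0 + w :]
        lp.sequence = break_long_orfs(new, rng, protected=(l0, l0 + w))
        lp.duplex_window = (l0, l0 + w)
        duplex_rows.append(
            {
                "del_transcript": lp.transcript_id, "deg_transcript": cp.transcript_id,
                "lnc_start": l0 + 1, "lnc_end": l0 + w,
                "mrna_start": m0 + 1, "mrna_end": m0 + w,
            }
        )

    # --- baits: each violates exactly one structural filter
    bait_plans: dict[str, _GenePlan] = {}
    for i, gid in enumerate(bait_ids):
        reason = BAIT_REASONS[i % len(BAIT_REASONS)]
        if reason == "mono_exonic":
            seq, n_exons = make_noncoding_sequence(rng, int(rng.integers(300, 501))), 1
        elif reason == "too_short":
            seq, n_exons = make_noncoding_sequence(rng, int(rng.integers(120, 181))), 2
        else:  # low_expression
            seq, n_exons = make_noncoding_sequence(rng, int(rng.integers(300, 501))), 2
        bait_plans[gid] = _GenePlan(
            gene_id=gid, transcript_id=f"{gid}.t1", true_class="bait",
            sequence=seq, n_exons=n_exons, bait_reason=reason,
            strand="+" if rng.random() < 0.5 else "-",
        )

    # --- layout order: cis pairs adjacent, everything else shuffled
    for lnc_gid, cod_gid in cis:
        coding_plans[cod_gid].cis_partner_of = lnc_gid
    cis_lnc = {l for l, _ in cis}
    cis_cod = {c for _, c in cis}
    loose = (
        [p for g, p in coding_plans.items() if g not in cis_cod]
        + [p for g, p in lnc_plans.items() if g not in cis_lnc]
        + list(bait_plans.values())
    )
    order_idx = rng.permutation(len(loose))
    layout: list[_GenePlan] = []
    # interleave the cis blocks at deterministic positions
    loose_shuffled = [loose[i] for i in order_idx]
    cis_blocks = [[lnc_plans[l], coding_plans[c]] for l, c in cis]
    step = max(1, len(loose_shuffled) // (len(cis_blocks) + 1)) if cis_blocks else 1
    pos = 0
    for block in cis_blocks:
        pos += step
        loose_shuffled[pos:pos] = block
    layout = loose_shuffled

    # --- place genes on chromosomes and assemble genome
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}
    genes: list[GeneModel] = []
    cis_gap_actual: dict[tuple[str, str], int] = {}
    chrom_i = 0
    k = 0
    while k < len(layout):
        plan = layout[k]
        is_cis_block = plan.gene_id in cis_lnc
        block = [plan, layout[k + 1]] if is_cis_block else [plan]
        chrom = chrom_names[chrom_i % len(chrom_names)]
        chrom_i += 1

        built = []
        total_len = 0
        for j, p in enumerate(block):
            exon_lens = _split_exons(rng, len(p.sequence), p.n_exons)
            intron_lens = [int(rng.integers(100, 801)) for _ in range(p.n_exons - 1)]
            if p.strand == "+":
                pieces = _cut(p.sequence, exon_lens)
            else:
                pieces = [core.reverse_complement(x) for x in reversed(_cut(p.sequence, exon_lens))]
            built.append((p, pieces, intron_lens))
            total_len += sum(exon_lens) + sum(intron_lens)

        gap_before = int(rng.integers(3000, 12001))
        need = gap_before + total_len + (config.cis_gap_bp if is_cis_block else 0) + 1000
        if cursors[chrom] + need > config.chromosome_length:
            free = [c for c in chrom_names if cursors[c] + need <= config.chromosome_length]
            if not free:
                raise CapacityError(
                    "chromosomes too short for the requested gene content"
                )
            chrom = free[0]
        chrom_parts[chrom].append(random_dna(rng, gap_before))
        cursors[chrom] += gap_before

        for j, (p, pieces, intron_lens) in enumerate(built):
            if j == 1:  # second member of a cis pair: exact span gap
                gap = config.cis_gap_bp
                chrom_parts[chrom].append(random_dna(rng, gap))
                cursors[chrom] += gap
            exons = []
            for e, piece in enumerate(pieces):
                start = cursors[chrom] + 1
                chrom_parts[chrom].append(piece)
                cursors[chrom] += len(piece)
                exons.append(GenomicInterval(chrom, start, cursors[chrom], p.strand))
                if e < len(pieces) - 1:
                    chrom_parts[chrom].append(random_dna(rng, intron_lens[e]))
                    cursors[chrom] += intron_lens[e]
            # known-ness is discovered by similarity search downstream; the
            # emitted annotation only distinguishes protein-coding vs not
            biotype = "protein_coding" if p.true_class == "coding" else "novel"
            tm = TranscriptModel(p.transcript_id, p.gene_id, exons,
                                 sequence=p.sequence, biotype=biotype)
            genes.append(GeneModel(p.gene_id, [tm]))
        if is_cis_block:
            g_lnc, g_cod = genes[-2], genes[-1]
            gap = g_cod.span.start - g_lnc.span.end - 1
            cis_gap_actual[(g_lnc.gene_id, g_cod.gene_id)] = gap
        k += len(block)

    genome = {
        c: "".join(parts) + random_dna(rng, 1000) for c, parts in chrom_parts.items()
    }

    # --- reference lncRNA set: each known lncRNA at ~98% identity
    reference = {}
    for gid in known_ids:
        seq = list(lnc_plans[gid].sequence)
        n_mut = max(1, int(round(0.02 * len(seq))))
        for p in rng.choice(len(seq), size=n_mut, replace=False):
            alts = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alts[rng.integers(0, 3)]
        reference[f"REF_{gid}"] = "".join(seq)

    # --- expression plan
    all_plans = list(coding_plans.values()) + list(lnc_plans.values()) + list(bait_plans.values())
    planted_de: dict[str, tuple[str, float]] = {}
    trans_group: dict[str, int] = {}
    pair_sets = [("cis", cis), ("duplex", duplex), ("prot", prot_pos + prot_neg)]
    t_cycle = list(config.tissues)
    ti = 0
    for _, pairs in pair_sets:
        for lnc_gid, cod_gid in pairs:
            tissue = t_cycle[ti % 3]
            ti += 1
            lfc = float(max(config.planted_log2fc))
            planted_de[lnc_gid] = (tissue, lfc)
            planted_de[cod_gid] = (tissue, lfc)
    for gi, (lnc_gid, cod_gid) in enumerate(trans):
        tissue = t_cycle[ti % 3]
        ti += 1
        lfc = float(rng.uniform(*config.trans_log2fc))
        planted_de[lnc_gid] = (tissue, lfc)
        planted_de[cod_gid] = (tissue, lfc)
        trans_group[lnc_gid] = gi
        trans_group[cod_gid] = gi
    # extra DE genes among the unplanted features
    unplanted = [p.gene_id for p in all_plans
                 if p.gene_id not in planted_de and p.true_class != "bait"]
    n_extra = int(round(config.de_fraction * len(unplanted)))
    extra = rng.choice(unplanted, size=n_extra, replace=False)
    for gid in extra:
        tissue = t_cycle[int(rng.integers(0, 3))]
        lfc = float(rng.choice(config.planted_log2fc))
        planted_de[gid] = (tissue, lfc)

    exp_rows = []
    for p in all_plans:
        if p.true_class == "bait" and p.bait_reason == "low_expression":
            base = 0.1
        elif p.gene_id in planted_de:
            base = float(rng.uniform(300, 2000))
        elif p.true_class == "coding":
            base = float(np.clip(rng.lognormal(np.log(150), 1.0), 5, 5000))
        else:
            base = float(np.clip(rng.lognormal(np.log(60), 0.8), 20, 2000))
        tissue, lfc = planted_de.get(p.gene_id, ("none", 0.0))
        exp_rows.append(
            {
                "gene_id": p.gene_id, "base_mean": base, "de_tissue": tissue,
                "log2fc": lfc, "trans_group": trans_group.get(p.gene_id, -1),
            }
        )

    manifest = TruthManifest(
        classes=pd.DataFrame(
            [
                {
                    "transcript_id": p.transcript_id, "gene_id": p.gene_id,
                    "true_class": p.true_class, "bait_reason": p.bait_reason,
                }
                for p in all_plans
            ]
        ),
        expression=pd.DataFrame(exp_rows),
        orfs=pd.DataFrame(
            [
                {
                    "gene_id": p.gene_id, "transcript_id": p.transcript_id,
                    "orf_start": p.orf[0] + 1, "orf_end": p.orf[1],
                }
                for p in coding_plans.values()
            ]
        ),
        cis_pairs=pd.DataFrame(
            [
                {"del_gene": l, "deg_gene": c, "gap_bp": cis_gap_actual[(l, c)]}
                for l, c in cis
            ]
        ),
        trans_pairs=pd.DataFrame(
            [
                {"del_gene": l, "deg_gene": c, "trans_group": trans_group[l]}
                for l, c in trans
            ]
        ),
        duplex_pairs=pd.DataFrame(duplex_rows),
        protein_pairs=pd.DataFrame(
            [
                {"del_transcript": f"{l}.t1", "deg_gene": c, "label": "positive"}
                for l, c in prot_pos
            ]
            + [
                {"del_transcript": f"{l}.t1", "deg_gene": c, "label": "negative"}
                for l, c in prot_neg
            ]
        ),
    )
    return genome, genes, manifest, reference


def _cut(seq: str, lens: list[int]) -> list[str]:
    out, p = [], 0
    for L in lens:
        out.append(seq[p : p + L])
        p += L
    return out


# ---------------------------------------------------------------------------
# counts and proteins


def generate_counts(
    genes: list[GeneModel], manifest: TruthManifest, config: SimulationConfig
) -> CountMatrix:
    """Negative-binomial counts per gene with planted tissue effects.

    A planted DE gene's mean is multiplied by 2**log2fc in its designated
    tissue. TRANS pair members additionally share a per-sample log-normal
    latent factor (sd = ``trans_factor_sd``), which lifts their expression
    correlation above the tissue effect alone.
    """
    rng = np.random.default_rng(config.seed + 1)
    tissues = list(config.tissues)
    reps = config.replicates_per_tissue
    sample_ids = [f"{t}_{r + 1}" for t in tissues for r in range(reps)]
    sample_tissue = np.array([t for t in tissues for _ in range(reps)])
    samples = pd.DataFrame(
        {
            "tissue": sample_tissue,
            "replicate": [r + 1 for _ in tissues for r in range(reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    exp = manifest.expression.set_index("gene_id")
    gene_ids = [g.gene_id for g in genes]
    n_samples = len(sample_ids)

    groups = sorted(g for g in exp["trans_group"].unique() if g >= 0)
    factors = {
        g: np.exp(config.trans_factor_sd * rng.standard_normal(n_samples)
                  - config.trans_factor_sd**2 / 2)
        for g in groups
    }

    means = np.zeros((len(gene_ids), n_samples))
    for i, gid in enumerate(gene_ids):
        row = exp.loc[gid]
        m = np.full(n_samples, float(row["base_mean"]))
        if row["de_tissue"] in tissues:
            m[sample_tissue == row["de_tissue"]] *= 2.0 ** float(row["log2fc"])
        if row["trans_group"] >= 0:
            m = m * factors[int(row["trans_group"])]
        means[i] = m
    counts = draw_nb_counts(rng, means, config.nb_dispersion)
    values = pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                          columns=sample_ids)
    return CountMatrix(values=values, samples=samples)


def generate_proteins(
    genes: list[GeneModel], manifest: TruthManifest, config: SimulationConfig
) -> dict[str, str]:
    """Amino-acid sequences for every protein-partner DEG, from its planted ORF."""
    seq_of = {t.transcript_id: t.sequence for g in genes for t in g.transcripts}
    orfs = manifest.orfs.set_index("gene_id")
    out: dict[str, str] = {}
    for gid in manifest.protein_pairs["deg_gene"].unique():
        if gid not in orfs.index:
            raise ValueError(f"protein partner gene {gid} lacks a planted ORF")
        row = orfs.loc[gid]
        cds = seq_of[row["transcript_id"]][int(row["orf_start"]) - 1 : int(row["orf_end"])]
        out[gid] = translate_orf(cds)
    return out


def translate_orf(cds: str) -> str:
    """Standard-code translation of an ORF, trailing stop dropped."""
    aa = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# dataset on disk


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete synthetic dataset and write it as flat text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, manifest, reference = generate_annotation(config)
    counts = generate_counts(genes, manifest, config)
    proteins = generate_proteins(genes, manifest, config)

    paths = {
        "genome": outdir / "genome.fasta",
        "gtf": outdir / "annotation.gtf",
        "transcripts": outdir / "transcripts.fasta",
        "reference_lncrna": outdir / "reference_lncrna.fasta",
        "proteins": outdir / "proteins.fasta",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
    }
    core.write_fasta(genome, paths["genome"])
    core.write_gtf(genes, paths["gtf"])
    core.write_fasta(
        {t.transcript_id: t.sequence for g in genes for t in g.transcripts},
        paths["transcripts"],
    )
    core.write_fasta(reference, paths["reference_lncrna"])
    core.write_fasta(proteins, paths["proteins"])
    counts.to_tsv(paths["counts"], paths["samples"])
    manifest.write(outdir)
    return paths
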