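"""End-to-end orchestration: filtering -> coding potential -> differential
expression -> profile groups -> interaction tiers -> reporting.

Every threshold is carried in :class:`PipelineConfig` (defaults are the
study's published cutoffs) and handed to the stage functions; stage code
contains no threshold literals. A run directory receives one flat text file
per stage output plus ``run_summary.tsv`` and a log; identical inputs and
config give byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coding, core, de, filtering, interactions
from .core import CountMatrix, ValidationError

logger = logging.getLogger("lncreg")


@dataclass
class PipelineConfig:
    """All inputs and thresholds for a pipeline run."""

    # input paths
    gtf: str = "annotation.gtf"
    transcripts_fasta: str = "transcripts.fasta"
    genome_fasta: str | None = None          # used when transcripts_fasta absent
    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    reference_lncrna: str = "reference_lncrna.fasta"
    proteins_fasta: str | None = "proteins.fasta"
    motif_library: str | None = None         # None -> bundled library
    subset_genes: str | None = None          # optional gene list (one id per line)
    outdir: str = "run"
    seed: int = 42

    # thresholds (study defaults)
    similarity_identity: float = 90.0
    similarity_evalue: float = 1e-10
    min_length: int = 200
    min_exons: int = 2
    min_total_counts: int = 10
    noncoding_votes: int = 5
    q_threshold: float = 0.01
    min_abs_log2fc: float = 1.0
    cis_max_distance: int = 100_000
    trans_min_abs_r: float = 0.9
    trans_max_p: float = 0.05
    ndg_threshold: float = -0.1
    protein_min_probability: float = 0.90

    def validate(self) -> None:
        if not (0 <= self.similarity_identity <= 100):
            raise ValidationError("similarity_identity outside [0, 100]")
        if not (0 < self.q_threshold < 1) or not (0 < self.trans_max_p < 1):
            raise ValidationError("q/p thresholds must lie in (0, 1)")
        if not (0 <= self.trans_min_abs_r <= 1):
            raise ValidationError("trans_min_abs_r outside [0, 1]")
        if not (0 <= self.protein_min_probability <= 1):
            raise ValidationError("protein_min_probability outside [0, 1]")
        if self.cis_max_distance < 0 or self.min_exons < 1:
            raise ValidationError("invalid structural thresholds")
        if not (0 <= self.noncoding_votes <= 7):
            raise ValidationError("noncoding_votes must lie in 0..7")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    outdir: Path
    filter_report: filtering.FilterReport
    assessments: pd.DataFrame
    de_results: pd.DataFrame
    groups: dict[str, list[str]]
    relations: pd.DataFrame
    counts_table: pd.DataFrame
    summary: pd.DataFrame
    novel_ids: list[str]
    known_ids: list[str]
    dels: pd.DataFrame
    degs: pd.DataFrame


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage=%s status=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                logger.error("stage=%s status=error cause=%r", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage=%s status=done", name)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    # ---- inputs -----------------------------------------------------------
    genes = _load_inputs(config)
    transcripts = [t for g in genes for t in g.transcripts]
    counts = CountMatrix.from_tsv(config.counts, config.samples)
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    totals = counts.values.sum(axis=1)
    tx_totals = {
        t.transcript_id: float(
            totals.get(t.transcript_id, totals.get(t.gene_id, 0.0))
        )
        for t in transcripts
    }
    reference = core.read_fasta(config.reference_lncrna)

    # ---- filtering --------------------------------------------------------
    known, candidates, hits = _filter_stage(config, transcripts, reference)
    report = filtering.apply_structural_filters(
        candidates,
        counts=None,
        counts_by_transcript=tx_totals,
        min_total_counts=config.min_total_counts,
        min_length=config.min_length,
        min_exons=config.min_exons,
    )
    retained = [t for t in candidates if report.status[t.transcript_id] == "retained"]
    logger.info(
        "stage=filter input=%d known=%d retained=%d",
        len(transcripts), len(known), len(retained),
    )
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    pd.DataFrame([vars(h) for h in hits]).to_csv(
        outdir / "similarity_hits.tsv", sep="\t", index=False
    )
    core.write_fasta({t.transcript_id: t.sequence for t in known},
                     outdir / "known_lncrna.fasta")
    core.write_fasta({t.transcript_id: t.sequence for t in retained},
                     outdir / "candidates.fasta")

    # ---- coding potential -------------------------------------------------
    assessments, novel = _classify_stage(config, retained)
    assessments.to_csv(outdir / "coding_assessment.tsv", sep="\t", index=False)
    novel_seqs = {t.transcript_id: t.sequence for t in retained
                  if t.transcript_id in novel}
    core.write_fasta(novel_seqs, outdir / "novel_lncrnas.fasta")
    logger.info("stage=classify candidates=%d novel=%d", len(retained), len(novel))

    # ---- differential expression ------------------------------------------
    gene_class = _gene_classes(genes, known, novel)
    lengths = {
        g.gene_id: max(t.spliced_length for t in g.transcripts) for g in genes
    }
    gene_counts = _gene_level_counts(counts, genes)
    fpkm = core.compute_fpkm(gene_counts, lengths)
    de_results = _de_stage(config, gene_counts, fpkm)
    de_results.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    fpkm.values.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="feature_id")

    de_hits = de_results[de_results["is_de"]]
    dels = de_hits[de_hits["feature_id"].map(gene_class).isin(
        ["known_lncRNA", "novel_lncRNA"])]
    degs = de_hits[de_hits["feature_id"].map(gene_class) == "protein_coding"]
    dels.to_csv(outdir / "dels.tsv", sep="\t", index=False)
    degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)

    groups = de.group_profiles(de_results)
    pd.DataFrame(
        [{"group": g, "feature_id": f} for g, feats in groups.items() for f in feats]
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)

    del_ids = sorted(set(dels["feature_id"]))
    if del_ids:
        de.zscore_matrix(fpkm, del_ids).to_csv(
            outdir / "zscores.tsv", sep="\t", index_label="feature_id"
        )
    for comp in de.COMPARISONS:
        de.ma_table(gene_counts, de_results, comp).to_csv(
            outdir / f"ma_{comp}.tsv", sep="\t", index=False
        )
        de.volcano_table(de_results, comp).to_csv(
            outdir / f"volcano_{comp}.tsv", sep="\t", index=False
        )

    # ---- interactions -----------------------------------------------------
    records = _interaction_stage(
        config, genes, transcripts, known, novel, dels, degs, fpkm
    )
    subset = None
    if config.subset_genes:
        subset = {
            line.strip()
            for line in Path(config.subset_genes).read_text().splitlines()
            if line.strip()
        }
    relations, counts_table, gene_classes_df, n_dup = interactions.assemble_relations(
        records, subset=subset
    )
    if n_dup:
        logger.warning("stage=interactions duplicates_collapsed=%d", n_dup)
    relations.to_csv(outdir / "relations.tsv", sep="\t", index=False)
    counts_table.to_csv(outdir / "cumulative_counts.tsv", sep="\t", index=False)
    gene_classes_df.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    if len(relations):
        interactions.export_network(
            relations, outdir / "network.sif", outdir / "network.graphml"
        )
        prot = sorted(
            set(relations.loc[relations["kind"] == "RNA_PROTEIN", "deg_id"])
        )
        (outdir / "protein_list.txt").write_text("\n".join(prot) + "\n")

    # ---- summary ----------------------------------------------------------
    summary = _summarize(transcripts, known, report, retained, novel,
                         de_results, gene_class, relations)
    summary.to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
    return PipelineResult(
        outdir=outdir,
        filter_report=report,
        assessments=assessments,
        de_results=de_results,
        groups=groups,
        relations=relations,
        counts_table=counts_table,
        summary=summary,
        novel_ids=sorted(novel),
        known_ids=[t.transcript_id for t in known],
        dels=dels,
        degs=degs,
    )


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    genes = core.read_gtf(config.gtf)
    if config.transcripts_fasta and Path(config.transcripts_fasta).exists():
        seqs = core.read_fasta(config.transcripts_fasta)
        for g in genes:
            for t in g.transcripts:
                if t.transcript_id not in seqs:
                    raise ValidationError(f"no sequence for {t.transcript_id}")
                t.sequence = seqs[t.transcript_id]
    elif config.genome_fasta:
        core.extract_transcript_sequences(core.read_fasta(config.genome_fasta), genes)
    else:
        raise ValidationError("need transcripts_fasta or genome_fasta")
    return genes


@_stage("annotate_known")
def _filter_stage(config, transcripts, reference):
    return filtering.annotate_known_lncrnas(
        transcripts,
        reference,
        identity_threshold=config.similarity_identity,
        evalue_threshold=config.similarity_evalue,
    )


@_stage("classify")
def _classify_stage(config, retained):
    library = coding.load_motif_library(config.motif_library)
    rows = []
    novel = set()
    for t in retained:
        a = coding.score_all(t.sequence, t.transcript_id)
        a.consensus = (
            "noncoding" if a.noncoding_votes >= config.noncoding_votes else "coding"
        )
        final = coding.domain_filter(a, t.sequence, library)
        if final == "novel_lncRNA":
            novel.add(t.transcript_id)
        row = {"transcript_id": t.transcript_id}
        for r in a.results:
            row[f"{r.scorer_name}_score"] = r.raw_score
            row[f"{r.scorer_name}_vote"] = r.vote
        row.update(
            noncoding_votes=a.noncoding_votes,
            consensus=a.consensus,
            domain_hit=a.domain_hit or "",
            final_class=final,
        )
        rows.append(row)
    return pd.DataFrame(rows), novel


@_stage("differential_expression")
def _de_stage(config, gene_counts, fpkm):
    return de.call_de(
        gene_counts,
        fpkm,
        q_threshold=config.q_threshold,
        min_abs_log2fc=config.min_abs_log2fc,
    )


def _gene_classes(genes, known, novel) -> dict[str, str]:
    known_ids = {t.transcript_id for t in known}
    classes = {}
    for g in genes:
        if any(t.biotype == "protein_coding" for t in g.transcripts):
            classes[g.gene_id] = "protein_coding"
        elif any(t.transcript_id in known_ids for t in g.transcripts):
            classes[g.gene_id] = "known_lncRNA"
        elif any(t.transcript_id in novel for t in g.transcripts):
            classes[g.gene_id] = "novel_lncRNA"
        else:
            classes[g.gene_id] = "other"
    return classes


def _gene_level_counts(counts: CountMatrix, genes) -> CountMatrix:
    """Collapse the count matrix to gene level (sum of member transcript rows;
    rows already at gene level pass through)."""
    rows = {}
    for g in genes:
        if g.gene_id in counts.values.index:
            rows[g.gene_id] = counts.values.loc[g.gene_id]
        else:
            member = [t.transcript_id for t in g.transcripts
                      if t.transcript_id in counts.values.index]
            if member:
                rows[g.gene_id] = counts.values.loc[member].sum(axis=0)
    values = pd.DataFrame(rows).T
    values.index.name = "feature_id"
    return CountMatrix(values=values, samples=counts.samples)


@_stage("interactions")
def _interaction_stage(config, genes, transcripts, known, novel, dels, degs, fpkm):
    span_of = {g.gene_id: g.span for g in genes}
    seq_of_gene: dict[str, str] = {}
    for g in genes:
        t = max(g.transcripts, key=lambda t: t.spliced_length)
        seq_of_gene[g.gene_id] = t.sequence

    proteins = {}
    if config.proteins_fasta and Path(config.proteins_fasta).exists():
        proteins = core.read_fasta(config.proteins_fasta)

    records: list[interactions.RelationRecord] = []
    model = interactions.get_rnaprotein_model() if proteins else None
    for comp in de.COMPARISONS:
        del_ids = sorted(dels.loc[dels["comparison"] == comp, "feature_id"])
        deg_ids = sorted(degs.loc[degs["comparison"] == comp, "feature_id"])
        if not del_ids or not deg_ids:
            continue
        records += interactions.find_cis(
            {d: span_of[d] for d in del_ids},
            {d: span_of[d] for d in deg_ids},
            max_distance=config.cis_max_distance,
            tag=comp,
        )
        # co-expression on log2(FPKM+1): raw-scale Pearson is dominated by
        # the few highest-expression samples
        log_fpkm = np.log2(fpkm.values + 1.0)
        trans_recs, _ = interactions.find_trans(
            log_fpkm.loc[del_ids],
            log_fpkm.loc[deg_ids],
            min_abs_r=config.trans_min_abs_r,
            max_p=config.trans_max_p,
            tag=comp,
        )
        records += trans_recs
        records += interactions.find_rna_rna(
            {d: seq_of_gene[d] for d in del_ids},
            {d: seq_of_gene[d] for d in deg_ids},
            ndg_threshold=config.ndg_threshold,
            tag=comp,
        )
        if proteins:
            records += interactions.find_rna_protein(
                {d: seq_of_gene[d] for d in del_ids},
                {g: proteins[g] for g in deg_ids if g in proteins},
                min_probability=config.protein_min_probability,
                tag=comp,
                model=model,
            )
    return records


def _summarize(transcripts, known, report, retained, novel, de_results,
               gene_class, relations) -> pd.DataFrame:
    rows = [("transcripts_input", len(transcripts)),
            ("known_lncrnas", len(known))]
    rows += [(f"filter_{stage}_survivors", n) for stage, n in report.stage_counts]
    removed = pd.Series(list(report.reason.values())).value_counts() if report.reason else {}
    for reason in filtering.CASCADE_ORDER:
        rows.append((f"removed_{reason}", int(removed.get(reason, 0))))
    rows.append(("candidates_retained", len(retained)))
    rows.append(("novel_lncrnas", len(novel)))
    rows.append(("lncrnas_total", len(novel) + len(known)))
    de_hits = de_results[de_results["is_de"]]
    for comp in de.COMPARISONS:
        sub = de_hits[de_hits["comparison"] == comp]
        lnc = sub[sub["feature_id"].map(gene_class).isin(
            ["known_lncRNA", "novel_lncRNA"])]
        rows.append((f"dels_{comp}", len(lnc)))
        rows.append((f"dels_{comp}_up", int((lnc["direction"] == "up").sum())))
        rows.append((f"dels_{comp}_down", int((lnc["direction"] == "down").sum())))
        rows.append((
            f"degs_{comp}",
            int((sub["feature_id"].map(gene_class) == "protein_coding").sum()),
        ))
    for kind in interactions.KINDS:
        rows.append((f"relations_{kind}", int((relations["kind"] == kind).sum())
                     if len(relations) else 0))
    return pd.DataFrame(rows, columns=["metric", "value"])
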