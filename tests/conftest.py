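import numpy as np
import pytest

from lncreg import calibration, pipeline, simulate


@pytest.fixture(scope="session")
def coding_calibration():
    return calibration.get_calibration()


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset (seed 42) written to disk once per session."""
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = simulate.SimulationConfig()
    simulate.write_dataset(cfg, outdir)
    manifest = simulate.TruthManifest.read(outdir)
    return {"dir": outdir, "config": cfg, "manifest": manifest}


def make_pipeline_config(datadir, outdir, **overrides) -> pipeline.PipelineConfig:
    cfg = pipeline.PipelineConfig(
        gtf=str(datadir / "annotation.gtf"),
        transcripts_fasta=str(datadir / "transcripts.fasta"),
        counts=str(datadir / "counts.tsv"),
        samples=str(datadir / "samples.tsv"),
        reference_lncrna=str(datadir / "reference_lncrna.fasta"),
        proteins_fasta=str(datadir / "proteins.fasta"),
        outdir=str(outdir),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """One full pipeline run on the default dataset, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = make_pipeline_config(dataset["dir"], outdir)
    result = pipeline.run_pipeline(cfg)
    return {"result": result, "outdir": outdir, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# 12-transcript structural-filter fixture with its hand-written oracle

FILTER_FIXTURE = {
    # transcript_id: (spliced length, n_exons, biotype, total counts)
    "keep1": (201, 2, "novel", 11),
    "keep2": (500, 3, "novel", 50),
    "keep3": (800, 2, "novel", 1000),
    "pc1": (900, 4, "protein_coding", 500),
    "pc2": (150, 1, "protein_coding", 3),  # fails several; cascade head wins
    "short1": (150, 3, "novel", 50),
    "short2": (200, 2, "novel", 50),       # exactly 200 nt -> removed (strict)
    "low1": (500, 2, "novel", 5),
    "low2": (500, 2, "novel", 10),         # exactly 10 counts -> removed (strict)
    "mono1": (500, 1, "novel", 50),
    "mono2": (300, 1, "novel", 400),
    "lowshort": (100, 2, "novel", 2),      # low_expression precedes too_short
}

FILTER_ORACLE = {
    "keep1": ("retained", ""),
    "keep2": ("retained", ""),
    "keep3": ("retained", ""),
    "pc1": ("removed", "annotated_protein_coding"),
    "pc2": ("removed", "annotated_protein_coding"),
    "short1": ("removed", "too_short"),
    "short2": ("removed", "too_short"),
    "low1": ("removed", "low_expression"),
    "low2": ("removed", "low_expression"),
    "mono1": ("removed", "mono_exonic"),
    "mono2": ("removed", "mono_exonic"),
    "lowshort": ("removed", "low_expression"),
}


def make_filter_fixture():
    """(transcripts, per-transcript total counts) for the bundled fixture."""
    from lncreg.core import GenomicInterval, TranscriptModel

    transcripts = []
    for tid, (length, n_exons, biotype, _counts) in FILTER_FIXTURE.items():
        seq_rng = np.random.default_rng(abs(hash(tid)) % 2**31)
        seq = "".join("ACGT"[i] for i in seq_rng.integers(0, 4, length))
        exon_len = length // n_exons
        exons, pos = [], 1
        for i in range(n_exons):
            L = exon_len if i < n_exons - 1 else length - exon_len * (n_exons - 1)
            exons.append(GenomicInterval("chr1", pos, pos + L - 1, "+"))
            pos += L + 100
        transcripts.append(
            TranscriptModel(tid, f"g_{tid}", exons, sequence=seq, biotype=biotype)
        )
    totals = {tid: float(c) for tid, (_, _, _, c) in FILTER_FIXTURE.items()}
    return transcripts, totals
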