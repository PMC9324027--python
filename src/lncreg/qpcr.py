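"""Relative qPCR quantification (delta-delta-Ct) and NGS concordance checks.

Ct values are cycle thresholds: one PCR cycle is one doubling, so reference
normalization by the *geometric mean of expression levels* corresponds to
the arithmetic mean of the reference Ct values. RQ = 2^(-ddCt), with the
calibrator tissue's mean dCt as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    tissue: str
    target_ct: float
    reference_cts: tuple[float, ...]

    def __post_init__(self):
        if self.target_ct <= 0 or any(c <= 0 for c in self.reference_cts):
            raise ValidationError("Ct values must be positive")
        if not self.reference_cts:
            raise ValidationError(f"{self.sample_id}: at least one reference Ct required")


def combined_reference_ct(reference_cts: Sequence[float]) -> float:
    """Arithmetic mean of reference Cts = geometric mean on the linear scale."""
    return float(np.mean(reference_cts))


def ddct_quantify(records: Sequence[QpcrRecord], calibrator_tissue: str) -> pd.DataFrame:
    """Per-sample relative quantity by the ddCt method.

    dCt = target Ct - combined reference Ct; ddCt subtracts the calibrator
    tissue's mean dCt; RQ = 2^(-ddCt).
    """
    if not any(r.tissue == calibrator_tissue for r in records):
        raise ValidationError(f"calibrator tissue {calibrator_tissue!r} absent")
    dct = {r.sample_id: r.target_ct - combined_reference_ct(r.reference_cts)
           for r in records}
    cal = float(np.mean([dct[r.sample_id] for r in records
                         if r.tissue == calibrator_tissue]))
    rows = []
    for r in records:
        ddct = dct[r.sample_id] - cal
        rows.append(
            {
                "sample_id": r.sample_id,
                "tissue": r.tissue,
                "dct": dct[r.sample_id],
                "ddct": ddct,
                "rq": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


def validate_against_ngs(
    rq_by_tissue: pd.DataFrame, fpkm_by_tissue: pd.DataFrame
) -> pd.DataFrame:
    """Concordance of qPCR RQ with NGS FPKM tissue means.

    Both inputs are feature x tissue tables. Reports, per feature, the
    fraction of tissue-pair contrasts whose sign agrees and the Pearson r of
    log2 RQ vs log2 FPKM across tissues.
    """
    common = [f for f in rq_by_tissue.index if f in fpkm_by_tissue.index]
    if not common:
        raise ValidationError("no overlapping features between qPCR and NGS tables")
    tissues = [t for t in rq_by_tissue.columns if t in fpkm_by_tissue.columns]
    rows = []
    for f in common:
        rq = rq_by_tissue.loc[f, tissues].to_numpy(dtype=float)
        fp = fpkm_by_tissue.loc[f, tissues].to_numpy(dtype=float)
        agree, total = 0, 0
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                d1, d2 = rq[i] - rq[j], fp[i] - fp[j]
                if d1 == 0 and d2 == 0:
                    agree += 1
                elif np.sign(d1) == np.sign(d2):
                    agree += 1
                total += 1
        lrq = np.log2(np.clip(rq, 1e-12, None))
        lfp = np.log2(np.clip(fp, 1e-12, None))
        if np.std(lrq) == 0 or np.std(lfp) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(lrq, lfp)[0, 1])
        rows.append(
            {
                "feature_id": f,
                "direction_agreement": agree / total if total else np.nan,
                "log_pearson_r": r,
            }
        )
    return pd.DataFrame(rows)
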