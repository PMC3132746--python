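"""Relative quantification arithmetic for qRT-PCR and ChIP-qPCR.

Expression is quantified by the Livak 2^-ddCt method with a fixed
amplification efficiency of 2: per sample, dCt = mean Ct(target) - mean
Ct(reference); against a calibrator sample, ddCt = dCt_sample -
dCt_calibrator and the relative quantity is 2^-ddCt. ChIP signals are
expressed as fold of a control amplicon from the same immunoprecipitate:
2^(Ct_control - Ct_target).

Standard errors propagate the replicate Ct spread to the fold-change scale
by the first-order delta method: sd(log2 rq) is the root sum of the
standard errors of the contributing mean Cts, and sem(rq) = ln2 * rq *
sd(log2 rq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    target_gene: str
    reference_gene: str
    ct_target: Sequence[float]
    ct_reference: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.ct_target) < 1 or len(self.ct_reference) < 1:
            raise ValueError("at least one Ct replicate per channel required")
        for ct in list(self.ct_target) + list(self.ct_reference):
            if not math.isfinite(ct):
                raise ValueError("Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return _mean(self.ct_target) - _mean(self.ct_reference)


@dataclass(frozen=True)
class RelativeQuantity:
    sample_id: str
    target_gene: str
    rq: float
    sem: float


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _sem_of_mean(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mu = _mean(values)
    var = sum((v - mu) ** 2 for v in values) / (n - 1)
    return math.sqrt(var / n)


def _delta_ct_sem(record: QpcrRecord) -> float:
    return math.sqrt(
        _sem_of_mean(record.ct_target) ** 2 + _sem_of_mean(record.ct_reference) ** 2
    )


def ddct(record: QpcrRecord, calibrator: QpcrRecord) -> RelativeQuantity:
    """2^-ddCt fold change of ``record`` relative to ``calibrator``."""
    if record.target_gene != calibrator.target_gene:
        raise ValueError(
            f"target mismatch: {record.target_gene} vs {calibrator.target_gene}"
        )
    if record.reference_gene != calibrator.reference_gene:
        raise ValueError(
            f"reference mismatch: {record.reference_gene} vs {calibrator.reference_gene}"
        )
    dd = record.delta_ct - calibrator.delta_ct
    rq = 2.0 ** (-dd)
    sd_log2 = math.sqrt(_delta_ct_sem(record) ** 2 + _delta_ct_sem(calibrator) ** 2)
    return RelativeQuantity(
        sample_id=record.sample_id,
        target_gene=record.target_gene,
        rq=rq,
        sem=math.log(2.0) * rq * sd_log2,
    )


def chip_relative(ip_ct: QpcrRecord, control_amplicon_ct: QpcrRecord) -> RelativeQuantity:
    """ChIP enrichment of a target amplicon as fold of the control amplicon.

    Both records must come from the same immunoprecipitate; the control
    record carries the control amplicon's Cts in its target channel.
    """
    if ip_ct.sample_id != control_amplicon_ct.sample_id:
        raise ValueError(
            f"records from different immunoprecipitates: "
            f"{ip_ct.sample_id} vs {control_amplicon_ct.sample_id}"
        )
    diff = _mean(control_amplicon_ct.ct_target) - _mean(ip_ct.ct_target)
    rq = 2.0 ** diff
    sd_log2 = math.sqrt(
        _sem_of_mean(ip_ct.ct_target) ** 2
        + _sem_of_mean(control_amplicon_ct.ct_target) ** 2
    )
    return RelativeQuantity(
        sample_id=ip_ct.sample_id,
        target_gene=ip_ct.target_gene,
        rq=rq,
        sem=math.log(2.0) * rq * sd_log2,
    )


def read_qpcr_table(path) -> List[QpcrRecord]:
    """Long-format TSV (sample, gene, role=target|reference, ct) to records.

    Within a sample the target rows name the assayed gene and the
    reference rows the internal control (e.g. actin).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "role", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    records = []
    for sample, group in df.groupby("sample", sort=False):
        targets = group[group["role"] == "target"]
        refs = group[group["role"] == "reference"]
        if targets.empty or refs.empty:
            raise ValueError(f"sample {sample!r} lacks target or reference rows")
        records.append(
            QpcrRecord(
                sample_id=str(sample),
                target_gene=str(targets["gene"].iloc[0]),
                reference_gene=str(refs["gene"].iloc[0]),
                ct_target=targets["ct"].astype(float).tolist(),
                ct_reference=refs["ct"].astype(float).tolist(),
            )
        )
    return records
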