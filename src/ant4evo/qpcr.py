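"""Relative quantification by 2^-ddCt and sex-linkage from gene dosage.

A target gene's mean Ct is normalized against a reference (housekeeping)
gene in the same sample (dCt), then against a calibrator (ddCt); relative
quantity is 2^-ddCt under the ideal doubling-per-cycle assumption — no
efficiency correction is applied. For genomic DNA the same arithmetic gives
relative copy number, and dividing the female by the male value yields the
dosage ratio: ~2 for a gene on the heterologous part of the X chromosome of
a male-heterogametic species, ~1 for an autosomal or pseudoautosomal gene.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    pass


# female/male ratio bands separating 2-fold (X-linked) from 1-fold with a
# guard gap; the interpretation rule, not a measured quantity
X_LINKED_BAND = (1.6, 2.5)
AUTOSOMAL_BAND = (0.8, 1.25)


@dataclass
class CtRecord:
    sample: str
    sex: str  # F | M | NA
    gene: str
    cts: list[float]

    def __post_init__(self):
        if self.sex not in ("F", "M", "NA"):
            raise QpcrError(f"sex must be F, M or NA, got {self.sex!r}")
        if not self.cts:
            raise QpcrError(f"{self.sample}/{self.gene}: need at least one Ct replicate")
        if any(not (0.0 < ct < 50.0) for ct in self.cts):
            raise QpcrError(f"{self.sample}/{self.gene}: Ct values must lie in (0, 50)")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.cts, ddof=1)) if len(self.cts) > 1 else 0.0


@dataclass
class QuantResult:
    gene: str
    sample: str
    rq: float  # 2^-ddCt
    sd: float  # replicate SD propagated on the dCt scale

    def __post_init__(self):
        if self.rq <= 0:
            raise QpcrError("relative quantity must be positive")


@dataclass
class DosageResult:
    gene: str
    ratio_FM: float
    call: str  # x_linked_heterologous | autosomal_or_pseudoautosomal | ambiguous


def ddct_quantity(
    target: CtRecord, reference: CtRecord, calibrator_dct: float = 0.0
) -> QuantResult:
    """2^-(dCt - calibrator_dct) for one sample, with replicate SD.

    dCt = mean Ct(target) - mean Ct(reference); the SD combines the two
    replicate SDs in quadrature (independent errors on the dCt scale).
    """
    if target.sample != reference.sample:
        raise QpcrError(
            f"target sample {target.sample!r} != reference sample {reference.sample!r}"
        )
    dct = target.mean_ct - reference.mean_ct
    rq = 2.0 ** (-(dct - calibrator_dct))
    sd = math.sqrt(target.sd_ct**2 + reference.sd_ct**2)
    return QuantResult(target.gene, target.sample, rq, sd)


def dosage_ratio(female: QuantResult, male: QuantResult) -> DosageResult:
    """Female/male relative copy number and its sex-linkage call."""
    if female.gene != male.gene:
        raise QpcrError(f"gene mismatch: {female.gene!r} vs {male.gene!r}")
    ratio = female.rq / male.rq
    return DosageResult(female.gene, ratio, classify_sex_linkage(ratio))


def classify_sex_linkage(
    ratio_FM: float,
    x_linked_band: tuple[float, float] = X_LINKED_BAND,
    autosomal_band: tuple[float, float] = AUTOSOMAL_BAND,
) -> str:
    if ratio_FM <= 0:
        raise QpcrError(f"ratio must be positive, got {ratio_FM}")
    if x_linked_band[0] <= ratio_FM <= x_linked_band[1]:
        return "x_linked_heterologous"
    if autosomal_band[0] <= ratio_FM <= autosomal_band[1]:
        return "autosomal_or_pseudoautosomal"
    return "ambiguous"


def records_from_table(df: pd.DataFrame) -> list[CtRecord]:
    """Group a long Ct table (sample, sex, gene, ct) into CtRecords."""
    required = {"sample", "sex", "gene", "ct"}
    if not required <= set(df.columns):
        raise QpcrError(f"Ct table must have columns {sorted(required)}")
    out = []
    for (sample, sex, gene), grp in df.groupby(["sample", "sex", "gene"], sort=True):
        out.append(CtRecord(str(sample), str(sex), str(gene), list(grp["ct"])))
    return out


def dosage_from_table(
    df: pd.DataFrame, target_gene: str, reference_gene: str = "actb"
) -> DosageResult:
    """End-to-end F/M dosage for one gene from a long Ct table.

    Expects one female and one male sample each carrying target and
    reference measurements; quantities are computed per sample (reference-
    normalized, shared calibrator cancels in the ratio) and then divided.
    """
    records = {(r.sex, r.gene): r for r in records_from_table(df)}
    try:
        q = {
            sex: ddct_quantity(records[(sex, target_gene)], records[(sex, reference_gene)])
            for sex in ("F", "M")
        }
    except KeyError as e:
        raise QpcrError(f"missing Ct record for (sex, gene) = {e.args[0]}") from None
    return dosage_ratio(q["F"], q["M"])


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
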