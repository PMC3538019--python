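"""Allelic-ratio computation, gDNA standardization, 60:40 calling and summaries.

The decision procedure, in order:

1. each measurement's percent pair becomes a ratio ``pct_a / pct_b``;
2. a gene's reference is the arithmetic mean of its heterozygous-gDNA ratios
   (heterozygous genomic DNA should be 1:1, so this mean captures the
   assay's technical bias);
3. each cDNA ratio is divided by that reference — this standardization is
   what lets small true imbalances survive a biased assay;
4. the standardized ratio, re-expressed as a majority-allele percent, is
   called imbalanced iff it reaches the 60:40 threshold (boundary inclusive:
   exactly 60.0 is imbalanced);
5. per gene and tissue, folded ratios (higher/lower, direction neglected)
   are summarised per direction group and overall, and a two-tailed Welch
   t-test compares cDNA folded ratios against gDNA folded ratios.

Monoallelic cDNA rows (one allele at 0 %) are capped at a 99.5:0.5 ratio
(199) for summary arithmetic and flagged, so means stay finite while the
"nearly monoallelic" character is preserved.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MissingReferenceError, ValidationError
from .io_formats import MeasurementTable, RunConfig

logger = logging.getLogger("pyroaei")

#: ratio assigned to monoallelic (100:0) measurements: 99.5 / 0.5
MONOALLELIC_CAP = 199.0


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllelicRatio:
    sample_id: str
    gene: str
    tissue: str
    material: str
    ratio_ab: float  # pct_a / pct_b; capped when monoallelic
    monoallelic: bool


def fold(ratio: float) -> float:
    """Direction-neglecting ratio: max(r, 1/r); fold(r) == fold(1/r) >= 1."""
    if ratio <= 0:
        raise ValidationError(f"fold requires a positive ratio, got {ratio}")
    return ratio if ratio >= 1.0 else 1.0 / ratio


def percent_to_ratio(pct_a: float, pct_b: float) -> tuple[float, bool]:
    """(ratio_ab, monoallelic_flag) from an allele percent pair.

    Monoallelic pairs (one percent at zero) have no finite ratio; they are
    reported at the cap with the flag set.
    """
    if pct_a < 0 or pct_b < 0:
        raise ValidationError(f"negative percentages ({pct_a}, {pct_b})")
    if abs(pct_a + pct_b - 100.0) > 0.1:
        raise ValidationError(f"pct_a + pct_b = {pct_a + pct_b:g} deviates from 100 by more than 0.1")
    if pct_b == 0.0:
        return MONOALLELIC_CAP, True
    if pct_a == 0.0:
        return 1.0 / MONOALLELIC_CAP, True
    return pct_a / pct_b, False


def row_to_ratio(row: pd.Series) -> AllelicRatio:
    ratio, mono = percent_to_ratio(float(row["pct_a"]), float(row["pct_b"]))
    return AllelicRatio(
        sample_id=str(row["sample_id"]),
        gene=str(row["gene"]),
        tissue=str(row["tissue"]),
        material=str(row["material"]),
        ratio_ab=ratio,
        monoallelic=mono,
    )


# ---------------------------------------------------------------------------
# gDNA reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GdnaReference:
    """Assay-bias reference: mean allelic ratio over heterozygous gDNA samples."""

    gene: str
    mean_gdna_ratio: float
    n_gdna: int
    max_observed_deviation_pct: float

    def relabelled(self) -> "GdnaReference":
        """The reference with allele labels swapped (ratio orientation inverted)."""
        return GdnaReference(
            gene=self.gene,
            mean_gdna_ratio=1.0 / self.mean_gdna_ratio,
            n_gdna=self.n_gdna,
            max_observed_deviation_pct=self.max_observed_deviation_pct,
        )


def build_gdna_reference(gdna_rows: pd.DataFrame, qc_max_deviation_pct: float = 10.0) -> GdnaReference:
    """Arithmetic mean of heterozygous-gDNA allelic ratios for one gene.

    Monoallelic gDNA rows cannot come from a heterozygote and are rejected
    with a warning.  The maximum percent deviation from 50 is recorded for
    QC and warned about above ``qc_max_deviation_pct``.
    """
    genes = set(gdna_rows["gene"].astype(str))
    if len(genes) > 1:
        raise ValidationError(f"gDNA rows span multiple genes: {sorted(genes)}")
    ratios, devs = [], []
    for _, row in gdna_rows.iterrows():
        ratio, mono = percent_to_ratio(float(row["pct_a"]), float(row["pct_b"]))
        if mono:
            logger.warning("gDNA row %s is monoallelic; rejected from reference", row["sample_id"])
            continue
        ratios.append(ratio)
        devs.append(abs(float(row["pct_a"]) - 50.0))
    if not ratios:
        raise MissingReferenceError(f"no usable heterozygous gDNA rows for gene {genes or '?'}")
    max_dev = float(max(devs))
    if max_dev > qc_max_deviation_pct:
        logger.warning("gDNA deviation %.2f%% exceeds QC bound %.2f%%", max_dev, qc_max_deviation_pct)
    return GdnaReference(
        gene=genes.pop() if genes else "",
        mean_gdna_ratio=float(np.mean(ratios)),
        n_gdna=len(ratios),
        max_observed_deviation_pct=max_dev,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImbalanceCall:
    sample_id: str
    gene: str
    tissue: str
    normalized_ratio: float
    normalized_pct_a: float
    status: str  # balanced | imbalanced
    direction: str  # A | B | none
    folded_ratio: float
    monoallelic: bool = False


def normalize_and_call(
    cdna: AllelicRatio,
    ref: GdnaReference,
    threshold_pct: float = 60.0,
) -> ImbalanceCall:
    """Standardize one cDNA ratio by the gene's gDNA reference and apply the threshold.

    The threshold acts on the standardized majority-allele percent
    ``100 * r / (1 + r)``; the boundary is inclusive (exactly ``threshold_pct``
    is imbalanced, anything below is balanced).  Direction is the allele with
    the higher standardized percent.
    """
    if not 50.0 < threshold_pct <= 100.0:
        raise ValidationError("threshold_pct must be in (50, 100]")
    if ref.gene and cdna.gene != ref.gene:
        raise ValidationError(f"gene mismatch: cDNA {cdna.gene!r} vs reference {ref.gene!r}")
    r = cdna.ratio_ab / ref.mean_gdna_ratio
    pct_a = 100.0 * r / (1.0 + r)
    imbalanced = cdna.monoallelic or pct_a >= threshold_pct or pct_a <= 100.0 - threshold_pct
    direction = "none"
    if imbalanced:
        direction = "A" if pct_a > 50.0 else "B"
    return ImbalanceCall(
        sample_id=cdna.sample_id,
        gene=cdna.gene,
        tissue=cdna.tissue,
        normalized_ratio=r,
        normalized_pct_a=pct_a,
        status="imbalanced" if imbalanced else "balanced",
        direction=direction,
        folded_ratio=fold(r),
        monoallelic=cdna.monoallelic,
    )


# ---------------------------------------------------------------------------
# summaries and significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTissueSummary:
    gene: str
    tissue: str
    n_total: int
    n_balanced: int
    n_imbalanced_toward_a: int
    n_imbalanced_toward_b: int
    group_mean_sd_a: tuple[float, float]
    group_mean_sd_b: tuple[float, float]
    overall_mean_folded: float
    p_value: float


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return (math.nan, math.nan)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else math.nan
    return mean, sd


def summarize_gene_tissue(
    calls: Sequence[ImbalanceCall],
    gdna_folded: Sequence[float] | None = None,
) -> GeneTissueSummary:
    """Per-direction group statistics and the overall folded mean for one gene/tissue.

    Direction groups contain only imbalanced samples (mean and sample SD of
    folded ratios); the overall folded mean averages ALL samples, balanced
    included.  When gDNA folded ratios are supplied and both groups have
    n >= 2, the two-tailed Welch t-test p-value is attached.
    """
    if not calls:
        raise ValidationError("summarize_gene_tissue requires at least one call")
    keys = {(c.gene, c.tissue) for c in calls}
    if len(keys) > 1:
        raise ValidationError(f"calls span multiple gene/tissue combinations: {sorted(keys)}")
    gene, tissue = keys.pop()
    toward_a = [c.folded_ratio for c in calls if c.status == "imbalanced" and c.direction == "A"]
    toward_b = [c.folded_ratio for c in calls if c.status == "imbalanced" and c.direction == "B"]
    all_folded = [c.folded_ratio for c in calls]
    p = math.nan
    if gdna_folded is not None and len(all_folded) >= 2 and len(gdna_folded) >= 2:
        p = test_significance(all_folded, list(gdna_folded))
    return GeneTissueSummary(
        gene=gene,
        tissue=tissue,
        n_total=len(calls),
        n_balanced=sum(c.status == "balanced" for c in calls),
        n_imbalanced_toward_a=len(toward_a),
        n_imbalanced_toward_b=len(toward_b),
        group_mean_sd_a=_mean_sd(toward_a),
        group_mean_sd_b=_mean_sd(toward_b),
        overall_mean_folded=float(np.mean(all_folded)),
        p_value=p,
    )


def test_significance(
    cdna_folded: Sequence[float],
    gdna_folded: Sequence[float],
    one_sample: bool = False,
) -> float:
    """Two-tailed t-test on folded ratios: cDNA vs gDNA (Welch) or cDNA vs 1.

    Folding neglects direction, so one-directional and bidirectional
    imbalance are pooled into a single magnitude comparison.  Degenerate
    zero-variance inputs return 1.0 when the means agree and 0.0 otherwise.
    """
    c = np.asarray(cdna_folded, dtype=float)
    if not np.isfinite(c).all():
        raise ValidationError("non-finite folded ratios")
    if len(c) < 2:
        raise InsufficientDataError("need at least 2 cDNA folded ratios")
    if one_sample:
        t, p = stats.ttest_1samp(c, 1.0)
        mean_diff = float(c.mean() - 1.0)
    else:
        g = np.asarray(gdna_folded, dtype=float)
        if len(g) < 2:
            raise InsufficientDataError("need at least 2 gDNA folded ratios")
        if not np.isfinite(g).all():
            raise ValidationError("non-finite folded ratios")
        t, p = stats.ttest_ind(c, g, equal_var=False)
        mean_diff = float(c.mean() - g.mean())
    if math.isnan(p):  # zero variance in both groups
        return 1.0 if mean_diff == 0.0 else 0.0
    return float(p)


def significance_stars(p: float) -> str:
    """Star coding used in the summary table: * p<0.05, ** p<0.01, *** p<0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_aei(
    measurements: MeasurementTable,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full AEI analysis of a measurement table.

    Returns (calls, summaries): one call row per cDNA sample and one summary
    row per gene/tissue, with significance stars.  Genes lacking gDNA rows
    raise MissingReferenceError.
    """
    cfg = config or RunConfig()
    call_rows, summary_rows = [], []
    df = measurements.df
    for gene in df["gene"].unique():
        gdna_rows = measurements.gdna(gene)
        ref = build_gdna_reference(gdna_rows, qc_max_deviation_pct=cfg.gdna_qc_max_deviation_pct)
        # gDNA folded ratios are taken on the same standardized scale as the
        # cDNA calls (each ratio divided by the gene's mean gDNA ratio), so the
        # t-test compares residual gDNA scatter against standardized cDNA AEI
        # rather than re-detecting the assay bias standardization removed
        gdna_folded = [
            fold(percent_to_ratio(float(r["pct_a"]), float(r["pct_b"]))[0] / ref.mean_gdna_ratio)
            for _, r in gdna_rows.iterrows()
        ]
        cdna_rows = measurements.cdna(gene)
        for tissue in cdna_rows["tissue"].unique():
            calls = [
                normalize_and_call(row_to_ratio(row), ref, cfg.imbalance_threshold_pct)
                for _, row in cdna_rows[cdna_rows["tissue"] == tissue].iterrows()
            ]
            call_rows.extend(dataclass_rows(calls))
            summary = summarize_gene_tissue(calls, gdna_folded=gdna_folded)
            summary_rows.append({
                "gene": summary.gene,
                "tissue": summary.tissue,
                "n_total": summary.n_total,
                "n_balanced": summary.n_balanced,
                "n_toward_a": summary.n_imbalanced_toward_a,
                "n_toward_b": summary.n_imbalanced_toward_b,
                "group_a_mean": summary.group_mean_sd_a[0],
                "group_a_sd": summary.group_mean_sd_a[1],
                "group_b_mean": summary.group_mean_sd_b[0],
                "group_b_sd": summary.group_mean_sd_b[1],
                "overall_mean_folded": summary.overall_mean_folded,
                "p_value": summary.p_value,
                "significance": significance_stars(summary.p_value),
            })
            logger.info(
                "run_aei: %s/%s n=%d imbalanced=%d p=%.3g",
                gene, tissue, summary.n_total,
                summary.n_imbalanced_toward_a + summary.n_imbalanced_toward_b,
                summary.p_value,
            )
    return pd.DataFrame(call_rows), pd.DataFrame(summary_rows)


def dataclass_rows(calls: Sequence[ImbalanceCall]) -> list[dict]:
    return [
        {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "tissue": c.tissue,
            "normalized_ratio": c.normalized_ratio,
            "normalized_pct_a": c.normalized_pct_a,
            "status": c.status,
            "direction": c.direction,
            "folded_ratio": c.folded_ratio,
            "monoallelic": c.monoallelic,
        }
        for c in calls
    ]
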