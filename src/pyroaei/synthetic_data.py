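"""Synthetic inputs with the statistical structure the study design assumes.

The generator emulates, download-free:

* Hardy-Weinberg genotypes across a default population of 40 animals;
* the technical deviation of heterozygous-gDNA pyrosequencing reads from the
  theoretical 50:50 (3 % mean absolute deviation, 8 % hard maximum);
* cDNA allelic-imbalance archetypes — one-directional (LEP-like),
  strongly bidirectional up to near-monoallelic (IGF2-like) and weakly
  bidirectional (CCL2-like) — with per-direction group fold-ratio targets
  taken from the study's per-tissue results;
* promoter sequences with planted CpG islands, motif occurrences and SNPs;
* PCR-RFLP and forced-RFLP template/assay pairs.

Every generator is deterministic for a fixed seed, and each emits truth
records so downstream stages can be scored for recovery.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf, erfinv

from ._sequence import BASES, IUPAC, revcomp
from .aei_core import MONOALLELIC_CAP
from .errors import AssayError, ValidationError
from .io_formats import EnzymeRecord, MeasurementTable
from .rflp_genotyping import PrimerPair, RflpAssay, amplify, digest

logger = logging.getLogger("pyroaei")

_SQRT2 = math.sqrt(2.0)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    gene: str
    allele_a: str
    allele_b: str
    allele_freq: float  # frequency of allele A

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValidationError(f"{self.gene}: allele_freq must be in (0, 1)")


#: Marker cSNP panel for the genes with informative assays; allele
#: frequencies chosen to span the observed per-SNP heterozygosity range
#: (roughly 15-67 % across the surveyed genes).
DEFAULT_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("LEP", "C", "T", 0.35),
    SnpSpec("IGF2", "G", "T", 0.50),
    SnpSpec("CCL2", "C", "T", 0.30),
    SnpSpec("PI", "C", "T", 0.25),
    SnpSpec("GH", "C", "G", 0.40),
    SnpSpec("SCD", "C", "T", 0.10),
)


@dataclass(frozen=True)
class PopulationSpec:
    n_animals: int = 40
    snps: tuple[SnpSpec, ...] = DEFAULT_SNPS

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValidationError("n_animals must be >= 2")


def simulate_genotypes(spec: PopulationSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Hardy-Weinberg genotypes: animals x genes, values AA/AB/BB.

    Each animal draws two alleles independently at frequency
    ``allele_freq`` for allele A, so genotype proportions are
    (p^2, 2pq, q^2).
    """
    rng = _rng(seed)
    animals = [f"B{i + 1:02d}" for i in range(spec.n_animals)]
    data = {}
    for snp in spec.snps:
        draws = rng.random((spec.n_animals, 2)) < snp.allele_freq
        n_a = draws.sum(axis=1)
        data[snp.gene] = np.array(["BB", "AB", "AA"])[n_a]
    df = pd.DataFrame(data, index=animals)
    logger.info("simulate_genotypes: %d animals x %d SNPs", spec.n_animals, len(spec.snps))
    return df


# ---------------------------------------------------------------------------
# measurement model: gDNA technical bias and cDNA noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementModel:
    """Technical model of pyrosequencing allele quantification.

    gdna_bias_mean_pct / gdna_bias_max_pct: mean and hard maximum of the
        absolute deviation of heterozygous gDNA from 50 % (percent points).
        The deviation |d| is half-normal truncated at the maximum, with the
        scale solved so the post-truncation mean hits the target.
    noise_sd_pct: cDNA measurement noise, expressed as the percent-scale SD
        at a 50:50 sample; applied on the log-ratio scale as mean-one
        lognormal so it is unbiased on the ratio scale.
    """

    gdna_bias_mean_pct: float = 3.0
    gdna_bias_max_pct: float = 8.0
    noise_sd_pct: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gdna_bias_mean_pct <= self.gdna_bias_max_pct <= 50.0:
            raise ValidationError("need 0 <= bias mean <= bias max <= 50")
        if self.noise_sd_pct < 0:
            raise ValidationError("noise_sd_pct must be >= 0")
        if self.gdna_bias_mean_pct > 0 and self.gdna_bias_mean_pct >= self.gdna_bias_max_pct / 2.0:
            raise ValidationError(
                "truncated half-normal bias requires mean < max/2 "
                f"(got mean {self.gdna_bias_mean_pct}, max {self.gdna_bias_max_pct})"
            )

    @property
    def log_ratio_noise_sd(self) -> float:
        # d(pct)/d(ln r) = 25 at 50:50, so percent-scale SD / 25 on the log scale
        return self.noise_sd_pct / 25.0


def _trunc_halfnormal_mean(sigma: float, cap: float) -> float:
    b = cap / sigma
    return sigma * math.sqrt(2.0 / math.pi) * (1.0 - math.exp(-b * b / 2.0)) / erf(b / _SQRT2)


@lru_cache(maxsize=64)
def _bias_sigma(mean: float, cap: float) -> float:
    """Half-normal scale whose mean AFTER truncation at ``cap`` equals ``mean``."""
    if mean == 0.0:
        return 0.0
    return float(brentq(lambda s: _trunc_halfnormal_mean(s, cap) - mean, 1e-9, 1e3))


def _sample_bias(model: MeasurementModel, rng: np.random.Generator, size: int) -> np.ndarray:
    """Signed percent deviations d with E|d| = mean and |d| <= max."""
    if model.gdna_bias_mean_pct == 0.0:
        return np.zeros(size)
    sigma = _bias_sigma(model.gdna_bias_mean_pct, model.gdna_bias_max_pct)
    cdf_cap = erf(model.gdna_bias_max_pct / (sigma * _SQRT2))
    mag = sigma * _SQRT2 * erfinv(rng.random(size) * cdf_cap)
    sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
    return sign * mag


def simulate_gdna_measurement(model: MeasurementModel, seed: int | np.random.Generator) -> tuple[float, float]:
    """One heterozygous-gDNA percent pair: 50 + d and its complement."""
    pct_a = simulate_gdna_measurements(model, 1, seed)[0]
    return float(pct_a), float(100.0 - pct_a)


def simulate_gdna_measurements(
    model: MeasurementModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Vector of n heterozygous-gDNA pct_a draws (pct_b = 100 - pct_a)."""
    rng = _rng(seed)
    return 50.0 + _sample_bias(model, rng, n)


# ---------------------------------------------------------------------------
# imbalance archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionGroup:
    """One over-expressed-allele group: target folded-ratio mean/SD and its
    share of the imbalanced samples."""

    direction: str  # 'A' or 'B'
    fold_mean: float
    fold_sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.direction not in ("A", "B"):
            raise ValidationError("direction must be 'A' or 'B'")
        if self.fold_mean < 1.0 or self.fold_sd < 0.0 or not 0.0 <= self.weight <= 1.0:
            raise ValidationError("need fold_mean >= 1, fold_sd >= 0, weight in [0, 1]")


@dataclass(frozen=True)
class ImbalanceArchetype:
    """Distribution of true folded allelic ratios for one gene/tissue pattern.

    Folded ratios are lognormal on the natural scale, moment-matched to the
    group mean and SD (support > 0, right-skewed, which suits groups ranging
    from mild skew to near-monoallelic).  ``fraction_imbalanced`` of samples
    come from the direction groups; the rest draw a mild "balanced" ratio.
    Near-monoallelic draws are capped at 99.5:0.5 (ratio 199) so ratios stay
    finite; the cap is logged.
    """

    name: str
    groups: tuple[DirectionGroup, ...] = ()
    fraction_imbalanced: float = 0.0
    balanced_fold_mean: float = 1.2
    balanced_fold_sd: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_imbalanced <= 1.0:
            raise ValidationError("fraction_imbalanced must be in [0, 1]")
        if self.groups:
            total = sum(g.weight for g in self.groups)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"group weights must sum to 1, got {total}")
        elif self.fraction_imbalanced > 0:
            raise ValidationError("fraction_imbalanced > 0 requires direction groups")

    @property
    def direction_mix(self) -> float:
        """Fraction of imbalanced samples directed toward allele A."""
        return sum(g.weight for g in self.groups if g.direction == "A")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given natural-scale mean and SD."""
    if mean <= 0:
        raise ValidationError("lognormal mean must be positive")
    if sd == 0.0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _largest_remainder_counts(weights: Sequence[float], total: int) -> list[int]:
    raw = [w * total for w in weights]
    counts = [int(math.floor(x)) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def sample_true_folds(
    archetype: ImbalanceArchetype, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Draw (fold_ratio, direction, is_imbalanced_group) for n samples.

    Sample counts per group are fixed (largest-remainder rounding of the
    weights), mirroring the fixed per-tissue counts the study reports; the
    assignment order is shuffled.
    """
    n_imb = int(round(archetype.fraction_imbalanced * n))
    folds: list[float] = []
    dirs: list[str] = []
    from_group: list[bool] = []
    if n_imb:
        for group, count in zip(
            archetype.groups,
            _largest_remainder_counts([g.weight for g in archetype.groups], n_imb),
        ):
            mu, sig = _lognormal_params(group.fold_mean, group.fold_sd)
            draws = np.exp(mu + sig * rng.standard_normal(count)) if sig else np.full(count, group.fold_mean)
            folds.extend(draws)
            dirs.extend([group.direction] * count)
            from_group.extend([True] * count)
    n_bal = n - n_imb
    if n_bal:
        mu, sig = _lognormal_params(archetype.balanced_fold_mean, archetype.balanced_fold_sd)
        draws = np.exp(mu + sig * rng.standard_normal(n_bal)) if sig else np.full(n_bal, archetype.balanced_fold_mean)
        folds.extend(draws)
        dirs.extend(rng.choice(["A", "B"], size=n_bal))
        from_group.extend([False] * n_bal)
    folds_arr = np.asarray(folds)
    n_capped = int((folds_arr > MONOALLELIC_CAP).sum())
    if n_capped:
        logger.info("sample_true_folds: capped %d draws at %.0f (99.5:0.5)", n_capped, MONOALLELIC_CAP)
        folds_arr = np.minimum(folds_arr, MONOALLELIC_CAP)
    order = rng.permutation(n)
    return (
        folds_arr[order],
        [dirs[i] for i in order],
        np.asarray(from_group)[order],
    )


def simulate_cdna_measurements(
    archetype: ImbalanceArchetype,
    n_samples: int,
    model: MeasurementModel,
    seed: int | np.random.Generator,
    *,
    gene: str = "GENE",
    tissue: str = "tissue",
    sample_prefix: str = "S",
    assay_bias_pct: float = 0.0,
    threshold_pct: float = 60.0,
) -> tuple[MeasurementTable, pd.DataFrame]:
    """cDNA measurement rows plus truth labels for one gene/tissue.

    Each sample's true fold ratio and direction define a true allelic ratio
    r; ``assay_bias_pct`` (the same systematic skew the gene's gDNA shows,
    as a percent at 50:50) multiplies it, measurement noise is applied on
    the ratio scale, and the result is re-expressed as a percent pair
    summing to exactly 100.  Truth labels use the same inclusive threshold
    as the caller so zero-noise recovery is exact.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = _rng(seed)
    folds, dirs, _ = sample_true_folds(archetype, n_samples, rng)
    ratio_true = np.where(np.array(dirs) == "A", folds, 1.0 / folds)
    bias_ratio = (50.0 + assay_bias_pct) / (50.0 - assay_bias_pct)
    sig = model.log_ratio_noise_sd
    noise = np.exp(rng.normal(-sig * sig / 2.0, sig, n_samples)) if sig > 0 else 1.0
    r = ratio_true * bias_ratio * noise
    pct_a = 100.0 * r / (1.0 + r)
    rows = pd.DataFrame({
        "sample_id": [f"{sample_prefix}{i + 1:02d}" for i in range(n_samples)],
        "gene": gene,
        "tissue": tissue,
        "material": "cDNA",
        "pct_a": pct_a,
        "pct_b": 100.0 - pct_a,
    })
    true_pct = 100.0 * folds / (1.0 + folds)
    truth = pd.DataFrame({
        "sample_id": rows["sample_id"],
        "gene": gene,
        "tissue": tissue,
        "true_fold": folds,
        "true_direction": dirs,
        "true_status": np.where(true_pct >= threshold_pct, "imbalanced", "balanced"),
    })
    return MeasurementTable(rows), truth


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    """One gene/tissue condition: marker alleles, sample counts, archetype."""

    name: str
    gene: str
    tissue: str
    allele_a: str
    allele_b: str
    n_cdna: int
    n_gdna: int
    archetype: ImbalanceArchetype


def _preset(name, gene, tissue, a, b, n, groups, frac, **kw) -> ExperimentPreset:
    return ExperimentPreset(
        name=name, gene=gene, tissue=tissue, allele_a=a, allele_b=b,
        n_cdna=n, n_gdna=n,
        archetype=ImbalanceArchetype(name=name, groups=groups, fraction_imbalanced=frac, **kw),
    )


#: Per-tissue calibration presets.  Group means/SDs and counts follow the
#: study's per-tissue results: LEP is one-directional toward C; IGF2 is
#: bidirectional and near-monoallelic in pituitary (7 of 9 toward T);
#: CCL2 is weakly bidirectional.  Allele A is the first allele of each
#: assay definition (LEP C/T, IGF2 G/T, CCL2 C/T).
PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in (
        _preset("lep-liver", "LEP", "liver", "C", "T", 8,
                (DirectionGroup("A", 4.38, 2.46, 1.0),), 7 / 8),
        _preset("lep-pituitary", "LEP", "pituitary", "C", "T", 9,
                (DirectionGroup("A", 5.39, 3.64, 1.0),), 6 / 9),
        _preset("lep-kidney", "LEP", "kidney", "C", "T", 9,
                (DirectionGroup("A", 1.71, 0.07, 1.0),), 2 / 9),
        _preset("igf2-liver", "IGF2", "liver", "G", "T", 9, (), 0.0),
        _preset("igf2-pituitary", "IGF2", "pituitary", "G", "T", 9,
                (DirectionGroup("B", 31.37, 7.37, 7 / 9), DirectionGroup("A", 15.67, 10.1, 2 / 9)), 1.0),
        _preset("igf2-kidney", "IGF2", "kidney", "G", "T", 9,
                (DirectionGroup("B", 4.51, 0.12, 7 / 9), DirectionGroup("A", 5.94, 1.88, 2 / 9)), 1.0),
        _preset("ccl2-pituitary", "CCL2", "pituitary", "C", "T", 7,
                (DirectionGroup("A", 1.67, 0.06, 3 / 5), DirectionGroup("B", 1.58, 0.05, 2 / 5)), 5 / 7),
        _preset("ccl2-kidney", "CCL2", "kidney", "C", "T", 9,
                (DirectionGroup("A", 1.65, 0.08, 1.0),), 2 / 9),
        _preset("null", "NULL", "tissue", "C", "T", 9, (), 0.0,
                balanced_fold_mean=1.0, balanced_fold_sd=0.0),
    )
}


def simulate_experiment(
    preset: ExperimentPreset | str,
    seed: int | np.random.Generator,
    model: MeasurementModel | None = None,
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Simulate one gene/tissue experiment: gDNA reference rows plus cDNA rows.

    A single per-assay bias is drawn from the gDNA deviation model and
    applied to BOTH the gene's gDNA rows (plus replicate noise, truncated at
    the hard maximum) and its cDNA rows — the shared technical skew that
    gDNA standardization is designed to neutralize.  Returns the combined
    measurement table and the cDNA truth labels.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    model = model or MeasurementModel()
    rng = _rng(seed)
    bias = float(_sample_bias(model, rng, 1)[0])
    jitter = rng.normal(0.0, model.noise_sd_pct, preset.n_gdna) if model.noise_sd_pct else np.zeros(preset.n_gdna)
    dev = np.clip(bias + jitter, -model.gdna_bias_max_pct, model.gdna_bias_max_pct)
    gdna = pd.DataFrame({
        "sample_id": [f"G{i + 1:02d}" for i in range(preset.n_gdna)],
        "gene": preset.gene,
        "tissue": "blood",
        "material": "gDNA",
        "pct_a": 50.0 + dev,
        "pct_b": 50.0 - dev,
    })
    cdna, truth = simulate_cdna_measurements(
        preset.archetype,
        preset.n_cdna,
        model,
        rng,
        gene=preset.gene,
        tissue=preset.tissue,
        assay_bias_pct=bias,
    )
    table = MeasurementTable(pd.concat([gdna, cdna.df], ignore_index=True))
    return table, truth


# ---------------------------------------------------------------------------
# promoter fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterTruth:
    """A generated promoter and the ground truth of what was planted in it."""

    sequence: str
    islands: tuple[tuple[int, int], ...]
    motifs: tuple[tuple[str, int, str], ...]  # (consensus, start, strand)
    snps: tuple[tuple[int, str, str], ...]  # (position, ref, alt), 0-based

    def island_bed(self, chrom: str = "chrP") -> list[tuple]:
        return [(chrom, s, e, f"island_{i + 1}") for i, (s, e) in enumerate(self.islands)]


def _markov_seq(
    rng: np.random.Generator, length: int, gc: float, cpg_factor: float, prev: str = ""
) -> str:
    """First-order chain with G+C fraction ``gc`` and P(G | previous C)
    damped (or boosted) by ``cpg_factor`` — for this parameterisation the
    CpG observed/expected ratio lands near ``cpg_factor`` itself."""
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    after_c = base_p.copy()
    after_c[2] *= cpg_factor
    after_c /= after_c.sum()
    cum = np.cumsum(base_p)
    cum_c = np.cumsum(after_c)
    draws = rng.random(length)
    out = []
    prev_c = prev == "C"
    for u in draws:
        idx = int(np.searchsorted(cum_c if prev_c else cum, u, side="right"))
        b = BASES[min(idx, 3)]
        out.append(b)
        prev_c = b == "C"
    return "".join(out)


#: Background promoter composition: 40 % GC with CpG depletion factor 0.25,
#: so planted islands are unambiguous against background.
BACKGROUND_GC = 0.40
BACKGROUND_CPG_FACTOR = 0.25


def _sample_island(
    rng: np.random.Generator, length: int, gc: float, oe: float, max_tries: int = 100
) -> str:
    from .regulatory_analysis import cpg_stats

    for _ in range(max_tries):
        seq = _markov_seq(rng, length, gc, oe)
        st = cpg_stats(seq)
        if (
            max(0.5, gc - 0.05) <= st.gc_fraction <= gc + 0.05
            and st.obs_exp >= max(0.6, oe - 0.15)
        ):
            return seq
    raise ValidationError(
        f"could not sample a {length} bp island at GC {gc}, obs/exp {oe}; targets may be inconsistent"
    )


def generate_promoter(
    length: int,
    planted_islands: Sequence[tuple[int, int, float, float]] = (),
    planted_motifs: Sequence[tuple[str, int, str]] = (),
    planted_snps: Sequence[tuple[int, str, str]] = (),
    seed: int | np.random.Generator = 0,
) -> PromoterTruth:
    """Background promoter with verifiable planted islands, motifs and SNPs.

    ``planted_islands``: (start, end, target_gc, target_obs_exp);
    ``planted_motifs``: (IUPAC consensus, start, strand); the consensus is
    written at the position (reverse-complemented on '-');
    ``planted_snps``: (position, ref, alt) — ref is written into the
    sequence.  Features may not overlap.  Coordinates 0-based half-open.
    """
    rng = _rng(seed)
    spans: list[tuple[int, int, str]] = []
    for s, e, _gc, _oe in planted_islands:
        spans.append((s, e, "island"))
    for cons, pos, strand in planted_motifs:
        if strand not in "+-":
            raise ValidationError(f"motif strand must be + or -, got {strand!r}")
        spans.append((pos, pos + len(cons), "motif"))
    for pos, _ref, _alt in planted_snps:
        spans.append((pos, pos + 1, "snp"))
    for s, e, kind in spans:
        if not 0 <= s < e <= length:
            raise ValidationError(f"planted {kind} [{s}, {e}) outside sequence of length {length}")
    for (s1, e1, k1), (s2, e2, k2) in zip(sorted(spans), sorted(spans)[1:]):
        if s2 < e1:
            raise ValidationError(f"planted {k1} [{s1}, {e1}) overlaps planted {k2} [{s2}, {e2})")

    seq = list(_markov_seq(rng, length, BACKGROUND_GC, BACKGROUND_CPG_FACTOR))
    for s, e, gc, oe in planted_islands:
        seq[s:e] = _sample_island(rng, e - s, gc, oe)
    for cons, pos, strand in planted_motifs:
        word = cons if strand == "+" else revcomp(cons)
        # concretise any ambiguity codes so the motif is literally present
        word = "".join(c if c in BASES else rng.choice(list(IUPAC[c])) for c in word)
        seq[pos:pos + len(word)] = word
    snps = []
    for pos, ref, alt in planted_snps:
        if ref == alt:
            raise ValidationError(f"SNP at {pos} has identical alleles")
        seq[pos] = ref
        snps.append((pos, ref, alt))
    truth = PromoterTruth(
        sequence="".join(seq),
        islands=tuple((s, e) for s, e, *_ in planted_islands),
        motifs=tuple(planted_motifs),
        snps=tuple(snps),
    )
    logger.info(
        "generate_promoter: %d bp, %d islands, %d motifs, %d SNPs",
        length, len(truth.islands), len(truth.motifs), len(truth.snps),
    )
    return truth


# ---------------------------------------------------------------------------
# RFLP assay fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRflp:
    """A generated RFLP template pair and the assay that interrogates it."""

    assay: RflpAssay
    templates: dict[str, str]  # allele label -> template sequence
    cut_allele: str  # which allele's amplicon the enzyme cuts
    site_span: tuple[int, int]  # recognition site span on the template
    snp_position: int


def _discriminating_positions(enzyme: EnzymeRecord, allele_a: str, allele_b: str) -> list[tuple[int, str]]:
    """Site indices where exactly one allele satisfies the IUPAC code.

    Returns (index, cut_allele_label) candidates.
    """
    out = []
    for j, code in enumerate(enzyme.recognition):
        a_in, b_in = allele_a in IUPAC[code], allele_b in IUPAC[code]
        if a_in and not b_in:
            out.append((j, "A"))
        elif b_in and not a_in:
            out.append((j, "B"))
    return out


def _concretise(rng: np.random.Generator, pattern: str) -> list[str]:
    return [c if c in BASES else rng.choice(list(IUPAC[c])) for c in pattern]


def generate_rflp_template(
    snp_alleles: tuple[str, str],
    enzyme: EnzymeRecord,
    flank_len: int = 60,
    force_site: bool = False,
    seed: int | np.random.Generator = 0,
    primer_len: int = 20,
    max_tries: int = 200,
) -> SyntheticRflp:
    """Template pair + assay for a SNP genotyped by (forced-)RFLP.

    Natural mode (``force_site=False``): the recognition site spans the SNP
    and is complete for exactly one allele.

    Forced mode: neither allele natively carries the site.  The forward
    primer ends immediately 5' of the SNP and carries one substituted base
    near its 3' end; primer incorporation completes the site for exactly
    one allele, so digestion of the unmodified template cuts neither.
    """
    allele_a, allele_b = (a.upper() for a in snp_alleles)
    if allele_a == allele_b or allele_a not in BASES or allele_b not in BASES:
        raise AssayError(f"need two distinct concrete SNP alleles, got {snp_alleles}")
    if flank_len < primer_len:
        raise AssayError(f"flank_len {flank_len} shorter than primer length {primer_len}: amplicon shorter than primers")
    rng = _rng(seed)
    candidates = _discriminating_positions(enzyme, allele_a, allele_b)
    if not candidates:
        raise AssayError(
            f"{enzyme.name} site {enzyme.recognition} cannot discriminate alleles {allele_a}/{allele_b}"
        )
    if force_site:
        return _generate_forced(rng, enzyme, allele_a, allele_b, candidates, flank_len, primer_len, max_tries)
    return _generate_natural(rng, enzyme, allele_a, allele_b, candidates, flank_len, primer_len, max_tries)


def _finish_assay(
    enzyme: EnzymeRecord,
    primers: PrimerPair,
    templates: dict[str, str],
    cut_allele: str,
    site_span: tuple[int, int],
    snp_position: int,
    forced: bool,
) -> SyntheticRflp:
    amp = {al: amplify(templates[al], primers, allele=al) for al in ("A", "B")}
    patterns = {al: digest(amp[al], enzyme) for al in ("A", "B")}
    assay = RflpAssay(
        gene="SYN",
        snp_alleles=("A", "B"),
        enzyme=enzyme,
        primers=primers,
        expected_a=patterns["A"],
        expected_b=patterns["B"],
        snp_position=snp_position,
        forced=forced,
    )
    return SyntheticRflp(
        assay=assay,
        templates=dict(templates),
        cut_allele=cut_allele,
        site_span=site_span,
        snp_position=snp_position,
    )


def _clean_flanks_ok(enzyme: EnzymeRecord, seqs: dict[str, str], expect_cut: dict[str, int]) -> bool:
    for allele, n_frag in expect_cut.items():
        if len(digest(seqs[allele], enzyme).fragment_lengths) != n_frag:
            return False
    return True


def _random_flank(rng: np.random.Generator, length: int) -> str:
    from ._sequence import random_seq

    return random_seq(rng, length, gc=0.5)


def _generate_natural(rng, enzyme, allele_a, allele_b, candidates, flank_len, primer_len, max_tries):
    j, cut_allele = candidates[rng.integers(len(candidates))]
    site = _concretise(rng, enzyme.recognition)
    site[j] = allele_a if cut_allele == "A" else allele_b
    other_base = allele_b if cut_allele == "A" else allele_a
    L = len(enzyme.recognition)
    for _ in range(max_tries):
        left = _random_flank(rng, flank_len)
        right = _random_flank(rng, flank_len)
        cut_template = left + "".join(site) + right
        other_site = site.copy()
        other_site[j] = other_base
        other_template = left + "".join(other_site) + right
        templates = {cut_allele: cut_template, ("B" if cut_allele == "A" else "A"): other_template}
        if not _clean_flanks_ok(enzyme, templates, {cut_allele: 2, "B" if cut_allele == "A" else "A": 1}):
            continue
        primers = PrimerPair(
            forward=cut_template[:primer_len],
            reverse=revcomp(cut_template[-primer_len:]),
        )
        try:
            return _finish_assay(
                enzyme, primers, templates, cut_allele,
                site_span=(flank_len, flank_len + L),
                snp_position=flank_len + j,
                forced=False,
            )
        except AssayError:
            continue
    raise AssayError(f"could not build a clean natural-site assay for {enzyme.name} in {max_tries} tries")


def _generate_forced(rng, enzyme, allele_a, allele_b, candidates, flank_len, primer_len, max_tries):
    L = len(enzyme.recognition)
    # need at least one site position 5' of the SNP to host the primer substitution
    usable = [
        (j, cut)
        for j, cut in candidates
        if j >= 1 and any(len(IUPAC[enzyme.recognition[q]]) < 4 for q in range(max(0, j - 8), j))
    ]
    if not usable:
        raise AssayError(
            f"{enzyme.name}: no arrangement allows a forced site for alleles {allele_a}/{allele_b}"
        )
    j, cut_allele = usable[rng.integers(len(usable))]
    # substitution position inside the primer: prefer the penultimate 3' base
    q_options = [q for q in range(max(0, j - 8), j) if len(IUPAC[enzyme.recognition[q]]) < 4]
    q = j - 2 if (j - 2) in q_options else q_options[-1]
    site = _concretise(rng, enzyme.recognition)
    site[j] = allele_a if cut_allele == "A" else allele_b
    broken = site.copy()
    # template base at q must NOT satisfy the recognition code
    non_matching = [b for b in BASES if b not in IUPAC[enzyme.recognition[q]]]
    broken[q] = non_matching[rng.integers(len(non_matching))]
    other = "B" if cut_allele == "A" else "A"
    other_base = allele_b if cut_allele == "A" else allele_a
    for _ in range(max_tries):
        left = _random_flank(rng, flank_len)
        right = _random_flank(rng, flank_len)
        seqs = {}
        for allele, snp_base in (
            (cut_allele, site[j]),
            (other, other_base),
        ):
            body = broken.copy()
            body[j] = snp_base
            seqs[allele] = left + "".join(body) + right
        # natively, neither allele may carry any site
        if not _clean_flanks_ok(enzyme, seqs, {"A": 1, "B": 1}):
            continue
        snp_position = flank_len + j
        p0 = snp_position - primer_len
        primer = list(seqs[cut_allele][p0:snp_position])
        sub_index = flank_len + q - p0
        primer[sub_index] = site[q]
        offset_from_3p = primer_len - 1 - sub_index
        primers = PrimerPair(
            forward="".join(primer),
            reverse=revcomp(seqs[cut_allele][-primer_len:]),
            forward_forced=((offset_from_3p, site[q]),),
        )
        try:
            result = _finish_assay(
                enzyme, primers, seqs, cut_allele,
                site_span=(flank_len, flank_len + L),
                snp_position=snp_position,
                forced=True,
            )
        except AssayError:
            continue
        cut_bands = result.assay.expected_a if cut_allele == "A" else result.assay.expected_b
        uncut_bands = result.assay.expected_b if cut_allele == "A" else result.assay.expected_a
        if len(cut_bands.fragment_lengths) == 2 and len(uncut_bands.fragment_lengths) == 1:
            return result
    raise AssayError(f"could not build a clean forced-site assay for {enzyme.name} in {max_tries} tries")
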