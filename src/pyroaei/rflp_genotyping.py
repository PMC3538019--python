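"""In-silico PCR-RFLP and forced-RFLP genotyping.

The forced variant reproduces the bench trick of placing one primer
immediately 5' of the marker SNP and substituting a base near the primer's
3' end, so that primer incorporation during amplification *creates* a
diagnostic restriction site for exactly one allele.  Digestion assumes
complete cutting (how RFLP gels are read); fragments of equal length are
merged for genotype calling, mimicking gel resolution, but kept distinct in
FragmentPattern reports.

All coordinates are 0-based half-open internally.  1-based "g./c." positions
from assay definitions must be converted on input (``pos - 1``).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._sequence import find_sites, revcomp
from .errors import (
    AmbiguousAmplificationError,
    AssayError,
    NoAmplificationError,
    UninformativeAssayError,
)
from .io_formats import EnzymeRecord

logger = logging.getLogger("pyroaei")

MIN_PRIMER_LEN = 12
#: forced substitutions must sit in the last 8 nt of a primer (3'-anchored)
MAX_FORCED_OFFSET = 7


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers with optional forced (mismatch) positions.

    Forced positions are (offset from the 3' end, substituted base); offset 0
    is the 3'-terminal base.  The substituted base is part of the primer
    sequence as written; the offset marks where a template mismatch is
    tolerated during binding and overwritten during amplification.
    """

    forward: str
    reverse: str
    forward_forced: tuple[tuple[int, str], ...] = ()
    reverse_forced: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        for name, primer, forced in (
            ("forward", self.forward, self.forward_forced),
            ("reverse", self.reverse, self.reverse_forced),
        ):
            if len(primer) < MIN_PRIMER_LEN:
                raise AssayError(f"{name} primer shorter than {MIN_PRIMER_LEN} nt")
            if len(forced) > 1:
                raise AssayError(f"{name} primer has more than one forced position")
            for off, base in forced:
                if not 0 <= off <= MAX_FORCED_OFFSET:
                    raise AssayError(f"{name} forced offset {off} outside last {MAX_FORCED_OFFSET + 1} nt")
                if primer[len(primer) - 1 - off] != base:
                    raise AssayError(f"{name} primer does not carry forced base {base} at 3'-offset {off}")


@dataclass(frozen=True)
class Amplicon:
    """A primer-incorporated PCR product from one template allele."""

    sequence: str
    allele: str
    coords_on_template: tuple[int, int]  # 0-based half-open span on the template


@dataclass(frozen=True)
class FragmentPattern:
    """Top-strand fragment lengths of a complete digest, ascending."""

    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_lengths", tuple(sorted(int(x) for x in self.fragment_lengths)))
        if any(x < 1 for x in self.fragment_lengths):
            raise AssayError("fragment lengths must all be >= 1")

    @property
    def gel_bands(self) -> frozenset[int]:
        """Distinct lengths, i.e. what an agarose gel can resolve."""
        return frozenset(self.fragment_lengths)

    def total(self) -> int:
        return sum(self.fragment_lengths)


@dataclass(frozen=True)
class GenotypeCall:
    animal: str
    gene: str
    call: str  # AA | AB | BB | ambiguous


@dataclass(frozen=True)
class RflpAssay:
    """A complete in-silico assay: primers, enzyme and expected allele patterns."""

    gene: str
    snp_alleles: tuple[str, str]
    enzyme: EnzymeRecord
    primers: PrimerPair
    expected_a: FragmentPattern
    expected_b: FragmentPattern
    snp_position: int  # 0-based position on the template
    forced: bool = False


# ---------------------------------------------------------------------------
# primer location and amplification
# ---------------------------------------------------------------------------

def _binding_pattern(primer: str, forced: tuple[tuple[int, str], ...]) -> str:
    """Primer as a template-matching pattern: forced positions accept any base."""
    chars = list(primer)
    for off, _base in forced:
        chars[len(primer) - 1 - off] = "N"
    return "".join(chars)


def locate_primers(template: str, pair: PrimerPair) -> tuple[int, int]:
    """Find the unique product span [forward start, reverse-site end) on the template.

    Matching is exact except at declared forced positions.  The forward primer
    binds the plus strand; the reverse primer is matched as its reverse
    complement downstream of the forward site.  Zero candidates raise
    NoAmplificationError; multiple raise AmbiguousAmplificationError.
    """
    if len(template) < len(pair.forward) + len(pair.reverse):
        raise NoAmplificationError("template shorter than combined primer length")
    fwd_sites = find_sites(template, _binding_pattern(pair.forward, pair.forward_forced))
    rev_pattern = revcomp(_binding_pattern(pair.reverse, pair.reverse_forced))
    rev_sites = find_sites(template, rev_pattern)
    if len(fwd_sites) > 1 or len(rev_sites) > 1:
        raise AmbiguousAmplificationError(
            f"{len(fwd_sites)} forward and {len(rev_sites)} reverse primer sites on template"
        )
    products = [
        (f, r + len(pair.reverse))
        for f in fwd_sites
        for r in rev_sites
        if r >= f + len(pair.forward)
    ]
    if not products:
        raise NoAmplificationError("no ordered forward/reverse primer pair on template")
    return products[0]


def amplify(template: str, pair: PrimerPair, allele: str = "") -> Amplicon:
    """Return the PCR product with both primer sequences substituted in.

    Because the primers are physically incorporated into the product, any
    forced base they carry is present in the amplicon even though the
    template lacks it — this is what creates a forced restriction site.
    """
    start, end = locate_primers(template, pair)
    inner = template[start + len(pair.forward): end - len(pair.reverse)]
    seq = pair.forward + inner + revcomp(pair.reverse)
    return Amplicon(sequence=seq, allele=allele, coords_on_template=(start, end))


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(amplicon: Amplicon | str, enzyme: EnzymeRecord) -> FragmentPattern:
    """Completely digest an amplicon; report top-strand fragment lengths.

    Sites are found on both strands (a site on the bottom strand cuts the top
    strand at ``site_start + len - cut_offset_bottom``).  Overlapping sites
    are resolved left to right: a site destroyed by an earlier cut is not
    cut.  Cut positions falling outside the amplicon (distal cutters near an
    end) clamp to no-cut with a warning.  Zero sites give a single fragment.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    n = len(seq)
    site = enzyme.recognition
    length = len(site)
    # (site_start, top-strand cut, bottom-strand cut) in plus-strand coordinates
    events: set[tuple[int, int, int]] = set()
    for s in find_sites(seq, site):
        events.add((s, s + enzyme.cut_offset_top, s + enzyme.cut_offset_bottom))
    rc = revcomp(site)
    for s in find_sites(seq, rc):
        events.add((s, s + length - enzyme.cut_offset_bottom, s + length - enzyme.cut_offset_top))
    cuts: list[int] = []
    for site_start, cut, cut_bottom in sorted(events):
        if any(site_start < p < site_start + length for p in cuts):
            continue  # recognition site destroyed by an earlier cut
        if not (0 < cut < n and 0 < cut_bottom < n):
            # a double-strand break needs both strand cuts inside the molecule
            logger.warning(
                "%s: cut at %d/%d outside amplicon of length %d; treated as no cut",
                enzyme.name, cut, cut_bottom, n,
            )
            continue
        cuts.append(cut)
    bounds = [0] + sorted(set(cuts)) + [n]
    return FragmentPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


# ---------------------------------------------------------------------------
# genotype calling and heterozygote selection
# ---------------------------------------------------------------------------

def call_genotype(
    observed: FragmentPattern | Sequence[int],
    expected_a: FragmentPattern,
    expected_b: FragmentPattern,
    animal: str = "",
    gene: str = "",
) -> GenotypeCall:
    """Match an observed gel ladder against the two allele patterns.

    A heterozygote shows the union of both allele ladders, deduplicated by
    length as on a gel.  Anything else that matches neither pure pattern nor
    the union is ambiguous.
    """
    bands_a, bands_b = expected_a.gel_bands, expected_b.gel_bands
    if bands_a == bands_b:
        raise UninformativeAssayError("expected allele patterns are identical on a gel")
    obs = frozenset(int(x) for x in (observed.fragment_lengths if isinstance(observed, FragmentPattern) else observed))
    if obs == bands_a:
        call = "AA"
    elif obs == bands_b:
        call = "BB"
    elif obs == bands_a | bands_b:
        call = "AB"
    else:
        call = "ambiguous"
    return GenotypeCall(animal=animal, gene=gene, call=call)


def observed_bands(genotype: str, expected_a: FragmentPattern, expected_b: FragmentPattern) -> frozenset[int]:
    """Gel bands a given true genotype would produce (union for heterozygotes)."""
    if genotype == "AA":
        return expected_a.gel_bands
    if genotype == "BB":
        return expected_b.gel_bands
    if genotype == "AB":
        return expected_a.gel_bands | expected_b.gel_bands
    raise ValueError(f"unknown genotype {genotype!r}")


@dataclass(frozen=True)
class HetSelection:
    gene: str
    n_animals: int
    n_het: int
    min_required: int
    passed: bool
    het_ids: tuple[str, ...]


def select_heterozygotes(
    genotypes: pd.DataFrame,
    min_het_fraction: float = 0.125,
    n_animals: int | None = None,
) -> dict[str, HetSelection]:
    """Per-gene heterozygosity filter for the expression analysis.

    A gene passes iff its heterozygote count reaches
    ``ceil(min_het_fraction * n_animals)`` — with the study's defaults
    (fraction 0.125, 40 animals) the minimum qualifying count is 5.
    Returns the heterozygote ids per gene for downstream AEI.
    """
    n = len(genotypes) if n_animals is None else n_animals
    min_required = math.ceil(round(min_het_fraction * n, 9))
    out: dict[str, HetSelection] = {}
    for gene in genotypes.columns:
        hets = tuple(str(i) for i in genotypes.index[genotypes[gene] == "AB"])
        out[gene] = HetSelection(
            gene=gene,
            n_animals=n,
            n_het=len(hets),
            min_required=min_required,
            passed=len(hets) >= min_required,
            het_ids=hets,
        )
    n_pass = sum(s.passed for s in out.values())
    logger.info("select_heterozygotes: %d/%d genes pass at fraction %.3f", n_pass, len(out), min_het_fraction)
    return out


def genotype_population(
    assay: RflpAssay,
    templates: dict[str, str],
    true_genotypes: pd.Series,
) -> list[GenotypeCall]:
    """Amplify + digest each animal's alleles and call its genotype.

    ``templates`` maps allele label ('A'/'B') to the template sequence for
    that allele; heterozygotes contribute both amplicon digests to the gel.
    """
    patterns = {
        allele: digest(amplify(templates[allele], assay.primers, allele=allele), assay.enzyme)
        for allele in ("A", "B")
    }
    calls = []
    for animal, gt in true_genotypes.items():
        obs = observed_bands(gt, patterns["A"], patterns["B"])
        calls.append(call_genotype(obs, patterns["A"], patterns["B"], animal=str(animal), gene=assay.gene))
    return calls
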