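"""Prioritise candidate causal variants from carrier re-sequencing data.

Given sequence-derived genotypes for a cohort around a deficit region, the
filters mirror the logic of recessive-lethal fine-mapping:

* ``lethal_recessive`` mode — a fully penetrant recessive lethal can never be
  alt-homozygous in a healthy adult, and should be heterozygous in (most)
  haplotype carriers. The carrier-heterozygosity threshold k-of-m is kept
  below m to tolerate heterozygote under-calling in low-coverage sequence
  data.
* ``affected_homozygote`` mode — with a known affected (haplotype-homozygous)
  animal, keep sites alt-homozygous in every affected animal and never
  alt-homozygous in any other animal.
* cross-population screening removes candidates that occur alt-homozygous in
  unrelated cohorts (other breeds), where a breed-specific lethal cannot be
  homozygous either.

Genotypes are alt-allele counts (0/1/2, missing = -1). Missing calls are
conservative in both directions: a missing call in a carrier does not count
as heterozygous and a missing call in an adult does not count as
alt-homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1


@dataclass
class SequencedCohort:
    """Per-animal metadata plus a site x animal genotype matrix.

    ``animals`` columns: animal, breed, carrier (bool), affected (bool),
    optional mean_coverage. ``genotypes[s, a]`` is the alt-allele count of
    animal ``a`` at site ``s`` (rows aligned with the site table passed to
    the filters).
    """

    animals: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        required = {"animal", "breed", "carrier"}
        if not required.issubset(self.animals.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if "affected" not in self.animals.columns:
            self.animals = self.animals.assign(affected=False)
        if self.genotypes.shape[1] != len(self.animals):
            raise ValueError("genotype matrix does not match cohort size")


@dataclass(frozen=True)
class FilterConfig:
    pad_bp: int = 1_000_000
    min_het_carriers: int = 5
    mode: str = "lethal_recessive"  # or "affected_homozygote"


@dataclass
class CascadeReport:
    steps: list = field(default_factory=list)  # (step name, surviving count)

    def record(self, step: str, n: int) -> None:
        self.steps.append((step, int(n)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "surviving"])


def region_of_interest(region, pad_bp: int = 1_000_000, chrom_length: int | None = None):
    """Pad a deficit region by ``pad_bp`` on either side, clipped to [1, chrom end]."""
    if pad_bp < 0:
        raise ValueError("pad must be non-negative")
    start = max(1, int(region.start_bp) - pad_bp)
    end = int(region.end_bp) + pad_bp
    if chrom_length is not None:
        end = min(end, int(chrom_length))
    return region.chrom, start, end


def filter_lethal_candidates(
    sites: pd.DataFrame,
    cohort: SequencedCohort,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, CascadeReport]:
    """Two-step recessive-lethal cascade with per-step surviving counts.

    Step 1 removes sites alt-homozygous in any (healthy adult) animal of the
    cohort; step 2 keeps sites heterozygous in at least ``min_het_carriers``
    of the flagged carriers.
    """
    if cfg.mode != "lethal_recessive":
        raise ValueError("filter_lethal_candidates requires mode='lethal_recessive'")
    carriers = cohort.animals["carrier"].to_numpy(dtype=bool)
    adults = ~cohort.animals["affected"].to_numpy(dtype=bool)
    if cfg.min_het_carriers > int(carriers.sum()):
        raise ValueError(
            f"min_het_carriers={cfg.min_het_carriers} exceeds the "
            f"{int(carriers.sum())} flagged carriers"
        )
    report = CascadeReport()
    report.record("input", len(sites))

    g = cohort.genotypes
    if g.shape[0] != len(sites):
        raise ValueError("genotype rows do not align with the site table")
    keep1 = ~((g[:, adults] == 2).any(axis=1))
    report.record("no_adult_alt_homozygote", int(keep1.sum()))

    het_counts = (g[:, carriers] == 1).sum(axis=1)
    keep2 = keep1 & (het_counts >= cfg.min_het_carriers)
    out = sites[keep2].copy()
    out["het_carriers"] = het_counts[keep2]
    report.record(f"het_in_ge_{cfg.min_het_carriers}_carriers", int(keep2.sum()))
    return out, report


def filter_affected_homozygote(
    sites: pd.DataFrame, cohort: SequencedCohort
) -> pd.DataFrame:
    """Keep sites alt-homozygous in every affected animal and in no other animal."""
    affected = cohort.animals["affected"].to_numpy(dtype=bool)
    if not affected.any():
        raise ValueError("no affected animal flagged in the cohort")
    g = cohort.genotypes
    hom_in_affected = (g[:, affected] == 2).all(axis=1)
    hom_elsewhere = (g[:, ~affected] == 2).any(axis=1)
    return sites[hom_in_affected & ~hom_elsewhere].copy()


def cross_population_filter(
    candidates: pd.DataFrame,
    candidate_genotypes: np.ndarray,
    other_cohorts: list[SequencedCohort],
    flag_segregating: bool = True,
) -> pd.DataFrame:
    """Remove candidates alt-homozygous in any animal of any other cohort.

    ``candidate_genotypes`` rows align with ``candidates``; each other cohort
    must carry genotypes for the same rows. Candidates merely segregating
    (heterozygous) elsewhere are flagged, not removed.
    """
    out = candidates.copy()
    if not other_cohorts:
        return out
    hom = np.zeros(len(out), dtype=bool)
    seg = np.zeros(len(out), dtype=bool)
    for cohort in other_cohorts:
        g = cohort.genotypes
        if g.shape[0] != len(out):
            raise ValueError("cohort genotypes do not align with candidate rows")
        hom |= (g == 2).any(axis=1)
        seg |= (g == 1).any(axis=1)
    if flag_segregating:
        out["segregates_elsewhere"] = seg
    return out[~hom]


def carrier_allele_frequency(cohort: SequencedCohort) -> float:
    """Frequency implied by heterozygous carriers: carriers / (2 x animals)."""
    n = len(cohort.animals)
    if n == 0:
        raise ValueError("empty cohort")
    return float(cohort.animals["carrier"].sum()) / (2 * n)


def hwe_deficit_test(n: int, n_het: int, n_hom_alt: int) -> tuple[float, float, float]:
    """Expected homozygote count under HWE and the exact lower-tail deficit P.

    Returns (allele frequency q, expected homozygotes n*q^2,
    P(X <= n_hom_alt | Binomial(n, q^2))).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n_het + n_hom_alt > n:
        raise ValueError("genotype counts exceed sample size")
    q = (n_het + 2 * n_hom_alt) / (2 * n)
    expected = n * q * q
    p = float(stats.binom.cdf(n_hom_alt, n, q * q))
    return q, expected, p


def haplotype_variant_concordance(
    carrier_flags, genotypes
) -> tuple[float | None, pd.DataFrame]:
    """Squared correlation between carrier status and variant dosage.

    The carrier flag (0/1) is used as an allele-dosage proxy for the focal
    haplotype; perfect concordance (every carrier heterozygous, every
    non-carrier reference-homozygous, no homozygotes) gives r^2 = 1. Returns
    the r^2 (None when either vector is constant) and the carrier x genotype
    contingency table including a mismatch flag.
    """
    c = np.asarray(carrier_flags, dtype=int)
    g = np.asarray(genotypes, dtype=int)
    if c.shape != g.shape:
        raise ValueError("carrier flags and genotypes must align")
    table = pd.crosstab(
        pd.Series(c, name="carrier"), pd.Series(g, name="genotype"), dropna=False
    )
    expected = np.where(c == 1, 1, 0)
    mismatches = int(((g != MISSING) & (g != expected)).sum())
    table.attrs["mismatches"] = mismatches
    ok = g != MISSING
    if ok.sum() < 2 or np.all(c[ok] == c[ok][0]) or np.all(g[ok] == g[ok][0]):
        return None, table
    r = np.corrcoef(c[ok], g[ok])[0, 1]
    return float(r * r), table
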