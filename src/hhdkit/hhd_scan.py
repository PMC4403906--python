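"""Sliding-window scan for homozygous haplotype deficiency (HHD).

A recessive allele that kills homozygotes before genotyping manifests as a
haplotype that is common among genotyped animals yet (almost) never observed
in homozygous state. The scan slides variable-size windows along each
chromosome, enumerates the haplotypes above a frequency threshold in each
window, computes for every scorable animal the probability of being
homozygous for a given haplotype from its sire's and maternal grandsire's
haplotype states plus the population frequency, and compares the observed
homozygote count against that expectation with an exact lower-tail test.

The per-animal homozygosity probability is

    p_i = P(paternal allele = h) * P(maternal allele = h)

with P(paternal = h) = (sire copies of h) / 2 and
P(maternal = h) = 0.5 * (MGS copies of h) / 2 + 0.5 * f_h
(falling back to the population frequency f_h when the maternal grandsire is
unknown or ungenotyped). Animals whose sire is ungenotyped are not scored.

The sum of independent, non-identical Bernoulli trials follows a
Poisson-binomial distribution; its exact lower tail is the deficit P-value.
A mean-probability binomial is provided as a pooled alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geno_io import HaplotypeMatrix, MarkerMap, PedigreeTable

# Smallest representable tail; P is reported in (0, 1].
_TINY = 5e-324


@dataclass(frozen=True)
class WindowSpec:
    chrom: object
    start_bp: int
    end_bp: int  # closed interval
    size_mb: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("window end must exceed start")


@dataclass
class HaplotypeCatalog:
    """Distinct haplotypes of one window with frequencies and per-animal copies.

    Frequencies are counted over all 2N chromosomes (the denominator includes
    haplotypes later dropped by the frequency threshold).
    """

    window: WindowSpec
    animals: list
    strings: np.ndarray  # (n_haps, n_markers) int8, retained haplotypes only
    freq: np.ndarray  # (n_haps,) frequency over all 2N chromosomes
    copies: np.ndarray  # (n_animals, n_haps) copy counts 0/1/2
    n_chromosomes: int

    @property
    def n_haps(self) -> int:
        return len(self.freq)

    def carriers(self, hap: int) -> frozenset:
        return frozenset(
            a for a, c in zip(self.animals, self.copies[:, hap]) if c > 0
        )


@dataclass(frozen=True)
class HHDTestResult:
    window: WindowSpec
    hap: int
    hap_string: tuple
    f_h: float
    n_scored: int
    expected: float
    observed: int
    p_value: float
    carriers: frozenset


@dataclass(frozen=True)
class HHDRegion:
    label: str
    chrom: object
    start_bp: int
    end_bp: int
    representative: HHDTestResult
    n_windows: int
    min_p: float


@dataclass(frozen=True)
class ScanConfig:
    sizes_mb: tuple = (0.75, 1.5, 3.0, 5.0, 10.0)
    step_factor: float = 0.5
    min_freq: float = 0.02
    alpha: float = 1e-6
    mode: str = "poisson_binomial"  # or "binomial_meanp"
    min_markers: int = 2
    # windows whose cheap pooled-binomial tail exceeds this are not re-tested
    # with the exact Poisson-binomial; alpha decisions always use the exact test
    exact_refine_threshold: float = 1e-3


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(
    mmap: MarkerMap, sizes_mb=(0.75, 1.5, 3.0, 5.0, 10.0), step_factor: float = 0.5
) -> list[WindowSpec]:
    """Sliding windows of each size, advanced by ``step_factor * size``.

    Windows start at the chromosome start (position 1) and advance until one
    reaches the last marker; the terminal window is clipped to the last marker
    position (a chromosome shorter than the window yields a single clipped
    window).
    """
    if len(mmap) == 0:
        raise ValueError("empty marker map")
    windows = []
    for chrom in mmap.chroms:
        pos = mmap.df.loc[mmap.df["chrom"] == chrom, "pos_bp"]
        last = int(pos.max())
        for size in sizes_mb:
            size_bp = int(round(size * 1e6))
            step = int(round(step_factor * size * 1e6))
            start = 1
            while start <= last:
                end = min(start + size_bp - 1, last)
                if end > start:
                    windows.append(WindowSpec(chrom, start, end, size))
                if end >= last:
                    break
                start += step
    return windows


# ---------------------------------------------------------------------------
# haplotype enumeration
# ---------------------------------------------------------------------------


def enumerate_haplotypes(
    h: HaplotypeMatrix, window: WindowSpec, min_freq: float = 0.02
) -> HaplotypeCatalog:
    """Catalogue distinct allele strings of a window over all 2N chromosomes.

    Strings with frequency <= ``min_freq`` are dropped from the catalogue but
    remain in the frequency denominator.
    """
    idx = h.markers.marker_indices(window.chrom, window.start_bp, window.end_bp)
    if len(idx) < 2:
        raise ValueError(
            f"window {window.chrom}:{window.start_bp}-{window.end_bp} "
            f"contains fewer than 2 markers"
        )
    n = len(h.animals)
    chroms = h.alleles[:, idx, :].transpose(0, 2, 1).reshape(2 * n, len(idx))
    uniq, inverse, counts = np.unique(
        chroms, axis=0, return_inverse=True, return_counts=True
    )
    freq = counts / (2 * n)
    keep = freq > min_freq
    kept_ids = np.flatnonzero(keep)
    remap = -np.ones(len(uniq), dtype=np.int64)
    remap[kept_ids] = np.arange(len(kept_ids))
    per_chrom = remap[inverse].reshape(n, 2)
    copies = np.zeros((n, len(kept_ids)), dtype=np.int8)
    for k in range(2):
        lab = per_chrom[:, k]
        ok = lab >= 0
        np.add.at(copies, (np.flatnonzero(ok), lab[ok]), 1)
    return HaplotypeCatalog(
        window=window,
        animals=list(h.animals),
        strings=uniq[kept_ids],
        freq=freq[kept_ids],
        copies=copies,
        n_chromosomes=2 * n,
    )


# ---------------------------------------------------------------------------
# homozygosity probability and exact deficit test
# ---------------------------------------------------------------------------


def homozygosity_probability(
    animal, hap: int, cat: HaplotypeCatalog, ped: PedigreeTable
) -> float:
    """P(animal is homozygous for haplotype ``hap``) from sire/MGS states.

    Requires the sire's diplotype in the catalogue; raises if the animal is
    absent from the pedigree, returns ``None`` if the animal cannot be scored.
    """
    from .geno_io import maternal_grandsire

    if animal not in ped:
        raise KeyError(f"animal {animal} absent from pedigree")
    index = {a: i for i, a in enumerate(cat.animals)}
    sire = ped.sire_of(animal)
    if sire is None or sire not in index:
        return None
    f_h = float(cat.freq[hap])
    p_pat = cat.copies[index[sire], hap] / 2.0
    mgs = maternal_grandsire(ped, animal)
    if mgs is not None and mgs in index:
        p_mat = 0.5 * cat.copies[index[mgs], hap] / 2.0 + 0.5 * f_h
    else:
        p_mat = f_h
    return float(p_pat * p_mat)


def poisson_binomial_cdf(k: int, p: np.ndarray) -> float:
    """Exact P(X <= k) for X a sum of independent Bernoulli(p_i) trials.

    Groups equal probabilities and convolves the (truncated) binomial PMFs of
    the groups; truncation beyond k+1 terms is exact for the lower tail.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if k >= n:
        return 1.0
    if k < 0:
        return 0.0
    vals, counts = np.unique(p, return_counts=True)
    dist = np.ones(1)
    for v, c in zip(vals, counts):
        m = int(min(c, k + 1))
        pmf = stats.binom.pmf(np.arange(m + 1), c, v)
        dist = np.convolve(dist, pmf)[: k + 2]
    return float(min(1.0, dist[: k + 1].sum()))


def hhd_test(observed: int, p_list, mode: str = "poisson_binomial") -> float:
    """Lower-tail P(X <= observed) for the homozygote count.

    ``poisson_binomial`` evaluates the exact distribution of the sum of
    heterogeneous Bernoulli trials; ``binomial_meanp`` pools the trials into
    Binomial(n, mean p).
    """
    p = np.asarray(p_list, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    n = len(p)
    if observed > n:
        raise ValueError("observed count exceeds number of trials")
    if mode == "poisson_binomial":
        out = poisson_binomial_cdf(observed, p)
    elif mode == "binomial_meanp":
        out = float(stats.binom.cdf(observed, n, p.mean())) if n else 1.0
    else:
        raise ValueError(f"unknown test mode: {mode}")
    return max(out, _TINY)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def _score_window(
    cat: HaplotypeCatalog,
    sire_idx: np.ndarray,
    mgs_idx: np.ndarray,
    cfg: ScanConfig,
) -> list[HHDTestResult]:
    results = []
    scored = sire_idx >= 0
    n_scored = int(scored.sum())
    if n_scored == 0:
        return results
    for hap in range(cat.n_haps):
        f_h = float(cat.freq[hap])
        cop = cat.copies[:, hap]
        p_pat = np.where(scored, cop[np.clip(sire_idx, 0, None)] / 2.0, 0.0)
        has_mgs = mgs_idx >= 0
        p_mat = np.where(
            has_mgs, 0.5 * cop[np.clip(mgs_idx, 0, None)] / 2.0 + 0.5 * f_h, f_h
        )
        p = (p_pat * p_mat)[scored]
        observed = int((cop == 2)[scored].sum())
        expected = float(p.sum())
        p_nz = p[p > 0]
        obs_eff = min(observed, len(p_nz))
        if cfg.mode == "poisson_binomial":
            # cheap pooled prefilter; exact refinement near the tail
            p_pool = hhd_test(observed, p, mode="binomial_meanp")
            if p_pool <= cfg.exact_refine_threshold:
                p_val = hhd_test(obs_eff, p_nz, mode="poisson_binomial")
            else:
                p_val = p_pool
        else:
            p_val = hhd_test(observed, p, mode=cfg.mode)
        results.append(
            HHDTestResult(
                window=cat.window,
                hap=hap,
                hap_string=tuple(int(a) for a in cat.strings[hap]),
                f_h=f_h,
                n_scored=n_scored,
                expected=expected,
                observed=observed,
                p_value=p_val,
                carriers=cat.carriers(hap),
            )
        )
    return results


def scan(
    h: HaplotypeMatrix,
    ped: PedigreeTable,
    cfg: ScanConfig = ScanConfig(),
) -> list[HHDTestResult]:
    """Run the full deficit scan over every window and retained haplotype."""
    from .geno_io import maternal_grandsire

    order = sorted(range(len(h.animals)), key=lambda i: str(h.animals[i]))
    animals = [h.animals[i] for i in order]
    alleles = h.alleles[order]
    hs = HaplotypeMatrix(animals, alleles, h.markers)

    index = hs.animal_index()
    sire_idx = np.full(len(animals), -1, dtype=np.int64)
    mgs_idx = np.full(len(animals), -1, dtype=np.int64)
    for i, a in enumerate(animals):
        if a not in ped:
            continue
        s = ped.sire_of(a)
        if s is not None and s in index:
            sire_idx[i] = index[s]
        m = maternal_grandsire(ped, a)
        if m is not None and m in index:
            mgs_idx[i] = index[m]

    results: list[HHDTestResult] = []
    for window in make_windows(hs.markers, cfg.sizes_mb, cfg.step_factor):
        idx = hs.markers.marker_indices(window.chrom, window.start_bp, window.end_bp)
        if len(idx) < cfg.min_markers:
            continue
        cat = enumerate_haplotypes(hs, window, cfg.min_freq)
        results.extend(_score_window(cat, sire_idx, mgs_idx, cfg))
    return results


def significant(results: list[HHDTestResult], alpha: float = 1e-6) -> list[HHDTestResult]:
    return [r for r in results if r.p_value < alpha]


def merge_regions(results: list[HHDTestResult], jaccard: float = 0.5) -> list[HHDRegion]:
    """Merge overlapping significant windows with shared carrier sets.

    Windows merge into a growing region when they overlap it in base pairs and
    their carrier set shares at least ``jaccard`` of animals (Jaccard index)
    with the region's current representative (lowest-P) window. Region bounds
    are the union of the merged windows.
    """
    regions: list[HHDRegion] = []
    clusters: list[dict] = []
    for r in sorted(results, key=lambda r: (str(r.window.chrom), r.window.start_bp)):
        placed = False
        for cl in clusters:
            if r.window.chrom != cl["chrom"] or r.window.start_bp > cl["end"]:
                continue
            rep = cl["rep"]
            inter = len(r.carriers & rep.carriers)
            union = len(r.carriers | rep.carriers)
            if union and inter / union >= jaccard:
                cl["start"] = min(cl["start"], r.window.start_bp)
                cl["end"] = max(cl["end"], r.window.end_bp)
                cl["n"] += 1
                if r.p_value < rep.p_value:
                    cl["rep"] = r
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "chrom": r.window.chrom,
                    "start": r.window.start_bp,
                    "end": r.window.end_bp,
                    "rep": r,
                    "n": 1,
                }
            )
    for i, cl in enumerate(clusters, start=1):
        regions.append(
            HHDRegion(
                label=f"HR{i}",
                chrom=cl["chrom"],
                start_bp=cl["start"],
                end_bp=cl["end"],
                representative=cl["rep"],
                n_windows=cl["n"],
                min_p=cl["rep"].p_value,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# design: sample size needed to see a deficit
# ---------------------------------------------------------------------------


def required_sample_size(f_h: float, alpha: float, model: str = "hwe") -> int:
    """Smallest n with P(zero homozygotes among n) < alpha.

    ``hwe`` uses the per-animal homozygosity probability f_h^2. ``sire_mgs``
    evaluates the mean per-animal probability under random mating, where the
    sire's and maternal grandsire's copy numbers are Hardy-Weinberg draws;
    averaged over that pedigree mixture the per-animal probability is again
    f_h^2, so the two models coincide under random mating.
    """
    if not 0.0 < f_h < 1.0:
        raise ValueError("haplotype frequency must be in (0, 1)")
    if alpha >= 1.0:
        raise ValueError("alpha must be below 1")
    if model == "hwe":
        p0 = f_h * f_h
    elif model == "sire_mgs":
        # enumerate sire (S) and MGS (M) copy numbers under HWE
        probs = np.array([(1 - f_h) ** 2, 2 * f_h * (1 - f_h), f_h**2])
        p0 = 0.0
        for s in range(3):
            for m in range(3):
                p_i = (s / 2.0) * (0.5 * m / 2.0 + 0.5 * f_h)
                p0 += probs[s] * probs[m] * p_i
    else:
        raise ValueError(f"unknown expectation model: {model}")
    # closed form with local search to absorb rounding
    n = max(1, math.ceil(math.log(alpha) / math.log1p(-p0)))
    while (1 - p0) ** n >= alpha:
        n += 1
    while n > 1 and (1 - p0) ** (n - 1) < alpha:
        n -= 1
    return n
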