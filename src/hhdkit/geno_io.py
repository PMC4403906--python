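"""Genotype, haplotype and pedigree containers plus quality control.

This module holds the core in-memory objects used across the package:

* :class:`MarkerMap` — an ordered SNP map (marker id, chromosome, bp position).
* :class:`GenotypeMatrix` — unphased calls coded as alternate-allele counts
  (0/1/2, missing = -1).
* :class:`HaplotypeMatrix` — phased diploid alleles, two chromosome strings per
  animal, no missing entries.
* :class:`PedigreeTable` — animal/sire/dam links with ancestry validation.

Array coordinates are 1-based and fully closed, matching VCF conventions.
Quality control follows the usual array-genotyping cascade for livestock SNP
panels: autosome restriction, animal call rate, marker call rate, minor allele
frequency, exact Hardy-Weinberg test and sire-offspring Mendelian-conflict
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "CHRX", "CHRY", "CHRM", "CHRMT"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map; ``pos_bp`` strictly increasing within chromosome."""

    df: pd.DataFrame  # columns: marker_id, chrom, pos_bp

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos_bp"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if self.df["marker_id"].duplicated().any():
            dup = self.df.loc[self.df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if (self.df["pos_bp"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing or sub["pos_bp"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def marker_indices(self, chrom, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of markers inside the closed interval [start_bp, end_bp]."""
        m = (self.df["chrom"] == chrom) & (self.df["pos_bp"] >= start_bp) & (
            self.df["pos_bp"] <= end_bp
        )
        return np.flatnonzero(m.to_numpy())


@dataclass
class GenotypeMatrix:
    """Unphased calls, ``calls[i, j]`` = alt-allele count of animal i at marker j."""

    animals: list
    calls: np.ndarray  # (n_animals, n_markers) int8, MISSING = -1
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animals), len(self.markers)):
            raise ValueError("genotype matrix shape does not match animals/markers")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")

    def animal_index(self) -> dict:
        return {a: i for i, a in enumerate(self.animals)}


@dataclass
class HaplotypeMatrix:
    """Phased alleles, ``alleles[i, j, k]`` = allele of animal i, marker j, chromosome k."""

    animals: list
    alleles: np.ndarray  # (n_animals, n_markers, 2) int8, no missing
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.animals), len(self.markers), 2):
            raise ValueError("haplotype matrix shape does not match animals/markers")
        if (self.alleles < 0).any():
            raise ValueError("phased haplotypes may not contain missing alleles")

    def animal_index(self) -> dict:
        return {a: i for i, a in enumerate(self.animals)}

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phase: unordered allele pair -> alt-allele count."""
        return GenotypeMatrix(self.animals, self.alleles.sum(axis=2), self.markers)


@dataclass
class PedigreeTable:
    """animal -> (sire, dam) links. Unknown parents are ``None``."""

    df: pd.DataFrame  # columns: animal, sire, dam (+ optional sex, birth_date)
    _sire: dict = field(init=False, repr=False)
    _dam: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        if self.df["animal"].duplicated().any():
            dup = self.df.loc[self.df["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"duplicate animal id in pedigree: {dup}")
        df = self.df.copy()
        for col in ("sire", "dam"):
            df[col] = df[col].where(df[col].notna() & (df[col] != ""), None)
        self.df = df
        self._sire = dict(zip(df["animal"], df["sire"]))
        self._dam = dict(zip(df["animal"], df["dam"]))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict = {}  # 0 in-progress, 1 done

        for start in self._sire:
            if start in state:
                continue
            stack = [start]
            path = []
            while stack:
                a = stack[-1]
                if state.get(a) == 0:
                    # all parents processed
                    state[a] = 1
                    stack.pop()
                    path.pop()
                    continue
                if state.get(a) == 1:
                    stack.pop()
                    continue
                state[a] = 0
                path.append(a)
                for p in (self._sire.get(a), self._dam.get(a)):
                    if p is None or p not in self._sire:
                        continue
                    if state.get(p) == 0:
                        raise ValueError(f"pedigree cycle involving animal {p}")
                    if p not in state:
                        stack.append(p)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, animal) -> bool:
        return animal in self._sire

    def sire_of(self, animal):
        return self._sire.get(animal)

    def dam_of(self, animal):
        return self._dam.get(animal)


@dataclass(frozen=True)
class QcConfig:
    min_call_rate: float = 0.95
    min_maf: float = 0.02
    hwe_alpha: float = 1e-6
    max_mendel_errors: int = 500
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pedigree(path) -> PedigreeTable:
    """Read a delimited pedigree file with header ``animal,sire,dam(,sex,birth_date)``.

    Empty fields, ``NA`` and ``0`` are treated as unknown parents.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sire", "dam"):
        if col in df.columns:
            df[col] = df[col].replace({"0": None, "NA": None, "": None})
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    out = ped.df.copy()
    out.to_csv(path, index=False, na_rep="")


def read_phased_variants(path) -> tuple[MarkerMap, HaplotypeMatrix]:
    """Read a VCF of fully phased biallelic sites.

    The first-listed allele of each phased genotype becomes chromosome 0 of the
    animal (``0|1`` -> haplotypes (0, 1)). An unphased genotype anywhere is an
    error naming the site and sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    alleles = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.CHROM}:{var.POS} is not biallelic")
        site = np.empty((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a0, a1, phased = g[0], g[1], g[2]
            if not phased or a0 < 0 or a1 < 0:
                raise ValueError(
                    f"unphased or missing genotype at {var.CHROM}:{var.POS} "
                    f"for sample {samples[i]}"
                )
            site[i, 0] = a0
            site[i, 1] = a1
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS))
        alleles.append(site)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"]))
    arr = np.stack(alleles, axis=1)  # (n_samples, n_markers, 2)
    return mmap, HaplotypeMatrix(samples, arr, mmap)


# ---------------------------------------------------------------------------
# pedigree-derived relations
# ---------------------------------------------------------------------------


def maternal_grandsire(ped: PedigreeTable, animal):
    """Sire of the animal's dam, or ``None`` if dam or dam's sire is unrecorded."""
    if animal not in ped:
        raise KeyError(f"unknown animal id: {animal}")
    dam = ped.dam_of(animal)
    if dam is None or dam not in ped:
        return None
    return ped.sire_of(dam)


def mendelian_error_counts(g: GenotypeMatrix, ped: PedigreeTable) -> np.ndarray:
    """Per-marker counts of opposing-homozygote sire/offspring pairs.

    Only the conflict that is unambiguous from a single parent is counted:
    sire and offspring homozygous for opposite alleles (0 vs 2). Missing calls
    never contribute.
    """
    idx = g.animal_index()
    counts = np.zeros(len(g.markers), dtype=np.int64)
    for animal in g.animals:
        if animal not in ped:
            continue
        sire = ped.sire_of(animal)
        if sire is None or sire not in idx:
            continue
        gs = g.calls[idx[sire]]
        go = g.calls[idx[animal]]
        counts += ((gs == 0) & (go == 2)) | ((gs == 2) & (go == 0))
    return counts


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test (conditional on allele counts)
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE test P, conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts no more probable than
    the observed one, under the hypergeometric-type conditional distribution
    of heterozygotes given allele counts. Robust at low minor allele
    frequency, where the chi-square approximation fails.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    # heterozygote count has the parity of the rare allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalised log-probabilities via the recurrence of the conditional pmf
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # P(h) / P(h-2) = (nr - h + 2)(2n - nr - h + 2) / (h (h - 1))
        num = (n_rare - h + 2) * (2 * n - n_rare - h + 2)
        den = h * (h - 1)
        logp[i] = logp[i - 1] + np.log(num) - np.log(den)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    if obs not in hets:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = p[np.searchsorted(hets, obs)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix, ped: PedigreeTable, cfg: QcConfig = QcConfig()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the QC cascade and return the filtered matrix plus an exclusion report.

    Steps, in order: autosome restriction, animal call rate, marker call rate,
    minor allele frequency, exact HWE exclusion, Mendelian-error markers.
    The report lists one row per removed animal or marker with the reason and
    the offending value.
    """
    records = []
    calls = g.calls
    animals = list(g.animals)
    mdf = g.markers.df.reset_index(drop=True)
    keep_m = np.ones(len(mdf), dtype=bool)

    if cfg.autosomes_only:
        sex = mdf["chrom"].astype(str).str.upper().isin(_AUTOSOME_EXCLUDE).to_numpy()
        for mid in mdf.loc[sex, "marker_id"]:
            records.append(("marker", mid, "non_autosomal", np.nan))
        keep_m &= ~sex

    # animal call rate (over currently kept markers)
    sub = calls[:, keep_m]
    if sub.shape[1] == 0:
        raise ValueError("all markers removed during QC")
    a_rate = (sub != MISSING).mean(axis=1)
    keep_a = a_rate >= cfg.min_call_rate
    for i in np.flatnonzero(~keep_a):
        records.append(("animal", animals[i], "call_rate", float(a_rate[i])))
    calls = calls[keep_a]
    animals = [a for a, k in zip(animals, keep_a) if k]

    # marker call rate
    m_rate = np.where(keep_m, (calls != MISSING).mean(axis=0) if len(calls) else 0.0, 0.0)
    low = keep_m & (m_rate < cfg.min_call_rate)
    for i in np.flatnonzero(low):
        records.append(("marker", mdf.at[i, "marker_id"], "call_rate", float(m_rate[i])))
    keep_m &= ~low

    # minor allele frequency
    with np.errstate(invalid="ignore"):
        obs = calls != MISSING
        alt = np.where(obs, calls, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        freq = np.divide(alt, 2 * n_obs, out=np.zeros(len(mdf)), where=n_obs > 0)
    maf = np.minimum(freq, 1 - freq)
    low = keep_m & (maf < cfg.min_maf)
    for i in np.flatnonzero(low):
        records.append(("marker", mdf.at[i, "marker_id"], "maf", float(maf[i])))
    keep_m &= ~low

    # exact HWE
    for j in np.flatnonzero(keep_m):
        col = calls[:, j]
        col = col[col != MISSING]
        p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if p < cfg.hwe_alpha:
            records.append(("marker", mdf.at[j, "marker_id"], "hwe", float(p)))
            keep_m[j] = False

    # Mendelian errors
    gm = GenotypeMatrix(animals, calls, g.markers)
    mend = mendelian_error_counts(gm, ped)
    high = keep_m & (mend > cfg.max_mendel_errors)
    for i in np.flatnonzero(high):
        records.append(("marker", mdf.at[i, "marker_id"], "mendel_errors", float(mend[i])))
    keep_m &= ~high

    if not keep_m.any():
        raise ValueError("all markers removed during QC")

    out_map = MarkerMap(mdf.loc[keep_m].reset_index(drop=True))
    out = GenotypeMatrix(animals, calls[:, keep_m], out_map)
    report = pd.DataFrame(records, columns=["kind", "id", "reason", "value"])
    return out, report


# ---------------------------------------------------------------------------
# half-sib phase correction
# ---------------------------------------------------------------------------


def correct_halfsib_phase(
    h: HaplotypeMatrix, ped: PedigreeTable, min_family: int = 10
) -> HaplotypeMatrix:
    """Fix paternal/maternal labelling in large half-sib families.

    Within each half-sib family of at least ``min_family`` genotyped offspring
    whose sire is genotyped, each offspring string is scored against the sire's
    two haplotypes by its minimum opposite-allele mismatch count. If the string
    labelled maternal (chromosome 1) is strictly more consistent with descent
    from the sire than the string labelled paternal (chromosome 0), the labels
    are swapped. Ties leave the phase unchanged; genotypes (unordered allele
    pairs) are never altered.
    """
    idx = h.animal_index()
    families: dict = {}
    for animal in h.animals:
        if animal not in ped:
            continue
        sire = ped.sire_of(animal)
        if sire is not None and sire in idx:
            families.setdefault(sire, []).append(animal)

    out = h.alleles.copy()
    for sire, offspring in families.items():
        if len(offspring) < min_family:
            continue
        sire_h = h.alleles[idx[sire]]  # (n_markers, 2)
        for animal in offspring:
            i = idx[animal]
            pat, mat = h.alleles[i, :, 0], h.alleles[i, :, 1]
            score_pat = min(
                int((pat != sire_h[:, 0]).sum()), int((pat != sire_h[:, 1]).sum())
            )
            score_mat = min(
                int((mat != sire_h[:, 0]).sum()), int((mat != sire_h[:, 1]).sum())
            )
            if score_mat < score_pat:
                out[i, :, 0], out[i, :, 1] = h.alleles[i, :, 1], h.alleles[i, :, 0]
    return HaplotypeMatrix(h.animals, out, h.markers)
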