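"""Gene-drop simulator for pedigreed populations with a recessive lethal.

The generator emulates the structure that makes haplotype-deficiency scans
work in commercial cattle: a small set of heavily used sires produces large
paternal half-sib families via artificial insemination, a focal founder
haplotype segregates at a few percent and is in complete linkage with a
causal recessive allele, and lethality removes homozygotes either at
conception (insemination failure), at birth (stillbirth) or during the first
year of life — before they could ever be genotyped.

Structure (two bred generations on one or more chromosomes):

* G0: ``n_sires`` founder sires (genotyped) and an unlimited pool of
  unrelated founder dams (ungenotyped, so G1 animals have no maternal
  grandsire on record).
* G1: each sire is mated to fresh founder dams to produce
  ``daughters_per_sire`` cows and ``sons_per_sire`` service bulls.
* G2: every surviving cow enters an insemination campaign; each service
  draws an independent service bull, succeeds with the baseline probability,
  and a failed conception returns the cow to oestrus about three weeks later.
  Calves therefore have a genotyped sire and a genotyped maternal grandsire.

Founder chromosomes are copies of a small pool of ancestral haplotypes, one
of which (the focal haplotype, initial frequency ``q0``) carries the causal
allele; meioses recombine at ``recomb_rate_per_mb`` expected crossovers per
Mb (Poisson counts per marker interval — roughly a 1 cM/Mb genetic map).
All randomness flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import HaplotypeMatrix, MarkerMap, PedigreeTable

EPOCH = pd.Timestamp("2012-01-01")
GESTATION_DAYS = 280

FATE_CONCEIVED_FAILED = "conceived_failed"
FATE_STILLBORN = "stillborn"
FATE_DIED = "died"
FATE_EXPORTED = "exported"
FATE_SURVIVED = "survived"


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_sires: int = 50
    daughters_per_sire: int = 200
    sons_per_sire: int = 4
    n_chrom: int = 1
    chrom_length_mb: float = 20.0
    markers_per_mb: float = 35.0
    n_founder_haplotypes: int = 30
    q0: float = 0.04
    causal_pos_mb: float = 10.0
    lethality: str = "none"  # none | embryonic | perinatal | juvenile
    penetrance: float = 1.0
    baseline_success: float = 0.5
    max_services: int = 4
    baseline_stillbirth: float = 0.02
    baseline_juvenile_mortality: float = 0.03
    juvenile_death_by_365: float = 1.0
    export_rate: float = 0.05
    recomb_rate_per_mb: float = 0.01

    def __post_init__(self) -> None:
        if self.lethality not in ("none", "embryonic", "perinatal", "juvenile"):
            raise ValueError(f"unknown lethality mode: {self.lethality}")
        for name in (
            "q0",
            "penetrance",
            "baseline_success",
            "baseline_stillbirth",
            "baseline_juvenile_mortality",
            "juvenile_death_by_365",
            "export_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.q0 == 0.0 and self.lethality != "none":
            raise ValueError("q0 = 0 with lethality enabled is impossible")
        if not 0 < self.causal_pos_mb < self.chrom_length_mb:
            raise ValueError("causal position outside the chromosome")


@dataclass
class SimTruth:
    """Ground truth: per-conceptus causal diplotype, carrier flag and fate."""

    df: pd.DataFrame  # id, generation, causal_copies, carrier, fate, sire, dam, mgs
    causal_chrom: str
    causal_pos_bp: int
    causal_site_id: str
    panel_causal_alleles: np.ndarray  # (n_panel, 2) causal allele per chromosome
    focal_frequency: float  # realised founder-generation frequency

    def carriers(self) -> set:
        d = self.df
        return set(d.loc[(d["causal_copies"] > 0), "id"])


@dataclass
class SimResult:
    config: SimConfig
    pedigree: PedigreeTable
    haplotypes: HaplotypeMatrix  # genotyped panel (survivors + founder sires)
    inseminations: pd.DataFrame  # bull, cow, cow_sire, date, success
    calvings: pd.DataFrame  # calf, sire, mgs, birth_date, stillborn, exit_date, exit_reason
    truth: SimTruth


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _gametes(
    parent_h: np.ndarray,
    parent_idx: np.ndarray,
    chrom_slices: list,
    pos_mb: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row of ``parent_idx`` (Poisson recombination per interval)."""
    n = len(parent_idx)
    gam = np.empty((n, parent_h.shape[1]), dtype=np.int8)
    sub = parent_h[parent_idx]  # (n, sites, 2)
    for sl in chrom_slices:
        pos = pos_mb[sl]
        crossings = rng.poisson(rate * np.diff(pos), size=(n, len(pos) - 1))
        phase = rng.integers(0, 2, size=(n, 1))
        which = (phase + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(crossings, axis=1)], axis=1
        )) % 2
        gam[:, sl] = np.take_along_axis(sub[:, sl, :], which[:, :, None], axis=2)[:, :, 0]
    return gam


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def simulate_population(cfg: SimConfig) -> SimResult:
    rng = np.random.default_rng(cfg.seed)

    # --- site layout: evenly spaced markers plus the causal pseudo-site -----
    n_mark = int(round(cfg.chrom_length_mb * cfg.markers_per_mb))
    spacing = cfg.chrom_length_mb * 1e6 / n_mark
    marker_rows = []
    site_chrom, site_pos = [], []
    causal_index = None
    causal_pos_bp = int(round(cfg.causal_pos_mb * 1e6)) + 1
    for c in range(1, cfg.n_chrom + 1):
        chrom = str(c)
        pos_bp = (np.arange(n_mark) * spacing + spacing / 2).round().astype(np.int64)
        inserted = False
        for j, p in enumerate(pos_bp):
            if chrom == "1" and not inserted and p > causal_pos_bp:
                causal_index = len(site_chrom)
                site_chrom.append(chrom)
                site_pos.append(causal_pos_bp)
                inserted = True
            site_chrom.append(chrom)
            site_pos.append(int(p))
            marker_rows.append((f"M{chrom}_{j:04d}", chrom, int(p)))
    if causal_index is None:
        raise ValueError("causal position beyond the last marker")
    site_pos = np.asarray(site_pos, dtype=np.float64)
    pos_mb = site_pos / 1e6
    n_sites = len(site_pos)
    marker_mask = np.ones(n_sites, dtype=bool)
    marker_mask[causal_index] = False
    chrom_slices = []
    start = 0
    for c in range(1, cfg.n_chrom + 1):
        count = sum(1 for ch in site_chrom if ch == str(c))
        chrom_slices.append(slice(start, start + count))
        start += count
    mmap = MarkerMap(pd.DataFrame(marker_rows, columns=["marker_id", "chrom", "pos_bp"]))

    # --- founder haplotype pool --------------------------------------------
    K = cfg.n_founder_haplotypes
    marker_freq = rng.uniform(0.15, 0.85, size=n_sites)
    pool = (rng.random((K, n_sites)) < marker_freq).astype(np.int8)
    pool[:, causal_index] = 0
    pool[0, causal_index] = 1  # the focal haplotype carries the causal allele
    weights = np.empty(K)
    weights[0] = cfg.q0
    rest = rng.dirichlet(np.full(K - 1, 5.0))
    weights[1:] = (1.0 - cfg.q0) * rest

    def founder_chromosomes(n: int) -> np.ndarray:
        labels = rng.choice(K, size=(n, 2), p=weights)
        return pool[labels].transpose(0, 2, 1).copy()  # (n, sites, 2)

    # --- containers ---------------------------------------------------------
    truth_rows: list = []  # (id, gen, copies, carrier, fate, sire, dam, mgs)
    ped_rows: list = []  # (animal, sire, dam)

    def _fate_live_animal(copies: np.ndarray) -> tuple:
        """Vectorised post-birth fate draw; returns (fate codes, exit day)."""
        n = len(copies)
        death_day = np.full(n, 10**6)
        base_dead = rng.random(n) < cfg.baseline_juvenile_mortality
        d1 = rng.integers(1, 366, size=n)
        death_day = np.where(base_dead, d1, death_day)
        if cfg.lethality == "juvenile":
            extra = (copies == 2) & (rng.random(n) < cfg.penetrance * cfg.juvenile_death_by_365)
            d2 = rng.integers(30, 366, size=n)
            death_day = np.where(extra, np.minimum(death_day, d2), death_day)
        exported = rng.random(n) < cfg.export_rate
        export_day = rng.integers(1, 366, size=n)
        fate = np.full(n, FATE_SURVIVED, dtype=object)
        day = np.full(n, -1)
        dead = death_day <= 365
        exp = exported & (export_day < death_day)
        fate[dead] = FATE_DIED
        day[dead] = death_day[dead]
        fate[exp] = FATE_EXPORTED
        day[exp] = export_day[exp]
        return fate, day

    # --- G0 sires ------------------------------------------------------------
    sire_ids = [f"S{i:04d}" for i in range(cfg.n_sires)]
    sires_h = founder_chromosomes(cfg.n_sires)
    for sid, cp in zip(sire_ids, sires_h[:, causal_index, :].sum(axis=1)):
        ped_rows.append((sid, None, None))
        truth_rows.append((sid, 0, int(cp), cp > 0, FATE_SURVIVED, None, None, None))

    # --- G1: daughters and service bulls -------------------------------------
    per_sire = cfg.daughters_per_sire + cfg.sons_per_sire
    n_g1 = cfg.n_sires * per_sire
    g1_sire_idx = np.repeat(np.arange(cfg.n_sires), per_sire)
    dams_h = founder_chromosomes(n_g1)
    realised_q = float(
        np.concatenate(
            [sires_h[:, causal_index, :].ravel(), dams_h[:, causal_index, :].ravel()]
        ).mean()
    )
    gam_sire = _gametes(sires_h, g1_sire_idx, chrom_slices, pos_mb, cfg.recomb_rate_per_mb, rng)
    gam_dam = _gametes(dams_h, np.arange(n_g1), chrom_slices, pos_mb, cfg.recomb_rate_per_mb, rng)
    g1_h = np.stack([gam_sire, gam_dam], axis=2)  # chromosome 0 = paternal
    g1_copies = g1_h[:, causal_index, :].sum(axis=1)

    is_son = np.zeros(n_g1, dtype=bool)
    for s in range(cfg.n_sires):
        is_son[s * per_sire : s * per_sire + cfg.sons_per_sire] = True
    g1_ids = np.empty(n_g1, dtype=object)
    g1_ids[is_son] = [f"B{i:04d}" for i in range(int(is_son.sum()))]
    g1_ids[~is_son] = [f"C{i:06d}" for i in range(int((~is_son).sum()))]
    dam_ids = np.array([f"D{i:06d}" for i in range(n_g1)], dtype=object)

    # conception-stage lethality for G1
    g1_alive = np.ones(n_g1, dtype=bool)
    g1_fate = np.full(n_g1, FATE_SURVIVED, dtype=object)
    if cfg.lethality == "embryonic":
        lost = (g1_copies == 2) & (rng.random(n_g1) < cfg.penetrance)
        g1_fate[lost] = FATE_CONCEIVED_FAILED
        g1_alive &= ~lost
    stillborn_p = np.where(
        (cfg.lethality == "perinatal") & (g1_copies == 2),
        cfg.penetrance,
        cfg.baseline_stillbirth,
    )
    sb = g1_alive & (rng.random(n_g1) < stillborn_p)
    g1_fate[sb] = FATE_STILLBORN
    g1_alive &= ~sb
    live_idx = np.flatnonzero(g1_alive)
    fate_live, _ = _fate_live_animal(g1_copies[live_idx])
    g1_fate[live_idx] = fate_live

    for i in range(n_g1):
        if g1_fate[i] == FATE_CONCEIVED_FAILED:
            truth_rows.append(
                (f"E1_{i:06d}", 1, int(g1_copies[i]), g1_copies[i] > 0,
                 FATE_CONCEIVED_FAILED, sire_ids[g1_sire_idx[i]], dam_ids[i], None)
            )
            continue
        ped_rows.append((dam_ids[i], None, None))
        ped_rows.append((g1_ids[i], sire_ids[g1_sire_idx[i]], dam_ids[i]))
        truth_rows.append(
            (g1_ids[i], 1, int(g1_copies[i]), g1_copies[i] > 0, g1_fate[i],
             sire_ids[g1_sire_idx[i]], dam_ids[i], None)
        )

    born = g1_fate != FATE_CONCEIVED_FAILED
    usable = np.isin(g1_fate, [FATE_SURVIVED])
    cow_idx = np.flatnonzero(usable & ~is_son)
    bull_idx = np.flatnonzero(usable & is_son)
    if len(bull_idx) == 0:
        raise ValueError("no surviving service bulls; increase sons_per_sire")

    # --- G2: insemination campaign -------------------------------------------
    n_cows = len(cow_idx)
    insem_rows: list = []
    calf_store: list = []  # (cow position, bull position, conception day, gametes...)
    day = rng.integers(0, 60, size=n_cows)
    active = np.ones(n_cows, dtype=bool)
    calf_h_parts, calf_meta = [], []
    for _service in range(cfg.max_services):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        service_bulls = rng.integers(0, len(bull_idx), size=len(idx))
        conceived = rng.random(len(idx)) < cfg.baseline_success
        conc = np.flatnonzero(conceived)
        gb = _gametes(
            g1_h, bull_idx[service_bulls[conc]], chrom_slices, pos_mb,
            cfg.recomb_rate_per_mb, rng,
        )
        gc = _gametes(
            g1_h, cow_idx[idx[conc]], chrom_slices, pos_mb,
            cfg.recomb_rate_per_mb, rng,
        )
        copies = gb[:, causal_index].astype(np.int16) + gc[:, causal_index]
        success = conceived.copy()
        failed_conception = np.zeros(len(conc), dtype=bool)
        if cfg.lethality == "embryonic":
            failed_conception = (copies == 2) & (rng.random(len(conc)) < cfg.penetrance)
            success[conc[failed_conception]] = False
        for j, k in enumerate(idx):
            ci = cow_idx[k]
            insem_rows.append(
                (
                    g1_ids[bull_idx[service_bulls[j]]],
                    g1_ids[ci],
                    sire_ids[g1_sire_idx[ci]],
                    int(day[k]),
                    int(success[j]),
                )
            )
        for j in np.flatnonzero(failed_conception):
            ci = cow_idx[idx[conc[j]]]
            truth_rows.append(
                (
                    f"E2_{len(truth_rows):06d}", 2, int(copies[j]), copies[j] > 0,
                    FATE_CONCEIVED_FAILED,
                    g1_ids[bull_idx[service_bulls[conc[j]]]], g1_ids[ci],
                    sire_ids[g1_sire_idx[ci]],
                )
            )
        kept = np.flatnonzero(~failed_conception)
        if len(kept):
            calf_h_parts.append(np.stack([gb[kept], gc[kept]], axis=2))
            for j in kept:
                k = idx[conc[j]]
                ci = cow_idx[k]
                calf_meta.append(
                    (
                        g1_ids[bull_idx[service_bulls[conc[j]]]],  # sire
                        g1_ids[ci],  # dam (the cow)
                        sire_ids[g1_sire_idx[ci]],  # maternal grandsire
                        int(day[k]) + GESTATION_DAYS,
                    )
                )
        if len(kept):
            active[idx[conc[kept]]] = False
        day[idx] += rng.integers(18, 25, size=len(idx))

    calvings_rows: list = []
    if calf_h_parts:
        calves_h = np.concatenate(calf_h_parts, axis=0)
    else:
        calves_h = np.empty((0, n_sites, 2), dtype=np.int8)
    n_calves = len(calf_meta)
    calf_ids = np.array([f"K{i:06d}" for i in range(n_calves)], dtype=object)
    calf_copies = calves_h[:, causal_index, :].sum(axis=1) if n_calves else np.empty(0, int)

    stillborn_p = np.where(
        (cfg.lethality == "perinatal") & (calf_copies == 2),
        cfg.penetrance,
        cfg.baseline_stillbirth,
    )
    stillborn = rng.random(n_calves) < stillborn_p
    calf_fate = np.full(n_calves, FATE_SURVIVED, dtype=object)
    exit_day = np.full(n_calves, -1)
    calf_fate[stillborn] = FATE_STILLBORN
    live = np.flatnonzero(~stillborn)
    if len(live):
        fate_live, day_live = _fate_live_animal(calf_copies[live])
        calf_fate[live] = fate_live
        exit_day[live] = day_live

    for i in range(n_calves):
        sire, dam, mgs, birthday = calf_meta[i]
        ped_rows.append((calf_ids[i], sire, dam))
        truth_rows.append(
            (calf_ids[i], 2, int(calf_copies[i]), calf_copies[i] > 0,
             calf_fate[i], sire, dam, mgs)
        )
        if calf_fate[i] == FATE_STILLBORN:
            exit_date, reason = EPOCH + pd.Timedelta(days=birthday), "death"
            sb_flag = 1
        elif calf_fate[i] == FATE_DIED:
            exit_date, reason = EPOCH + pd.Timedelta(days=birthday + int(exit_day[i])), "death"
            sb_flag = 0
        elif calf_fate[i] == FATE_EXPORTED:
            exit_date, reason = EPOCH + pd.Timedelta(days=birthday + int(exit_day[i])), "export"
            sb_flag = 0
        else:
            exit_date, reason = pd.NaT, "none"
            sb_flag = 0
        calvings_rows.append(
            (calf_ids[i], sire, mgs, EPOCH + pd.Timedelta(days=birthday),
             sb_flag, exit_date, reason)
        )

    # --- genotyped panel: founder sires + surviving G1 + surviving calves ----
    panel_ids = list(sire_ids)
    panel_h = [sires_h]
    g1_keep = np.flatnonzero(np.isin(g1_fate, [FATE_SURVIVED]))
    panel_ids += list(g1_ids[g1_keep])
    panel_h.append(g1_h[g1_keep])
    calf_keep = np.flatnonzero(calf_fate == FATE_SURVIVED)
    panel_ids += list(calf_ids[calf_keep])
    if len(calf_keep):
        panel_h.append(calves_h[calf_keep])
    panel = np.concatenate(panel_h, axis=0)

    haplotypes = HaplotypeMatrix(panel_ids, panel[:, marker_mask, :], mmap)
    pedigree = PedigreeTable(pd.DataFrame(ped_rows, columns=["animal", "sire", "dam"]))
    inseminations = pd.DataFrame(
        insem_rows, columns=["bull", "cow", "cow_sire", "date", "success"]
    )
    inseminations["date"] = EPOCH + pd.to_timedelta(inseminations["date"], unit="D")
    calvings = pd.DataFrame(
        calvings_rows,
        columns=["calf", "sire", "mgs", "birth_date", "stillborn", "exit_date", "exit_reason"],
    )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["id", "generation", "causal_copies", "carrier", "fate", "sire", "dam", "mgs"],
    )
    truth = SimTruth(
        df=truth_df,
        causal_chrom="1",
        causal_pos_bp=causal_pos_bp,
        causal_site_id="causal",
        panel_causal_alleles=panel[:, causal_index, :].copy(),
        focal_frequency=realised_q,
    )
    return SimResult(cfg, pedigree, haplotypes, inseminations, calvings, truth)


# ---------------------------------------------------------------------------
# re-sequencing emulation
# ---------------------------------------------------------------------------


def embed_causal_variant(
    result: SimResult,
    ld: float = 1.0,
    het_undercall: float = 0.0,
    n_background: int = 120,
    n_sequenced: int = 145,
    region_halfwidth_bp: int = 1_500_000,
    seed: int | None = None,
):
    """Build a re-sequencing variant table around the causal locus.

    A subset of the genotyped panel is "sequenced": the causal site genotype
    derives from the true causal alleles (decorrelated when ``ld`` < 1 by
    redrawing each chromosome's allele from the population frequency with
    probability 1 - ld), plus ``n_background`` neutral sites with independent
    Hardy-Weinberg genotypes. True heterozygous calls are under-called to
    reference-homozygous with probability ``het_undercall``, emulating
    low-coverage sequencing. Returns (site table, genotype matrix, cohort
    table); genotype rows align with the site table.
    """
    from .variant_prioritize import SequencedCohort

    if not 0.0 <= ld <= 1.0:
        raise ValueError("ld must be in [0, 1]")
    if not 0.0 <= het_undercall <= 1.0:
        raise ValueError("het_undercall must be in [0, 1]")
    rng = np.random.default_rng(result.config.seed + 7919 if seed is None else seed)

    panel_ids = list(result.haplotypes.animals)
    n_panel = len(panel_ids)
    take = min(n_sequenced, n_panel)
    chosen = np.sort(rng.choice(n_panel, size=take, replace=False))
    ids = [panel_ids[i] for i in chosen]

    alleles = result.truth.panel_causal_alleles[chosen].astype(np.int8)
    q_hat = float(result.truth.panel_causal_alleles.mean())
    if ld < 1.0:
        redraw = rng.random(alleles.shape) >= ld
        random_alleles = (rng.random(alleles.shape) < q_hat).astype(np.int8)
        alleles = np.where(redraw, random_alleles, alleles)
    causal_geno = alleles.sum(axis=1).astype(np.int8)

    pos0 = result.truth.causal_pos_bp
    lo, hi = max(1, pos0 - region_halfwidth_bp), pos0 + region_halfwidth_bp
    bg_pos = np.sort(rng.choice(np.arange(lo, hi), size=n_background, replace=False))
    bg_freq = rng.uniform(0.05, 0.5, size=n_background)
    bg_geno = rng.binomial(2, bg_freq[:, None], size=(n_background, take)).astype(np.int8)

    rows = [
        {
            "chrom": result.truth.causal_chrom,
            "pos_bp": int(p),
            "ref": "A",
            "alt": "T",
            "type": "snv",
            "is_causal": False,
        }
        for p in bg_pos
    ]
    geno = np.vstack([bg_geno, causal_geno[None, :]])
    rows.append(
        {
            "chrom": result.truth.causal_chrom,
            "pos_bp": pos0,
            "ref": "A",
            "alt": "T",
            "type": "indel",
            "is_causal": True,
        }
    )
    sites = pd.DataFrame(rows)
    order = np.argsort(sites["pos_bp"].to_numpy(), kind="stable")
    sites = sites.iloc[order].reset_index(drop=True)
    geno = geno[order]

    if het_undercall > 0:
        flip = (geno == 1) & (rng.random(geno.shape) < het_undercall)
        geno = np.where(flip, 0, geno).astype(np.int8)

    truth_carrier = {
        r.id: r.causal_copies > 0 for r in result.truth.df.itertuples()
    }
    cohort = SequencedCohort(
        animals=pd.DataFrame(
            {
                "animal": ids,
                "breed": "sim",
                "carrier": [bool(truth_carrier.get(a, False)) for a in ids],
                "affected": False,
            }
        ),
        genotypes=geno,
    )
    return sites, geno, cohort


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_phased_vcf(h: HaplotypeMatrix, path) -> None:
    """Write phased haplotypes as an uncompressed VCF (GT only, 0|1 coding)."""
    mdf = h.markers.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in h.markers.chroms:
            end = int(mdf.loc[mdf["chrom"] == chrom, "pos_bp"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in h.animals)
            + "\n"
        )
        gt = h.alleles
        for j in range(len(mdf)):
            row = mdf.iloc[j]
            calls = "\t".join(f"{gt[i, j, 0]}|{gt[i, j, 1]}" for i in range(len(h.animals)))
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.marker_id}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_outputs(result: SimResult, directory) -> dict:
    """Write the simulated dataset as plain-text files; returns the path map.

    Re-reading the VCF and pedigree with :mod:`hhdkit.geno_io` reproduces the
    in-memory objects; outputs are byte-identical for a fixed seed.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "phased.vcf"),
        "pedigree": os.path.join(directory, "pedigree.csv"),
        "inseminations": os.path.join(directory, "inseminations.csv"),
        "calvings": os.path.join(directory, "calvings.csv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_phased_vcf(result.haplotypes, paths["vcf"])
    result.pedigree.df.to_csv(paths["pedigree"], index=False)
    ins = result.inseminations.copy()
    ins["date"] = ins["date"].dt.strftime("%Y-%m-%d")
    ins.to_csv(paths["inseminations"], index=False)
    cal = result.calvings.copy()
    for col in ("birth_date", "exit_date"):
        cal[col] = pd.to_datetime(cal[col]).dt.strftime("%Y-%m-%d")
    cal.to_csv(paths["calvings"], index=False)
    result.truth.df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
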