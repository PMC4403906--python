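"""Containers, file I/O, QC cascade and pedigree-derived relations."""

import math

import numpy as np
import pandas as pd
import pytest

import hhdkit as hk
from hhdkit.geno_io import MISSING, hwe_exact_test, write_pedigree

from conftest import make_marker_map


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def test_read_pedigree_links_parents(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("animal,sire,dam\ncalf,bull,cow\nbull,,\ncow,,\n")
    ped = hk.read_pedigree(p)
    assert len(ped) == 3
    assert ped.sire_of("calf") == "bull"
    assert ped.dam_of("calf") == "cow"
    assert ped.sire_of("bull") is None


def test_read_pedigree_rejects_duplicates_and_cycles(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("animal,sire,dam\na,,\na,,\n")
    with pytest.raises(ValueError, match="duplicate"):
        hk.read_pedigree(p)
    p2 = tmp_path / "cyc.csv"
    p2.write_text("animal,sire,dam\nA,B,\nB,A,\n")
    with pytest.raises(ValueError, match="cycle"):
        hk.read_pedigree(p2)


def test_pedigree_roundtrip(neutral_sim, tmp_path):
    path = tmp_path / "ped.csv"
    write_pedigree(neutral_sim.pedigree, path)
    again = hk.read_pedigree(path)
    a = neutral_sim.pedigree.df.fillna("").astype(str)
    b = again.df.fillna("").astype(str)
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def test_maternal_grandsire_rules():
    ped = hk.PedigreeTable(
        pd.DataFrame(
            {
                "animal": ["calf", "dam", "mgs", "orphan"],
                "sire": ["bull", "mgs", None, None],
                "dam": ["dam", None, None, None],
            }
        )
    )
    assert hk.maternal_grandsire(ped, "calf") == "mgs"
    assert hk.maternal_grandsire(ped, "dam") is None  # dam of 'dam' unrecorded
    assert hk.maternal_grandsire(ped, "orphan") is None
    with pytest.raises(KeyError):
        hk.maternal_grandsire(ped, "ghost")


def test_maternal_grandsire_matches_simulator_truth(neutral_sim):
    truth = neutral_sim.truth.df
    calves = truth[truth["generation"] == 2].dropna(subset=["mgs"])
    assert len(calves) > 100
    for row in calves.head(200).itertuples():
        assert hk.maternal_grandsire(neutral_sim.pedigree, row.id) == row.mgs


# ---------------------------------------------------------------------------
# phased VCF reading
# ---------------------------------------------------------------------------


def _write_vcf(path, rows, samples):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1,length=10000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines += rows
    path.write_text("\n".join(lines) + "\n")


def test_read_phased_variants_toy(tmp_path):
    p = tmp_path / "toy.vcf"
    _write_vcf(
        p,
        [
            "1\t100\tm0\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
            "1\t200\tm1\tA\tG\t.\tPASS\t.\tGT\t0|0\t1|0",
            "1\t300\tm2\tA\tG\t.\tPASS\t.\tGT\t1|0\t0|0",
        ],
        ["s1", "s2"],
    )
    mmap, hap = hk.read_phased_variants(p)
    assert len(mmap) == 3 and hap.alleles.shape == (2, 3, 2)
    # first-listed allele is chromosome 0
    assert hap.alleles[0, :, 0].tolist() == [0, 0, 1]
    assert hap.alleles[1, :, 1].tolist() == [1, 0, 0]


def test_read_phased_variants_rejects_unphased(tmp_path):
    p = tmp_path / "bad.vcf"
    _write_vcf(
        p,
        [
            "1\t100\tm0\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
            "1\t200\tm1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|0",
        ],
        ["s1", "s2"],
    )
    with pytest.raises(ValueError, match="unphased.*1:200.*s1"):
        hk.read_phased_variants(p)


def test_vcf_roundtrip_preserves_frequencies(neutral_sim, tmp_path):
    path = tmp_path / "out.vcf"
    hk.write_phased_vcf(neutral_sim.haplotypes, path)
    _, hap = hk.read_phased_variants(path)
    assert hap.animals == list(neutral_sim.haplotypes.animals)
    assert np.array_equal(hap.alleles, neutral_sim.haplotypes.alleles)
    freq_file = hap.alleles.mean(axis=(0, 2))
    freq_mem = neutral_sim.haplotypes.alleles.mean(axis=(0, 2))
    assert np.allclose(freq_file, freq_mem)


# ---------------------------------------------------------------------------
# Mendelian conflicts
# ---------------------------------------------------------------------------


def _brute_force_mendel(g, ped):
    idx = g.animal_index()
    out = np.zeros(len(g.markers), dtype=int)
    for a in g.animals:
        s = ped.sire_of(a) if a in ped else None
        if s is None or s not in idx:
            continue
        for j in range(len(g.markers)):
            gs, go = g.calls[idx[s], j], g.calls[idx[a], j]
            if {gs, go} == {0, 2}:
                out[j] += 1
    return out


def test_mendelian_error_counts_rules(marker_map3):
    ped = hk.PedigreeTable(
        pd.DataFrame({"animal": ["s", "o1", "o2"], "sire": [None, "s", "s"], "dam": [None] * 3})
    )
    calls = np.array([[0, 1, 2], [2, 2, 0], [1, 0, MISSING]])
    g = hk.GenotypeMatrix(["s", "o1", "o2"], calls, marker_map3)
    counts = hk.mendelian_error_counts(g, ped)
    # marker0: sire 0 vs o1 2 -> 1 conflict; marker1: sire het -> none;
    # marker2: sire 2 vs o1 0 conflict, o2 missing ignored
    assert counts.tolist() == [1, 0, 1]


def test_mendelian_error_counts_matches_brute_force():
    rng = np.random.default_rng(42)
    n_a, n_m = 30, 25
    mmap = make_marker_map(n_m)
    animals = [f"a{i}" for i in range(n_a)]
    sires = [None] * 10 + [f"a{i % 10}" for i in range(n_a - 10)]
    ped = hk.PedigreeTable(
        pd.DataFrame({"animal": animals, "sire": sires, "dam": [None] * n_a})
    )
    calls = rng.choice([MISSING, 0, 1, 2], size=(n_a, n_m), p=[0.05, 0.4, 0.3, 0.25])
    g = hk.GenotypeMatrix(animals, calls, mmap)
    assert hk.mendelian_error_counts(g, ped).tolist() == _brute_force_mendel(g, ped).tolist()


# ---------------------------------------------------------------------------
# exact HWE test
# ---------------------------------------------------------------------------


def _hwe_enumeration(n_aa, n_ab, n_bb):
    """Oracle: conditional probability of each het count by direct combinatorics."""
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * n_bb
    def weight(h):
        bb = (nb - h) // 2
        aa = n - h - bb
        if bb < 0 or aa < 0:
            return 0.0
        return math.factorial(n) / (
            math.factorial(aa) * math.factorial(h) * math.factorial(bb)
        ) * 2**h
    hets = [h for h in range(nb % 2, min(nb, 2 * n - nb) + 1, 2)]
    w = {h: weight(h) for h in hets}
    total = sum(w.values())
    p_obs = w[n_ab] / total
    return sum(v for v in w.values() if v / total <= p_obs * (1 + 1e-12)) / total


@pytest.mark.parametrize(
    "counts", [(50, 21, 29), (10, 1, 0), (5, 0, 5), (100, 10, 0), (7, 7, 7), (0, 2, 3)]
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(_hwe_enumeration(*counts), rel=1e-9)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


def _empty_ped():
    return hk.PedigreeTable(pd.DataFrame({"animal": ["x"], "sire": [None], "dam": [None]}))


def test_qc_removes_low_call_rate_and_maf():
    n, m = 100, 42
    mmap = make_marker_map(m)
    rng = np.random.default_rng(0)
    calls = rng.choice([0, 1, 2], size=(n, m), p=[0.49, 0.42, 0.09])
    calls[:6, 0] = MISSING  # marker m0: call rate 0.94 (animals keep 41/42 = 0.976)
    calls[:, 1] = 0
    calls[:2, 1] = 1  # marker m1: MAF 0.01
    g = hk.GenotypeMatrix([f"a{i}" for i in range(n)], calls, mmap)
    out, report = hk.qc_filter(g, _empty_ped())
    assert "m0" not in set(out.markers.df["marker_id"])
    assert "m1" not in set(out.markers.df["marker_id"])
    assert len(out.animals) == n  # no animal falls below the call-rate threshold
    reasons = dict(zip(report["id"], report["reason"]))
    assert reasons["m0"] == "call_rate" and reasons["m1"] == "maf"


def test_qc_clean_matrix_unchanged_and_idempotent():
    rng = np.random.default_rng(1)
    n, m = 120, 8
    mmap = make_marker_map(m)
    f = rng.uniform(0.2, 0.5, m)
    calls = rng.binomial(1, f, size=(n, m)) + rng.binomial(1, f, size=(n, m))
    g = hk.GenotypeMatrix([f"a{i}" for i in range(n)], calls, mmap)
    out, report = hk.qc_filter(g, _empty_ped())
    assert len(report) == 0
    assert np.array_equal(out.calls, g.calls)
    out2, report2 = hk.qc_filter(out, _empty_ped())
    assert len(report2) == 0 and np.array_equal(out2.calls, out.calls)


def test_qc_hwe_exclusion_flags_extreme_excess_het():
    mmap = make_marker_map(2)
    n = 400
    rng = np.random.default_rng(2)
    het_only = np.ones(n, dtype=int)  # every animal heterozygous: extreme HWE violation
    normal = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
    g = hk.GenotypeMatrix(
        [f"a{i}" for i in range(n)], np.stack([het_only, normal], axis=1), mmap
    )
    out, report = hk.qc_filter(g, _empty_ped())
    assert list(out.markers.df["marker_id"]) == ["m1"]
    assert report.iloc[0]["reason"] == "hwe"


def test_qc_all_markers_removed_is_an_error():
    mmap = make_marker_map(1)
    g = hk.GenotypeMatrix(["a", "b"], np.array([[0], [0]]), mmap)  # MAF 0
    with pytest.raises(ValueError, match="all markers removed"):
        hk.qc_filter(g, _empty_ped())


# ---------------------------------------------------------------------------
# half-sib phase correction
# ---------------------------------------------------------------------------


def _family_matrix(n_offspring, n_markers=20, seed=3):
    rng = np.random.default_rng(seed)
    mmap = make_marker_map(n_markers)
    sire = rng.integers(0, 2, size=(n_markers, 2))
    animals = ["sire"] + [f"o{i}" for i in range(n_offspring)]
    alleles = np.zeros((1 + n_offspring, n_markers, 2), dtype=np.int8)
    alleles[0] = sire
    for i in range(n_offspring):
        pat = sire[:, rng.integers(0, 2)]
        mat = rng.integers(0, 2, size=n_markers)
        alleles[1 + i, :, 0] = pat
        alleles[1 + i, :, 1] = mat
    ped = hk.PedigreeTable(
        pd.DataFrame(
            {
                "animal": animals,
                "sire": [None] + ["sire"] * n_offspring,
                "dam": [None] * (1 + n_offspring),
            }
        )
    )
    return hk.HaplotypeMatrix(animals, alleles, mmap), ped


def test_phase_swap_when_maternal_string_is_sire_derived():
    h, ped = _family_matrix(12)
    # corrupt offspring 0: swap its labels so the 'paternal' slot holds the
    # maternal string (which mismatches both sire haplotypes heavily)
    h.alleles[1, :, 0], h.alleles[1, :, 1] = (
        h.alleles[1, :, 1].copy(),
        h.alleles[1, :, 0].copy(),
    )
    before = h.alleles[1].copy()
    fixed = hk.correct_halfsib_phase(h, ped, min_family=10)
    assert np.array_equal(fixed.alleles[1, :, 0], before[:, 1])
    assert np.array_equal(fixed.alleles[1, :, 1], before[:, 0])


def test_phase_consistent_offspring_unchanged():
    h, ped = _family_matrix(12, seed=4)
    fixed = hk.correct_halfsib_phase(h, ped, min_family=10)
    assert np.array_equal(fixed.alleles, h.alleles)


def test_phase_small_family_untouched():
    h, ped = _family_matrix(9, seed=5)
    h.alleles[1, :, 0], h.alleles[1, :, 1] = (
        h.alleles[1, :, 1].copy(),
        h.alleles[1, :, 0].copy(),
    )
    fixed = hk.correct_halfsib_phase(h, ped, min_family=10)
    assert np.array_equal(fixed.alleles, h.alleles)


def test_phase_correction_preserves_genotypes():
    h, ped = _family_matrix(15, seed=6)
    rng = np.random.default_rng(7)
    for i in rng.choice(15, 5, replace=False):
        h.alleles[1 + i, :, 0], h.alleles[1 + i, :, 1] = (
            h.alleles[1 + i, :, 1].copy(),
            h.alleles[1 + i, :, 0].copy(),
        )
    fixed = hk.correct_halfsib_phase(h, ped, min_family=10)
    assert np.array_equal(np.sort(fixed.alleles, axis=2), np.sort(h.alleles, axis=2))
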